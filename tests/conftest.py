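import numpy as np
import pytest

from clampkit.synthetic_data import make_toy_interface

# mirror-symmetric plan used by the pulling-directionality experiments
SYMMETRIC_PLAN = [
    ("salt_bridge", 0.10),
    ("hydrophobic", 0.30),
    ("backbone_hbond", 0.45),
    ("backbone_hbond", 0.55),
    ("hydrophobic", 0.70),
    ("salt_bridge", 0.90),
]


@pytest.fixture(scope="session")
def toy_interface():
    """Default planted-contact interface: (structure, table, spec, ground truth)."""
    return make_toy_interface(seed=0)


@pytest.fixture(scope="session")
def symmetric_interface():
    """Top/bottom mirror-symmetric interface for pulling experiments."""
    return make_toy_interface(contact_plan=SYMMETRIC_PLAN, seed=0)


@pytest.fixture(scope="session")
def tiny_dimer():
    """Two one-residue chains, a handful of atoms, fully parameterized."""
    from clampkit.structure_model import AtomRecord, ParameterizedStructure

    spec = [
        # chain A: a 3-atom polar group
        ("N", "N", "A", 1, (0.0, 0.0, 0.0), -0.4, 1.55, 1.824, 0.17),
        ("H", "H", "A", 1, (-1.0, 0.0, 0.0), 0.3, 1.20, 0.60, 0.0157),
        ("O", "O", "A", 1, (1.2, 0.8, 0.0), -0.5, 1.50, 1.6612, 0.21),
        # chain B: a 3-atom group across a 4 A gap
        ("O", "O", "B", 1, (4.0, 0.0, 0.0), -0.5, 1.50, 1.6612, 0.21),
        ("C", "C", "B", 1, (5.0, 0.8, 0.0), 0.4, 1.70, 1.908, 0.1094),
        ("N", "N", "B", 1, (4.6, -1.2, 0.5), -0.3, 1.55, 1.824, 0.17),
    ]
    atoms = [AtomRecord(atom_id=k + 1, atom_name=n, element=e,
                        residue_index=r, residue_name="XXX", chain_id=c,
                        position=np.array(p), charge=q, gb_radius=rg,
                        vdw_rmin_half=rv, lj_epsilon=eps)
             for k, (n, e, c, r, p, q, rg, rv, eps) in enumerate(spec)]
    return ParameterizedStructure(atoms, title="tiny dimer")
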