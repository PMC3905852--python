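"""Synthetic fixtures: toy interfaces, jitter ensembles, scripted ruptures.

The generators emulate the architecture shared by sliding-clamp subunit
interfaces — an antiparallel strand pair flanked by looser segments —
with planted contacts of each interaction class at chosen heights along
the bottom->top interface axis.  Geometry is idealized (3.5 A strand
rise, 6 A strand separation); only contact geometry matters downstream,
not stereochemical realism.  Everything is deterministic under a fixed
seed.  No attempt is made to mimic real clamp sequences or crystal
structures.

``table1_fixture`` carries the literature reference values for the four
clamp interfaces (PCNA/PCNA and the three checkpoint-clamp interfaces),
used purely for bookkeeping and ratio arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_dynamics import Contact, ContactCriteria, classify_contacts
from .structure_model import (AtomRecord, InterfaceSpec, ParameterTable,
                              ParameterizedStructure)

__all__ = [
    "RuptureScript",
    "ScriptedContact",
    "make_toy_interface",
    "make_jitter_ensemble",
    "make_scripted_rupture",
    "table1_fixture",
    "DEFAULT_CONTACT_PLAN",
]

_RISE = 3.5          # strand rise per residue, A
_GAP = 6.0           # inter-strand axis separation, A

# planted-contact classes and their axis-height targets
DEFAULT_CONTACT_PLAN = [
    ("salt_bridge", 0.10),
    ("backbone_hbond", 0.45),
    ("backbone_hbond", 0.55),
    ("sidechain_hbond", 0.70),
    ("hydrophobic", 0.30),
    ("hydrophobic", 0.90),
    ("polar_proximal", 0.60),
]

_CLASS_RESIDUES = {
    "salt_bridge": ("GLU", "LYS"),
    "backbone_hbond": ("GLY", "GLY"),
    "sidechain_hbond": ("SER", "SER"),
    "hydrophobic": ("LEU", "PHE"),
    "polar_proximal": ("THR", "ASN"),
}

# element -> (gb_radius, vdw_rmin_half, lj_epsilon); charges set per atom
_ELEMENT_PARAMS = {
    "H": (1.20, 0.60, 0.0157),
    "C": (1.70, 1.908, 0.1094),
    "N": (1.55, 1.824, 0.1700),
    "O": (1.50, 1.6612, 0.2100),
}


def _backbone_atoms(x0: float, s: float, z: float):
    """Default backbone pointing away from the interface (sign ``s`` = +1
    for chain A, -1 for chain B)."""
    return [
        ("N", "N", (x0 - 1.2 * s, 0.5, z), -0.45),
        ("H", "H", (x0 - 2.2 * s, 0.5, z), 0.30),
        ("CA", "C", (x0, 0.0, z), 0.05),
        ("C", "C", (x0 - 0.5 * s, -1.0, z + 0.5), 0.55),
        ("O", "O", (x0 - 1.5 * s, -1.6, z + 0.5), -0.55),
    ]


def _sidechain_atoms(kind: str, role: str, x0: float, s: float, z: float):
    """Side-chain atoms for one planted contact residue.

    ``role`` is 'a' (chain A side) or 'b' (chain B side); positions are
    laid out so the designed interaction geometry holds exactly in the
    reference frame.
    """
    mid = x0 + s * _GAP / 2.0  # interface midplane x

    def toward(dist):  # x coordinate ``dist`` A from this chain's axis
        return x0 + s * dist

    if kind == "GLY":
        return []
    if kind == "ALA":
        return [("CB", "C", (toward(-1.0), 1.5, z), 0.10)]
    if kind == "GLU":  # carboxylate presented to the interface
        return [("CB", "C", (toward(0.2), -1.2, z), 0.00),
                ("CG", "C", (toward(0.4), -0.8, z + 0.6), -0.10),
                ("CD", "C", (toward(0.60), 0.5, z), 0.80),
                ("OE1", "O", (toward(1.70), 0.0, z), -0.80),
                ("OE2", "O", (toward(1.20), -1.1, z + 0.3), -0.80)]
    if kind == "LYS":  # ammonium presented to the interface
        return [("CB", "C", (toward(0.2), 0.8, z), 0.05),
                ("CE", "C", (toward(0.70), 0.4, z), 0.25),
                ("NZ", "N", (toward(1.50), 0.0, z), -0.30),
                ("HZ1", "H", (toward(2.50), 0.0, z), 0.35),
                ("HZ2", "H", (toward(1.2), 0.9, z + 0.3), 0.35),
                ("HZ3", "H", (toward(1.2), -0.9, z + 0.3), 0.30)]
    if kind == "SER":
        return [("CB", "C", (toward(0.8), 0.8, z), 0.30),
                ("OG", "O", (toward(1.55), 0.0, z), -0.65),
                ("HG", "H", (toward(2.55) if role == "a" else toward(0.55),
                             0.0, z), 0.45)]
    if kind == "LEU":
        return [("CB", "C", (toward(0.3), 0.9, z), 0.00),
                ("CG", "C", (toward(0.7), 0.3, z + 0.5), 0.05),
                ("CD1", "C", (toward(1.05), 0.0, z), 0.00),
                ("CD2", "C", (toward(0.7), -0.9, z + 0.7), 0.05)]
    if kind == "PHE":
        return [("CB", "C", (toward(0.3), 0.9, z), 0.05),
                ("CG", "C", (toward(0.7), 0.3, z + 0.5), 0.00),
                ("CD1", "C", (toward(1.05), 0.0, z), 0.05),
                ("CD2", "C", (toward(0.7), -0.9, z + 0.7), 0.00)]
    if kind == "THR":
        return [("CB", "C", (toward(0.9), 0.0, z), 0.05),
                ("OG1", "O", (toward(-0.6), 0.8, z), -0.60),
                ("HG1", "H", (toward(-1.3), 1.4, z), 0.45),
                ("CG2", "C", (toward(1.9), 0.0, z), 0.20)]
    if kind == "ASN":
        return [("CB", "C", (toward(0.9), 0.0, z), 0.05),
                ("CG", "C", (toward(0.4), 1.2, z), 0.55),
                ("OD1", "O", (toward(-0.5), 1.8, z), -0.55),
                ("ND2", "N", (toward(0.6), 2.4, z + 0.6), -0.80),
                ("HD21", "H", (toward(0.0), 3.1, z + 0.6), 0.425),
                ("HD22", "H", (toward(1.4), 2.8, z + 0.8), 0.425)]
    raise ValueError(f"no side-chain template for residue {kind!r}")


def _contact_geometry(cls: str, z: float):
    """Override positions for the interface-facing atoms of one planted
    contact so its defining geometry is exact.  Returns
    {(role, atom_name): position} with x measured per chain below."""
    # chain A axis x=0 (s=+1), chain B axis x=_GAP (s=-1); the table stores
    # absolute coordinates for clarity.
    xb = _GAP
    if cls == "backbone_hbond":
        # A carbonyl O ... H-N of B, collinear along x: N-O = 2.9 A
        return {("a", "C"): (0.45, 0.0, z), ("a", "O"): (1.55, 0.0, z),
                ("b", "N"): (xb - 1.55, 0.0, z), ("b", "H"): (xb - 2.55, 0.0, z)}
    if cls == "salt_bridge":
        # GLU OE1 ... NZ of LYS at 2.8 A, HZ1 on the axis
        return {("a", "OE1"): (1.70, 0.0, z),
                ("b", "NZ"): (xb - 1.50, 0.0, z),
                ("b", "HZ1"): (xb - 2.50, 0.0, z),
                ("b", "CE"): (xb - 0.70, 0.4, z)}
    if cls == "sidechain_hbond":
        # SER OG (A, acceptor) ... HG-OG of SER (B, donor) at 2.9 A
        return {("a", "OG"): (1.55, 0.0, z), ("a", "HG"): (0.55, 0.0, z),
                ("b", "OG"): (xb - 1.55, 0.0, z),
                ("b", "HG"): (xb - 2.55, 0.0, z)}
    if cls == "hydrophobic":
        # LEU CD1 ... PHE CD1 at 3.9 A (within vdW contact)
        return {("a", "CD1"): (1.05, 0.0, z), ("b", "CD1"): (xb - 1.05, 0.0, z)}
    if cls == "polar_proximal":
        # THR CG2 ... ASN CB at 3.2 A; polar side-chain atoms point away
        return {("a", "CG2"): (1.9, 0.0, z), ("b", "CB"): (xb - 0.9, 0.0, z)}
    raise ValueError(f"unknown contact class {cls!r}")


def make_toy_interface(n_residues_per_chain: int = 21,
                       contact_plan=None, seed: int = 0):
    """Build a two-chain interface with planted contacts of each class.

    Chains A and B run antiparallel along z; each planned contact's
    residues are placed at the height realizing its target axis fraction
    (within the 1/(n-1) residue granularity).  Returns
    ``(structure, parameter_table, interface_spec, ground_truth)`` where
    ``ground_truth`` lists (residue_a, residue_b, class, axis_target).

    The seed only perturbs non-contact spacer side chains (tiny jitter) so
    regenerated fixtures are bitwise identical per seed.
    """
    plan = DEFAULT_CONTACT_PLAN if contact_plan is None else list(contact_plan)
    if not plan:
        raise ValueError("contact plan must name at least one contact")
    n = n_residues_per_chain
    rng = np.random.default_rng(seed)

    # choose one residue of chain A per planned contact
    used: dict[int, tuple[str, float]] = {}
    for cls, target in plan:
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"axis target {target} outside [0, 1]")
        i = int(round(target * (n - 1)))
        if i in used:
            raise ValueError(
                f"infeasible plan: contacts at axis targets {used[i][1]} and "
                f"{target} collide on residue {i + 1} (chain of {n} residues)")
        used[i] = (cls, target)

    def z_of(i):  # residue slot i = 0..n-1
        return i * _RISE

    atoms: list[AtomRecord] = []
    table = ParameterTable()
    seen_params = set()
    ground_truth = []

    def add_atom(name, element, pos, charge, resname, resid, chain):
        rgb, rmh, eps = _ELEMENT_PARAMS[element]
        atoms.append(AtomRecord(
            atom_id=len(atoms) + 1, atom_name=name, element=element,
            residue_index=resid, residue_name=resname,
            position=np.asarray(pos, dtype=float), chain_id=chain,
            charge=charge, gb_radius=rgb, vdw_rmin_half=rmh, lj_epsilon=eps))
        key = (resname, name)
        if key not in seen_params:
            seen_params.add(key)
            table.add(resname, name, charge, rgb, rmh, eps)

    for chain, x0, s in (("A", 0.0, 1.0), ("B", _GAP, -1.0)):
        for resid in range(1, n + 1):
            # antiparallel: B residue j sits at the height of A residue n+1-j
            slot = (resid - 1) if chain == "A" else (n - resid)
            z = z_of(slot)
            planned = used.get(slot)
            if planned is None:
                resname = "ALA"
                overrides = {}
            else:
                cls, _target = planned
                res_a, res_b = _CLASS_RESIDUES[cls]
                resname = res_a if chain == "A" else res_b
                geo = _contact_geometry(cls, z)
                role = "a" if chain == "A" else "b"
                overrides = {aname: pos for (r, aname), pos in geo.items()
                             if r == role}
            records = (_backbone_atoms(x0, s, z)
                       + _sidechain_atoms(resname, "a" if chain == "A" else "b",
                                          x0, s, z))
            for name, element, pos, charge in records:
                if name in overrides:
                    pos = overrides[name]
                elif resname == "ALA":
                    pos = tuple(np.asarray(pos)
                                + rng.normal(0.0, 0.01, size=3))
                add_atom(name, element, pos, charge, resname, resid, chain)

    structure = ParameterizedStructure(atoms, title="synthetic toy clamp interface")
    spec = InterfaceSpec(subunit_a="A", subunit_b="B",
                         domain_a=(1, n), domain_b=(1, n),
                         top_anchor=(_GAP / 2.0, 0.0, z_of(n - 1)),
                         bottom_anchor=(_GAP / 2.0, 0.0, 0.0))
    for slot, (cls, target) in sorted(used.items()):
        res_a = slot + 1
        res_b = n - slot
        ground_truth.append((("A", res_a), ("B", res_b), cls, target))

    # construction check: every planted contact must be detected as planned
    pairs = {(g[0], g[1]): -2.0 for g in ground_truth}
    built = classify_contacts(structure, pairs, ContactCriteria(), interface=spec)
    by_pair = {(c.residue_a, c.residue_b): c for c in built}
    for res_a, res_b, cls, target in ground_truth:
        c = by_pair[(res_a, res_b)]
        if c.contact_class != cls:
            raise ValueError(f"infeasible plan: {res_a}-{res_b} built as "
                             f"{c.contact_class}, wanted {cls}")
        if abs(c.axis_fraction - target) > 0.05:
            raise ValueError(f"infeasible plan: {res_a}-{res_b} axis fraction "
                             f"{c.axis_fraction:.3f} misses target {target}")
    return structure, table, spec, ground_truth


def make_jitter_ensemble(structure: ParameterizedStructure, sigma: float,
                         n_frames: int, seed: int = 0) -> np.ndarray:
    """Gaussian positional jitter around the reference conformation.

    Frame 0 is the reference itself; frames 1..n-1 add i.i.d. N(0, sigma)
    displacements per coordinate.  Stands in for a sampled MD ensemble.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ref = structure.positions
    frames = np.empty((n_frames, structure.n_atoms, 3))
    frames[0] = ref
    for k in range(1, n_frames):
        frames[k] = ref + rng.normal(0.0, sigma, size=ref.shape)
    return frames


@dataclass(frozen=True)
class ScriptedContact:
    """Rupture schedule for one contact: last occurrence plus optional
    break-and-reform gaps (absent for gap_start <= t < gap_end)."""

    contact: Contact
    last_time: float
    gaps: tuple[tuple[float, float], ...] = ()

    def present_at(self, t: float) -> bool:
        if t > self.last_time:
            return False
        return not any(a <= t < b for a, b in self.gaps)


@dataclass(frozen=True)
class RuptureScript:
    entries: tuple[ScriptedContact, ...]
    frame_spacing: float = 10.0   # ps
    duration: float = 600.0       # ps

    def __post_init__(self):
        for e in self.entries:
            if e.last_time > self.duration:
                raise ValueError(f"{e.contact.name}: last_time {e.last_time} "
                                 "exceeds script duration")
            for a, b in e.gaps:
                if not (a < b <= e.last_time):
                    raise ValueError(f"{e.contact.name}: gap ({a}, {b}) must "
                                     "close before the last occurrence")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_spacing))
        return self.frame_spacing * np.arange(1, n + 1, dtype=float)


def make_scripted_rupture(structure: ParameterizedStructure,
                          script: RuptureScript, seed: int = 0,
                          displacement: float = 8.0,
                          jitter_sigma: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory whose contacts break (and optionally re-form) on schedule.

    While a contact is scripted absent, its chain-B defining atoms (plus
    their hydrogens) are rigidly displaced ``displacement`` A away from
    the interface, putting them well beyond every presence criterion;
    during re-formed stretches the native geometry returns.  All other
    atoms receive only tiny Gaussian jitter, so unrelated contacts stay
    intact.  Returns ``(frames, times)``.
    """
    rng = np.random.default_rng(seed)
    ref = structure.positions
    times = script.times
    frames = np.empty((len(times), structure.n_atoms, 3))
    shift = np.array([displacement, 0.0, 0.0])
    # sanity: one atom may not serve two scripted contacts with conflicting moves
    owner: dict[int, str] = {}
    for e in script.entries:
        b_atoms = set(e.contact.atoms_b)
        for i in e.contact.atoms_b:
            b_atoms.update(e.contact.hydrogens.get(i, ()))
        for i in b_atoms:
            if owner.setdefault(i, e.contact.name) != e.contact.name:
                raise ValueError(f"conflicting displacement for atom {i} "
                                 f"({owner[i]} vs {e.contact.name})")
    for k, t in enumerate(times):
        pos = ref + rng.normal(0.0, jitter_sigma, size=ref.shape)
        for e in script.entries:
            if not e.present_at(t):
                b_atoms = set(e.contact.atoms_b)
                for i in e.contact.atoms_b:
                    b_atoms.update(e.contact.hydrogens.get(i, ()))
                for i in b_atoms:
                    pos[i] = ref[i] + shift
        frames[k] = pos
    return frames, times


# ---------------------------------------------------------------------------
# Literature reference values (clamp interface binding-energy table)
# ---------------------------------------------------------------------------

_TABLE1 = {
    # interface: (mean, std) per component, ratio, BSA (A^2)
    "PCNA/PCNA": {
        "E_ele": (866.04, 46.68), "E_vdw": (-80.65, 5.38),
        "G_nonpolar": (-11.68, 0.42), "G_polar": (-827.27, 46.05),
        "G_sol": (-838.95, 45.83), "G_ele": (38.77, 10.49),
        "G_b": (-53.56, 8.91), "ratio": 1.00, "bsa": 1555.0},
    "Rad9/Hus1": {
        "E_ele": (-479.45, 88.28), "E_vdw": (-98.14, 7.77),
        "G_nonpolar": (-16.58, 0.70), "G_polar": (502.33, 84.81),
        "G_sol": (485.75, 84.34), "G_ele": (22.88, 10.65),
        "G_b": (-91.84, 9.08), "ratio": 1.71, "bsa": 2117.0},
    "Hus1/Rad1": {
        "E_ele": (-38.87, 37.04), "E_vdw": (-92.49, 6.27),
        "G_nonpolar": (-12.62, 0.55), "G_polar": (69.78, 34.50),
        "G_sol": (57.17, 34.42), "G_ele": (30.91, 7.73),
        "G_b": (-74.19, 8.16), "ratio": 1.39, "bsa": 1629.0},
    "Rad9/Rad1": {
        "E_ele": (-584.25, 53.97), "E_vdw": (-80.12, 6.12),
        "G_nonpolar": (-12.84, 0.46), "G_polar": (618.16, 50.82),
        "G_sol": (605.31, 50.74), "G_ele": (33.90, 10.94),
        "G_b": (-59.06, 8.68), "ratio": 1.10, "bsa": 1645.0},
}


def table1_fixture() -> dict:
    """Published per-interface binding-energy components (kcal/mol).

    Literature values, returned verbatim for bookkeeping and ratio
    arithmetic — not computed by this package.  Each interface maps to
    ``{"mean": {...}, "std": {...}, "ratio": float, "bsa": float,
    "source": "literature"}``.
    """
    out = {}
    for name, vals in _TABLE1.items():
        mean = {k: v[0] for k, v in vals.items() if isinstance(v, tuple)}
        std = {k: v[1] for k, v in vals.items() if isinstance(v, tuple)}
        out[name] = {"mean": mean, "std": std, "ratio": vals["ratio"],
                     "bsa": vals["bsa"], "source": "literature"}
    return out
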