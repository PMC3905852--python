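import math

import numpy as np
import pytest

from clampkit.energetics import (COULOMB_CONSTANT, SolvationParams,
                                 binding_components, effective_born_radii,
                                 gb_polar_energy, mm_pair_energy,
                                 nonpolar_energy, sasa, sphere_points)
from clampkit.structure_model import AtomRecord, ParameterizedStructure


def make_atoms(rows):
    """rows: (name, element, chain, pos, charge, gb_r, rmin_half, eps)."""
    atoms = [AtomRecord(atom_id=k + 1, atom_name=n, element=e,
                        residue_index=1, residue_name="XXX", chain_id=c,
                        position=np.array(p, dtype=float), charge=q,
                        gb_radius=rg, vdw_rmin_half=rv, lj_epsilon=eps)
             for k, (n, e, c, p, q, rg, rv, eps) in enumerate(rows)]
    return ParameterizedStructure(atoms)


class TestMMPairEnergy:
    def test_coulomb_closed_form(self):
        # k_e * 0.5 * (-0.5) / 3.320637 = -25.00 kcal/mol exactly
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.5, 1.7, 1.7, 0.0),
                        ("B1", "C", "B", (3.320637, 0, 0), -0.5, 1.7, 1.7, 0.0)])
        e_ele, e_vdw = mm_pair_energy(s, s.chain_mask("A"), s.chain_mask("B"))
        assert e_ele == pytest.approx(-25.00, abs=1e-10)
        assert e_vdw == 0.0

    def test_lj_minimum_equals_minus_epsilon(self):
        # rmin_ij = 3.4, eps_ij = 0.1: the well bottom sits at -eps_ij
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.0, 1.7, 1.7, 0.1),
                        ("B1", "C", "B", (3.4, 0, 0), 0.0, 1.7, 1.7, 0.1)])
        e_ele, e_vdw = mm_pair_energy(s, s.chain_mask("A"), s.chain_mask("B"))
        assert e_ele == 0.0
        assert e_vdw == pytest.approx(-0.1, abs=1e-12)

    def test_distant_neutral_atoms_negligible(self):
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.0, 1.7, 1.7, 0.1),
                        ("B1", "C", "B", (12.5, 0, 0), 0.0, 1.7, 1.7, 0.1)])
        e_ele, e_vdw = mm_pair_energy(s, s.chain_mask("A"), s.chain_mask("B"))
        assert e_ele == 0.0
        assert abs(e_vdw) < 1e-4

    def test_overlapping_groups_error(self, tiny_dimer):
        with pytest.raises(ValueError, match="overlap"):
            mm_pair_energy(tiny_dimer, [0, 1], [1, 2])

    def test_coincident_atoms_error(self):
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.1, 1.7, 1.7, 0.1),
                        ("B1", "C", "B", (0, 0, 0), 0.1, 1.7, 1.7, 0.1)])
        with pytest.raises(ValueError, match="zero distance"):
            mm_pair_energy(s, [0], [1])


class TestGBPolar:
    def test_single_ion_matches_born_equation(self):
        # intrinsic radius 2.09 A -> effective radius 2.00 A after the
        # standard 0.09 A dielectric offset
        s = make_atoms([("I", "N", "A", (0, 0, 0), 1.0, 2.09, 1.8, 0.1)])
        g, radii, terms = gb_polar_energy(s)
        born = -0.5 * (1 - 1 / 78.0) * COULOMB_CONSTANT * 1.0 / 2.0
        assert radii[0] == pytest.approx(2.0, rel=1e-12)
        assert g == pytest.approx(born, rel=1e-6)
        assert g == pytest.approx(-81.95, abs=0.005)

    def test_zero_charges_zero_energy(self, tiny_dimer):
        import dataclasses
        atoms = [dataclasses.replace(a, charge=0.0) for a in tiny_dimer.atoms]
        s = ParameterizedStructure(atoms)
        g, _, terms = gb_polar_energy(s)
        assert g == 0.0
        assert np.all(terms == 0.0)

    def test_isolated_atom_keeps_intrinsic_radius(self):
        # two atoms 60 A apart barely descreen each other
        s = make_atoms([("A1", "O", "A", (0, 0, 0), -0.5, 1.5, 1.66, 0.21),
                        ("B1", "O", "B", (60, 0, 0), -0.5, 1.5, 1.66, 0.21)])
        radii = effective_born_radii(s)
        np.testing.assert_allclose(radii, [1.41, 1.41], atol=1e-4)

    def test_pair_terms_sum_to_total(self, tiny_dimer):
        g, _, terms = gb_polar_energy(tiny_dimer)
        assert terms.sum() == pytest.approx(g, rel=1e-9)

    def test_descreening_shrinks_born_radii_in_dimer(self, tiny_dimer):
        radii = effective_born_radii(tiny_dimer)
        # buried atoms must report larger effective radii than in isolation
        iso = tiny_dimer.gb_radii - 0.09
        assert np.all(radii > iso)


class TestSASA:
    def test_isolated_atom_is_a_sphere(self):
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.0, 1.7, 1.6, 0.1)])
        total, per_atom = sasa(s)
        exact = 4 * math.pi * (1.6 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.01)
        assert per_atom[0] == total

    def test_enclosed_atom_has_zero_area(self):
        # a small atom caged by six large neighbors
        rows = [("C0", "C", "A", (0, 0, 0), 0.0, 1.7, 0.8, 0.1)]
        for k, d in enumerate([(2.2, 0, 0), (-2.2, 0, 0), (0, 2.2, 0),
                               (0, -2.2, 0), (0, 0, 2.2), (0, 0, -2.2)]):
            rows.append((f"C{k+1}", "C", "A", d, 0.0, 1.7, 2.4, 0.1))
        total, per_atom = sasa(make_atoms(rows))
        assert per_atom[0] == 0.0

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_spheres_match_cap_formula(self, d):
        r1, r2, probe = 1.6, 1.9, 1.4
        s = make_atoms([("A1", "C", "A", (0, 0, 0), 0.0, 1.7, r1, 0.1),
                        ("B1", "C", "B", (d, 0, 0), 0.0, 1.7, r2, 0.1)])
        total, _ = sasa(s)
        # closed-form accessible area of two intersecting spheres
        R1, R2 = r1 + probe, r2 + probe
        x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        h1, h2 = R1 - x1, R2 - (d - x1)
        exact = (4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1
                 + 4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2)
        assert total == pytest.approx(exact, rel=0.02)

    def test_point_doubling_converges(self, tiny_dimer):
        t1, _ = sasa(tiny_dimer, SolvationParams(sasa_points=960))
        t2, _ = sasa(tiny_dimer, SolvationParams(sasa_points=1920))
        assert abs(t2 - t1) / t1 < 0.005

    def test_deterministic_at_fixed_points(self, tiny_dimer):
        t1, p1 = sasa(tiny_dimer)
        t2, p2 = sasa(tiny_dimer)
        assert t1 == t2
        np.testing.assert_array_equal(p1, p2)
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestNonpolar:
    @pytest.mark.parametrize("area,expected", [(1000.0, 7.2), (0.0, 0.0),
                                               (100.0, 0.72)])
    def test_gamma_area_plus_b(self, area, expected):
        assert nonpolar_energy(area) == pytest.approx(expected, abs=1e-12)

    def test_negative_area_errors(self):
        with pytest.raises(ValueError):
            nonpolar_energy(-1.0)


class TestBindingComponents:
    def test_non_interacting_limit(self):
        rows = [("A1", "C", "A", (0, 0, 0), 0.0, 1.7, 1.9, 0.1),
                ("A2", "C", "A", (1.5, 0, 0), 0.0, 1.7, 1.9, 0.1),
                ("B1", "C", "B", (55, 0, 0), 0.0, 1.7, 1.9, 0.1),
                ("B2", "C", "B", (56.5, 0, 0), 0.0, 1.7, 1.9, 0.1)]
        comp = binding_components(make_atoms(rows), "A", "B")
        for name, val in comp.as_dict().items():
            assert abs(val) < 0.02, name

    def test_delta_e_ele_equals_cross_term(self, tiny_dimer):
        comp = binding_components(tiny_dimer, "A", "B")
        e_ele, e_vdw = mm_pair_energy(tiny_dimer, tiny_dimer.chain_mask("A"),
                                      tiny_dimer.chain_mask("B"))
        assert comp.E_ele == pytest.approx(e_ele, rel=1e-12)
        assert comp.E_vdw == pytest.approx(e_vdw, rel=1e-12)

    def test_delta_g_polar_matches_three_evaluation_oracle(self, tiny_dimer):
        comp = binding_components(tiny_dimer, "A", "B")
        # oracle: explicit-loop GB on each of the three systems
        def slow_gb(sub):
            radii = effective_born_radii(sub)
            pos, q = sub.positions, sub.charges
            tau = 0.5 * (1 - 1 / 78.0) * COULOMB_CONSTANT
            g = 0.0
            for i in range(sub.n_atoms):
                for j in range(sub.n_atoms):
                    r2 = float(np.sum((pos[i] - pos[j]) ** 2))
                    f = math.sqrt(r2 + radii[i] * radii[j]
                                  * math.exp(-r2 / (4 * radii[i] * radii[j])))
                    g -= tau * q[i] * q[j] / f
            return g

        ma = tiny_dimer.chain_mask("A")
        oracle = (slow_gb(tiny_dimer) - slow_gb(tiny_dimer.subset(ma))
                  - slow_gb(tiny_dimer.subset(~ma)))
        assert comp.G_polar == pytest.approx(oracle, abs=1e-9)

    def test_symmetry_in_part_order(self, tiny_dimer):
        ab = binding_components(tiny_dimer, "A", "B")
        ba = binding_components(tiny_dimer, "B", "A")
        for k, v in ab.as_dict().items():
            assert ba.as_dict()[k] == pytest.approx(v, rel=1e-12, abs=1e-12)

    def test_derived_identities(self, tiny_dimer):
        comp = binding_components(tiny_dimer, "A", "B")
        assert comp.G_sol == pytest.approx(comp.G_polar + comp.G_nonpolar,
                                           abs=1e-9)
        assert comp.G_ele == pytest.approx(comp.E_ele + comp.G_polar, abs=1e-9)
        assert comp.G_total == pytest.approx(
            comp.E_ele + comp.E_vdw + comp.G_sol, abs=1e-9)

    def test_non_partition_errors(self, tiny_dimer):
        with pytest.raises(ValueError, match="partition"):
            binding_components(tiny_dimer, [0, 1], [1, 2])
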