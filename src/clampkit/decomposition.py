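"""Per-residue (1D) and residue-pair (2D) decomposition of the GB binding energy.

The total binding energy dG_b is exactly redistributed over residue pairs
spanning the interface plus a per-residue remainder:

* pair cell (i in A, j in B): cross-residue Coulomb + Lennard-Jones +
  GB pair terms (ordered sum over both (a,b) and (b,a) atom pairs);
* per-residue remainder: the change of intra-subunit GB terms caused by
  Born-radius shifts on complexation (split half/half between the two
  residues owning an atom pair, self terms to the owner), plus the
  nonpolar term attributed per atom via SASA differences times gamma.

Conservation — cells + remainders = dG_b of ``binding_components`` — holds
to numerical round-off on every frame and is enforced in tests.
Significance screening mirrors the field's conventions: a symmetric
threshold on per-residue magnitudes (stabilizing and destabilizing), and a
one-sided threshold keeping only favorable pairs for pair energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .energetics import (COULOMB_CONSTANT, SolvationParams, binding_components,
                         gb_polar_energy, sasa)
from .energetics import _partition_masks
from .structure_model import ParameterizedStructure

__all__ = [
    "PairEnergyMatrix",
    "ResidueContribution",
    "pairwise_decomposition",
    "per_residue_contributions",
    "significance_filter",
]

ResKey = tuple[str, int]


@dataclass
class PairEnergyMatrix:
    """Residue-pair decomposition of the binding energy.

    ``matrix[i, j]`` is the mean interaction energy (kcal/mol) between
    ``residues_a[i]`` and ``residues_b[j]``; ``remainder`` holds each
    residue's non-pairwise share (GB desolvation shift + nonpolar term).
    """

    residues_a: list[ResKey]
    residues_b: list[ResKey]
    matrix: np.ndarray
    remainder: dict[ResKey, float]
    n_frames: int
    total: float  # mean dG_b over the frames used

    def cell(self, res_a: ResKey, res_b: ResKey) -> float:
        return float(self.matrix[self.residues_a.index(res_a),
                                 self.residues_b.index(res_b)])

    def pair_energies(self) -> dict[tuple[ResKey, ResKey], float]:
        return {(ra, rb): float(self.matrix[i, j])
                for i, ra in enumerate(self.residues_a)
                for j, rb in enumerate(self.residues_b)}

    def conservation_error(self) -> float:
        return abs(float(self.matrix.sum()) + sum(self.remainder.values())
                   - self.total)


@dataclass(frozen=True)
class ResidueContribution:
    residue: ResKey
    energy: float
    above_threshold: bool = False


def _residue_index_map(s: ParameterizedStructure, mask: np.ndarray):
    """Ordered residue keys under ``mask`` and a per-atom residue slot array."""
    keys: list[ResKey] = []
    slot = np.full(s.n_atoms, -1, dtype=int)
    index: dict[ResKey, int] = {}
    for i in np.flatnonzero(mask):
        a = s.atoms[i]
        key = (a.chain_id, a.residue_index)
        if key not in index:
            index[key] = len(keys)
            keys.append(key)
        slot[i] = index[key]
    return keys, slot


def _frame_decomposition(s: ParameterizedStructure, ma, mb, params, pos,
                         keys_a, slot_a, keys_b, slot_b):
    """One frame's pair matrix and per-residue remainder (exact ledger)."""
    ia, ib = np.flatnonzero(ma), np.flatnonzero(mb)
    q, rmh, eps = s.charges, s.vdw_rmin_half, s.lj_epsilon
    r = cdist(pos[ia], pos[ib])
    e_ele = COULOMB_CONSTANT / params.eps_solute * (
        q[ia][:, None] * q[ib][None, :] / r)
    rmin = rmh[ia][:, None] + rmh[ib][None, :]
    x6 = (rmin / r) ** 6
    e_vdw = np.sqrt(eps[ia][:, None] * eps[ib][None, :]) * (x6 * x6 - 2.0 * x6)

    _, _, terms_ab = gb_polar_energy(s, params, positions=pos)
    sub_a, sub_b = s.subset(ma), s.subset(mb)
    _, _, terms_a = gb_polar_energy(sub_a, params, positions=pos[ia])
    _, _, terms_b = gb_polar_energy(sub_b, params, positions=pos[ib])

    # cross GB block: ordered sum counts (i,j) and (j,i)
    gb_cross = 2.0 * terms_ab[np.ix_(ia, ib)]

    na, nb = len(keys_a), len(keys_b)
    matrix = np.zeros((na, nb))
    cross = e_ele + e_vdw + gb_cross
    np.add.at(matrix, (slot_a[ia][:, None].repeat(len(ib), 1),
                       slot_b[ib][None, :].repeat(len(ia), 0)), cross)

    # intra-subunit GB shifts, half/half per atom-pair between owning residues
    remainder = {k: 0.0 for k in keys_a + keys_b}
    for idx, keys, slot, terms_iso in ((ia, keys_a, slot_a, terms_a),
                                       (ib, keys_b, slot_b, terms_b)):
        delta = terms_ab[np.ix_(idx, idx)] - terms_iso
        per_atom = 0.5 * (delta.sum(axis=1) + delta.sum(axis=0))
        per_res = np.zeros(len(keys))
        np.add.at(per_res, slot[idx], per_atom)
        for k, val in zip(keys, per_res):
            remainder[k] += float(val)

    # nonpolar: per-atom SASA change x gamma, assigned to the owning residue
    _, sasa_ab = sasa(s, params, positions=pos)
    _, sasa_a = sasa(sub_a, params, positions=pos[ia])
    _, sasa_b = sasa(sub_b, params, positions=pos[ib])
    d_area = np.zeros(s.n_atoms)
    d_area[ia] = sasa_ab[ia] - sasa_a
    d_area[ib] = sasa_ab[ib] - sasa_b
    for idx, keys, slot in ((ia, keys_a, slot_a), (ib, keys_b, slot_b)):
        per_res = np.zeros(len(keys))
        np.add.at(per_res, slot[idx], params.gamma * d_area[idx])
        for k, val in zip(keys, per_res):
            remainder[k] += float(val)
    # b-offset cancels once per part: dG_np picks up -b_offset overall
    if params.b_offset:
        remainder[keys_a[0]] -= params.b_offset
    return matrix, remainder


def pairwise_decomposition(complex_s: ParameterizedStructure, part_a, part_b,
                           params: SolvationParams = SolvationParams(),
                           frames: np.ndarray | None = None) -> PairEnergyMatrix:
    """2D decomposition of the binding energy, averaged over frames.

    ``frames`` defaults to the structure's own coordinates (single frame).
    """
    if not complex_s.is_parameterized():
        raise ValueError("structure is not fully parameterized")
    ma, mb = _partition_masks(complex_s, part_a, part_b)
    if frames is None:
        frames = complex_s.positions[None, :, :]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    keys_a, slot_a = _residue_index_map(complex_s, ma)
    keys_b, slot_b = _residue_index_map(complex_s, mb)

    acc_matrix = np.zeros((len(keys_a), len(keys_b)))
    acc_rem = {k: 0.0 for k in keys_a + keys_b}
    acc_total = 0.0
    for pos in frames:
        m, rem = _frame_decomposition(complex_s, ma, mb, params, pos,
                                      keys_a, slot_a, keys_b, slot_b)
        acc_matrix += m
        for k, v in rem.items():
            acc_rem[k] += v
        acc_total += binding_components(complex_s, ma, mb, params,
                                        positions=pos).G_total
    n = len(frames)
    return PairEnergyMatrix(residues_a=keys_a, residues_b=keys_b,
                            matrix=acc_matrix / n,
                            remainder={k: v / n for k, v in acc_rem.items()},
                            n_frames=n, total=acc_total / n)


def per_residue_contributions(m: PairEnergyMatrix,
                              threshold: float | None = None
                              ) -> list[ResidueContribution]:
    """Fold the pair matrix to per-residue (1D) contributions.

    Each pair cell is split half/half between its two residues; each
    residue adds its own remainder.  Contributions over both subunits sum
    to the total binding energy.
    """
    out = []
    row_half = 0.5 * m.matrix.sum(axis=1)
    col_half = 0.5 * m.matrix.sum(axis=0)
    for keys, halves in ((m.residues_a, row_half), (m.residues_b, col_half)):
        for key, h in zip(keys, halves):
            e = float(h) + m.remainder.get(key, 0.0)
            flag = bool(threshold is not None and abs(e) >= threshold)
            out.append(ResidueContribution(residue=key, energy=e,
                                           above_threshold=flag))
    return out


def significance_filter(values, mode: str, threshold: float):
    """Select significant entries from a residue or pair energy mapping.

    ``threshold`` is a positive magnitude.  Residue mode keeps entries with
    |E| >= threshold (both stabilizing and destabilizing); pair mode keeps
    only favorable pairs with E <= -threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be a positive magnitude")
    if mode not in ("residue", "pair"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if isinstance(values, dict):
        items = values.items()
        if mode == "residue":
            return {k: v for k, v in items if abs(v) >= threshold}
        return {k: v for k, v in items if v <= -threshold}
    if mode == "residue":
        return [v for v in values if abs(v) >= threshold]
    return [v for v in values if v <= -threshold]
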