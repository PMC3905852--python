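"""Single-frame MM/GBSA energy terms and interface differences.

The binding energy of a two-subunit interface is evaluated end-point
style:

    dG_b = dE_ele + dE_vdw + dG_polar + dG_nonpolar

with gas-phase molecular-mechanics electrostatics and Lennard-Jones
terms, a Generalized Born polar solvation term (OBC-II effective radii
over HCT pairwise descreening) and a SASA-proportional nonpolar term
(gamma * A + b).  Entropy is deliberately excluded, so totals are
comparative binding energies, not free energies.

All differences use the single-trajectory convention: the isolated
subunits are evaluated at the complex's coordinates, so gas-phase terms
reduce exactly to cross-group sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_model import ParameterizedStructure

__all__ = [
    "COULOMB_CONSTANT",
    "SolvationParams",
    "EnergyComponents",
    "mm_pair_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "sphere_points",
    "sasa",
    "nonpolar_energy",
    "binding_components",
]

#: Coulomb's constant in kcal * Angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.0637

# OBC-II rescaling constants and the common dielectric-offset convention.
_OBC_ALPHA, _OBC_BETA, _OBC_GAMMA = 1.0, 0.8, 4.85
_GB_OFFSET = 0.09  # Angstrom

# HCT descreening scale factors by element.
_HCT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96, "P": 0.86}
_HCT_SCREEN_DEFAULT = 0.80


@dataclass(frozen=True)
class SolvationParams:
    """Implicit-solvent settings.

    gamma and b_offset define the nonpolar term gamma*SASA + b
    (0.0072 kcal/mol/A^2 and 0); the probe radius is 1.4 A; solute and
    solvent dielectrics are 1.0 and 78.0; sasa_points controls the
    Shrake-Rupley sphere sampling density.
    """

    gamma: float = 0.0072
    b_offset: float = 0.0
    probe_radius: float = 1.4
    eps_solute: float = 1.0
    eps_solvent: float = 78.0
    sasa_points: int = 960

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if not (self.eps_solvent > self.eps_solute >= 1.0):
            raise ValueError("need eps_solvent > eps_solute >= 1")
        if self.sasa_points < 60:
            raise ValueError("sasa_points must be >= 60")


@dataclass(frozen=True)
class EnergyComponents:
    """One frame's (or one ensemble mean's) energy ledger, kcal/mol."""

    E_ele: float
    E_vdw: float
    G_polar: float
    G_nonpolar: float

    @property
    def G_sol(self) -> float:
        return self.G_polar + self.G_nonpolar

    @property
    def G_ele(self) -> float:
        return self.E_ele + self.G_polar

    @property
    def G_total(self) -> float:
        return self.E_ele + self.E_vdw + self.G_sol

    def as_dict(self) -> dict[str, float]:
        return {"E_ele": self.E_ele, "E_vdw": self.E_vdw,
                "G_polar": self.G_polar, "G_nonpolar": self.G_nonpolar,
                "G_sol": self.G_sol, "G_ele": self.G_ele,
                "G_total": self.G_total}

    FIELDS = ("E_ele", "E_vdw", "G_polar", "G_nonpolar", "G_sol", "G_ele", "G_total")


def _as_index(selection, n: int) -> np.ndarray:
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValueError("boolean selection has wrong length")
        return np.flatnonzero(sel)
    return sel.astype(int)


def mm_pair_energy(s: ParameterizedStructure, group_a, group_b,
                   params: SolvationParams = SolvationParams(),
                   positions: np.ndarray | None = None) -> tuple[float, float]:
    """Gas-phase cross-group Coulomb and Lennard-Jones energies.

    E_ele = sum k_e q_i q_j / (eps_solute r_ij); E_vdw uses the 12-6 form
    eps_ij [ (rmin_ij/r)^12 - 2 (rmin_ij/r)^6 ] with rmin_ij the sum of
    the half-rmins and eps_ij the geometric mean.  No distance cutoff.
    """
    n = s.n_atoms
    ia, ib = _as_index(group_a, n), _as_index(group_b, n)
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom groups overlap")
    if not s.is_parameterized():
        raise ValueError("structure is not fully parameterized")
    pos = s.positions if positions is None else np.asarray(positions, dtype=float)
    r = cdist(pos[ia], pos[ib])
    if np.any(r == 0.0):
        i, j = np.argwhere(r == 0.0)[0]
        raise ValueError(f"zero distance between atoms "
                         f"{s.atoms[ia[i]].atom_id} and {s.atoms[ib[j]].atom_id}")
    q = s.charges
    e_ele = COULOMB_CONSTANT / params.eps_solute * float(
        (q[ia][:, None] * q[ib][None, :] / r).sum())
    rmh, eps = s.vdw_rmin_half, s.lj_epsilon
    rmin = rmh[ia][:, None] + rmh[ib][None, :]
    eps_ij = np.sqrt(eps[ia][:, None] * eps[ib][None, :])
    x6 = (rmin / r) ** 6
    e_vdw = float((eps_ij * (x6 * x6 - 2.0 * x6)).sum())
    return e_ele, e_vdw


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def effective_born_radii(s: ParameterizedStructure,
                         positions: np.ndarray | None = None) -> np.ndarray:
    """Per-atom effective Born radii (HCT descreening + OBC-II rescaling)."""
    rho = s.gb_radii
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise ValueError("all atoms need a positive gb_radius")
    pos = s.positions if positions is None else np.asarray(positions, dtype=float)
    n = len(rho)
    rho_t = rho - _GB_OFFSET  # offset-reduced intrinsic radii
    screen = np.array([_HCT_SCREEN.get(a.element, _HCT_SCREEN_DEFAULT)
                       for a in s.atoms])
    if n == 1:
        return rho_t.copy()
    r = cdist(pos, pos)
    s_j = (screen * rho_t)[None, :]          # descreening radius of atom j
    or_i = rho_t[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.maximum(or_i, np.abs(r - s_j))
        U = r + s_j
        I = 0.5 * (1.0 / L - 1.0 / U
                   + 0.25 * (r - s_j ** 2 / r) * (1.0 / U ** 2 - 1.0 / L ** 2)
                   + 0.5 * np.log(L / U) / r)
        # atom i lies inside the descreening sphere of j
        inside = s_j - r > or_i
        I = np.where(inside, I + (1.0 / or_i - 1.0 / L), I)
        # no contribution when the sphere of j is buried inside atom i
        I = np.where(r + s_j <= or_i, 0.0, I)
    np.fill_diagonal(I, 0.0)
    Ii = I.sum(axis=1)
    psi = Ii * rho_t
    inv_R = 1.0 / rho_t - np.tanh(_OBC_ALPHA * psi - _OBC_BETA * psi ** 2
                                  + _OBC_GAMMA * psi ** 3) / rho
    if np.any(inv_R <= 0):
        raise ValueError("non-positive effective Born radius encountered")
    return 1.0 / inv_R


def gb_polar_energy(s: ParameterizedStructure,
                    params: SolvationParams = SolvationParams(),
                    positions: np.ndarray | None = None,
                    born_radii: np.ndarray | None = None):
    """GB polar solvation energy with its per-pair decomposition.

    Returns ``(G_polar, born_radii, pair_terms)`` where ``pair_terms`` is
    the full ordered n x n matrix (diagonal = Born self terms) whose sum
    is exactly G_polar:

        G = -1/2 (1/eps_in - 1/eps_out) k_e  sum_ij q_i q_j / f_GB(r_ij)
        f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))
    """
    pos = s.positions if positions is None else np.asarray(positions, dtype=float)
    R = effective_born_radii(s, pos) if born_radii is None else np.asarray(born_radii, dtype=float)
    q = s.charges
    if np.any(~np.isfinite(q)):
        raise ValueError("structure is not fully parameterized (charges)")
    tau = 0.5 * (1.0 / params.eps_solute - 1.0 / params.eps_solvent) * COULOMB_CONSTANT
    r2 = cdist(pos, pos) ** 2
    RiRj = R[:, None] * R[None, :]
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    pair_terms = -tau * (q[:, None] * q[None, :]) / f
    return float(pair_terms.sum()), R, pair_terms


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(s: ParameterizedStructure,
         params: SolvationParams = SolvationParams(),
         positions: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area, total and per atom.

    Atom radii are vdw_rmin_half + probe_radius.  The fixed spiral point
    set makes results bit-for-bit reproducible at a given sasa_points.
    """
    radii = s.vdw_rmin_half
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need a positive vdw_rmin_half for SASA")
    pos = s.positions if positions is None else np.asarray(positions, dtype=float)
    n = s.n_atoms
    ext = radii + params.probe_radius
    pts = sphere_points(params.sasa_points)
    per_atom = np.zeros(n)
    d = cdist(pos, pos)
    for i in range(n):
        neighbors = np.flatnonzero((d[i] < ext[i] + ext) & (np.arange(n) != i))
        surf = pos[i] + ext[i] * pts
        if neighbors.size:
            dd = cdist(surf, pos[neighbors])
            buried = (dd < ext[neighbors][None, :]).any(axis=1)
            acc = int((~buried).sum())
        else:
            acc = params.sasa_points
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * acc / params.sasa_points
    return float(per_atom.sum()), per_atom


def nonpolar_energy(area: float, params: SolvationParams = SolvationParams()) -> float:
    """Nonpolar solvation term gamma * SASA + b."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return params.gamma * area + params.b_offset


# ---------------------------------------------------------------------------
# Interface differences
# ---------------------------------------------------------------------------

def _partition_masks(s: ParameterizedStructure, part_a, part_b):
    n = s.n_atoms
    def to_mask(part):
        if isinstance(part, str) or (isinstance(part, (list, tuple))
                                     and part and isinstance(part[0], str)):
            return s.chain_mask(part)
        arr = np.asarray(part)
        if arr.dtype == bool:
            return arr
        mask = np.zeros(n, dtype=bool)
        mask[arr.astype(int)] = True
        return mask
    ma, mb = to_mask(part_a), to_mask(part_b)
    if np.any(ma & mb) or not np.all(ma | mb):
        raise ValueError("part_a and part_b must partition the complex's atoms")
    return ma, mb


def binding_components(complex_s: ParameterizedStructure, part_a, part_b,
                       params: SolvationParams = SolvationParams(),
                       positions: np.ndarray | None = None) -> EnergyComponents:
    """Interface energy differences dX = X(AB) - X(A) - X(B).

    Parts are evaluated at the complex's coordinates (single-trajectory
    convention), so the gas-phase terms are computed directly as
    cross-group sums; GB and SASA require the three separate evaluations
    because Born radii and burial change on dissociation.
    """
    ma, mb = _partition_masks(complex_s, part_a, part_b)
    pos = complex_s.positions if positions is None else np.asarray(positions, dtype=float)
    d_ele, d_vdw = mm_pair_energy(complex_s, ma, mb, params, positions=pos)

    g_ab, _, _ = gb_polar_energy(complex_s, params, positions=pos)
    sub_a, sub_b = complex_s.subset(ma), complex_s.subset(mb)
    g_a, _, _ = gb_polar_energy(sub_a, params, positions=pos[ma])
    g_b, _, _ = gb_polar_energy(sub_b, params, positions=pos[mb])
    d_polar = g_ab - g_a - g_b

    a_ab, _ = sasa(complex_s, params, positions=pos)
    a_a, _ = sasa(sub_a, params, positions=pos[ma])
    a_b, _ = sasa(sub_b, params, positions=pos[mb])
    d_np = (nonpolar_energy(a_ab, params) - nonpolar_energy(a_a, params)
            - nonpolar_energy(a_b, params))
    return EnergyComponents(E_ele=d_ele, E_vdw=d_vdw, G_polar=d_polar,
                            G_nonpolar=d_np)
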