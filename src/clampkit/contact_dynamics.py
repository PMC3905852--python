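"""Interface contact classification, rupture timelines and opening pathways.

Significant residue pairs from the pairwise energy decomposition are
classified by interaction type (salt bridge, backbone/side-chain hydrogen
bond, hydrophobic, or generic polar proximity), then tracked frame by
frame along pulling trajectories.  A contact's break-up time is the time
of its last occurrence, which tolerates transient breaking and re-forming.
Runs whose interface substantially re-forms after the initial opening are
screened out, and the remaining runs are classified as top-down,
bottom-up, or concerted by comparing mean break-up times of contacts in
the top and bottom halves of the interface axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .structure_model import InterfaceSpec, ParameterizedStructure, axis_fraction

__all__ = [
    "ContactCriteria",
    "Contact",
    "ContactTimeline",
    "PullingRun",
    "NEVER_FORMED",
    "UNBROKEN",
    "classify_contacts",
    "contact_present",
    "build_timelines",
    "breakup_time",
    "reformation_screen",
    "classify_pathway",
    "breakup_map",
]

NEVER_FORMED = "never_formed"
UNBROKEN = "unbroken"

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
_ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
          "HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for contact presence.

    Hydrogen bonds: donor-acceptor heavy-atom distance <= 3.3 A and, when
    hydrogens are available, a D-H...A deviation from linearity <= 50 deg.
    Hydrophobic/polar contacts: heavy atoms within the sum of vdW radii
    plus ``vdw_slack``.
    """

    hbond_heavy_cutoff: float = 3.3
    hbond_angle_cutoff: float = 50.0
    vdw_slack: float = 0.5

    def __post_init__(self):
        if self.hbond_heavy_cutoff <= 0 or self.vdw_slack <= 0:
            raise ValueError("cutoffs must be > 0")
        if not (0 < self.hbond_angle_cutoff <= 90):
            raise ValueError("angle cutoff must be in (0, 90] degrees")


@dataclass(frozen=True)
class Contact:
    """One classified residue-residue interface contact.

    ``atoms_a``/``atoms_b`` are the defining heavy-atom indices on each
    side; ``hydrogens`` maps a donor heavy-atom index to its attached
    hydrogen indices (used by the angle test).
    """

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    contact_class: str
    atoms_a: tuple[int, ...]
    atoms_b: tuple[int, ...]
    hydrogens: dict = field(default_factory=dict, hash=False, compare=False)
    axis_fraction: float = 0.5
    pair_energy: float = 0.0

    @property
    def name(self) -> str:
        return (f"{self.residue_a[0]}{self.residue_a[1]}-"
                f"{self.residue_b[0]}{self.residue_b[1]}")


@dataclass
class ContactTimeline:
    contact: Contact
    times: np.ndarray       # ps
    present: np.ndarray     # bool per frame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.times.shape != self.present.shape or self.times.size == 0:
            raise ValueError("times and presence must be equal-length, non-empty")


@dataclass
class PullingRun:
    """One pulling trajectory's contact timelines plus protocol metadata."""

    timelines: list[ContactTimeline]
    protocol: dict = field(default_factory=dict)
    pathway_label: str | None = None

    @property
    def times(self) -> np.ndarray:
        return self.timelines[0].times

    def presence_matrix(self) -> np.ndarray:
        return np.array([tl.present for tl in self.timelines], dtype=bool)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _residue_atoms(s: ParameterizedStructure, key):
    idx = s.atoms_of(*key)
    if not idx:
        raise ValueError(f"residue {key} not found in structure")
    return idx


def _attached_hydrogens(s: ParameterizedStructure, heavy: int) -> tuple[int, ...]:
    pos = s.atoms[heavy].position
    out = []
    for i in s.atoms_of(s.atoms[heavy].chain_id, s.atoms[heavy].residue_index):
        a = s.atoms[i]
        if a.is_hydrogen and np.linalg.norm(a.position - pos) < 1.3:
            out.append(i)
    return tuple(out)


def _polar_heavy(s, idx, backbone=None, sidechain_only=False):
    out = []
    for i in idx:
        a = s.atoms[i]
        if a.element not in ("N", "O", "S"):
            continue
        if sidechain_only and a.is_backbone:
            continue
        if backbone is not None and a.is_backbone != backbone:
            continue
        out.append(i)
    return out


def _named_atoms(s, idx, names):
    return [i for i in idx if s.atoms[i].atom_name in names]


def _min_cross_distance(s, ia, ib):
    if not ia or not ib:
        return np.inf
    pa = np.array([s.atoms[i].position for i in ia])
    pb = np.array([s.atoms[i].position for i in ib])
    return float(cdist(pa, pb).min())


def classify_contacts(s: ParameterizedStructure, significant_pairs,
                      criteria: ContactCriteria = ContactCriteria(),
                      interface: InterfaceSpec | None = None) -> list[Contact]:
    """Assign a contact class to each significant residue pair.

    ``significant_pairs`` maps ((chain_a, res_a), (chain_b, res_b)) to the
    pair energy (kcal/mol), as produced by the pair-mode significance
    filter.  Precedence: salt bridge > backbone H-bond > side-chain
    H-bond > hydrophobic > polar proximity (fallback).
    """
    if isinstance(significant_pairs, dict):
        pairs = list(significant_pairs.items())
    else:
        pairs = [(p, 0.0) for p in significant_pairs]
    contacts = []
    for (key_a, key_b), energy in pairs:
        if key_a[0] == key_b[0]:
            raise ValueError(f"contact {key_a}-{key_b} is within one subunit")
        idx_a, idx_b = _residue_atoms(s, key_a), _residue_atoms(s, key_b)
        name_a = s.atoms[idx_a[0]].residue_name
        name_b = s.atoms[idx_b[0]].residue_name
        cut = criteria.hbond_heavy_cutoff

        cls, sel_a, sel_b = None, None, None
        # salt bridge: acidic carboxylate O vs basic side-chain N
        for acid_idx, acid_name, base_idx, base_name in (
                (idx_a, name_a, idx_b, name_b), (idx_b, name_b, idx_a, name_a)):
            if acid_name in _ACIDIC and base_name in _BASIC:
                o_atoms = _named_atoms(s, acid_idx, _ACIDIC[acid_name])
                n_atoms = _named_atoms(s, base_idx, _BASIC[base_name])
                if _min_cross_distance(s, o_atoms, n_atoms) <= cut:
                    cls = "salt_bridge"
                    sel_a, sel_b = ((o_atoms, n_atoms) if acid_idx is idx_a
                                    else (n_atoms, o_atoms))
                    break
        if cls is None:  # backbone H-bond: both partners backbone N/O
            bb_a = _polar_heavy(s, idx_a, backbone=True)
            bb_b = _polar_heavy(s, idx_b, backbone=True)
            if _min_cross_distance(s, bb_a, bb_b) <= cut:
                cls, sel_a, sel_b = "backbone_hbond", bb_a, bb_b
        if cls is None:  # side-chain H-bond: any donor/acceptor pair
            po_a, po_b = _polar_heavy(s, idx_a), _polar_heavy(s, idx_b)
            if _min_cross_distance(s, po_a, po_b) <= cut:
                cls, sel_a, sel_b = "sidechain_hbond", po_a, po_b
        if cls is None and (name_a in HYDROPHOBIC_RESIDUES
                            and name_b in HYDROPHOBIC_RESIDUES):
            sc_a = [i for i in idx_a if not s.atoms[i].is_hydrogen
                    and not s.atoms[i].is_backbone]
            sc_b = [i for i in idx_b if not s.atoms[i].is_hydrogen
                    and not s.atoms[i].is_backbone]
            if sc_a and sc_b:
                cls, sel_a, sel_b = "hydrophobic", sc_a, sc_b
        if cls is None:  # generic polar-proximity fallback
            cls = "polar_proximal"
            sel_a = [i for i in idx_a if not s.atoms[i].is_hydrogen]
            sel_b = [i for i in idx_b if not s.atoms[i].is_hydrogen]

        hydrogens = {}
        if cls in ("salt_bridge", "backbone_hbond", "sidechain_hbond"):
            for i in list(sel_a) + list(sel_b):
                hs = _attached_hydrogens(s, i)
                if hs:
                    hydrogens[i] = hs
        centroid = np.mean([s.atoms[i].position
                            for i in list(sel_a) + list(sel_b)], axis=0)
        frac = axis_fraction(interface, centroid) if interface is not None else 0.5
        contacts.append(Contact(residue_a=key_a, residue_b=key_b,
                                contact_class=cls,
                                atoms_a=tuple(sel_a), atoms_b=tuple(sel_b),
                                hydrogens=hydrogens,
                                axis_fraction=frac, pair_energy=float(energy)))
    return contacts


# ---------------------------------------------------------------------------
# Presence and timelines
# ---------------------------------------------------------------------------

def _hbond_pair_ok(pos, contact, i, j, criteria):
    d = float(np.linalg.norm(pos[i] - pos[j]))
    if d > criteria.hbond_heavy_cutoff:
        return False
    # angle test on whichever side donates (has attached hydrogens);
    # skipped entirely when no hydrogens are recorded (heavy-atom-only input)
    any_hydrogens = False
    for donor, acceptor in ((i, j), (j, i)):
        for h in contact.hydrogens.get(donor, ()):
            any_hydrogens = True
            dh = pos[donor] - pos[h]
            ah = pos[acceptor] - pos[h]
            cosang = float(dh @ ah / (np.linalg.norm(dh) * np.linalg.norm(ah)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            # D-H...A angle >= 180 - cutoff (deviation from linearity)
            if angle >= 180.0 - criteria.hbond_angle_cutoff:
                return True
    return not any_hydrogens  # distance-only when no hydrogens exist


def contact_present(s: ParameterizedStructure, positions: np.ndarray,
                    contact: Contact,
                    criteria: ContactCriteria = ContactCriteria()) -> bool:
    """Is the contact satisfied in this frame's coordinates?"""
    pos = np.asarray(positions, dtype=float)
    for i in contact.atoms_a + contact.atoms_b:
        if i >= len(pos):
            raise ValueError(f"contact {contact.name}: atom index {i} "
                             "missing from frame")
    if contact.contact_class in ("salt_bridge", "backbone_hbond",
                                 "sidechain_hbond"):
        return any(_hbond_pair_ok(pos, contact, i, j, criteria)
                   for i in contact.atoms_a for j in contact.atoms_b)
    radii = s.vdw_rmin_half
    for i in contact.atoms_a:
        for j in contact.atoms_b:
            cutoff = radii[i] + radii[j] + criteria.vdw_slack
            if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                return True
    return False


def build_timelines(s: ParameterizedStructure, frames: np.ndarray,
                    times: np.ndarray, contacts: list[Contact],
                    criteria: ContactCriteria = ContactCriteria()
                    ) -> list[ContactTimeline]:
    """Evaluate every contact's presence in every frame."""
    frames = np.asarray(frames, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(frames) != len(times):
        raise ValueError("frames and times differ in length")
    out = []
    for c in contacts:
        present = np.array([contact_present(s, f, c, criteria) for f in frames])
        out.append(ContactTimeline(contact=c, times=times, present=present))
    return out


def breakup_time(tl: ContactTimeline):
    """Time of last occurrence; NEVER_FORMED / (time, UNBROKEN) at the edges."""
    idx = np.flatnonzero(tl.present)
    if idx.size == 0:
        return NEVER_FORMED
    t_last = float(tl.times[idx[-1]])
    if idx[-1] == len(tl.present) - 1:
        return (t_last, UNBROKEN)
    return t_last


def _breakup_value(tl: ContactTimeline):
    """Break-up time as a float, UNBROKEN counted at trajectory end."""
    b = breakup_time(tl)
    if b == NEVER_FORMED:
        return None
    if isinstance(b, tuple):
        return float(tl.times[-1])
    return float(b)


# ---------------------------------------------------------------------------
# Run screening and pathway classification
# ---------------------------------------------------------------------------

def reformation_screen(run: PullingRun, reform_fraction: float = 0.30,
                       window: float = 500.0) -> str:
    """Flag runs whose interface substantially re-forms after opening.

    Opening = first frame where >= 80% of contacts are simultaneously
    absent.  If afterwards >= ``reform_fraction`` of contacts are again
    simultaneously present for a stretch of at least ``window`` ps, the
    run is labelled ``excluded_reforming``; otherwise ``retained``.
    """
    presence = run.presence_matrix()
    if presence.size == 0:
        raise ValueError("run has no timelines/frames")
    n_contacts = presence.shape[0]
    frac_present = presence.sum(axis=0) / n_contacts
    opened = np.flatnonzero(frac_present <= 0.2)
    if opened.size == 0:
        return "retained"
    t_open = opened[0]
    times = run.times
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    reformed = frac_present[t_open:] >= reform_fraction
    # contiguous re-formed stretches after opening; each frame spans dt
    edges = np.diff(np.concatenate(([0], reformed.astype(int), [0])))
    for start, stop in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        span = times[t_open + stop - 1] - times[t_open + start] + dt
        if span >= window:
            return "excluded_reforming"
    return "retained"


def classify_pathway(run: PullingRun, margin_delta: float = 500.0,
                     split: float = 0.5) -> str:
    """Top-down / bottom-up / concerted by mean half-interface break-up times.

    ``margin_delta`` (ps) is the minimum separation of the two means before
    a direction is declared; contacts that never formed are excluded and
    unbroken ones count at the trajectory end.
    """
    top_times, bottom_times = [], []
    for tl in run.timelines:
        v = _breakup_value(tl)
        if v is None:
            continue
        (top_times if tl.contact.axis_fraction > split else bottom_times).append(v)
    if not top_times or not bottom_times:
        raise ValueError("need at least one formed contact in each half")
    t_top, t_bottom = float(np.mean(top_times)), float(np.mean(bottom_times))
    if t_top + margin_delta < t_bottom:
        return "top_down"
    if t_bottom + margin_delta < t_top:
        return "bottom_up"
    return "concerted"


def breakup_map(runs: list[PullingRun], pathway: str,
                color_scale_ns: float = 8.0) -> dict:
    """Per-contact mean break-up times over all runs with one pathway label.

    Returns contact name -> (mean time ps, color in [0, 1]); the color
    axis runs red (0 ns) to blue (``color_scale_ns``), clamped.
    """
    selected = [r for r in runs if r.pathway_label == pathway]
    if not selected:
        raise ValueError(f"no retained runs with pathway {pathway!r}")
    acc: dict[str, list[float]] = {}
    for run in selected:
        for tl in run.timelines:
            v = _breakup_value(tl)
            if v is not None:
                acc.setdefault(tl.contact.name, []).append(v)
    out = {}
    for name, vals in acc.items():
        mean_ps = float(np.mean(vals))
        color = min(1.0, max(0.0, mean_ps / (color_scale_ns * 1000.0)))
        out[name] = (mean_ps, color)
    return out
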