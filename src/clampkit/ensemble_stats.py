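"""Frame scheduling, ensemble averaging and buried-surface-area bookkeeping.

Binding energies are averaged over conformational ensembles: frames are
sampled on a regular schedule after an equilibration discard, each frame's
energy components are evaluated at its coordinates, and means/standard
deviations are reported per component together with the mean buried
surface area (BSA).  Interface stabilities are compared through the ratio
of mean total binding energies against a reference interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energetics import (EnergyComponents, SolvationParams,
                         binding_components, sasa)
from .structure_model import ParameterizedStructure

__all__ = [
    "SampleSchedule",
    "EnsembleSummary",
    "schedule_frames",
    "average_components",
    "components_over_frames",
    "buried_surface_area",
    "stability_ratio",
    "format_summary_table",
]


@dataclass(frozen=True)
class SampleSchedule:
    """Regular frame sampling: discard an equilibration prefix, then stride.

    All times in ps.  The first sample falls at ``discard + stride`` and the
    last at or before ``total_duration`` (half-open convention), so a 20 ns
    run with 10 ns discard at 4 ps stride yields exactly 2500 frames, and a
    12 ns pulling run sampled every 10 ps yields exactly 1200.
    """

    total_duration: float
    discard: float = 0.0
    stride: float = 1.0

    def __post_init__(self):
        if self.stride <= 0:
            raise ValueError("stride must be > 0")
        if not (0 <= self.discard < self.total_duration):
            raise ValueError("need 0 <= discard < total_duration")

    @property
    def n_frames(self) -> int:
        return int(math.floor((self.total_duration - self.discard) / self.stride))


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and population standard deviation per energy component."""

    mean: dict[str, float]
    std: dict[str, float]
    n_frames: int
    mean_bsa: float | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(v < 0 for v in self.std.values()):
            raise ValueError("standard deviations must be >= 0")


def schedule_frames(sched: SampleSchedule) -> np.ndarray:
    """Sample times t_i = discard + i * stride for i = 1..n_frames (ps)."""
    n = sched.n_frames
    return sched.discard + sched.stride * np.arange(1, n + 1, dtype=float)


def average_components(per_frame: list[EnergyComponents]) -> EnsembleSummary:
    """Arithmetic mean and population (1/n) std of each component.

    Derived components (G_sol, G_ele, G_total) are averaged from their
    per-frame values; by linearity their means satisfy the same defining
    sums as the single-frame ledger.
    """
    if not per_frame:
        raise ValueError("cannot average an empty frame list")
    cols = {f: np.array([c.as_dict()[f] for c in per_frame])
            for f in EnergyComponents.FIELDS}
    mean = {f: float(v.mean()) for f, v in cols.items()}
    std = {f: float(v.std(ddof=0)) for f, v in cols.items()}
    return EnsembleSummary(mean=mean, std=std, n_frames=len(per_frame))


def components_over_frames(complex_s: ParameterizedStructure, part_a, part_b,
                           frames: np.ndarray,
                           params: SolvationParams = SolvationParams(),
                           with_bsa: bool = False):
    """Evaluate binding components (optionally BSA) on every frame.

    Returns ``(list of EnergyComponents, EnsembleSummary)``; when
    ``with_bsa`` is set the summary carries the mean buried surface area.
    """
    frames = np.asarray(frames, dtype=float)
    comps = [binding_components(complex_s, part_a, part_b, params, positions=f)
             for f in frames]
    summary = average_components(comps)
    if with_bsa:
        bsa = [buried_surface_area(complex_s, part_a, part_b, params, positions=f)
               for f in frames]
        summary = EnsembleSummary(mean=summary.mean, std=summary.std,
                                  n_frames=summary.n_frames,
                                  mean_bsa=float(np.mean(bsa)))
    return comps, summary


def buried_surface_area(complex_s: ParameterizedStructure, part_a, part_b,
                        params: SolvationParams = SolvationParams(),
                        positions: np.ndarray | None = None) -> float:
    """Total buried area BSA = SASA(A) + SASA(B) - SASA(AB), parts at
    complex coordinates.  Counts both buried faces."""
    from .energetics import _partition_masks

    ma, mb = _partition_masks(complex_s, part_a, part_b)
    pos = complex_s.positions if positions is None else np.asarray(positions, dtype=float)
    a_ab, _ = sasa(complex_s, params, positions=pos)
    a_a, _ = sasa(complex_s.subset(ma), params, positions=pos[ma])
    a_b, _ = sasa(complex_s.subset(mb), params, positions=pos[mb])
    return a_a + a_b - a_ab


def stability_ratio(target: float, reference: float) -> float:
    """Ratio of two binding energies (2 decimals); same sign required."""
    if reference == 0:
        raise ValueError("reference binding energy is zero")
    if target * reference < 0:
        raise ValueError("target and reference binding energies differ in sign")
    return round(target / reference, 2)


_ROW_LABELS = [("E_ele", "dE_ele"), ("E_vdw", "dE_vdw"),
               ("G_nonpolar", "dG_non-polar"), ("G_polar", "dG_polar"),
               ("G_sol", "dG_sol"), ("G_ele", "dG_ele"),
               ("G_total", "dG_b")]


def format_summary_table(summaries: dict[str, EnsembleSummary],
                         reference: str | None = None) -> str:
    """Render interface summaries as a TSV table of "mean (std)" cells.

    Rows follow the standard binding-energy ledger, plus a dG_b ratio row
    against ``reference`` (default: first interface) and a BSA row.
    Standard deviations are population (1/n).
    """
    names = list(summaries)
    if reference is None:
        reference = names[0]
    lines = ["Contribution\t" + "\t".join(names)]
    for field, label in _ROW_LABELS:
        cells = [f"{summaries[n].mean[field]:.2f} ({summaries[n].std[field]:.2f})"
                 for n in names]
        lines.append(label + "\t" + "\t".join(cells))
    ref_total = summaries[reference].mean["G_total"]
    lines.append("dG_b ratio\t" + "\t".join(
        f"{stability_ratio(summaries[n].mean['G_total'], ref_total):.2f}"
        for n in names))
    if all(summaries[n].mean_bsa is not None for n in names):
        lines.append("BSA (A^2)\t" + "\t".join(
            f"{summaries[n].mean_bsa:.0f}" for n in names))
    return "\n".join(lines) + "\n"
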