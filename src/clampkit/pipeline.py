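"""Configuration-driven orchestration: energy -> decomposition -> contacts/pathways.

A pipeline run takes a plain YAML (key: value) configuration, executes the
selected stages on either user-supplied structures/trajectories or the
built-in synthetic fixtures, writes one output directory of TSV/JSON
reports, and finishes with a manifest (parameters, seeds, checksums) for
provenance.  Every numeric default equals the protocol constants used
throughout the package (gamma = 0.0072, probe 1.4 A, dielectrics 1/78,
3.3 A and 50 deg contact cutoffs, spring k = 15, 1 A/ns, 12 ns).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact_dynamics import (ContactCriteria, breakup_map, breakup_time,
                               build_timelines, classify_contacts,
                               classify_pathway, reformation_screen,
                               NEVER_FORMED, PullingRun)
from .decomposition import (pairwise_decomposition, per_residue_contributions,
                            significance_filter)
from .energetics import SolvationParams
from .ensemble_stats import components_over_frames, format_summary_table
from .structure_model import (InterfaceSpec, ParameterTable, apply_parameters,
                              fill_default_lj, read_structure, read_trajectory,
                              write_structure, write_trajectory)
from .synthetic_data import make_jitter_ensemble, make_toy_interface
from .toy_smd import (asymmetric_depth_map, build_go_model,
                      default_pull_protocol, interface_timelines, run_pulling)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

_KNOWN_KEYS = {
    "out_dir", "seed", "stages", "complex", "trajectory", "parameter_table",
    "chain_a", "chain_b", "interface", "synthetic", "solvation", "criteria",
    "residue_threshold", "pair_threshold", "n_pulling_runs", "deep_half",
    "jitter_sigma", "n_frames", "time_scale",
}
_STAGES = ("energy", "decomposition", "contacts", "pathways")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see module docstring for defaults)."""

    out_dir: str = "clamp_out"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    complex: str | None = None
    trajectory: str | None = None
    parameter_table: str | None = None
    chain_a: str = "A"
    chain_b: str = "B"
    interface: dict | None = None
    synthetic: bool = True
    solvation: dict = field(default_factory=dict)
    criteria: dict = field(default_factory=dict)
    residue_threshold: float = 1.5
    pair_threshold: float = 1.0
    n_pulling_runs: int = 6
    deep_half: str | None = "bottom"
    jitter_sigma: float = 0.08
    n_frames: int = 5
    time_scale: float = 150.0

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.residue_threshold <= 0 or cfg.pair_threshold <= 0:
            raise ValueError("thresholds must be positive magnitudes")
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        for key in ("complex", "trajectory", "parameter_table"):
            path = getattr(cfg, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key} path does not exist: {path}")
        if not cfg.synthetic and cfg.complex is None:
            raise ValueError("non-synthetic runs need a complex structure path")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _interface_from_config(cfg: PipelineConfig) -> InterfaceSpec | None:
    if cfg.interface is None:
        return None
    d = cfg.interface
    return InterfaceSpec(subunit_a=d["subunit_a"], subunit_b=d["subunit_b"],
                         domain_a=tuple(d["domain_a"]),
                         domain_b=tuple(d["domain_b"]),
                         top_anchor=tuple(d["top_anchor"]),
                         bottom_anchor=tuple(d["bottom_anchor"]))


def _load_inputs(cfg: PipelineConfig, out: Path):
    """Structure + frames + interface, synthetic or from files."""
    if cfg.synthetic and cfg.complex is None:
        structure, table, spec, _ = make_toy_interface(seed=cfg.seed)
        frames = make_jitter_ensemble(structure, cfg.jitter_sigma,
                                      cfg.n_frames, seed=cfg.seed + 1)
        write_structure(out / "synthetic_complex.pdb", structure)
        table.to_file(out / "synthetic_params.tsv")
        write_trajectory(out / "synthetic_ensemble.pdb", structure, frames)
        return structure, frames, spec
    structure = read_structure(cfg.complex)
    if cfg.parameter_table is not None:
        structure = apply_parameters(structure,
                                     ParameterTable.from_file(cfg.parameter_table))
    if structure.is_parameterized(lj=False) and not structure.is_parameterized():
        structure = fill_default_lj(structure)  # PQR input: no well depths
    if not structure.is_parameterized():
        raise ValueError("input structure lacks charges/radii; supply a "
                         "parameter_table or a PQR file")
    if cfg.trajectory is not None:
        _, frames = read_trajectory(cfg.trajectory, topology=cfg.complex)
    else:
        frames = structure.positions[None, :, :]
    return structure, frames, _interface_from_config(cfg)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the selected stages; returns the manifest dictionary."""
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = SolvationParams(**config.solvation)
    criteria = ContactCriteria(**config.criteria)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stages": {}, "checksums": {}}
    chains = (config.chain_a, config.chain_b)

    try:
        structure, frames, interface = _load_inputs(config, out)
    except Exception as exc:
        _write_manifest(out, manifest, error=("inputs", exc))
        raise PipelineStageError("inputs", exc) from exc

    matrix = None
    contacts = None
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "energy":
                comps, summary = components_over_frames(
                    structure, *chains, frames, params, with_bsa=True)
                rows = [c.as_dict() for c in comps]
                pd.DataFrame(rows).to_csv(out / "energy_components.tsv",
                                          sep="\t", index=False)
                (out / "energy_summary.tsv").write_text(
                    format_summary_table({"interface": summary}))
                manifest["stages"]["energy"] = {
                    "n_frames": summary.n_frames,
                    "G_total_mean": summary.mean["G_total"],
                    "mean_bsa": summary.mean_bsa}
            elif stage == "decomposition":
                matrix = pairwise_decomposition(structure, *chains, params,
                                                frames=frames)
                contribs = per_residue_contributions(
                    matrix, threshold=config.residue_threshold)
                pd.DataFrame(
                    [{"chain": c.residue[0], "residue": c.residue[1],
                      "energy": c.energy, "significant": c.above_threshold}
                     for c in contribs]).to_csv(
                    out / "residue_contributions.tsv", sep="\t", index=False)
                pd.DataFrame(matrix.matrix,
                             index=[f"{c}{r}" for c, r in matrix.residues_a],
                             columns=[f"{c}{r}" for c, r in matrix.residues_b]
                             ).to_csv(out / "pair_matrix.tsv", sep="\t")
                per_res = {c.residue: c.energy for c in contribs}
                bfac = np.array([per_res.get((a.chain_id, a.residue_index), 0.0)
                                 for a in structure.atoms])
                write_structure(out / "residue_energies.pdb", structure,
                                format="pdb", bfactors=np.clip(bfac, -99, 99))
                manifest["stages"]["decomposition"] = {
                    "conservation_error": matrix.conservation_error(),
                    "n_significant_residues": int(sum(c.above_threshold
                                                      for c in contribs))}
            elif stage == "contacts":
                if matrix is None:
                    matrix = pairwise_decomposition(structure, *chains, params,
                                                    frames=frames)
                pairs = significance_filter(matrix.pair_energies(), "pair",
                                            config.pair_threshold)
                contacts = classify_contacts(structure, pairs, criteria,
                                             interface=interface)
                times = 10.0 * np.arange(1, len(frames) + 1, dtype=float)
                timelines = build_timelines(structure, frames, times, contacts,
                                            criteria)
                rows = []
                for tl in timelines:
                    b = breakup_time(tl)
                    rows.append({"contact": tl.contact.name,
                                 "class": tl.contact.contact_class,
                                 "axis_fraction": tl.contact.axis_fraction,
                                 "pair_energy": tl.contact.pair_energy,
                                 "breakup": str(b)})
                pd.DataFrame(rows).to_csv(out / "contacts.tsv", sep="\t",
                                          index=False)
                manifest["stages"]["contacts"] = {"n_contacts": len(contacts)}
            elif stage == "pathways":
                if interface is None:
                    raise ValueError("pathway stage needs an interface spec "
                                     "(anchors define top/bottom)")
                model = build_go_model(structure)
                depth_map = asymmetric_depth_map(model, interface,
                                                 config.deep_half)
                model = build_go_model(structure, depth_map=depth_map)
                labels: dict[str, int] = {}
                runs: list[PullingRun] = []
                for k in range(config.n_pulling_runs):
                    protocol = default_pull_protocol(
                        model, config.chain_a, seed=config.seed + k,
                        time_scale=config.time_scale)
                    run = interface_timelines(run_pulling(model, protocol),
                                              interface=interface)
                    status = reformation_screen(run)
                    if status == "retained":
                        run.pathway_label = classify_pathway(run)
                        labels[run.pathway_label] = labels.get(
                            run.pathway_label, 0) + 1
                    else:
                        run.pathway_label = status
                    runs.append(run)
                (out / "pathways.json").write_text(json.dumps(
                    {"labels": labels,
                     "n_retained": sum(labels.values()),
                     "n_runs": config.n_pulling_runs}, indent=2))
                if labels:
                    best = max(labels, key=labels.get)
                    bmap = breakup_map(runs, best)
                    pd.DataFrame(
                        [{"contact": k, "mean_breakup_ps": v[0], "color": v[1]}
                         for k, v in bmap.items()]).to_csv(
                        out / "breakup_map.tsv", sep="\t", index=False)
                manifest["stages"]["pathways"] = {"labels": labels}
        except Exception as exc:
            _write_manifest(out, manifest, error=(stage, exc))
            raise PipelineStageError(stage, exc) from exc

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict, error=None) -> None:
    if error is not None:
        manifest = dict(manifest)
        manifest["error"] = {"stage": error[0], "message": str(error[1])}
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
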