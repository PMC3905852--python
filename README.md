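# clampkit

Interface-stability analysis for ring-shaped DNA sliding clamps.

Sliding clamps — the homotrimeric PCNA ring and the heterotrimeric
Rad9–Rad1–Hus1 (9-1-1) checkpoint clamp — encircle DNA and must be
cracked open at exactly one subunit interface by a clamp loader. Which
interface opens, how hard it is to open, and in which direction it
unzips are questions about the energetics and mechanics of
protein–protein interfaces. `clampkit` packages the standard
computational answers for structural biologists and modellers:

* **End-point binding energies** (MM/GBSA style):
  ΔG_b = ΔE_ele + ΔE_vdw + ΔG_polar + ΔG_nonpolar, with OBC-II
  Generalized Born polar solvation, Shrake–Rupley SASA nonpolar term
  (γ·A + b, γ = 0.0072 kcal mol⁻¹ Å⁻², probe 1.4 Å, ε = 1/78), ensemble
  averaging, buried surface area, and stability ratios between
  interfaces.
* **Per-residue (1D) and residue-pair (2D) decomposition** of ΔG_b that
  re-sums exactly to the total, with significance screening
  (±1.5 kcal/mol residues; favorable pairs) to locate interface hot
  spots.
* **Contact-rupture analysis** of pulling trajectories: contacts typed as
  salt bridges, backbone/side-chain hydrogen bonds (3.3 Å / 50°
  criteria), hydrophobic or polar; break-up = time of last occurrence;
  re-forming runs screened out; opening pathways classified top-down /
  bottom-up / concerted along the interface axis.
* **A Gō-model pulling surrogate** implementing the constant-velocity
  protocol (spring k = 15 kcal mol⁻¹ Å⁻², 1 Å/ns, 12 ns, frames every
  10 ps) on coarse-grained beads, plus synthetic interface/ensemble/
  rupture generators so the entire pipeline is testable without MD
  trajectories.

Structures come in as PDB or PQR (multi-model PDB for ensembles; DCD/XTC
via MDAnalysis if installed); parameters as a plain-text table of
per-atom charge, GB radius, and Lennard-Jones r_min/2 and ε.

## Worked example

Run the full pipeline on the built-in synthetic two-chain interface
(seven planted contacts: a salt bridge, backbone and side-chain hydrogen
bonds, hydrophobic and polar contacts, spread along the interface axis):

```python
from clampkit.pipeline import run_pipeline

manifest = run_pipeline({"out_dir": "demo", "seed": 0,
                         "n_frames": 5, "n_pulling_runs": 6})
```

`demo/energy_summary.tsv` then holds the binding-energy ledger averaged
over a 5-frame jittered ensemble (mean and population std, kcal/mol):

```
Contribution    interface
dE_ele          -115.50 (4.94)
dE_vdw          -9.25 (1.90)
dG_non-polar    -4.38 (0.03)
dG_polar        107.40 (3.84)
dG_sol          103.03 (3.85)
dG_ele          -8.09 (1.22)
dG_b            -21.72 (1.51)
dG_b ratio      1.00
BSA (A^2)       608
```

Read: favorable gas-phase electrostatics (−115.5) are mostly paid back by
polar desolvation (+107.4); the interface is bound by −21.7 kcal/mol and
buries 608 Å² in total. The manifest reports the decomposition
conservation error (≈1e−13 kcal/mol — the residue/pair decomposition
re-sums the total exactly), the 6 significant contacts it classified, and
the pathway census of six pulling runs with bottom-heavy well depths:

```
"pathways": {"labels": {"top_down": 4, "bottom_up": 1, "concerted": 1}}
```

i.e. an interface whose strong contacts sit at the bottom preferentially
unzips top-down, as expected. The same stages are available as
`clamp` subcommands (`clamp synth`, `clamp energy`, `clamp decompose`,
`clamp contacts`, `clamp pathways`, `clamp simulate`, `clamp run`).

Library entry points: `binding_components`, `components_over_frames`,
`pairwise_decomposition` / `per_residue_contributions`,
`classify_contacts` / `build_timelines` / `breakup_time` /
`classify_pathway`, `build_go_model` / `run_pulling`, and the
`make_toy_interface` / `make_jitter_ensemble` / `make_scripted_rupture`
generators. See `docs/methods.md` for the model, conventions and
limitations.

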