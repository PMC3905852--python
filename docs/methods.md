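# Methods

`clampkit` analyzes the stability and forced opening of the subunit
interfaces of ring-shaped DNA sliding clamps (the homotrimeric PCNA ring
and the heterotrimeric Rad9–Rad1–Hus1 checkpoint clamp are the motivating
systems). It combines three layers: an end-point implicit-solvent binding
energy, its exact decomposition over interface residues and residue pairs,
and a contact-rupture analysis of pulling trajectories that classifies the
direction in which an interface opens. A coarse-grained Gō-model pulling
engine and a family of synthetic structure generators make the whole chain
testable on a desk without molecular-dynamics trajectories.

## Binding energy model

For a complex AB split into parts A and B, every term is an end-point
difference evaluated with the parts frozen at the complex's coordinates
(single-trajectory convention):

    ΔG_b = ΔE_ele + ΔE_vdw + ΔG_polar + ΔG_nonpolar
    ΔG_sol = ΔG_polar + ΔG_nonpolar,  ΔG_ele = ΔE_ele + ΔG_polar

* **ΔE_ele** — Coulomb sum over cross-group atom pairs,
  k_e q_i q_j / (ε_in r_ij) with k_e = 332.0637 kcal·Å/(mol·e²), no
  cutoff. Under the single-trajectory convention intra-group terms cancel
  exactly, so the difference reduces to the cross sum; the implementation
  exploits this.
* **ΔE_vdw** — 12-6 Lennard-Jones with r_min,ij = r_min,i/2 + r_min,j/2
  and ε_ij = √(ε_i ε_j), also a pure cross sum.
* **ΔG_polar** — Generalized Born with OBC-II effective radii:
  HCT pairwise descreening integrals, ψ-tanh rescaling (α = 1.0, β = 0.8,
  γ = 4.85) and the conventional 0.09 Å dielectric offset, followed by the
  canonical energy sum over ordered atom pairs (self terms included) with
  f_GB = √(r² + R_i R_j exp(−r²/4R_iR_j)). Dielectrics default to 1.0
  (solute) and 78.0 (water). The double sum is kept as an explicit n×n
  matrix of pair terms; its total equals the energy by construction, which
  the decomposition layer relies on. GB requires the three evaluations
  (AB, A, B) because effective radii change on dissociation.
* **ΔG_nonpolar** — γ·SASA + b with γ = 0.0072 kcal/(mol·Å²) and b = 0.
  SASA is Shrake–Rupley sampling with a deterministic golden-spiral point
  set (960 points/atom by default) over radii r_min,i/2 + 1.4 Å probe;
  determinism makes results bit-for-bit reproducible at fixed point count.

An entropy term is deliberately absent: totals are comparative binding
energies for ranking interfaces, not absolute free energies. Relative
stabilities are reported as ratios of mean ΔG_b against a reference
interface, rounded to two decimals.

The published four-interface component table that motivates the ledger
layout ships as a literature fixture (`table1_fixture`), tagged as such;
the package never claims to recompute those values, only to verify their
internal arithmetic (component sums and stability ratios). Note the
absolute totals of this GB implementation will differ from a
Poisson–Boltzmann evaluation of the same structures; the package uses GB
throughout because the pairwise decomposition requires an analytically
decomposable solvation model.

## Ensemble statistics

Frames are sampled on a half-open schedule: first sample at
discard + stride, last at or before the duration. This convention
reproduces the standard protocol counts exactly (2500 frames from the
last 10 ns of a 20 ns run at 4 ps, 1200 frames from a 12 ns pulling run
at 10 ps). Reported spreads are population (1/n) standard deviations, as
appropriate for describing an ensemble rather than inferring a mean.
Buried surface area is SASA(A) + SASA(B) − SASA(AB), i.e. the total over
both buried faces; per-face conventions differ by a factor of two and the
output headers say which is used.

## Decomposition

The pairwise (2D) decomposition distributes ΔG_b exactly:

* cell (i∈A, j∈B) = cross-residue Coulomb + LJ + GB pair terms (both
  orderings of each atom pair);
* a per-residue remainder carries what is not pairwise across the
  interface: the shift of intra-subunit GB terms caused by Born-radius
  changes on complexation (atom-pair shifts split ½:½ between the owning
  residues, self terms to the owner) and the nonpolar term attributed per
  atom as γ·ΔSASA. Cross-pair nonpolar cells are zero because SASA is not
  pairwise.

Cells plus remainders re-sum to ΔG_b to ~1e−13 kcal/mol in practice
(tested at 1e−4). The 1D (per-residue) view folds each cell half/half
onto its two residues and adds the remainder, preserving the total.
Significance screening keeps residues with |E| ≥ 1.5 kcal/mol (both
stabilizing and destabilizing) and pairs with E ≤ −threshold (favorable
only); thresholds are configurable and interpreted on the total pair
energy, not its GB part alone.

## Contact classification and rupture analysis

Significant residue pairs become typed contacts with precedence
salt bridge (Asp/Glu carboxylate O vs Lys/Arg/His side-chain N) >
backbone H-bond (both partners backbone N/O) > side-chain H-bond (any
donor/acceptor pair) > hydrophobic (both residues in
{Ala,Val,Leu,Ile,Pro,Phe,Met,Trp}) > generic polar proximity.

Presence per frame: H-bond classes need a donor–acceptor heavy-atom pair
within 3.3 Å and, when hydrogens exist, a D–H···A deviation from
linearity ≤ 50° (equivalently D–H···A angle ≥ 130°, the hydrogen-centered
convention; the angle test is skipped for hydrogen-free input).
Hydrophobic and polar contacts need any heavy-atom pair within the sum of
vdW radii + 0.5 Å slack. All cutoffs are configurable.

A contact's break-up time is the time of its **last occurrence**, which
tolerates transient breaking and re-forming. Runs where the interface
substantially re-forms after opening (≥ 30% of contacts simultaneously
present again for ≥ 500 ps after ≥ 80% were simultaneously absent) are
screened out before classification. Opening pathways are labelled by
comparing mean break-up times of contacts in the top (axis fraction
> 0.5) and bottom halves of the interface axis: a direction is declared
only when the means separate by more than δ = 0.5 ns; otherwise the run
is concerted. The interface axis runs bottom → top between two explicit
anchor points; by convention the face presenting the inter-domain
connector loop is "top". Anchors are user (or generator) inputs because
that assignment is a structural-biology judgment, not a computable one.

## Gō-model pulling surrogate

The pulling engine is a Cα-bead Gō model: harmonic bonds at native
lengths (k = 10 kcal/mol/Å²), 12-10 native-contact wells with minima at
native distances, and a truncated r⁻¹² excluded volume (σ = 3.8 Å)
between everything else. Native contacts are residue pairs with any
heavy-atom pair within 4.5 Å (intra-chain pairs only beyond sequence
separation 3). Default well depth is 2.0 kcal/mol; interface wells can be
scaled from pair-decomposition magnitudes or set asymmetric (one half of
the interface 3× deeper) to emulate the uneven charged-contact
distribution seen in directional interfaces.

Dynamics are overdamped Langevin: dx = F dt/γ + √(2kT dt/γ) ξ with
γ = 10 ps⁻¹, dt = 10 fs, T = 300 K. The pulling protocol mirrors the
constant-velocity steered-MD setup: one chain's beads restrained by stiff
anchors (10× the pulling spring), the other chain's center of mass
tethered by a k = 15 kcal/mol/Å² spring to an anchor moving at 1 Å/ns for
12 ns (12 Å total opening), frames every 10 ps (1200 frames).

Because overdamped beads relax far faster than a solvated protein,
simulated time is uniformly compressed by `time_scale` (default 150): the
anchor covers its 12 Å over duration/time_scale of simulated time while
frame timestamps stay on the nominal 12 ns clock. Pathway classification
depends only on relative rupture order, which the compression preserves;
absolute times carry no physical meaning. With these defaults one run
takes about two seconds, which sets the problem size used by the test
suite and the reproduction script (20–30 seeds per census).

The surrogate reproduces the qualitative phenomenology — asymmetric well
depths yield a dominant opening direction, uniform depths do not — and
nothing more; it makes no claim of quantitative agreement with all-atom
steered MD.

## Synthetic data

`make_toy_interface` builds two antiparallel 21-residue chains (3.5 Å
rise, 6 Å strand separation) with planted contacts of every class at
chosen heights along the interface axis, hydrogens on donors, and a
self-consistent parameter table (element-based radii/LJ, residue charges
summing to integer totals). Geometry is idealized — only contact geometry
matters downstream, not stereochemistry. The default plan places seven
contacts spanning axis fractions 0.1–0.9; the pulling experiments use a
six-contact top/bottom mirror-symmetric plan so that the uniform-depth
control is genuinely non-directional and the two asymmetric cases are
exact mirrors.

`make_jitter_ensemble` adds i.i.d. Gaussian noise (frame 0 = reference)
as a stand-in for a sampled MD ensemble: it reproduces ensemble-averaging
arithmetic, not conformational physics — passing ensemble tests says
nothing about real conformational sampling. `make_scripted_rupture`
displaces each contact's chain-B atoms 8 Å off the interface after its
scheduled last-occurrence time (optionally restoring them during
re-forming windows), giving exact ground truth for break-up-time
recovery. All generators are deterministic per seed.

## Numerical choices and edge cases

* Zero inter-atomic distance in an energy evaluation is an error naming
  the atom pair; negative SASA input and non-positive thresholds are
  rejected.
* The GB pair-term matrix and per-atom SASA are the single source of
  truth for totals, so conservation of the decomposition is exact up to
  floating-point accumulation.
* Contacts that never form are excluded from pathway means; contacts
  still present in the final frame count at the trajectory end and are
  flagged `unbroken`.
* Pathway margin comparisons are strict (`mean + δ < other mean`), and
  re-formation screening uses ≥ comparisons on both the fraction and the
  window.
* The Brownian integrator aborts with a diagnostic if any bead moves more
  than 10 Å in one step.

## Known limitations

* GB/SASA parameters are generic; no force-field assignment, protonation,
  or missing-residue repair is provided — structures must arrive
  parameterized (PQR or parameter table).
* No Poisson–Boltzmann solver and no entropy estimate; totals are
  comparative only.
* SASA is O(n²) per frame and sized for interface models (hundreds of
  atoms), not whole proteomes.
* The Gō surrogate's time axis is nominal; only rupture order and
  relative timing are meaningful.
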