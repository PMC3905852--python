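"""Desk-scale steered-pulling surrogate: a C-alpha Gō model under a moving spring.

One bead per residue sits at the native C-alpha position.  Consecutive
beads are bonded harmonically at their native length; residue pairs in
native contact attract through a 12-10 well with its minimum at the
native distance; everything else repels through a truncated excluded
volume.  A constant-velocity pulling protocol restrains one group of
beads and tethers the center of mass of another to an anchor moving at
fixed speed, mirroring the constant-velocity steered-MD protocol
(spring k = 15 kcal/mol/A^2, 1 A/ns, 12 ns, frames every 10 ps).

Because overdamped bead dynamics relax much faster than an explicit
solvent system, simulated time is uniformly compressed by
``time_scale`` while reported frame times stay on the nominal protocol
clock; pathway classification rests on relative, not absolute, rupture
times.  This is a qualitative surrogate, not a re-implementation of
all-atom SMD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contact_dynamics import Contact, ContactTimeline, PullingRun
from .structure_model import (AtomRecord, InterfaceSpec, ParameterizedStructure,
                              axis_fraction, write_trajectory)

__all__ = [
    "GoModel",
    "PullProtocol",
    "PullingTrajectory",
    "build_go_model",
    "run_pulling",
    "bead_structure",
    "interface_timelines",
    "asymmetric_depth_map",
    "default_pull_protocol",
    "pathway_census",
]

BOLTZMANN_KCAL = 0.0019872041  # kcal/mol/K


@dataclass
class GoModel:
    """Coarse-grained native-contact model (one bead per residue)."""

    positions: np.ndarray              # (n, 3) native bead coordinates
    residues: list[tuple[str, int]]    # (chain_id, residue_index) per bead
    residue_names: list[str]
    bonds: np.ndarray                  # (nb, 2) consecutive-bead indices
    bond_r0: np.ndarray
    contacts: np.ndarray               # (nc, 2) bead indices
    contact_r0: np.ndarray
    contact_depth: np.ndarray          # kcal/mol, > 0
    bond_k: float = 10.0               # kcal/mol/A^2
    excluded_sigma: float = 3.8        # A, truncated repulsion range
    excluded_eps: float = 1.0

    def __post_init__(self):
        if np.any(self.contact_depth <= 0):
            raise ValueError("contact depths must be > 0")
        for i, j in self.bonds:
            if self.residues[i][0] != self.residues[j][0] or abs(i - j) != 1:
                raise ValueError("bonds must connect consecutive beads of one chain")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def chain_of(self, bead: int) -> str:
        return self.residues[bead][0]

    def interface_contact_indices(self) -> np.ndarray:
        return np.flatnonzero([self.chain_of(i) != self.chain_of(j)
                               for i, j in self.contacts])


@dataclass(frozen=True)
class PullProtocol:
    """Constant-velocity pulling settings (nominal protocol clock).

    spring_k in kcal/mol/A^2, velocity in A/ns, duration in ns,
    sample_interval in ps.  ``time_scale`` compresses simulated time;
    reported frame times remain nominal (t_i = i * sample_interval).
    """

    restrained: tuple[int, ...]
    pulled: tuple[int, ...]
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    spring_k: float = 15.0
    velocity: float = 1.0
    duration: float = 12.0
    sample_interval: float = 10.0
    temperature: float = 300.0
    friction: float = 10.0      # ps^-1 (overdamped drag)
    timestep: float = 10.0      # fs
    seed: int = 0
    time_scale: float = 150.0

    def __post_init__(self):
        for name in ("spring_k", "duration", "sample_interval", "friction",
                     "timestep", "time_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.velocity < 0 or self.temperature < 0:
            raise ValueError("velocity and temperature must be >= 0")
        if set(self.restrained) & set(self.pulled):
            raise ValueError("restrained and pulled bead sets overlap")
        if not self.pulled:
            raise ValueError("need at least one pulled bead")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 1000.0 / self.sample_interval))

    @property
    def pull_extent(self) -> float:
        """Total anchor displacement in A (velocity x duration)."""
        return self.velocity * self.duration


@dataclass
class PullingTrajectory:
    model: GoModel
    protocol: PullProtocol
    frames: np.ndarray        # (n_frames, n_beads, 3)
    times: np.ndarray         # nominal ps
    anchor_displacement: float

    def write_pdb(self, path) -> None:
        write_trajectory(path, bead_structure(self.model), self.frames)


def build_go_model(structure: ParameterizedStructure, contact_cutoff: float = 4.5,
                   depth_map: dict | None = None, default_depth: float = 2.0,
                   min_sequence_separation: int = 3) -> GoModel:
    """Construct the Gō model from an all-atom (or bead) structure.

    Native contacts are residue pairs with any heavy-atom pair within
    ``contact_cutoff`` (intra-chain pairs only beyond
    ``min_sequence_separation``).  Well depths come from ``depth_map``
    keyed by frozenset of the two residue keys (e.g. scaled from pair
    decomposition energies), else ``default_depth``.
    """
    res_atoms = structure.residue_atom_indices()
    keys = structure.residue_keys()
    heavy = {k: [i for i in v if not structure.atoms[i].is_hydrogen]
             for k, v in res_atoms.items()}
    pos_all = structure.positions
    beads = []
    names = []
    for k in keys:
        idx = res_atoms[k]
        ca = [i for i in idx if structure.atoms[i].atom_name == "CA"]
        beads.append(pos_all[ca[0]] if ca else pos_all[heavy[k]].mean(axis=0))
        names.append(structure.atoms[idx[0]].residue_name)
    positions = np.array(beads)

    bonds, bond_r0 = [], []
    for a in range(len(keys) - 1):
        if keys[a][0] == keys[a + 1][0]:
            bonds.append((a, a + 1))
            bond_r0.append(float(np.linalg.norm(positions[a] - positions[a + 1])))

    contacts, c_r0, c_depth = [], [], []
    per_res_pos = {k: pos_all[heavy[k]] for k in keys}
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ka, kb = keys[a], keys[b]
            same_chain = ka[0] == kb[0]
            if same_chain and b - a < min_sequence_separation:
                continue
            if cdist(per_res_pos[ka], per_res_pos[kb]).min() <= contact_cutoff:
                contacts.append((a, b))
                c_r0.append(float(np.linalg.norm(positions[a] - positions[b])))
                depth = default_depth
                if depth_map:
                    depth = depth_map.get(frozenset((ka, kb)), default_depth)
                c_depth.append(float(depth))
    model = GoModel(positions=positions, residues=keys, residue_names=names,
                    bonds=np.array(bonds, dtype=int).reshape(-1, 2),
                    bond_r0=np.array(bond_r0),
                    contacts=np.array(contacts, dtype=int).reshape(-1, 2),
                    contact_r0=np.array(c_r0), contact_depth=np.array(c_depth))
    if model.interface_contact_indices().size == 0:
        raise ValueError("no native contacts across the interface")
    return model


def _forces(model: GoModel, x: np.ndarray) -> np.ndarray:
    f = np.zeros_like(x)
    # bonds
    bi, bj = model.bonds[:, 0], model.bonds[:, 1]
    dv = x[bj] - x[bi]
    d = np.linalg.norm(dv, axis=1)
    fb = (2.0 * model.bond_k * (d - model.bond_r0) / d)[:, None] * dv
    np.add.at(f, bi, fb)
    np.add.at(f, bj, -fb)
    # 12-10 native contact wells: U = eps [5 (r0/r)^12 - 6 (r0/r)^10]
    ci, cj = model.contacts[:, 0], model.contacts[:, 1]
    dv = x[cj] - x[ci]
    d = np.linalg.norm(dv, axis=1)
    s = model.contact_r0 / d
    dU_dr = 60.0 * model.contact_depth / d * (s ** 10 - s ** 12)
    fc = (-dU_dr / d)[:, None] * dv
    np.add.at(f, ci, -fc)
    np.add.at(f, cj, fc)
    # truncated excluded volume for all remaining pairs within sigma
    n = model.n_beads
    dmat = cdist(x, x)
    np.fill_diagonal(dmat, np.inf)
    mask = dmat < model.excluded_sigma
    mask[model.bonds[:, 0], model.bonds[:, 1]] = False
    mask[model.bonds[:, 1], model.bonds[:, 0]] = False
    mask[ci, cj] = False
    mask[cj, ci] = False
    ii, jj = np.nonzero(np.triu(mask))
    if ii.size:
        dv = x[jj] - x[ii]
        d = dmat[ii, jj]
        s = model.excluded_sigma / d
        dU_dr = -12.0 * model.excluded_eps * s ** 12 / d
        fr = (-dU_dr / d)[:, None] * dv
        np.add.at(f, ii, -fr)
        np.add.at(f, jj, fr)
    return f


def run_pulling(model: GoModel, protocol: PullProtocol) -> PullingTrajectory:
    """Overdamped Langevin pulling run, reproducible from the protocol seed.

    Positions update as dx = F dt / friction + sqrt(2 kT dt / friction) xi.
    Restrained beads sit in stiff anchors (10 x spring_k); the pulled
    group's center of mass is tethered by spring_k to an anchor moving
    linearly to ``pull_extent`` over the run.
    """
    rng = np.random.default_rng(protocol.seed)
    x = model.positions.copy()
    direction = np.asarray(protocol.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    restrained = np.array(protocol.restrained, dtype=int)
    pulled = np.array(protocol.pulled, dtype=int)
    restraint_k = 10.0 * protocol.spring_k
    anchors0 = model.positions[restrained]
    com0 = x[pulled].mean(axis=0)

    dt = protocol.timestep / 1000.0  # ps
    n_frames = protocol.n_frames
    sim_duration = protocol.duration * 1000.0 / protocol.time_scale  # ps
    steps_per_frame = max(1, int(round(sim_duration / n_frames / dt)))
    total_steps = n_frames * steps_per_frame
    kT = BOLTZMANN_KCAL * protocol.temperature
    noise_scale = np.sqrt(2.0 * kT * dt / protocol.friction)
    mob_dt = dt / protocol.friction

    frames = np.empty((n_frames, model.n_beads, 3))
    disp = 0.0
    for step in range(1, total_steps + 1):
        disp = protocol.pull_extent * step / total_steps
        anchor = com0 + disp * direction
        f = _forces(model, x)
        if restrained.size:
            f[restrained] += 2.0 * restraint_k * (anchors0 - x[restrained])
        com = x[pulled].mean(axis=0)
        f[pulled] += protocol.spring_k * (anchor - com) / len(pulled)
        dx = f * mob_dt
        if protocol.temperature > 0:
            dx = dx + noise_scale * rng.standard_normal(x.shape)
        step_max = float(np.abs(dx).max())
        if step_max > 10.0:
            raise RuntimeError(f"integration blow-up: bead displacement "
                               f"{step_max:.1f} A in one step (step {step})")
        x = x + dx
        if step % steps_per_frame == 0:
            frames[step // steps_per_frame - 1] = x
    times = protocol.sample_interval * np.arange(1, n_frames + 1, dtype=float)
    return PullingTrajectory(model=model, protocol=protocol, frames=frames,
                             times=times, anchor_displacement=disp)


def bead_structure(model: GoModel) -> ParameterizedStructure:
    """One CA pseudo-atom per bead, for writing bead trajectories as PDB."""
    atoms = [AtomRecord(atom_id=i + 1, atom_name="CA", element="C",
                        residue_index=res[1], residue_name=model.residue_names[i],
                        chain_id=res[0], position=model.positions[i].copy(),
                        charge=0.0, gb_radius=1.7, vdw_rmin_half=1.9,
                        lj_epsilon=0.1)
             for i, res in enumerate(model.residues)]
    return ParameterizedStructure(atoms, title="Go-model beads")


def interface_timelines(traj: PullingTrajectory,
                        interface: InterfaceSpec | None = None,
                        break_slack: float = 2.0,
                        pair_energies: dict | None = None) -> PullingRun:
    """Track every cross-chain native contact along a pulling trajectory.

    A Gō contact is present while the bead distance stays within its
    native length + ``break_slack``.  Axis fractions come from projecting
    the native contact midpoint on the interface axis (0.5 without an
    interface spec).  Returns a PullingRun ready for screening and
    pathway classification.
    """
    model = traj.model
    timelines = []
    for c_idx in model.interface_contact_indices():
        i, j = model.contacts[c_idx]
        r0 = model.contact_r0[c_idx]
        mid = 0.5 * (model.positions[i] + model.positions[j])
        frac = axis_fraction(interface, mid) if interface is not None else 0.5
        key_a, key_b = model.residues[i], model.residues[j]
        energy = 0.0
        if pair_energies:
            energy = pair_energies.get(frozenset((key_a, key_b)), 0.0)
        contact = Contact(residue_a=key_a, residue_b=key_b,
                          contact_class="native_contact",
                          atoms_a=(int(i),), atoms_b=(int(j),),
                          axis_fraction=frac, pair_energy=energy)
        d = np.linalg.norm(traj.frames[:, j] - traj.frames[:, i], axis=1)
        timelines.append(ContactTimeline(contact=contact, times=traj.times,
                                         present=d <= r0 + break_slack))
    protocol_info = {"spring_k": traj.protocol.spring_k,
                     "velocity": traj.protocol.velocity,
                     "duration": traj.protocol.duration,
                     "sample_interval": traj.protocol.sample_interval,
                     "seed": traj.protocol.seed,
                     "time_scale": traj.protocol.time_scale}
    return PullingRun(timelines=timelines, protocol=protocol_info)


# ---------------------------------------------------------------------------
# Canonical pulling experiments
# ---------------------------------------------------------------------------

def asymmetric_depth_map(model: GoModel, interface: InterfaceSpec,
                         deep_half: str | None = "bottom",
                         factor: float = 3.0, base: float = 2.0) -> dict:
    """Well-depth map with one interface half's wells ``factor`` x deeper.

    Emulates the uneven distribution of strong polar contacts that gives
    some clamp interfaces a preferred opening direction; ``deep_half``
    None yields a uniform (non-directional, PCNA-like) map.
    """
    if deep_half not in ("bottom", "top", None):
        raise ValueError("deep_half must be 'bottom', 'top' or None")
    out = {}
    for ci in model.interface_contact_indices():
        i, j = model.contacts[ci]
        frac = axis_fraction(interface, 0.5 * (model.positions[i]
                                               + model.positions[j]))
        if deep_half is None:
            depth = base
        else:
            in_deep = frac <= 0.5 if deep_half == "bottom" else frac > 0.5
            depth = base * factor if in_deep else base
        out[frozenset((model.residues[i], model.residues[j]))] = depth
    return out


def default_pull_protocol(model: GoModel, restrained_chain: str,
                          seed: int = 0, **overrides) -> PullProtocol:
    """Restrain one chain, pull the other chain's center of mass along +x."""
    restrained = tuple(i for i in range(model.n_beads)
                       if model.chain_of(i) == restrained_chain)
    pulled = tuple(i for i in range(model.n_beads)
                   if model.chain_of(i) != restrained_chain)
    if not restrained or not pulled:
        raise ValueError(f"chain {restrained_chain!r} does not split the beads")
    return PullProtocol(restrained=restrained, pulled=pulled, seed=seed,
                        **overrides)


def pathway_census(structure: ParameterizedStructure, interface: InterfaceSpec,
                   seeds, deep_half: str | None = None,
                   restrained_chain: str | None = None,
                   factor: float = 3.0, base: float = 2.0,
                   **protocol_overrides):
    """Run one pulling trajectory per seed and tally pathway labels.

    Returns ``(labels, n_retained)`` where ``labels`` maps pathway ->
    count over retained runs (re-forming runs are screened out).
    """
    from .contact_dynamics import classify_pathway, reformation_screen

    if restrained_chain is None:
        restrained_chain = sorted({r[0] for r in
                                   build_go_model(structure).residues})[0]
    base_model = build_go_model(structure)
    depth_map = asymmetric_depth_map(base_model, interface, deep_half,
                                     factor=factor, base=base)
    model = build_go_model(structure, depth_map=depth_map)
    labels: dict[str, int] = {}
    retained = 0
    for seed in seeds:
        protocol = default_pull_protocol(model, restrained_chain, seed=seed,
                                         **protocol_overrides)
        run = interface_timelines(run_pulling(model, protocol),
                                  interface=interface)
        if reformation_screen(run) != "retained":
            continue
        retained += 1
        label = classify_pathway(run)
        labels[label] = labels.get(label, 0) + 1
    return labels, retained
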