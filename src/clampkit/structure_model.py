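"""Structures of two-subunit clamp interfaces and their parameterization.

Coordinates are in Angstrom, charges in elementary units, energies in
kcal/mol throughout the package.  Residue indices follow the input file's
residue sequence numbers (1-based in PDB); ranges are inclusive on both
ends.

A :class:`ParameterizedStructure` is the package's central container: an
ordered list of atoms carrying positions, partial charges, GB radii and
Lennard-Jones parameters, grouped into chains.  Parameters come either
inline (PQR input) or from a plain-text :class:`ParameterTable` via
:func:`apply_parameters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "ParameterizedStructure",
    "InterfaceSpec",
    "ParameterTable",
    "StructureParseError",
    "ParameterLookupError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "apply_parameters",
    "truncate_to_interface",
    "axis_fraction",
]

# Backbone = N, CA, C, O (+ terminal OXT) plus their attached hydrogens.
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3",
                   "HA", "HA2", "HA3"}

_ELEMENT_DEFAULT_RADII = {  # fallback GB / vdW radii by element, Angstrom
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80, "P": 1.85,
}


class StructureParseError(ValueError):
    """Raised when a PDB/PQR file cannot be parsed; names the offending line."""


class ParameterLookupError(KeyError):
    """Raised in strict parameter assignment when atoms are missing from the table."""

    def __init__(self, missing):
        self.missing = list(missing)
        keys = ", ".join(f"({r}, {a})" for r, a in self.missing)
        super().__init__(f"parameter table is missing {len(self.missing)} "
                         f"(residue, atom) keys: {keys}")


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    if name[0].isdigit():  # e.g. 1HB
        name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return name[:2].capitalize()
    return name[0].upper()


@dataclass
class AtomRecord:
    """One atom with coordinates and (possibly unset) energy parameters.

    Unset numeric parameters are NaN until :func:`apply_parameters` fills
    them (PQR input supplies charge and radius inline).
    """

    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    charge: float = math.nan
    gb_radius: float = math.nan
    vdw_rmin_half: float = math.nan
    lj_epsilon: float = math.nan

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in _BACKBONE_NAMES

    def validate(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite position")
        for name, val, lo in (("gb_radius", self.gb_radius, 0.0),
                              ("vdw_rmin_half", self.vdw_rmin_half, 0.0)):
            if not math.isnan(val) and val <= lo:
                raise ValueError(f"atom {self.atom_id}: {name} must be > {lo}")
        if not math.isnan(self.lj_epsilon) and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_id}: lj_epsilon must be >= 0")


@dataclass
class ParameterizedStructure:
    """Ordered atoms plus a chain_id -> (first, last) residue-range map."""

    atoms: list[AtomRecord]
    chains: dict[str, tuple[int, int]] = field(default_factory=dict)
    title: str = ""
    remarks: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.chains:
            self.chains = self._derive_chains()
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom_ids")
        for a in self.atoms:
            if a.chain_id not in self.chains:
                raise ValueError(f"atom {a.atom_id}: chain {a.chain_id!r} "
                                 "not in chain map")

    def _derive_chains(self) -> dict[str, tuple[int, int]]:
        chains: dict[str, tuple[int, int]] = {}
        for a in self.atoms:
            lo, hi = chains.get(a.chain_id, (a.residue_index, a.residue_index))
            chains[a.chain_id] = (min(lo, a.residue_index), max(hi, a.residue_index))
        return chains

    # ---- numpy views -----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def gb_radii(self) -> np.ndarray:
        return np.array([a.gb_radius for a in self.atoms], dtype=float)

    @property
    def vdw_rmin_half(self) -> np.ndarray:
        return np.array([a.vdw_rmin_half for a in self.atoms], dtype=float)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.array([a.is_hydrogen for a in self.atoms], dtype=bool)

    def chain_mask(self, chain_id: str | list[str]) -> np.ndarray:
        wanted = {chain_id} if isinstance(chain_id, str) else set(chain_id)
        return np.array([a.chain_id in wanted for a in self.atoms], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) keys."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain_id, a.residue_index), []).append(i)
        return out

    def atoms_of(self, chain_id: str, residue_index: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms)
                if a.chain_id == chain_id and a.residue_index == residue_index]

    def with_positions(self, positions: np.ndarray) -> "ParameterizedStructure":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError(f"positions shape {positions.shape} != ({self.n_atoms}, 3)")
        atoms = [replace(a, position=positions[i].copy())
                 for i, a in enumerate(self.atoms)]
        return ParameterizedStructure(atoms, dict(self.chains), self.title,
                                      list(self.remarks))

    def subset(self, mask: np.ndarray) -> "ParameterizedStructure":
        atoms = [a for a, keep in zip(self.atoms, mask) if keep]
        if not atoms:
            raise ValueError("empty atom selection")
        return ParameterizedStructure(atoms, title=self.title)

    def is_parameterized(self, lj: bool = True) -> bool:
        fields = [self.charges, self.gb_radii]
        if lj:
            fields += [self.vdw_rmin_half, self.lj_epsilon]
        return all(np.all(np.isfinite(f)) for f in fields)


@dataclass(frozen=True)
class InterfaceSpec:
    """Which residue ranges form the interface and how it is oriented.

    ``top_anchor``/``bottom_anchor`` realize the clamp's orientation
    convention: the face presenting the inter-domain connector loop (IDCL)
    is "top".  The anchors are explicit inputs (synthetic generators emit
    them); axis fractions of 1 and 0 mean top and bottom.
    """

    subunit_a: str
    subunit_b: str
    domain_a: tuple[int, int]
    domain_b: tuple[int, int]
    top_anchor: tuple[float, float, float]
    bottom_anchor: tuple[float, float, float]

    def __post_init__(self):
        for name, (lo, hi) in (("domain_a", self.domain_a), ("domain_b", self.domain_b)):
            if hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if np.allclose(self.top_anchor, self.bottom_anchor):
            raise ValueError("top and bottom anchors coincide")


class ParameterTable:
    """(residue_name, atom_name) -> (charge, gb_radius, vdw_rmin_half, lj_epsilon).

    Stored on disk as whitespace-delimited text with '#' comments::

        # resname atomname charge gb_radius vdw_rmin_half lj_epsilon
        ALA  CA   0.0337  1.70  1.9080  0.1094
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float, float]] | None = None):
        self.entries: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        for key, vals in (entries or {}).items():
            self.add(key[0], key[1], *vals)

    def add(self, residue_name: str, atom_name: str, charge: float,
            gb_radius: float, vdw_rmin_half: float, lj_epsilon: float) -> None:
        key = (residue_name, atom_name)
        if key in self.entries:
            raise ValueError(f"duplicate parameter key {key}")
        vals = (float(charge), float(gb_radius), float(vdw_rmin_half), float(lj_epsilon))
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter for {key}")
        self.entries[key] = vals

    def get(self, residue_name: str, atom_name: str):
        return self.entries.get((residue_name, atom_name))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key) -> bool:
        return tuple(key) in self.entries

    @classmethod
    def from_file(cls, path) -> "ParameterTable":
        table = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 6:
                    raise StructureParseError(
                        f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
                try:
                    table.add(parts[0], parts[1], *(float(x) for x in parts[2:]))
                except ValueError as exc:
                    raise StructureParseError(f"{path}:{lineno}: {exc}") from exc
        return table

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# resname atomname charge gb_radius vdw_rmin_half lj_epsilon\n")
            for (res, atom), (q, rgb, rmh, eps) in sorted(self.entries.items()):
                fh.write(f"{res:<4s} {atom:<4s} {q:9.4f} {rgb:7.4f} {rmh:7.4f} {eps:8.4f}\n")


# ---------------------------------------------------------------------------
# PDB / PQR I/O
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int, path) -> AtomRecord:
    try:
        atom_id = int(line[6:11])
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip() or line[17:21].strip()
        chain_id = line[21].strip() or "A"
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"{path}:{lineno}: malformed ATOM record "
                                  f"({exc}): {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    element = element.capitalize() if element else _guess_element(atom_name)
    return AtomRecord(atom_id, atom_name, element, residue_index, residue_name,
                      chain_id, np.array([x, y, z], dtype=float))


def _parse_pqr_atom(line: str, lineno: int, path) -> AtomRecord:
    parts = line.split()
    # flavors: with or without a chain-id column
    if len(parts) == 11:
        _, aid, name, resname, chain, resid, x, y, z, q, r = parts
    elif len(parts) == 10:
        _, aid, name, resname, resid, x, y, z, q, r = parts
        chain = "A"
    else:
        raise StructureParseError(f"{path}:{lineno}: PQR ATOM line has "
                                  f"{len(parts)} fields (expected 10 or 11)")
    try:
        rec = AtomRecord(int(aid), name, _guess_element(name), int(resid),
                         resname, chain,
                         np.array([float(x), float(y), float(z)]),
                         charge=float(q), gb_radius=float(r),
                         vdw_rmin_half=float(r))
    except ValueError as exc:
        raise StructureParseError(f"{path}:{lineno}: malformed PQR record "
                                  f"({exc}): {line.rstrip()!r}") from exc
    return rec


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "pqr"):
            raise ValueError(f"unknown structure format {fmt!r} (use 'pdb' or 'pqr')")
        return fmt
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if suffix in ("pdb", "pqr"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def read_structure(path, format: str | None = None) -> ParameterizedStructure:
    """Read a PDB or PQR file; for multi-model PDB, return the first model."""
    structure, _ = read_trajectory(path, format=format, first_model_only=True)
    return structure


def read_trajectory(path, format: str | None = None,
                    first_model_only: bool = False,
                    topology=None):
    """Read a structure plus all models as a coordinate stack.

    Returns ``(structure, frames)`` where ``frames`` has shape
    (n_models, n_atoms, 3) and the structure holds model-1 coordinates.
    DCD/XTC trajectories are read through MDAnalysis and require a
    ``topology`` PDB/PQR path.
    """
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if format is None and suffix in ("dcd", "xtc", "trr"):
        return _read_mda_trajectory(path, topology)
    fmt = _infer_format(path, format)
    parse = _parse_pdb_atom if fmt == "pdb" else _parse_pqr_atom
    title = ""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
                if first_model_only and models:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                current.append(parse(line, lineno, path))
    if current or not models:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise StructureParseError(f"{path}: no ATOM records found")
    structure = ParameterizedStructure(models[0], title=title)
    n = structure.n_atoms
    for k, m in enumerate(models):
        if len(m) != n:
            raise StructureParseError(
                f"{path}: model {k + 1} has {len(m)} atoms, expected {n}")
    frames = np.array([[a.position for a in m] for m in models], dtype=float)
    return structure, frames


def _read_mda_trajectory(path, topology):
    if topology is None:
        raise ValueError("DCD/XTC input requires a topology PDB/PQR path")
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(path))
    structure = read_structure(topology)
    frames = np.array([u.atoms.positions.copy().astype(float)
                       for _ in u.trajectory])
    if frames.shape[1] != structure.n_atoms:
        raise StructureParseError(
            f"{path}: trajectory atom count {frames.shape[1]} != topology "
            f"{structure.n_atoms}")
    return structure, frames


def _pdb_line(a: AtomRecord) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
    x, y, z = a.position
    return (f"ATOM  {a.atom_id % 100000:5d} {name:<4s} {a.residue_name:<3s} "
            f"{a.chain_id[:1]}{a.residue_index % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")


def _pqr_line(a: AtomRecord) -> str:
    x, y, z = a.position
    q = 0.0 if math.isnan(a.charge) else a.charge
    r = 0.0 if math.isnan(a.gb_radius) else a.gb_radius
    return (f"ATOM  {a.atom_id:5d} {a.atom_name:<4s} {a.residue_name:<4s} "
            f"{a.chain_id[:1]} {a.residue_index:4d}   "
            f"{x:10.4f} {y:10.4f} {z:10.4f} {q:8.4f} {r:7.4f}")


def write_structure(path, s: ParameterizedStructure, format: str | None = None,
                    bfactors: np.ndarray | None = None) -> None:
    """Write a single-model PDB or PQR file.

    ``bfactors`` (PDB only) puts per-atom values in the B-factor column,
    used to map per-residue energies onto structures.
    """
    fmt = _infer_format(path, format)
    with open(path, "w") as fh:
        if s.title:
            fh.write(f"TITLE     {s.title}\n")
        for i, a in enumerate(s.atoms):
            if fmt == "pdb":
                line = _pdb_line(a)
                if bfactors is not None:
                    line = line[:60] + f"{float(bfactors[i]):6.2f}" + line[66:]
                fh.write(line + "\n")
            else:
                fh.write(_pqr_line(a) + "\n")
        fh.write("END\n")


def write_trajectory(path, s: ParameterizedStructure, frames: np.ndarray) -> None:
    """Write a multi-model PDB trajectory (one MODEL per frame)."""
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        if s.title:
            fh.write(f"TITLE     {s.title}\n")
        for k, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            for a, pos in zip(s.atoms, coords):
                fh.write(_pdb_line(replace(a, position=pos)) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Parameterization and interface geometry
# ---------------------------------------------------------------------------

def apply_parameters(s: ParameterizedStructure, table: ParameterTable,
                     strict: bool = True) -> ParameterizedStructure:
    """Assign charges, GB radii and LJ parameters from a lookup table.

    In strict mode every (residue_name, atom_name) must be present;
    otherwise missing atoms get zero charge and element-based radii, and
    each default is recorded in the returned structure's ``remarks``.
    """
    missing = []
    atoms = []
    remarks = list(s.remarks)
    for a in s.atoms:
        vals = table.get(a.residue_name, a.atom_name)
        if vals is None:
            missing.append((a.residue_name, a.atom_name))
            r = _ELEMENT_DEFAULT_RADII.get(a.element, 1.7)
            atoms.append(replace(a, charge=0.0, gb_radius=r,
                                 vdw_rmin_half=r, lj_epsilon=0.05))
            remarks.append(f"defaulted parameters for "
                           f"{a.chain_id}/{a.residue_index}/{a.residue_name}/{a.atom_name}")
        else:
            q, rgb, rmh, eps = vals
            atoms.append(replace(a, charge=q, gb_radius=rgb,
                                 vdw_rmin_half=rmh, lj_epsilon=eps))
    if strict and missing:
        raise ParameterLookupError(sorted(set(missing)))
    out = ParameterizedStructure(atoms, dict(s.chains), s.title, remarks)
    for a in out.atoms:
        a.validate()
    return out


_ELEMENT_DEFAULT_EPS = {"H": 0.0157, "C": 0.1094, "N": 0.17, "O": 0.21,
                        "S": 0.25, "P": 0.2}


def fill_default_lj(s: ParameterizedStructure) -> ParameterizedStructure:
    """Fill missing LJ well depths with element-based defaults.

    PQR input carries charges and radii but no well depths; this supplies
    generic values so gas-phase terms can still be evaluated.  Each filled
    atom is noted in ``remarks``.
    """
    atoms, remarks = [], list(s.remarks)
    for a in s.atoms:
        if math.isnan(a.lj_epsilon):
            eps = _ELEMENT_DEFAULT_EPS.get(a.element, 0.1)
            atoms.append(replace(a, lj_epsilon=eps))
            remarks.append(f"default lj_epsilon {eps} for "
                           f"{a.chain_id}/{a.residue_index}/{a.atom_name}")
        else:
            atoms.append(a)
    return ParameterizedStructure(atoms, dict(s.chains), s.title, remarks)


def truncate_to_interface(s: ParameterizedStructure,
                          spec: InterfaceSpec) -> ParameterizedStructure:
    """Keep only the two interface domains (one residue range per subunit).

    Clamp subunits touch through the N-terminal domain of one subunit and
    the C-terminal domain of its neighbor; residues outside those domains
    contribute negligibly and are dropped.  Atom order and chain identity
    are preserved; applying the truncation twice equals applying it once.
    """
    def keep(a: AtomRecord) -> bool:
        if a.chain_id == spec.subunit_a:
            lo, hi = spec.domain_a
        elif a.chain_id == spec.subunit_b:
            lo, hi = spec.domain_b
        else:
            return False
        return lo <= a.residue_index <= hi

    atoms = [a for a in s.atoms if keep(a)]
    if not atoms:
        raise ValueError("interface truncation selected no atoms")
    for subunit in (spec.subunit_a, spec.subunit_b):
        if not any(a.chain_id == subunit for a in atoms):
            raise ValueError(f"domain range for subunit {subunit!r} selects no atoms")
    return ParameterizedStructure(atoms, title=s.title, remarks=list(s.remarks))


def axis_fraction(spec: InterfaceSpec, point) -> float:
    """Fractional position of ``point`` along the bottom->top interface axis.

    Orthogonal projection onto the anchor segment, clamped to [0, 1];
    1 is the top (IDCL) face, 0 the bottom face.
    """
    bottom = np.asarray(spec.bottom_anchor, dtype=float)
    top = np.asarray(spec.top_anchor, dtype=float)
    axis = top - bottom
    denom = float(axis @ axis)
    if denom == 0.0:
        raise ValueError("top and bottom anchors coincide")
    t = float((np.asarray(point, dtype=float) - bottom) @ axis) / denom
    return min(1.0, max(0.0, t))
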