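"""Structures, trajectories and atom selections.

The data model is deliberately small: a :class:`Topology` (atom/residue
identity and masses), a :class:`Frame` (positions plus an orthorhombic box)
and a :class:`Trajectory` (time-ordered frames).  Internal units are fixed
throughout the package: nanometres, picoseconds and atomic mass units.
PDB coordinates (Angstrom) are converted on read.

Supported formats
-----------------
* GRO, including concatenated multi-frame GRO (the plain-text fixture
  dialect used by the synthetic generator and the tests) — implemented
  here, since multi-frame GRO is not covered by trajectory libraries.
* PDB (single and multi-model) — read/written through MDAnalysis.
* XTC and DCD binary trajectories — read/written through MDAnalysis.

Only orthorhombic periodic boxes are supported; triclinic input raises
:class:`UnsupportedFormatError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "ParseError",
    "SelectionError",
    "UnsupportedFormatError",
    "ELEMENT_MASSES",
    "WATER_RESNAMES",
    "infer_element",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]


class ParseError(ValueError):
    """A file did not parse under the named format standard."""


class SelectionError(ValueError):
    """A selection expression is syntactically or semantically invalid."""


class UnsupportedFormatError(ValueError):
    """Input uses a feature outside the supported subset (e.g. triclinic box)."""


#: Standard atomic masses (amu) for the elements that occur in protein /
#: water / nucleotide / fatty-acid systems, plus common counter-ions.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
}

#: Residue names recognised as water; user-extensible via ``water_resnames``
#: arguments.  Dialects vary across PDB/GRO writers.
WATER_RESNAMES: frozenset[str] = frozenset({"SOL", "HOH", "WAT", "TIP3"})

# Atom names that unambiguously denote a two-letter element in biomolecular
# files (ion dialects).  Plain "CA"/"CB"... inside a protein residue are
# carbon; calcium only appears as its own residue, handled below.
_ION_NAMES = {"NA", "NA+", "SOD", "CL", "CL-", "CLA", "MG", "MG2", "K", "K+", "POT", "ZN", "FE"}


def infer_element(atom_name: str, resname: str = "") -> str | None:
    """Infer an element symbol from an atom name.

    Follows the usual biomolecular-file convention: strip leading digits,
    recognise ion dialect names, otherwise take the first letter.  Returns
    ``None`` when nothing matches the known element table.
    """
    name = atom_name.strip().upper()
    if not name:
        return None
    if name in _ION_NAMES or resname.strip().upper() in _ION_NAMES:
        key = name.rstrip("+-0123456789")
        if key in ("SOD",):
            return "NA"
        if key in ("CLA",):
            return "CL"
        if key in ("POT",):
            return "K"
        if key in ELEMENT_MASSES:
            return key
    stripped = name.lstrip("0123456789")
    if not stripped:
        return None
    first = stripped[0]
    if first in ELEMENT_MASSES:
        return first
    if stripped[:2] in ELEMENT_MASSES:
        return stripped[:2]
    return None


@dataclass(frozen=True)
class Topology:
    """Atom and residue identity of a system.

    Residues carry both the author-assigned ``resid`` (the numbering used in
    the literature, e.g. R60 or Asp35) and a contiguous 0-based
    ``resindex``; configuration files always use author numbering.
    """

    names: np.ndarray          # (n_atoms,) atom names
    resids: np.ndarray         # (n_atoms,) author residue numbers
    resnames: np.ndarray       # (n_atoms,) residue names
    resindices: np.ndarray     # (n_atoms,) 0-based residue index
    masses: np.ndarray         # (n_atoms,) amu

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resids", "resnames", "resindices", "masses"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} length mismatch")
        if n and not np.all(np.asarray(self.masses, dtype=float) > 0):
            raise ValueError("all atom masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resindices))

    def atoms(self) -> Iterable[tuple[int, str, int, str, int, float]]:
        """Yield (atom_index, atom_name, residue_index, residue_name, residue_id, mass)."""
        for i in range(self.n_atoms):
            yield (i, str(self.names[i]), int(self.resindices[i]),
                   str(self.resnames[i]), int(self.resids[i]), float(self.masses[i]))

    def residue_atoms(self, resid: int) -> np.ndarray:
        """Atom indices of the residue with author number ``resid``."""
        idx = np.flatnonzero(np.asarray(self.resids) == resid)
        if idx.size == 0:
            raise KeyError(f"residue id {resid} not present in topology")
        return idx


@dataclass
class Frame:
    """One trajectory frame: time (ps), positions (nm) and box edges (nm)."""

    time: float
    positions: np.ndarray      # (n_atoms, 3) nm
    box: np.ndarray            # (3,) orthorhombic edge lengths, nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """A topology plus time-ordered frames; ``dt`` is the nominal spacing (ps)."""

    topology: Topology
    frames: list[Frame]
    dt: float | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(f"frame {i} has {fr.n_atoms} atoms, topology has {n}")
        times = self.times
        if len(times) > 1:
            if not np.all(np.diff(times) > 0):
                raise ValueError("frame times must be strictly increasing")
            if self.dt is None:
                self.dt = float(np.median(np.diff(times)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    def coordinates(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Stacked positions, shape (n_frames, n_atoms_or_selected, 3)."""
        if indices is None:
            return np.stack([fr.positions for fr in self.frames])
        indices = np.asarray(indices)
        return np.stack([fr.positions[indices] for fr in self.frames])

    def boxes(self) -> np.ndarray:
        return np.stack([fr.box for fr in self.frames])


@dataclass(frozen=True)
class Selection:
    """A labelled, ordered, duplicate-free set of atom indices."""

    label: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices contain duplicates")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# mass assignment

def assign_masses(
    names: Sequence[str],
    resnames: Sequence[str],
    mass_table: Mapping[str, float] | None = None,
    default_mass: float | None = None,
) -> np.ndarray:
    """Masses (amu) from element inference, overridable per atom name.

    ``mass_table`` maps atom names (exact, case-sensitive) to masses and
    takes precedence over element inference.  Unknown elements raise unless
    ``default_mass`` enables a fallback policy.
    """
    masses = np.empty(len(names), dtype=float)
    for i, (name, resname) in enumerate(zip(names, resnames)):
        if mass_table and name in mass_table:
            masses[i] = mass_table[name]
            continue
        elem = infer_element(name, resname)
        if elem is None:
            if default_mass is None:
                raise ValueError(
                    f"cannot infer element for atom name {name!r} "
                    "(supply a mass_table entry or a default_mass)"
                )
            masses[i] = default_mass
        else:
            masses[i] = ELEMENT_MASSES[elem]
    return masses


# ---------------------------------------------------------------------------
# GRO reading/writing (single- and multi-frame)

def _parse_gro_block(lines: list[str], start: int, path: str):
    """Parse one GRO frame starting at ``lines[start]``.

    Returns (names, resids, resnames, positions, box, time, next_line_index).
    """
    title = lines[start]
    time = None
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            time = None
    try:
        natoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(f"{path}: line {start + 2}: expected atom count")
    end = start + 2 + natoms
    if end >= len(lines):
        raise EOFError("truncated frame")
    names, resids, resnames = [], [], []
    positions = np.empty((natoms, 3), dtype=float)
    for j in range(natoms):
        ln = lines[start + 2 + j]
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            positions[j, 0] = float(ln[20:28])
            positions[j, 1] = float(ln[28:36])
            positions[j, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {start + 3 + j}: malformed GRO atom record")
    box_fields = lines[end].split()
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError:
        raise ParseError(f"{path}: line {end + 1}: malformed box line")
    if len(box_vals) == 3:
        box = np.array(box_vals)
    elif len(box_vals) == 9:
        if any(abs(v) > 1e-9 for v in box_vals[3:]):
            raise UnsupportedFormatError(
                f"{path}: triclinic box not supported (only orthorhombic)"
            )
        box = np.array(box_vals[:3])
    else:
        raise ParseError(f"{path}: line {end + 1}: box line needs 3 or 9 values")
    return names, resids, resnames, positions, box, time, end + 1


def _resindices_from_resids(resids: Sequence[int]) -> np.ndarray:
    """Contiguous 0-based residue indices from consecutive author ids."""
    resindices = np.empty(len(resids), dtype=int)
    current = -1
    prev = None
    for i, rid in enumerate(resids):
        if rid != prev:
            current += 1
            prev = rid
        resindices[i] = current
    return resindices


def _read_gro_frames(path: str | Path, max_frames: int | None = None):
    lines = Path(path).read_text().splitlines()
    out = []
    pos = 0
    while pos < len(lines) and lines[pos].strip() != "":
        try:
            out.append(_parse_gro_block(lines, pos, str(path)))
        except EOFError:
            warnings.warn(f"{path}: truncated final frame dropped")
            break
        pos = out[-1][-1]
        if max_frames is not None and len(out) >= max_frames:
            break
    if not out:
        raise ParseError(f"{path}: no GRO frames found")
    return out


def _write_gro_frame(fh, topology: Topology, frame: Frame, title: str) -> None:
    fh.write(f"{title}, t= {frame.time:.5f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    for i in range(topology.n_atoms):
        fh.write(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
            % (
                int(topology.resids[i]) % 100000,
                str(topology.resnames[i])[:5],
                str(topology.names[i])[:5],
                (i + 1) % 100000,
                frame.positions[i, 0],
                frame.positions[i, 1],
                frame.positions[i, 2],
            )
        )
    fh.write("%10.5f%10.5f%10.5f\n" % tuple(frame.box))


# ---------------------------------------------------------------------------
# MDAnalysis bridge (PDB, XTC, DCD)

def _mda():
    import MDAnalysis as mda  # deferred import: heavy

    return mda


def _box_from_dimensions(dims, path) -> np.ndarray:
    if dims is None or not np.all(np.asarray(dims[:3]) > 0):
        raise ParseError(f"{path}: no usable box record (CRYST1 or equivalent required)")
    if not np.allclose(dims[3:6], 90.0, atol=1e-2):
        raise UnsupportedFormatError(f"{path}: triclinic box not supported (angles {dims[3:6]})")
    return np.asarray(dims[:3], dtype=float) / 10.0


def _universe_from(topology: Topology) -> "object":
    mda = _mda()
    n_res = topology.n_residues
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        atom_resindex=np.asarray(topology.resindices),
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(s) for s in topology.names])
    first = np.searchsorted(np.asarray(topology.resindices), np.arange(n_res))
    u.add_TopologyAttr("resids", np.asarray(topology.resids)[first])
    u.add_TopologyAttr("resnames", [str(topology.resnames[i]) for i in first])
    u.add_TopologyAttr("masses", np.asarray(topology.masses))
    return u


# ---------------------------------------------------------------------------
# public I/O API

_STRUCTURE_FORMATS = {"GRO", "PDB"}
_TRAJ_FORMATS = {"GRO", "PDB", "XTC", "DCD"}


def _infer_format(path: str | Path, allowed: set[str]) -> str:
    fmt = Path(path).suffix.lstrip(".").upper()
    if fmt not in allowed:
        raise UnsupportedFormatError(f"cannot infer a supported format from {path!r}")
    return fmt


def read_structure(
    path: str | Path,
    format: str | None = None,
    mass_table: Mapping[str, float] | None = None,
    default_mass: float | None = None,
) -> tuple[Topology, Frame]:
    """Read a single-frame structure (GRO or PDB) into (Topology, Frame).

    Masses are assigned from the element inferred from each atom name;
    ``mass_table`` overrides per atom name and ``default_mass`` enables a
    fallback for unrecognisable names (otherwise they are an error).
    """
    fmt = (format or _infer_format(path, _STRUCTURE_FORMATS)).upper()
    if fmt == "GRO":
        names, resids, resnames, positions, box, time, _ = _read_gro_frames(path, max_frames=1)[0]
        topo = Topology(
            names=np.array(names, dtype=object),
            resids=np.array(resids, dtype=int),
            resnames=np.array(resnames, dtype=object),
            resindices=_resindices_from_resids(resids),
            masses=assign_masses(names, resnames, mass_table, default_mass),
        )
        return topo, Frame(time=time or 0.0, positions=positions, box=box)
    if fmt == "PDB":
        mda = _mda()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        names = [str(n) for n in u.atoms.names]
        resnames = [str(r) for r in u.atoms.resnames]
        topo = Topology(
            names=np.array(names, dtype=object),
            resids=np.asarray(u.atoms.resids, dtype=int),
            resnames=np.array(resnames, dtype=object),
            resindices=np.asarray(u.atoms.resindices, dtype=int),
            masses=assign_masses(names, resnames, mass_table, default_mass),
        )
        box = _box_from_dimensions(u.dimensions, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = u.trajectory.ts
            time = float(ts.time) if np.isfinite(ts.time) else 0.0
        return topo, Frame(time=time, positions=u.atoms.positions / 10.0, box=box)
    raise UnsupportedFormatError(f"unsupported structure format {fmt!r}")


def write_structure(path: str | Path, topology: Topology, frame: Frame,
                    format: str | None = None, title: str = "poreflow structure") -> None:
    fmt = (format or _infer_format(path, _STRUCTURE_FORMATS)).upper()
    if fmt == "GRO":
        with open(path, "w") as fh:
            _write_gro_frame(fh, topology, frame, title)
        return
    if fmt == "PDB":
        u = _universe_from(topology)
        u.atoms.positions = frame.positions * 10.0
        u.trajectory.ts.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
        return
    raise UnsupportedFormatError(f"unsupported structure format {fmt!r}")


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a trajectory (XTC, DCD, or multi-frame GRO/PDB) onto ``topology``.

    Times come from the file when present; otherwise they are synthesised as
    ``frame_index * dt``.  An atom-count mismatch is an error, never a
    silent truncation.
    """
    fmt = (format or _infer_format(path, _TRAJ_FORMATS)).upper()
    frames: list[Frame] = []
    if fmt == "GRO":
        blocks = _read_gro_frames(path)
        for i, (names, _r, _rn, positions, box, time, _next) in enumerate(blocks):
            if len(names) != topology.n_atoms:
                raise ValueError(
                    f"{path}: frame {i} has {len(names)} atoms, topology has {topology.n_atoms}"
                )
            frames.append(Frame(time=time if time is not None else i * dt,
                                positions=positions, box=box))
    elif fmt in ("PDB", "XTC", "DCD"):
        mda = _mda()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "PDB":
                u = mda.Universe(str(path))
            else:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(path), format=fmt)
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: file has {u.atoms.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        raw_times = []
        # multi-model PDBs may carry one file-level CRYST1 that the frame
        # iterator does not propagate: parse it as the fallback box
        last_box = None
        if u.dimensions is not None and np.all(np.asarray(u.dimensions[:3]) > 0):
            last_box = _box_from_dimensions(u.dimensions, path)
        elif fmt == "PDB":
            for line in Path(path).read_text().splitlines():
                if line.startswith("CRYST1"):
                    vals = [float(line[6 + 9 * k : 15 + 9 * k]) for k in range(3)]
                    angles = [float(line[33 + 7 * k : 40 + 7 * k]) for k in range(3)]
                    last_box = _box_from_dimensions(np.array(vals + angles), path)
                    break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                if ts.dimensions is not None and np.all(np.asarray(ts.dimensions[:3]) > 0):
                    last_box = _box_from_dimensions(ts.dimensions, path)
                if last_box is None:
                    raise ParseError(
                        f"{path}: no usable box record (CRYST1 or equivalent required)"
                    )
                raw_times.append(float(ts.time) if np.isfinite(ts.time) else 0.0)
                frames.append(Frame(time=raw_times[-1], positions=u.atoms.positions / 10.0,
                                    box=last_box))
        # files without real time stamps come back constant/zero: synthesise
        if len(frames) > 1 and not np.all(np.diff(raw_times) > 0):
            for i, fr in enumerate(frames):
                fr.time = i * dt
    else:
        raise UnsupportedFormatError(f"unsupported trajectory format {fmt!r}")
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(path: str | Path, traj: Trajectory, format: str | None = None,
                     title: str = "poreflow trajectory") -> None:
    fmt = (format or _infer_format(path, _TRAJ_FORMATS)).upper()
    if fmt == "GRO":
        with open(path, "w") as fh:
            for frame in traj.frames:
                _write_gro_frame(fh, traj.topology, frame, title)
        return
    mda = _mda()
    u = _universe_from(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms,
                        multiframe=True, format=fmt) as w:
            for frame in traj.frames:
                u.atoms.positions = frame.positions * 10.0
                u.trajectory.ts.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
                u.trajectory.ts.time = frame.time
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection mini-grammar
#
#   expr    := or
#   or      := and ("or" and)*
#   and     := not ("and" not)*
#   not     := "not" not | primary
#   primary := "(" expr ")" | "water" | "name" WORD+ | "resname" WORD+
#              | "resid" (INT | INT-INT)+

_KEYWORDS = {"and", "or", "not", "name", "resname", "resid", "water"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _SelParser:
    def __init__(self, expression: str, topology: Topology, water_resnames: frozenset[str]):
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.topo = topology
        self.water_resnames = water_resnames

    def _err(self, msg: str) -> SelectionError:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expr)
        return SelectionError(f"selection syntax error at position {at}: {msg} (in {self.expr!r})")

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            raise self._err(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() == "and":
            self.take()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.parse_not()
        return self.parse_primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS and self.peek() not in "()":
            vals.append(self.take())
        if not vals:
            raise self._err("expected one or more values")
        return vals

    def parse_primary(self) -> np.ndarray:
        tok = self.take()
        if tok == "(":
            mask = self.parse_or()
            if self.take() != ")":
                raise self._err("expected ')'")
            return mask
        if tok == "water":
            resnames = np.array([str(r).upper() for r in self.topo.resnames])
            return np.isin(resnames, sorted(self.water_resnames))
        if tok == "name":
            vals = self._values()
            return np.isin(np.array([str(n) for n in self.topo.names]), vals)
        if tok == "resname":
            vals = self._values()
            return np.isin(np.array([str(n) for n in self.topo.resnames]), vals)
        if tok == "resid":
            vals = self._values()
            mask = np.zeros(self.topo.n_atoms, dtype=bool)
            resids = np.asarray(self.topo.resids)
            for v in vals:
                if "-" in v[1:]:
                    lo_s, hi_s = v.split("-", 1) if not v.startswith("-") else v[1:].split("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise self._err(f"bad resid range {v!r}")
                    mask |= (resids >= lo) & (resids <= hi)
                else:
                    try:
                        mask |= resids == int(v)
                    except ValueError:
                        raise self._err(f"bad resid {v!r}")
            return mask
        raise self._err(f"unknown token {tok!r}")


def select(
    topology: Topology,
    expression: str,
    water_resnames: Iterable[str] | None = None,
    label: str | None = None,
) -> Selection:
    """Resolve a selection expression against a topology.

    The grammar supports ``name``, ``resname``, ``resid`` (ints and
    ``lo-hi`` ranges), ``water`` and the combinators ``and``/``or``/``not``
    with parentheses.  The result is deterministic and order-preserving
    (ascending atom index).  An empty result warns but is returned.
    """
    wset = frozenset(s.upper() for s in water_resnames) if water_resnames else WATER_RESNAMES
    mask = _SelParser(expression, topology, wset).parse()
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(label=label or expression, indices=indices)
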