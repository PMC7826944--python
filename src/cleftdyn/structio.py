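"""Structures, trajectories, coordinate I/O and atom selections.

Internal units are nm for lengths and ps for times (GROMACS convention);
conversion to/from Å happens only at the PDB boundary.  PDB parsing and
writing are delegated to biotite, DCD/XTC to mdtraj's low-level format
readers; this module owns the in-memory types and the selection grammar
that every downstream analysis consumes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .errors import (
    PDBFormatError,
    PDBParseError,
    SelectionError,
    TopologyError,
    TrajectoryFormatError,
)

ANGSTROM_PER_NM = 10.0

#: standard atomic masses in Da, keyed by element symbol (upper case)
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546,
    "NI": 58.693, "CO": 58.933, "CD": 112.414,
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
}

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC", "H2O"}

BACKBONE_NAMES = {"N", "CA", "C", "O"}

_TWO_LETTER_ELEMENTS = {
    "ZN", "FE", "MG", "MN", "CU", "NI", "CO", "NA", "CL", "BR", "SE", "CD",
}


def infer_element(atom_name: str, resname: str = "") -> str:
    """Guess the element from a PDB atom name.

    Handles monatomic ions (ZN, NA, CL...), hydrogens with leading digits
    (1HB2) and ordinary organic atoms where the first letter is the element.
    """
    name = atom_name.strip().upper()
    if not name:
        return ""
    if name in _TWO_LETTER_ELEMENTS or resname.strip().upper() in _TWO_LETTER_ELEMENTS:
        return name if name in _TWO_LETTER_ELEMENTS else resname.strip().upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    return stripped[0]


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        warnings.warn(f"unknown element {element!r}; assigning mass 12.011")
        return 12.011


class Atom(NamedTuple):
    """One atom record; position in nm."""

    serial: int
    name: str
    element: str
    mass: float
    resname: str
    resid: int
    chain: str
    position: np.ndarray


class Structure:
    """An ordered set of atoms with residue/chain identity (array backed).

    Residues are contiguous runs of equal ``(chain, resid)``;
    ``(chain, resid, name)`` is unique within a structure.
    """

    def __init__(
        self,
        *,
        names: Sequence[str],
        elements: Sequence[str],
        masses: Sequence[float],
        resnames: Sequence[str],
        resids: Sequence[int],
        chains: Sequence[str],
        coords: np.ndarray,
        serials: Sequence[int] | None = None,
        title: str = "",
    ):
        self.names = np.asarray(names, dtype=object)
        n = len(self.names)
        if n == 0:
            raise ValueError("Structure may not be empty")
        self.elements = np.asarray(elements, dtype=object)
        self.masses = np.asarray(masses, dtype=float)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atomic mass")
        self.serials = (
            np.arange(1, n + 1) if serials is None else np.asarray(serials, dtype=int)
        )
        self.title = title
        keys = list(zip(self.chains, self.resids, self.names))
        if len(set(keys)) != n:
            raise ValueError("(chain, resid, name) must be unique within a Structure")

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __getitem__(self, i: int) -> Atom:
        return Atom(
            int(self.serials[i]), str(self.names[i]), str(self.elements[i]),
            float(self.masses[i]), str(self.resnames[i]), int(self.resids[i]),
            str(self.chains[i]), self.coords[i].copy(),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self[i] for i in range(len(self)))

    @property
    def atoms(self) -> list[Atom]:
        return list(self)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chains, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_index(self) -> np.ndarray:
        """Per-atom integer residue index (contiguous runs)."""
        keys = list(zip(self.chains, self.resids))
        order = {k: i for i, k in enumerate(dict.fromkeys(keys))}
        return np.array([order[k] for k in keys], dtype=int)

    def atom_key(self, i: int) -> tuple[str, int, str]:
        return (str(self.chains[i]), int(self.resids[i]), str(self.names[i]))

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        return Structure(
            names=self.names, elements=self.elements, masses=self.masses,
            resnames=self.resnames, resids=self.resids, chains=self.chains,
            coords=coords, serials=self.serials,
            title=self.title if title is None else title,
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            names=self.names[idx], elements=self.elements[idx],
            masses=self.masses[idx], resnames=self.resnames[idx],
            resids=self.resids[idx], chains=self.chains[idx],
            coords=self.coords[idx], serials=self.serials[idx], title=self.title,
        )

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], title: str = "") -> "Structure":
        return cls(
            names=[a.name for a in atoms],
            elements=[a.element for a in atoms],
            masses=[a.mass for a in atoms],
            resnames=[a.resname for a in atoms],
            resids=[a.resid for a in atoms],
            chains=[a.chain for a in atoms],
            coords=np.array([a.position for a in atoms], dtype=float),
            serials=[a.serial for a in atoms],
            title=title,
        )


@dataclass
class Trajectory:
    """A reference topology plus time-stamped coordinate frames (nm, ps)."""

    topology: Structure
    times: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise ValueError("len(times) != len(frames)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frames(self) -> np.ndarray:
        return self.coords

    def __len__(self) -> int:
        return self.n_frames

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.topology, self.times[::stride], self.coords[::stride])


@dataclass(frozen=True)
class Selection:
    """An ordered set of atom indices into a Structure."""

    indices: np.ndarray
    n_atoms: int
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if len(idx) and (idx[0] < 0 or idx[-1] >= self.n_atoms):
            raise SelectionError("selection index out of range")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(np.intersect1d(self.indices, other.indices), self.n_atoms)

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(np.union1d(self.indices, other.indices), self.n_atoms)

    def __invert__(self) -> "Selection":
        mask = np.ones(self.n_atoms, dtype=bool)
        mask[self.indices] = False
        return Selection(np.nonzero(mask)[0], self.n_atoms)


# =============================================================================
# Selection grammar
# =============================================================================
#
#   expr     := or_expr
#   or_expr  := and_expr ( "or" and_expr )*
#   and_expr := unary ( "and" unary )*
#   unary    := "not" unary | "(" expr ")" | predicate
#   predicate:= "chain" VALUE+ | "resname" VALUE+ | "name" VALUE+
#             | "resid" (INT | INT ":" INT)+
#             | "backbone" | "heavy" | "water" | "protein" | "all"
#
# Value lists are greedy: ``name N CA C O`` selects four atom names.

_KEYWORDS = {
    "and", "or", "not", "(", ")",
    "chain", "resid", "resname", "name",
    "backbone", "heavy", "water", "protein", "all",
}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for m in re.finditer(r"\(|\)|[^\s()]+", expr):
        out.append((m.group(0), m.start()))
    return out


class _Parser:
    def __init__(self, s: Structure, expr: str):
        self.s = s
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def _err(self, msg: str) -> SelectionError:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expr)
        return SelectionError(f"{msg} (at position {at} in {self.expr!r})")

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise self._err(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.peek() != ")":
                raise self._err("expected ')'")
            self.take()
            return mask
        return self.predicate()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise self._err("expected at least one value")
        return vals

    def predicate(self) -> np.ndarray:
        s = self.s
        tok = self.take()
        if tok == "chain":
            vals = set(self._values())
            return np.isin(s.chains.astype(str), list(vals))
        if tok == "resname":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(s.resnames.astype(str)), list(vals))
        if tok == "name":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(s.names.astype(str)), list(vals))
        if tok == "resid":
            mask = np.zeros(s.n_atoms, dtype=bool)
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", v)
                if not m:
                    self.pos -= 1
                    raise self._err(f"bad resid value {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask |= (s.resids >= lo) & (s.resids <= hi)
            return mask
        if tok == "backbone":
            return np.isin(np.char.upper(s.names.astype(str)), list(BACKBONE_NAMES)) & \
                np.isin(np.char.upper(s.resnames.astype(str)), list(AMINO_ACIDS))
        if tok == "heavy":
            return np.char.upper(s.elements.astype(str)) != "H"
        if tok == "water":
            return np.isin(np.char.upper(s.resnames.astype(str)), list(WATER_RESNAMES))
        if tok == "protein":
            return np.isin(np.char.upper(s.resnames.astype(str)), list(AMINO_ACIDS))
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        self.pos -= 1
        raise self._err(f"unknown keyword {tok!r}")


def select(s: Structure, expr: str) -> Selection:
    """Resolve a selection expression against a structure.

    Empty results are legal but flagged with a warning so silently wrong
    residue numbers in configs do not pass unnoticed.
    """
    mask = _Parser(s, expr).parse()
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        warnings.warn(f"selection {expr!r} matched no atoms")
    return Selection(idx, s.n_atoms, label=expr)


def residue_selection(s: Structure, chain: str, resid: int) -> Selection:
    mask = (s.chains.astype(str) == chain) & (s.resids == resid)
    return Selection(np.nonzero(mask)[0], s.n_atoms, label=f"chain {chain} and resid {resid}")


# =============================================================================
# PDB I/O (biotite backend)
# =============================================================================

_TIME_REMARK = re.compile(r"REMARK\s+250\s+TIME:\s*([-+0-9.eE]+)\s*PS", re.I)


def _scan_for_bad_atom_line(path: Path) -> None:
    """Name the first malformed ATOM/HETATM record, if any."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise PDBParseError(
                        f"unparseable ATOM/HETATM record at line {lineno} of {path}"
                    ) from None


def _structure_from_atom_array(arr, title: str) -> Structure:
    # altloc policy: keep blank/'.'/'A' records only (crystal inputs feed
    # geometry, not ensembles)
    if "altloc_id" in arr.get_annotation_categories():
        keep = np.isin(arr.altloc_id, ["", " ", ".", "A"])
        arr = arr[..., keep]
    elements = []
    for el, name, resname in zip(arr.element, arr.atom_name, arr.res_name):
        el = str(el).strip()
        elements.append(el.upper() if el else infer_element(str(name), str(resname)))
    masses = [mass_of(e) for e in elements]
    coords = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    serials = (
        arr.atom_id if "atom_id" in arr.get_annotation_categories() else None
    )
    return Structure(
        names=[str(x) for x in arr.atom_name],
        elements=elements,
        masses=masses,
        resnames=[str(x) for x in arr.res_name],
        resids=[int(x) for x in arr.res_id],
        chains=[str(x) for x in arr.chain_id],
        coords=coords if coords.ndim == 2 else coords,
        serials=None if serials is None else [int(x) for x in serials],
        title=title,
    )


def read_pdb(path: str | Path, dt_ps: float = 1.0) -> Structure | Trajectory:
    """Read a (possibly multi-model) PDB file.

    Coordinates are converted Å→nm.  A single-model file yields a
    ``Structure``; a multi-model file yields a ``Trajectory`` whose times
    come from ``REMARK 250 TIME: <t> PS`` records when present, else are
    uniform with spacing ``dt_ps``.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pf = PDBFile.read(str(path))
        n_models = pf.get_model_count()
    except Exception as exc:
        _scan_for_bad_atom_line(path)
        raise PDBFormatError(f"cannot read PDB {path}: {exc}") from exc
    if n_models == 0:
        raise PDBFormatError(f"{path} contains no ATOM/HETATM records")

    title = ""
    for line in pf.lines:
        if line.startswith("TITLE"):
            title = line[10:].strip()
            break

    try:
        arr = pf.get_structure(
            model=1 if n_models == 1 else None,
            altloc="all",
            extra_fields=["atom_id"],
        )
    except Exception as exc:
        _scan_for_bad_atom_line(path)
        raise PDBFormatError(
            f"inconsistent or malformed models in {path}: {exc}"
        ) from exc

    if n_models == 1:
        return _structure_from_atom_array(arr, title)

    # multi-model → Trajectory; altloc filter must be applied consistently
    if "altloc_id" in arr.get_annotation_categories():
        keep = np.isin(arr.altloc_id, ["", " ", ".", "A"])
        arr = arr[..., keep]
    top = _structure_from_atom_array(arr[0], title)
    coords = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    times = [float(m.group(1)) for line in pf.lines if (m := _TIME_REMARK.search(line))]
    if len(times) == n_models:
        t = np.asarray(times)
    else:
        t = np.arange(n_models, dtype=float) * dt_ps
    return Trajectory(top, t, coords)


def _to_atom_array(s: Structure):
    import biotite.structure as bst

    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords * ANGSTROM_PER_NM
    arr.atom_name = s.names.astype(str)
    arr.res_name = s.resnames.astype(str)
    arr.res_id = s.resids
    arr.chain_id = s.chains.astype(str)
    arr.element = s.elements.astype(str)
    arr.set_annotation("atom_id", s.serials)
    hetero = ~np.isin(np.char.upper(s.resnames.astype(str)), list(AMINO_ACIDS))
    arr.hetero = hetero
    return arr


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) PDB.

    Trajectory times are stored as ``REMARK 250 TIME: <t> PS`` lines so the
    round trip preserves them.
    """
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pf = PDBFile()
    if isinstance(obj, Trajectory):
        top = obj.topology
        stack = bst.stack([_to_atom_array(top)] * obj.n_frames)
        stack.coord = obj.coords * ANGSTROM_PER_NM
        pf.set_structure(stack)
        lines, k = [], 0
        for line in pf.lines:
            lines.append(line)
            if line.startswith("MODEL"):
                lines.append(f"REMARK 250 TIME: {obj.times[k]:.6f} PS")
                k += 1
        pf.lines = lines
    else:
        pf.set_structure(_to_atom_array(obj))
        if obj.title:
            pf.lines = [f"TITLE     {obj.title}"] + pf.lines
    pf.write(str(path))


# =============================================================================
# DCD / XTC I/O (mdtraj backend)
# =============================================================================


def read_traj(
    coords_path: str | Path,
    topology: Structure,
    *,
    stride: int = 1,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Read a DCD or XTC coordinate file against a known topology.

    DCD files carry no timestamps; frames are stamped uniformly with
    ``dt_ps`` spacing.  XTC timestamps are honoured.  ``stride`` subsamples
    on read.
    """
    path = Path(coords_path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        try:
            with DCDTrajectoryFile(str(path)) as fh:
                xyz, _, _ = fh.read(stride=stride)
        except Exception as exc:
            raise TrajectoryFormatError(f"cannot read DCD {path}: {exc}") from exc
        if xyz is None or len(xyz) == 0:
            raise TrajectoryFormatError(f"{path} contains no frames")
        coords = np.asarray(xyz, dtype=float) / ANGSTROM_PER_NM
        times = np.arange(len(coords), dtype=float) * dt_ps * stride
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        try:
            with XTCTrajectoryFile(str(path)) as fh:
                xyz, times, _, _ = fh.read(stride=stride)
        except Exception as exc:
            raise TrajectoryFormatError(f"cannot read XTC {path}: {exc}") from exc
        if xyz is None or len(xyz) == 0:
            raise TrajectoryFormatError(f"{path} contains no frames")
        coords = np.asarray(xyz, dtype=float)
        times = np.asarray(times, dtype=float)
    elif suffix == ".pdb":
        out = read_pdb(path, dt_ps=dt_ps)
        if isinstance(out, Structure):
            out = Trajectory(out, np.zeros(1), out.coords[None])
        coords, times = out.coords[::stride], out.times[::stride]
    else:
        raise TrajectoryFormatError(f"unsupported trajectory format {suffix!r}")
    if coords.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"{path} has {coords.shape[1]} atoms per frame; "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(topology, times, coords)


def write_traj(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as DCD (Å internally), XTC (nm, with times) or
    multi-model PDB, chosen by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(traj.coords, dtype=np.float32) * ANGSTROM_PER_NM)
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as fh:
            fh.write(
                np.asarray(traj.coords, dtype=np.float32),
                time=np.asarray(traj.times, dtype=np.float32),
                step=np.arange(traj.n_frames),
            )
    elif suffix == ".pdb":
        write_pdb(traj, path)
    else:
        raise TrajectoryFormatError(f"unsupported trajectory format {suffix!r}")
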