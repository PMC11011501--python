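"""Structure and trajectory I/O plus atom selection.

All coordinates are in Angstrom internally.  File parsing is delegated to
MDAnalysis (PDB v3.3, GRO, XTC, DCD, multi-model PDB); this module converts
between MDAnalysis universes and the plain array-backed containers the
analysis layers consume.

Residue numbering is always the author numbering of the input file: the
analyses refer to residues such as R427 or H248 by that numbering and no
renumbering is ever performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Two-letter element symbols that occur as the first two characters of PDB
# atom names; needed to infer elements when the file omits them.
_TWO_LETTER = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "NA", "CA2", "SE", "CU", "NI", "CO",
}


class FormatError(ValueError):
    """A structure/trajectory file does not parse under its named format."""


class SelectionError(ValueError):
    """A selection expression is malformed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB-style atom name.

    Digits and primes are stripped; a leading two-letter symbol (FE, CL, ...)
    is honoured, otherwise the first alphabetic character is taken.
    """
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _TWO_LETTER and len(stripped) >= 2:
        return two.capitalize()
    return stripped[0].upper()


@dataclass
class Structure:
    """An ordered set of atoms with Angstrom coordinates.

    Arrays are parallel over atoms.  ``resids`` carry author numbering;
    ``occupancies`` may be NaN where the input format has no such field.
    """

    names: np.ndarray          # str, atom names
    elements: np.ndarray       # str, element symbols
    resnames: np.ndarray       # str
    resids: np.ndarray         # int, author numbering
    chainids: np.ndarray       # str
    coords: np.ndarray         # (N, 3) float, Angstrom
    occupancies: np.ndarray | None = None
    box: np.ndarray | None = None   # 3 lengths in Angstrom, optional

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for attr in ("names", "elements", "resnames", "chainids"):
            arr = np.asarray(getattr(self, attr), dtype=object)
            if len(arr) != n:
                raise ValueError(f"{attr} length {len(arr)} != {n} atoms")
            setattr(self, attr, arr)
        self.resids = np.asarray(self.resids, dtype=int)
        if len(self.resids) != n:
            raise ValueError("resids length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue key 'chain:RESNAME:resid' (e.g. 'A:ARG:427')."""
        return np.array(
            [f"{c}:{rn}:{ri}"
             for c, rn, ri in zip(self.chainids, self.resnames, self.resids)],
            dtype=object,
        )

    def subset(self, indices: np.ndarray | list[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            names=self.names[idx],
            elements=self.elements[idx],
            resnames=self.resnames[idx],
            resids=self.resids[idx],
            chainids=self.chainids[idx],
            coords=self.coords[idx].copy(),
            occupancies=None if self.occupancies is None else self.occupancies[idx],
            box=None if self.box is None else self.box.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = Structure(
            names=self.names, elements=self.elements, resnames=self.resnames,
            resids=self.resids, chainids=self.chainids,
            coords=np.asarray(coords, dtype=float),
            occupancies=self.occupancies, box=self.box,
        )
        return out


@dataclass
class Trajectory:
    """A topology plus T coordinate frames in Angstrom."""

    topology: Structure
    frames: np.ndarray               # (T, N, 3)
    frame_index: np.ndarray = None   # strictly increasing ints
    source_id: str = "traj0"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (T, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.frame_index is None:
            self.frame_index = np.arange(self.frames.shape[0])
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if len(self.frame_index) != self.frames.shape[0]:
            raise ValueError("frame_index length mismatch")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, t: int) -> Structure:
        return self.topology.with_coords(self.frames[t])


@dataclass
class AtomSelection:
    """Ordered, unique, in-bounds atom indices plus their source expression."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) and (
            np.any(np.diff(self.indices) <= 0) or self.indices.min() < 0
        ):
            raise ValueError("indices must be unique, ascending, non-negative")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# MDAnalysis bridge

def _universe_to_structure(u) -> Structure:
    atoms = u.atoms
    try:
        elements = np.array([str(e) for e in atoms.elements], dtype=object)
        if any(not e or e == "X" for e in elements):
            raise AttributeError
    except Exception:
        elements = np.array([infer_element(n) for n in atoms.names], dtype=object)
    try:
        chainids = np.array([str(c) for c in atoms.chainIDs], dtype=object)
    except Exception:
        chainids = np.array([str(s) for s in atoms.segids], dtype=object)
    chainids = np.array(
        [c if c and c.strip() and c != "SYSTEM" else "A" for c in chainids],
        dtype=object,
    )
    try:
        occ = np.asarray(atoms.occupancies, dtype=float)
    except Exception:
        occ = None
    dims = u.dimensions
    box = None
    if dims is not None and np.all(dims[:3] > 0):
        box = np.asarray(dims[:3], dtype=float)
    return Structure(
        names=np.array([str(n) for n in atoms.names], dtype=object),
        elements=elements,
        resnames=np.array([str(r) for r in atoms.resnames], dtype=object),
        resids=np.asarray(atoms.resids, dtype=int),
        chainids=chainids,
        coords=atoms.positions.astype(float),
        occupancies=occ,
        box=box,
    )


def structure_to_universe(s: Structure):
    """Build an in-memory MDAnalysis Universe mirroring a Structure."""
    import MDAnalysis as mda

    n = s.n_atoms
    # consecutive (chain, resid, resname) runs become residues
    res_index = np.zeros(n, dtype=int)
    r = 0
    for i in range(1, n):
        if (s.resids[i] != s.resids[i - 1]
                or s.chainids[i] != s.chainids[i - 1]
                or s.resnames[i] != s.resnames[i - 1]):
            r += 1
        res_index[i] = r
    n_res = r + 1
    first = np.zeros(n_res, dtype=int)
    seen = {}
    for i, ri in enumerate(res_index):
        if ri not in seen:
            seen[ri] = i
            first[ri] = i
    seg_labels = sorted({str(c) for c in s.chainids})
    seg_of = {c: k for k, c in enumerate(seg_labels)}
    res_seg = np.array([seg_of[str(s.chainids[f])] for f in first], dtype=int)

    u = mda.Universe.empty(
        n, n_residues=n_res, n_segments=len(seg_labels),
        atom_resindex=res_index, residue_segindex=res_seg, trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in s.names])
    u.add_TopologyAttr("elements", [str(x) for x in s.elements])
    u.add_TopologyAttr("resnames", [str(s.resnames[f]) for f in first])
    u.add_TopologyAttr("resids", [int(s.resids[f]) for f in first])
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs", [str(x) for x in s.chainids])
    u.add_TopologyAttr("occupancies",
                       np.ones(n) if s.occupancies is None else s.occupancies)
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.add_TopologyAttr("record_types", ["ATOM"] * n)
    u.atoms.positions = s.coords
    if s.box is not None:
        u.dimensions = [*s.box, 90.0, 90.0, 90.0]
    return u


# ---------------------------------------------------------------------------
# Readers / writers

def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or GRO file into a Structure (coordinates in Angstrom).

    GRO coordinates (nm) are converted to Angstrom by MDAnalysis on read.
    Author residue numbering is preserved.  Raises FormatError on files that
    do not parse; unknown elements are inferred from atom names with a
    warning.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure format: {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return _universe_to_structure(u)


def read_trajectory(
    topology: Structure,
    path: str | Path,
    format: str | None = None,
    source_id: str | None = None,
) -> Trajectory:
    """Read XTC/DCD/multi-model-PDB frames against a Structure topology.

    Frames are loaded in file order and normalised to Angstrom.  An
    atom-count mismatch with the topology, or an empty trajectory, is a hard
    error.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("xtc", "dcd", "pdb"):
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    u_top = structure_to_universe(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(u_top._topology, str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001
        msg = str(exc)
        if "atom" in msg.lower() or "shape" in msg.lower():
            raise ValueError(
                f"atom count mismatch between topology ({topology.n_atoms}) "
                f"and trajectory {path}: {exc}"
            ) from exc
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"atom count mismatch: topology {topology.n_atoms}, "
                    f"frame has {ts.n_atoms}"
                )
            frames.append(u.atoms.positions.astype(float).copy())
    if not frames:
        raise ValueError(f"trajectory {path} contains zero frames")
    return Trajectory(
        topology=topology,
        frames=np.stack(frames),
        source_id=source_id or path.stem,
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (deterministic output)."""
    path = Path(path)
    u = structure_to_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    # strip MDAnalysis REMARK timestamps for byte-stable rewrites
    lines = [
        ln for ln in path.read_text().splitlines()
        if not ln.startswith("REMARK")
    ]
    path.write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a Trajectory as multi-model PDB or XTC."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    u = structure_to_universe(traj.topology)
    from MDAnalysis.coordinates.memory import MemoryReader

    u.load_new(traj.frames.astype(np.float32), format=MemoryReader)
    kwargs = {}
    if fmt == "xtc":
        # default XTC precision (3 decimals in nm) quantises to 0.01 A;
        # 4 decimals keeps round-trip error below 0.001 A
        kwargs["precision"] = 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, **kwargs) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    if fmt == "pdb":
        lines = [
            ln for ln in path.read_text().splitlines()
            if not ln.startswith("REMARK")
        ]
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection expression grammar
#
#   expr     := term (('or') term)*
#   term     := factor (('and') factor)*
#   factor   := 'not' factor | '(' expr ')' | predicate
#   predicate:= 'heavy'
#             | ('name'|'resname'|'chain'|'element') VALUE+
#             | 'resid' INT+
#
# Multiple values after a keyword are OR-ed ("resid 427 426").

_KEYWORDS = {"and", "or", "not", "heavy", "name", "resname", "chain",
             "element", "resid"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expr: str, structure: Structure):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.s = structure

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        mask = self.expr_rule()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def expr_rule(self) -> np.ndarray:
        mask = self.term_rule()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.term_rule()
        return mask

    def term_rule(self) -> np.ndarray:
        mask = self.factor_rule()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.factor_rule()
        return mask

    def factor_rule(self) -> np.ndarray:
        tok, at = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        if tok == "not":
            self.next()
            return ~self.factor_rule()
        if tok == "(":
            self.next()
            mask = self.expr_rule()
            tok2, at2 = self.next()
            if tok2 != ")":
                raise SelectionError("expected ')'", at2)
            return mask
        return self.predicate_rule()

    def _values(self, keyword: str, at: int) -> list[str]:
        vals = []
        while True:
            tok, _ = self.peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self.next()[0])
        if not vals:
            raise SelectionError(f"keyword {keyword!r} needs at least one value", at)
        return vals

    def predicate_rule(self) -> np.ndarray:
        tok, at = self.next()
        s = self.s
        if tok == "heavy":
            return s.heavy_mask()
        if tok == "name":
            vals = set(self._values(tok, at))
            return np.array([n in vals for n in s.names], dtype=bool)
        if tok == "resname":
            vals = set(self._values(tok, at))
            return np.array([r in vals for r in s.resnames], dtype=bool)
        if tok == "chain":
            vals = set(self._values(tok, at))
            return np.array([c in vals for c in s.chainids], dtype=bool)
        if tok == "element":
            vals = {v.upper() for v in self._values(tok, at)}
            return np.array([e.upper() in vals for e in s.elements], dtype=bool)
        if tok == "resid":
            raw = self._values(tok, at)
            ids = set()
            for v in raw:
                try:
                    ids.add(int(v))
                except ValueError as exc:
                    raise SelectionError(f"resid value {v!r} is not an integer", at) from exc
            return np.isin(s.resids, sorted(ids))
        raise SelectionError(f"unknown keyword {tok!r}", at)


def select(structure: Structure, expression: str) -> AtomSelection:
    """Resolve a selection expression to an ordered AtomSelection.

    Supported predicates: resid, resname, name, chain, element, heavy;
    combinable with and/or/not and parentheses.  Deterministic and
    order-stable; an empty result is allowed.
    """
    mask = _Parser(expression, structure).parse()
    return AtomSelection(indices=np.nonzero(mask)[0], expression=expression)
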