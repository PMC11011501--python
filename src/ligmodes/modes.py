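"""Distance-based binding-mode assignment, occupancies and transitions.

A binding mode is a set of distance conditions between the ligand's
phosphorus atom and anchor atoms on charged residues (CZ for arginine, NZ
for lysine, NE2 for histidine by default).  A frame is assigned the
highest-precedence mode whose conditions all hold; frames matching no mode
fall into a dummy fallback mode.  The default profile encodes the G3P /
GPAT4 hotspot set: five modes anchored on R427, H248, K426, K365, K296,
R292, R148 and R374, with 5 A cutoffs except the H248 condition at 11 A,
plus fallback mode 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import AtomSelection, Structure, Trajectory, select

#: default anchor atom per residue one-letter type
ANCHOR_ATOMS = {"R": "CZ", "K": "NZ", "H": "NE2"}

RESNAME_OF = {"R": "ARG", "K": "LYS", "H": "HIS"}


@dataclass(frozen=True)
class AnchorAtom:
    """One anchor: a residue label like 'R427' plus the atom measured to."""

    label: str                  # e.g. "R427"
    resid: int
    atom_name: str              # CZ / NZ / NE2 (or ND1 if configured)
    resname: str | None = None
    chain: str | None = None

    @classmethod
    def from_label(cls, label: str, his_atom: str = "NE2",
                   chain: str | None = None) -> "AnchorAtom":
        """Build an anchor from a label such as 'R427', 'K365' or 'H248'."""
        kind = label[0].upper()
        if kind not in ANCHOR_ATOMS:
            raise ValueError(f"unsupported anchor residue type in {label!r}")
        atom = his_atom if kind == "H" else ANCHOR_ATOMS[kind]
        return cls(label=label, resid=int(label[1:]), atom_name=atom,
                   resname=RESNAME_OF[kind], chain=chain)

    def resolve(self, structure: Structure) -> int:
        """Structure index of this anchor atom; must be unique."""
        mask = (structure.resids == self.resid) & (structure.names == self.atom_name)
        if self.resname is not None:
            mask &= structure.resnames == self.resname
        if self.chain is not None:
            mask &= structure.chainids == self.chain
        hits = np.nonzero(mask)[0]
        if len(hits) != 1:
            raise ValueError(
                f"anchor {self.label} ({self.atom_name}) resolves to "
                f"{len(hits)} atoms; exactly one required"
            )
        return int(hits[0])


@dataclass
class ModeDefinition:
    """A binding mode: distance conditions plus a precedence rank."""

    mode_id: int
    conditions: list[tuple[AnchorAtom, float]]   # (anchor, cutoff in A)
    precedence_rank: int                          # lower = evaluated first
    is_fallback: bool = False

    def __post_init__(self):
        if self.is_fallback and self.conditions:
            raise ValueError("fallback mode must have no conditions")
        for _, cutoff in self.conditions:
            if cutoff <= 0:
                raise ValueError("cutoffs must be positive")


def default_mode_definitions(his_atom: str = "NE2") -> list[ModeDefinition]:
    """The default six-mode G3P binding-mode profile.

    Mode pairs: 1 R427+H248, 2 K296+R292, 3 R427+K426, 4 R148+R374,
    5 R427+K365; mode 6 is the fallback.  All cutoffs 5 A except the H248
    condition at 11 A.  Precedence order 1 > 2 > 4 > 5 > 3 > 6: the H248
    distance separates mode 1 from all others first; modes 2/4/5 are
    defined by residue pairs unique to them; mode 3 collects remaining
    R427+K426 frames; mode 6 gathers the rest.
    """
    A = lambda lbl: AnchorAtom.from_label(lbl, his_atom=his_atom)  # noqa: E731
    pairs = {
        1: [(A("R427"), 5.0), (A("H248"), 11.0)],
        2: [(A("K296"), 5.0), (A("R292"), 5.0)],
        3: [(A("R427"), 5.0), (A("K426"), 5.0)],
        4: [(A("R148"), 5.0), (A("R374"), 5.0)],
        5: [(A("R427"), 5.0), (A("K365"), 5.0)],
    }
    precedence = {1: 1, 2: 2, 4: 3, 5: 4, 3: 5, 6: 6}
    defs = [
        ModeDefinition(mode_id=m, conditions=pairs[m],
                       precedence_rank=precedence[m])
        for m in (1, 2, 3, 4, 5)
    ]
    defs.append(ModeDefinition(mode_id=6, conditions=[],
                               precedence_rank=precedence[6], is_fallback=True))
    _validate_definitions(defs)
    return defs


def _validate_definitions(defs: list[ModeDefinition]) -> None:
    ranks = [d.precedence_rank for d in defs]
    if len(set(ranks)) != len(ranks):
        raise ValueError("precedence ranks must be unique")
    fallbacks = [d for d in defs if d.is_fallback]
    if len(fallbacks) != 1:
        raise ValueError("exactly one fallback mode is required")
    if fallbacks[0].precedence_rank != max(ranks):
        raise ValueError("fallback mode must have the lowest precedence")


def load_mode_definitions(path) -> list[ModeDefinition]:
    """Read a mode profile from YAML (anchors, cutoffs in A, precedence)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defs = []
    for entry in doc["modes"]:
        conditions = []
        for cond in entry.get("conditions", []):
            anchor = AnchorAtom(
                label=cond["anchor"], resid=int(cond["resid"]),
                atom_name=cond["atom"], resname=cond.get("resname"),
                chain=cond.get("chain"),
            )
            conditions.append((anchor, float(cond["cutoff"])))
        defs.append(ModeDefinition(
            mode_id=int(entry["mode_id"]), conditions=conditions,
            precedence_rank=int(entry["precedence"]),
            is_fallback=bool(entry.get("fallback", False)),
        ))
    _validate_definitions(defs)
    return defs


def save_mode_definitions(defs: list[ModeDefinition], path) -> None:
    doc = {"modes": []}
    for d in defs:
        entry = {
            "mode_id": d.mode_id, "precedence": d.precedence_rank,
            "fallback": d.is_fallback,
            "conditions": [
                {"anchor": a.label, "resid": a.resid, "atom": a.atom_name,
                 **({"resname": a.resname} if a.resname else {}),
                 **({"chain": a.chain} if a.chain else {}),
                 "cutoff": c}
                for a, c in d.conditions
            ],
        }
        doc["modes"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class DistanceTable:
    """Per-frame distances (A) from the ligand P atom to each anchor."""

    distances: pd.DataFrame          # one column per anchor label
    boundaries: np.ndarray           # start index of each source trajectory

    def __post_init__(self):
        v = self.distances.to_numpy()
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("distances must be finite and non-negative")
        self.boundaries = np.asarray(self.boundaries, dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.distances)


@dataclass
class ModeTrace:
    """Per-frame mode labels with source-trajectory boundaries."""

    labels: np.ndarray               # per-frame mode id
    boundaries: np.ndarray           # start index of each source, first is 0
    mode_ids: tuple[int, ...]        # all declared mode ids

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.labels) == 0:
            raise ValueError("trace must be non-empty")
        unknown = set(np.unique(self.labels)) - set(self.mode_ids)
        if unknown:
            raise ValueError(f"labels contain undeclared mode ids {unknown}")
        if len(self.boundaries) == 0 or self.boundaries[0] != 0:
            raise ValueError("boundaries must start at 0")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly ascending")
        if self.boundaries[-1] >= len(self.labels):
            raise ValueError("boundary beyond trace length")

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def compute_distance_table(
    trajs: Trajectory | list[Trajectory],
    ligand_P_sel,
    anchors: list[AnchorAtom],
) -> DistanceTable:
    """Euclidean distance per frame from the ligand P atom to each anchor."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories supplied")
    top = trajs[0].topology
    psel = ligand_P_sel if isinstance(ligand_P_sel, AtomSelection) \
        else select(top, ligand_P_sel)
    if len(psel) != 1:
        raise ValueError(
            f"ligand P selection must resolve to exactly 1 atom, got {len(psel)}")
    p_idx = int(psel.indices[0])
    anchor_idx = {a.label: a.resolve(top) for a in anchors}

    blocks = []
    boundaries = []
    offset = 0
    for traj in trajs:
        boundaries.append(offset)
        p = traj.frames[:, p_idx, :]
        cols = {
            label: np.linalg.norm(traj.frames[:, idx, :] - p, axis=1)
            for label, idx in anchor_idx.items()
        }
        blocks.append(pd.DataFrame(cols))
        offset += traj.n_frames
    table = pd.concat(blocks, ignore_index=True)
    return DistanceTable(distances=table, boundaries=np.array(boundaries))


def assign_modes(table: DistanceTable,
                 definitions: list[ModeDefinition]) -> ModeTrace:
    """Assign each frame the highest-precedence mode whose conditions hold.

    A condition holds when the distance is within its cutoff (boundary
    inclusive).  Frames satisfying no non-fallback mode get the fallback.
    """
    _validate_definitions(definitions)
    for d in definitions:
        for anchor, _ in d.conditions:
            if anchor.label not in table.distances.columns:
                raise ValueError(
                    f"distance table lacks column for anchor {anchor.label}")
    n = table.n_frames
    labels = np.zeros(n, dtype=int)
    assigned = np.zeros(n, dtype=bool)
    fallback = next(d for d in definitions if d.is_fallback)
    for d in sorted(definitions, key=lambda d: d.precedence_rank):
        if d.is_fallback:
            continue
        ok = np.ones(n, dtype=bool)
        for anchor, cutoff in d.conditions:
            ok &= table.distances[anchor.label].to_numpy() <= cutoff
        take = ok & ~assigned
        labels[take] = d.mode_id
        assigned |= take
    labels[~assigned] = fallback.mode_id
    return ModeTrace(
        labels=labels, boundaries=table.boundaries,
        mode_ids=tuple(d.mode_id for d in definitions),
    )


def mode_occupancy(trace: ModeTrace) -> pd.Series:
    """Percentage of frames per declared mode (zero-count modes included)."""
    T = trace.n_frames
    counts = {m: 0 for m in trace.mode_ids}
    ids, n = np.unique(trace.labels, return_counts=True)
    for m, c in zip(ids, n):
        counts[int(m)] = int(c)
    return pd.Series({m: 100.0 * c / T for m, c in counts.items()},
                     name="occupancy_pct")


def _stride_indices(T: int, n: int) -> np.ndarray:
    """n uniform-stride indices into range(T), always including 0."""
    return np.floor(np.arange(n) * T / n).astype(int)


def represent_frames(obj, n: int = 1000):
    """Down-sample to n uniformly strided frames per source trajectory.

    Accepts a ModeTrace (returns a ModeTrace with recomputed boundaries),
    a Trajectory, or a list of Trajectories.  The first frame of every
    source is always retained.  Sources shorter than n are kept whole with
    a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(obj, ModeTrace):
        starts = list(obj.boundaries) + [obj.n_frames]
        out_labels, out_bounds = [], []
        pos = 0
        for s, e in zip(starts[:-1], starts[1:]):
            T = e - s
            if T < n:
                warnings.warn(
                    f"source of {T} frames shorter than n={n}; keeping all")
                idx = np.arange(T)
            else:
                idx = _stride_indices(T, n)
            out_bounds.append(pos)
            out_labels.append(obj.labels[s:e][idx])
            pos += len(idx)
        return ModeTrace(labels=np.concatenate(out_labels),
                         boundaries=np.array(out_bounds),
                         mode_ids=obj.mode_ids)
    if isinstance(obj, Trajectory):
        T = obj.n_frames
        if T < n:
            warnings.warn(f"source of {T} frames shorter than n={n}; keeping all")
            return obj
        idx = _stride_indices(T, n)
        return Trajectory(topology=obj.topology, frames=obj.frames[idx],
                          frame_index=obj.frame_index[idx],
                          source_id=obj.source_id)
    if isinstance(obj, (list, tuple)):
        return [represent_frames(t, n) for t in obj]
    raise TypeError(f"cannot represent object of type {type(obj)!r}")


def transition_summary(trace: ModeTrace
                       ) -> tuple[pd.DataFrame, list[tuple[int, int, int]]]:
    """Count mode changes between consecutive frames.

    Pairs straddling a source-trajectory boundary are concatenation
    artefacts and are excluded.  Returns a (from x to) count matrix over
    all declared modes and an event list of (frame, from_mode, to_mode),
    where frame is the index at which the new mode starts.
    """
    ids = list(trace.mode_ids)
    matrix = pd.DataFrame(0, index=ids, columns=ids)
    events = []
    boundary_set = set(int(b) for b in trace.boundaries)
    lab = trace.labels
    for i in range(1, len(lab)):
        if i in boundary_set:
            continue
        if lab[i] != lab[i - 1]:
            matrix.loc[int(lab[i - 1]), int(lab[i])] += 1
            events.append((i, int(lab[i - 1]), int(lab[i])))
    return matrix, events


def plot_timeline(trace: ModeTrace, path, title: str | None = None) -> None:
    """Render the mode-vs-frame timeline with boundary ticks.

    Mirrors the concatenated-copies presentation: mode id against frame
    index, vertical connectors at transitions, dashed lines at source
    boundaries.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(trace.n_frames)
    ax.step(x, trace.labels, where="post", lw=0.8, color="tab:blue")
    for b in trace.boundaries[1:]:
        ax.axvline(b, color="grey", ls="--", lw=0.6)
    ax.set_xlabel("frame ID")
    ax.set_ylabel("binding mode")
    ax.set_yticks(sorted(trace.mode_ids))
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
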