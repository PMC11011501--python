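"""Synthetic hotspot-hopping trajectories with known ground truth.

The generator emulates the statistical structure the analyses assume: a
small rigid ligand whose phosphorus atom hops between binding hotspots
anchored on charged residues (R427, K426, K365, K296, R292, R148, R374 and
the catalytic H248), following a Markov chain over binding modes, with
isotropic Gaussian positional jitter.  Hotspot geometry is constructed so
that every mode's distance conditions hold at its own hotspot with at
least ~2 A margin while all higher-precedence modes' conditions are
violated with similar margin, which is what makes label recovery by the
mode classifier provable rather than incidental.

No force field, membrane or solvent is modelled: the generator reproduces
label and geometry statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import Structure, Trajectory
from .modes import AnchorAtom, ModeDefinition, default_mode_definitions

# ---------------------------------------------------------------------------
# Fixed reference geometry (Angstrom).
#
# Modes 1/3/5 share R427, so H248, K426 and K365 cluster around it; the
# other two hotspots (K296+R292 for mode 2, R148+R374 for mode 4) and the
# detached mode-6 region are >= 15 A from everything else.

ANCHOR_COORDS: dict[str, tuple[float, float, float]] = {
    "R427": (0.0, 0.0, 0.0),
    "H248": (12.0, 0.0, 0.0),
    "K426": (-3.0, 5.0, 0.0),
    "K365": (-3.0, -5.0, 0.0),
    "K296": (20.0, 15.0, 0.0),
    "R292": (20.0, 20.5, 0.0),
    "R148": (-20.0, 15.0, 0.0),
    "R374": (-20.0, 20.5, 0.0),
}

MODE_POINTS: dict[int, tuple[float, float, float]] = {
    1: (3.0, 0.0, 0.0),        # near R427, within 11 A of H248
    2: (20.0, 17.75, 0.0),     # midway K296 / R292
    3: (-1.5, 2.5, 0.0),       # midway R427 / K426, > 11 A from H248
    4: (-20.0, 17.75, 0.0),    # midway R148 / R374
    5: (-1.5, -2.5, 0.0),      # midway R427 / K365, > 11 A from H248
    6: (0.0, 0.0, -25.0),      # detached: violates every mode
}

#: stationary mode occupancies used for the default transition matrix
#: (fractions of trajectory per mode 1..6)
DEFAULT_OCCUPANCIES = {1: 0.323, 2: 0.178, 3: 0.091, 4: 0.089,
                       5: 0.132, 6: 0.187}

#: per-frame probability of re-drawing the mode (hotspot persistence)
DEFAULT_HOP_RATE = 0.02

# Rigid 10-heavy-atom ligand: a P atom surrounded by 9 atoms at 1 A radius.
_S = 1.0 / np.sqrt(3.0)
LIGAND_TEMPLATE = [
    ("P",  "P", (0.0, 0.0, 0.0)),
    ("O1", "O", (1.0, 0.0, 0.0)),
    ("O2", "O", (0.0, 1.0, 0.0)),
    ("O3", "O", (0.0, 0.0, 1.0)),
    ("C1", "C", (-1.0, 0.0, 0.0)),
    ("C2", "C", (0.0, -1.0, 0.0)),
    ("C3", "C", (0.0, 0.0, -1.0)),
    ("C4", "C", (_S, _S, _S)),
    ("C5", "C", (-_S, -_S, _S)),
    ("C6", "C", (_S, -_S, -_S)),
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic hotspot-hopping trajectory.

    The transition matrix is row-stochastic over the declared modes; each
    mode-geometry point must satisfy its own mode's conditions and violate
    all higher-precedence modes' conditions (checked at construction).
    """

    anchors: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: np.array(v) for k, v in ANCHOR_COORDS.items()})
    mode_points: dict[int, np.ndarray] = field(
        default_factory=lambda: {k: np.array(v) for k, v in MODE_POINTS.items()})
    transition_matrix: np.ndarray | None = None
    jitter_sigma: float = 0.5
    n_frames: int = 10_000
    seed: int = 0
    definitions: list[ModeDefinition] = field(
        default_factory=default_mode_definitions)

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix()
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.validate()

    @property
    def mode_ids(self) -> list[int]:
        return sorted(self.mode_points)

    def validate(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        P = self.transition_matrix
        m = len(self.mode_ids)
        if P.shape != (m, m):
            raise ValueError(f"transition matrix must be {m}x{m}")
        if P.min() < 0 or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be stochastic")
        # geometric validation of every mode point against the definitions
        by_rank = sorted(self.definitions, key=lambda d: d.precedence_rank)
        for mode_id, point in self.mode_points.items():
            seen_self = False
            for d in by_rank:
                if d.is_fallback:
                    continue
                holds = all(
                    np.linalg.norm(point - self.anchors[a.label]) <= cutoff
                    for a, cutoff in d.conditions
                )
                if d.mode_id == mode_id:
                    if not holds:
                        raise ValueError(
                            f"mode {mode_id} point fails its own conditions")
                    seen_self = True
                    break
                if holds:
                    raise ValueError(
                        f"mode {mode_id} point satisfies higher-precedence "
                        f"mode {d.mode_id} conditions")
            fallback = next(d for d in self.definitions if d.is_fallback)
            if mode_id == fallback.mode_id and seen_self:
                raise ValueError("fallback mode point matched a condition set")

    def min_margin(self) -> float:
        """Smallest distance margin (A) protecting any mode assignment.

        The margin of a holding condition is cutoff - distance; of a
        violated higher-precedence condition set, the largest single-
        condition excess distance - cutoff.  Label recovery under jitter
        sigma degrades with the ratio margin / sigma.
        """
        by_rank = sorted(self.definitions, key=lambda d: d.precedence_rank)
        margins = []
        for mode_id, point in self.mode_points.items():
            for d in by_rank:
                if d.is_fallback:
                    continue
                dists = np.array([
                    np.linalg.norm(point - self.anchors[a.label])
                    for a, _ in d.conditions])
                cuts = np.array([c for _, c in d.conditions])
                if d.mode_id == mode_id:
                    margins.append(float((cuts - dists).min()))
                    break
                margins.append(float((dists - cuts).max()))
        return min(margins)


def default_transition_matrix(
    occupancies: dict[int, float] | None = None,
    hop_rate: float = DEFAULT_HOP_RATE,
) -> np.ndarray:
    """Persistence-plus-redraw chain with a prescribed stationary law.

    Each frame the ligand stays put with probability 1 - hop_rate and
    otherwise re-draws its mode from the stationary occupancies, giving
    T = (1 - a) I + a 1 pi^T, whose stationary distribution is exactly pi.
    """
    occ = occupancies or DEFAULT_OCCUPANCIES
    ids = sorted(occ)
    pi = np.array([occ[i] for i in ids], dtype=float)
    pi = pi / pi.sum()
    m = len(pi)
    return (1.0 - hop_rate) * np.eye(m) + hop_rate * np.tile(pi, (m, 1))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigvec)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Receptor construction

def _residue_atoms(resname: str, resid: int, anchor_name: str,
                   anchor_pos: np.ndarray):
    """A minimal residue: backbone placed 3-4 A 'behind' the anchor atom."""
    ca = anchor_pos + np.array([0.0, 0.0, 3.0])
    atoms = [
        ("N", "N", ca + np.array([-1.2, 0.8, 0.4])),
        ("CA", "C", ca),
        ("C", "C", ca + np.array([1.2, 0.8, 0.4])),
        ("O", "O", ca + np.array([1.4, 1.9, 0.7])),
        (anchor_name, anchor_name[0], anchor_pos.copy()),
    ]
    return [(n, e, p, resname, resid) for n, e, p in atoms]


def make_reference_receptor(seed: int = 0) -> Structure:
    """A minimal receptor carrying the eight anchor residues.

    Anchor residues (ARG/LYS/HIS with CZ/NZ/NE2 at the fixed hotspot
    geometry) are complemented by one glycine 'pocket probe' per mode,
    whose CA sits 1.2 A above the mode point so that its contact with the
    ligand is equivalent to the ligand occupying that mode, and one far
    glycine that is never in contact.  Deterministic: the same seed always
    yields a byte-identical structure.
    """
    del seed  # placement is fixed; the argument is kept for API symmetry
    records = []
    resname_of = {"R": "ARG", "K": "LYS", "H": "HIS"}
    for label, pos in sorted(ANCHOR_COORDS.items(), key=lambda kv: int(kv[0][1:])):
        kind = label[0]
        anchor = AnchorAtom.from_label(label)
        records.extend(_residue_atoms(resname_of[kind], int(label[1:]),
                                      anchor.atom_name, np.array(pos)))
    for mode_id, point in sorted(MODE_POINTS.items()):
        pos = np.array(point) + np.array([0.0, 0.0, 1.2])
        records.append(("CA", "C", pos, "GLY", 900 + mode_id))
    records.append(("CA", "C", np.array([60.0, 60.0, 60.0]), "GLY", 950))

    return Structure(
        names=np.array([r[0] for r in records], dtype=object),
        elements=np.array([r[1] for r in records], dtype=object),
        resnames=np.array([r[3] for r in records], dtype=object),
        resids=np.array([r[4] for r in records], dtype=int),
        chainids=np.array(["A"] * len(records), dtype=object),
        coords=np.array([r[2] for r in records], dtype=float),
    )


def pocket_probe_key(mode_id: int) -> str:
    """Residue key of the glycine probe tied to a mode."""
    return f"A:GLY:{900 + mode_id}"


# ---------------------------------------------------------------------------
# Trajectory generation

def simulate_mode_walk(
    transition_matrix: np.ndarray,
    n_frames: int,
    seed: int,
    mode_ids: list[int] | None = None,
    start_mode: int | None = None,
) -> np.ndarray:
    """One Markov-chain realisation of the mode labels.

    ``start_mode`` defaults to a draw from the stationary distribution.
    Reproducible: the same seed yields the same sequence.
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if P.min() < 0 or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    m = P.shape[0]
    ids = np.asarray(mode_ids if mode_ids is not None else range(1, m + 1))
    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=int)
    if start_mode is not None:
        state = int(np.nonzero(ids == start_mode)[0][0])
    else:
        pi = stationary_distribution(P)
        state = int(rng.choice(m, p=pi))
    cum = np.cumsum(P, axis=1)
    draws = rng.random(n_frames)
    for t in range(n_frames):
        states[t] = state
        state = int(np.searchsorted(cum[state], draws[t], side="right"))
        state = min(state, m - 1)
    return ids[states]


def ligand_structure_at(point: np.ndarray) -> Structure:
    """The rigid ligand fragment centred at a point (resname G3P)."""
    coords = np.array([p for _, _, p in LIGAND_TEMPLATE]) + np.asarray(point)
    n = len(LIGAND_TEMPLATE)
    return Structure(
        names=np.array([a[0] for a in LIGAND_TEMPLATE], dtype=object),
        elements=np.array([a[1] for a in LIGAND_TEMPLATE], dtype=object),
        resnames=np.array(["G3P"] * n, dtype=object),
        resids=np.array([999] * n, dtype=int),
        chainids=np.array(["L"] * n, dtype=object),
        coords=coords,
    )


def misassignment_bound(margin: float, sigma: float) -> float:
    """Upper bound on per-frame label error probability.

    The ligand is displaced by an isotropic 3-D Gaussian; a condition with
    distance margin ``m`` flips only if the displacement magnitude exceeds
    m, so P(flip) <= P(chi2_3 > (m/sigma)^2) per condition; twelve
    condition checks bound the union.
    """
    if sigma == 0:
        return 0.0
    per = float(chi2.sf((margin / sigma) ** 2, df=3))
    return min(1.0, 12.0 * per)


def emit_trajectory(
    receptor: Structure,
    labels: np.ndarray,
    spec: SyntheticSpec,
    source_id: str = "synthetic",
) -> tuple[Trajectory, pd.DataFrame]:
    """Place the ligand at each labelled hotspot with Gaussian jitter.

    Per frame the rigid ligand is translated to the labelled mode's
    geometry point plus one isotropic Gaussian displacement (sigma =
    spec.jitter_sigma).  Returns the trajectory (receptor static, ligand
    appended as resname G3P) and a ground-truth table (frame, true_mode).
    """
    labels = np.asarray(labels, dtype=int)
    unknown = set(np.unique(labels)) - set(spec.mode_points)
    if unknown:
        raise ValueError(f"labels reference undefined modes {unknown}")
    margin = spec.min_margin()
    if spec.jitter_sigma > 0:
        bound = misassignment_bound(margin, spec.jitter_sigma)
        if bound > 0.05:
            warnings.warn(
                f"jitter sigma {spec.jitter_sigma} A is large for the "
                f"{margin:.2f} A hotspot margins; expected misassignment "
                f"rate up to {bound:.1%}")

    rng = np.random.default_rng(spec.seed)
    T = len(labels)
    lig_template = np.array([p for _, _, p in LIGAND_TEMPLATE])
    n_rec = receptor.n_atoms
    n_lig = len(lig_template)

    frames = np.empty((T, n_rec + n_lig, 3))
    frames[:, :n_rec, :] = receptor.coords
    jitter = rng.normal(0.0, spec.jitter_sigma, size=(T, 3)) \
        if spec.jitter_sigma > 0 else np.zeros((T, 3))
    points = np.array([spec.mode_points[m] for m in labels])
    frames[:, n_rec:, :] = (points + jitter)[:, None, :] + lig_template[None, :, :]

    ligand = ligand_structure_at(np.zeros(3))
    topology = Structure(
        names=np.concatenate([receptor.names, ligand.names]),
        elements=np.concatenate([receptor.elements, ligand.elements]),
        resnames=np.concatenate([receptor.resnames, ligand.resnames]),
        resids=np.concatenate([receptor.resids, ligand.resids]),
        chainids=np.concatenate([receptor.chainids, ligand.chainids]),
        coords=frames[0].copy(),
    )
    truth = pd.DataFrame({"frame": np.arange(T), "true_mode": labels})
    traj = Trajectory(topology=topology, frames=frames, source_id=source_id)
    return traj, truth


def make_pose_blobs(
    k: int,
    n_per_pose: int | list[int],
    sigma: float,
    separation: float,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """k rigid ligand poses with Gaussian atomic jitter, plus ground truth.

    Pose centres are spaced ``separation`` apart along x and each pose gets
    a distinct fixed orientation.  A static 4-atom protein scaffold is
    included so the receptor-alignment step of pose clustering has a
    well-defined (identity) fit.  Returns the trajectory and the per-frame
    ground-truth pose index (0-based).
    """
    if isinstance(n_per_pose, int):
        counts = [n_per_pose] * k
    else:
        counts = list(n_per_pose)
        if len(counts) != k:
            raise ValueError("n_per_pose list must have k entries")
    rng = np.random.default_rng(seed)
    lig_template = np.array([p for _, _, p in LIGAND_TEMPLATE])
    n_lig = len(lig_template)

    scaffold_coords = np.array([
        [0.0, 40.0, 0.0], [8.0, 40.0, 0.0], [0.0, 48.0, 0.0], [0.0, 40.0, 8.0],
    ])
    poses = []
    for i in range(k):
        angle = rng.uniform(0, 2 * np.pi)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        centre = np.array([i * separation, 0.0, 0.0])
        poses.append(lig_template @ R.T + centre)

    total = sum(counts)
    frames = np.empty((total, 4 + n_lig, 3))
    frames[:, :4, :] = scaffold_coords
    truth = np.empty(total, dtype=int)
    t = 0
    for i, c in enumerate(counts):
        block = poses[i][None, :, :] + rng.normal(0, sigma, size=(c, n_lig, 3)) \
            if sigma > 0 else np.tile(poses[i], (c, 1, 1))
        frames[t:t + c, 4:, :] = block
        truth[t:t + c] = i
        t += c

    ligand = ligand_structure_at(np.zeros(3))
    topology = Structure(
        names=np.concatenate([np.array(["CA"] * 4, dtype=object), ligand.names]),
        elements=np.concatenate([np.array(["C"] * 4, dtype=object), ligand.elements]),
        resnames=np.concatenate([np.array(["GLY"] * 4, dtype=object), ligand.resnames]),
        resids=np.concatenate([np.array([801, 802, 803, 804]), ligand.resids]),
        chainids=np.concatenate([np.array(["A"] * 4, dtype=object), ligand.chainids]),
        coords=frames[0].copy(),
    )
    traj = Trajectory(topology=topology, frames=frames, source_id="pose_blobs")
    return traj, truth
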