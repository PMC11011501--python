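"""Gromos (Daura-style) clustering of ligand poses in the receptor frame.

Each frame is first rigid-body superposed onto a reference frame using a
protein selection; ligand RMSDs are then computed pairwise without
re-fitting, and the greedy neighbour-count algorithm partitions the frames:
the frame with the most neighbours within the cutoff becomes a cluster
centroid, it and its neighbours are removed, and the step repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import AtomSelection, Structure, Trajectory, select
from .geometry import kabsch_fit


@dataclass
class DistanceMatrix:
    """Symmetric ligand-RMSD matrix (Angstrom) over frames."""

    values: np.ndarray   # (n, n)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if v.min() < 0:
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    """Ordered clusters of frames; formation order = decreasing size."""

    clusters: list[tuple[int, np.ndarray]]   # (centroid_frame, member_frames)
    cutoff: float
    n_frames: int

    def membership(self) -> np.ndarray:
        """Per-frame cluster index (0-based, formation order)."""
        lab = np.full(self.n_frames, -1, dtype=int)
        for k, (_, members) in enumerate(self.clusters):
            lab[members] = k
        return lab

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (c, members) in enumerate(self.clusters):
            rows.append({
                "cluster_id": k + 1, "centroid_frame": c,
                "size": len(members),
                "size_pct": 100.0 * len(members) / self.n_frames,
            })
        return pd.DataFrame(rows)


def _resolve(structure: Structure, sel) -> AtomSelection:
    if isinstance(sel, AtomSelection):
        return sel
    return select(structure, sel)


def align_frames(
    trajs: Trajectory | list[Trajectory],
    protein_align_sel,
    reference: Structure | None = None,
) -> tuple[np.ndarray, Structure]:
    """Superpose all frames onto a reference by the protein selection.

    Reference defaults to frame 0 of the first trajectory.  Returns the
    stacked aligned coordinates (T_total, N, 3) and the topology.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    top = trajs[0].topology
    sel = _resolve(top, protein_align_sel)
    if len(sel) < 3:
        raise ValueError("protein alignment selection needs at least 3 atoms")
    ref_coords = (reference.coords if reference is not None
                  else trajs[0].frames[0])[sel.indices]
    aligned = []
    for traj in trajs:
        for t in range(traj.n_frames):
            frame = traj.frames[t]
            tf, _ = kabsch_fit(frame[sel.indices], ref_coords)
            aligned.append(tf.apply(frame))
    return np.stack(aligned), top


def ligand_rmsd_matrix(
    trajs: Trajectory | list[Trajectory],
    protein_align_sel,
    ligand_sel,
    reference: Structure | None = None,
) -> DistanceMatrix:
    """Pairwise ligand RMSD with the receptor aligned.

    Frames are superposed onto the reference frame via the protein
    selection (Kabsch), then RMSD over the ligand heavy-atom selection is
    taken pairwise without re-fitting the ligand.  When several ligand
    residues are selected their atoms are concatenated into one vector, so
    e.g. G3P and CoA can be clustered jointly.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    top = trajs[0].topology
    lig = _resolve(top, ligand_sel)
    if len(lig) == 0:
        raise ValueError("ligand selection is empty")
    heavy = top.heavy_mask()
    lig_idx = lig.indices[heavy[lig.indices]]
    if len(lig_idx) == 0:
        raise ValueError("ligand selection contains only hydrogens")

    aligned, _ = align_frames(trajs, protein_align_sel, reference)
    X = aligned[:, lig_idx, :].reshape(len(aligned), -1)  # (T, 3L)
    L = len(lig_idx)
    # rmsd_ij^2 = |x_i - x_j|^2 / L on the flattened vectors
    d = squareform(pdist(X)) / np.sqrt(L)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0)


def gromos_cluster(matrix: DistanceMatrix, cutoff: float = 3.0) -> Clustering:
    """Greedy neighbour-count clustering (Daura algorithm).

    Iteratively the unassigned frame with the most unassigned neighbours
    within the cutoff (boundary inclusive, ties by lowest frame index)
    becomes a centroid; it and its neighbours form a cluster and are
    removed.  Singleton clusters are allowed.
    """
    n = matrix.n
    within = matrix.values <= cutoff
    np.fill_diagonal(within, False)
    remaining = np.ones(n, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (within & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.nonzero((within[centroid] & remaining))[0]
        members = np.sort(np.append(members, centroid))
        clusters.append((centroid, members))
        remaining[members] = False
    return Clustering(clusters=clusters, cutoff=cutoff, n_frames=n)


def cluster_sizes(clustering: Clustering) -> np.ndarray:
    """Cluster sizes as percentages of the frame count, formation order."""
    sizes = np.array([len(m) for _, m in clustering.clusters], dtype=float)
    return 100.0 * sizes / clustering.n_frames


def centroid_structure(
    trajs: Trajectory | list[Trajectory],
    clustering: Clustering,
    k: int,
    protein_align_sel=None,
    reference: Structure | None = None,
) -> Structure:
    """Full-system coordinates of cluster k's centroid frame.

    If a protein alignment selection is given, the centroid frame is
    returned in the receptor-aligned frame (the frame used for clustering);
    otherwise raw coordinates are returned.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not 0 <= k < len(clustering.clusters):
        raise IndexError(f"cluster index {k} out of range "
                         f"(have {len(clustering.clusters)} clusters)")
    centroid = clustering.clusters[k][0]
    lengths = [t.n_frames for t in trajs]
    if centroid >= sum(lengths):
        raise IndexError("centroid frame outside supplied trajectories")
    offset = centroid
    for traj in trajs:
        if offset < traj.n_frames:
            coords = traj.frames[offset].copy()
            break
        offset -= traj.n_frames
    top = trajs[0].topology
    if protein_align_sel is not None:
        sel = _resolve(top, protein_align_sel)
        ref_coords = (reference.coords if reference is not None
                      else trajs[0].frames[0])[sel.indices]
        tf, _ = kabsch_fit(coords[sel.indices], ref_coords)
        coords = tf.apply(coords)
    return top.with_coords(coords)
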