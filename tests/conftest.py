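import numpy as np
import pytest

import ligmodes as lm


@pytest.fixture(scope="session")
def receptor():
    return lm.make_reference_receptor(seed=0)


@pytest.fixture(scope="session")
def mode_definitions():
    return lm.default_mode_definitions()


@pytest.fixture(scope="session")
def anchors(mode_definitions):
    return sorted({a for d in mode_definitions for a, _ in d.conditions},
                  key=lambda a: a.label)


@pytest.fixture(scope="session")
def noiseless_walk(receptor):
    """2000-frame synthetic trajectory at sigma=0 with its ground truth."""
    spec = lm.SyntheticSpec(jitter_sigma=0.0, n_frames=2000, seed=11)
    labels = lm.simulate_mode_walk(spec.transition_matrix, spec.n_frames,
                                   seed=11, mode_ids=spec.mode_ids)
    traj, truth = lm.emit_trajectory(receptor, labels, spec)
    return traj, labels, spec


@pytest.fixture
def tiny_pdb(tmp_path):
    """A minimal hand-written 3-atom PDB file."""
    text = (
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00"
        "           N\n"
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00"
        "           C\n"
        "ATOM      3  C   ALA A   1       3.200   3.100   3.500  1.00  0.00"
        "           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_gro(tmp_path):
    """The same 3 atoms as tiny_pdb, in GRO format (nm, 3 decimals)."""
    text = (
        "tiny\n"
        "    3\n"
        "    1ALA      N    1   0.100   0.200   0.300\n"
        "    1ALA     CA    2   0.250   0.200   0.300\n"
        "    1ALA      C    3   0.320   0.310   0.350\n"
        "   5.00000   5.00000   5.00000\n"
    )
    path = tmp_path / "tiny.gro"
    path.write_text(text)
    return path


def random_distance_matrix(rng, n, scale=6.0, p_close=0.5):
    """A random valid RMSD-like matrix mixing near and far pairs."""
    d = np.where(rng.random((n, n)) < p_close,
                 rng.uniform(0, 3.0, (n, n)),
                 rng.uniform(3.0, scale, (n, n)))
    d = np.triu(d, 1)
    d = d + d.T
    return lm.DistanceMatrix(d)


def brute_force_daura(values, cutoff):
    """Independent greedy neighbour-count clustering, plain loops.

    Used as the oracle for gromos_cluster: at each step count, for every
    unassigned frame, its unassigned neighbours within the cutoff; the
    frame with the most (lowest index on ties) seeds the next cluster.
    """
    n = len(values)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(
                1 for j in remaining if j != i and values[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(
            {best} | {j for j in remaining if j != best
                      and values[best][j] <= cutoff})
        clusters.append((best, members))
        remaining -= set(members)
    return clusters


def quaternion_superpose(mobile, reference):
    """Horn's quaternion-based absolute orientation (independent oracle)."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, np.argmax(vals)]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    return R, t


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
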