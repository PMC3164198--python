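"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the rotation-grid
search enumerates SO(3) instead of solving the least-squares problem in
closed form, and the lifetime scan checks every window explicitly.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def rotation_grid(step_deg: float = 2.0) -> np.ndarray:
    """All rotation matrices on a z-y-z Euler grid with the given step."""
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + step_deg / 2, step_deg)
    gammas = np.arange(0.0, 360.0, step_deg)
    angles = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1)
    return Rotation.from_euler("zyz", angles.reshape(-1, 3), degrees=True).as_matrix()


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                  grid: np.ndarray) -> float:
    """Minimal RMSD over a rotation grid after centroid removal.

    Uses rmsd^2 = (|P|^2 + |Q|^2 - 2 tr(R M)) / n with the cross-covariance
    M = P^T Q, so the whole grid reduces to one einsum.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    cross = mob.T @ ref
    const = np.sum(mob ** 2) + np.sum(ref ** 2)
    best_trace = -np.inf
    for start in range(0, len(grid), 500_000):
        traces = np.einsum("nij,ji->n", grid[start:start + 500_000], cross)
        best_trace = max(best_trace, float(traces.max()))
    return float(np.sqrt(max(const - 2.0 * best_trace, 0.0) / len(mob)))


def scan_lifetime(distances: np.ndarray, times: np.ndarray,
                  threshold: float, dwell: int):
    """First window of >= dwell consecutive frames at/above threshold.

    Returns the time from trace start, or None (censored)."""
    n = len(distances)
    for i in range(n - dwell + 1):
        if all(distances[i + j] >= threshold for j in range(dwell)):
            return float(times[i] - times[0])
    return None
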