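"""Independent brute-force oracles, coded separately from the package paths.

The Kabsch oracle here uses explicit centroid subtraction and an SVD
rotation with the textbook determinant correction — no shared code with
mdsieve's RMSD implementation (which goes through MDAnalysis QCP).
"""

import math

import numpy as np


def brute_force_kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal-RMSD superposition by centroid subtraction + SVD rotation."""
    x = np.asarray(mobile, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    aligned = x @ rotation.T
    return float(np.sqrt(np.mean(np.sum((aligned - y) ** 2, axis=1))))


def brute_force_bhattacharyya(p, q) -> float:
    """Scalar-loop Bhattacharyya distance on two probability sequences."""
    bc = 0.0
    for pi, qi in zip(p, q):
        bc += math.sqrt(pi * qi)
    if bc <= 0.0:
        return math.inf
    return -math.log(min(bc, 1.0))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation via QR with sign fixing."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
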