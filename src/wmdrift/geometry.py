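"""Neural state-space geometry: condition distances and classical MDS.

The joint geometry of the orientation code and a second factor (impulse
number or cued location) is summarised by the Mahalanobis distances between
the average patterns of 8 conditions — four orientation quadrants ([0,45),
[45,90), [90,135), [135,180) degrees) crossed with the two levels of the
factor — embedded in few dimensions by classical (Torgerson) MDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf

from .decoder import _chol_precision, _mahal_distances
from .features import FeatureMatrix

QUADRANT_EDGES = (0.0, 45.0, 90.0, 135.0, 180.0)
QUADRANT_LABELS = ("0-45", "45-90", "90-135", "135-180")


def orientation_quadrant(orientations) -> np.ndarray:
    """Quadrant index (0..3) of each orientation."""
    ori = np.asarray(orientations, dtype=float) % 180.0
    return np.minimum((ori // 45.0).astype(int), 3)


@dataclass
class ConditionDistanceMatrix:
    """Symmetric 8x8 Mahalanobis distances between condition averages."""

    labels: list[str]
    distances: np.ndarray
    n_repeats: int

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        self.distances = d


def _subsample_mean(x, cells, m, rng):
    """Equalise cell counts by subsampling m trials per cell, then average."""
    means = []
    used = []
    for idx in cells:
        pick = rng.choice(idx, size=m, replace=False)
        means.append(x[pick].mean(axis=0))
        used.append(pick)
    return np.asarray(means), np.concatenate(used)


def condition_distances(
    features_imp1: FeatureMatrix,
    features_imp2: FeatureMatrix,
    orientations,
    cue_side,
    scheme: str = "impulse",
    n_repeats: int = 100,
    rng=None,
) -> ConditionDistanceMatrix:
    """Average Mahalanobis distances between 8 condition patterns.

    scheme="impulse"
        Conditions are orientation quadrant x impulse.  Computed separately
        for left and right trials and averaged.  Per repeat, each
        quadrant's trials are randomly halved: one half contributes its
        impulse-1 data, the other its impulse-2 data; counts are equalised
        by subsampling before averaging, and the covariance is estimated
        from all contributing trials of both impulses.
    scheme="location"
        Conditions are orientation quadrant x cued side, computed on the
        per-trial average of the two impulse epochs; counts equalised per
        cell, covariance from all left and right trials.
    """
    rng = np.random.default_rng(rng)
    ori = np.asarray(orientations, dtype=float)
    side = np.asarray(cue_side)
    quad = orientation_quadrant(ori)
    x1 = np.asarray(features_imp1.values, dtype=float)
    x2 = np.asarray(features_imp2.values, dtype=float)

    if scheme == "impulse":
        labels = [f"imp{k}:{q}" for k in (1, 2) for q in QUADRANT_LABELS]
        per_side = []
        for s in ("left", "right"):
            sel = np.flatnonzero(side == s)
            if sel.size == 0:
                continue
            acc = np.zeros((8, 8))
            for _ in range(n_repeats):
                cells1, cells2 = [], []
                for q in range(4):
                    idx = sel[quad[sel] == q]
                    if idx.size < 2:
                        raise ValueError(
                            f"empty/degenerate cell: quadrant {QUADRANT_LABELS[q]}, side {s}"
                        )
                    idx = rng.permutation(idx)
                    half = idx.size // 2
                    cells1.append(idx[:half])
                    cells2.append(idx[half:])
                m = min(min(len(c) for c in cells1), min(len(c) for c in cells2))
                m1, used1 = _subsample_mean(x1, cells1, m, rng)
                m2, used2 = _subsample_mean(x2, cells2, m, rng)
                rows = np.concatenate([x1[used1], x2[used2]])
                cov, _ = ledoit_wolf(rows)
                pats = np.concatenate([m1, m2])
                acc += _mahal_distances(pats, pats, _chol_precision(cov))
            per_side.append(acc / n_repeats)
        dist = np.mean(per_side, axis=0)
    elif scheme == "location":
        labels = [f"{s}:{q}" for s in ("left", "right") for q in QUADRANT_LABELS]
        x = (x1 + x2) / 2.0
        cells = []
        for s in ("left", "right"):
            for q in range(4):
                idx = np.flatnonzero((side == s) & (quad == q))
                if idx.size == 0:
                    raise ValueError(f"empty cell: side {s}, quadrant {QUADRANT_LABELS[q]}")
                cells.append(idx)
        m = min(len(c) for c in cells)
        acc = np.zeros((8, 8))
        for _ in range(n_repeats):
            pats, used = _subsample_mean(x, cells, m, rng)
            cov, _ = ledoit_wolf(x[np.concatenate(cells)])
            acc += _mahal_distances(pats, pats, _chol_precision(cov))
        dist = acc / n_repeats
    else:
        raise ValueError("scheme must be 'impulse' or 'location'")

    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return ConditionDistanceMatrix(labels, dist, n_repeats)


def classical_mds(matrix: ConditionDistanceMatrix | np.ndarray, n_dims: int = 3):
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared-distance matrix, eigendecomposes it, and
    returns the coordinates along the top ``n_dims`` axes ordered by
    eigenvalue.  Axes with non-positive eigenvalues contribute zero
    coordinates (negative eigenvalues are truncated).

    Returns ``(coords, eigenvalues)`` with coords of shape (n, n_dims).
    """
    d = matrix.distances if isinstance(matrix, ConditionDistanceMatrix) else np.asarray(matrix, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, n_dims))
    for k in range(min(n_dims, n)):
        if evals[k] > 0:
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    return coords, evals
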