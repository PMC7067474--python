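"""Cross-condition generalisation and categorical state decoding.

Two families of analyses probe the structure of the impulse response:

* *Orientation-code generalisation* re-runs the Mahalanobis orientation
  reconstruction while training and testing in different conditions —
  across the two impulse epochs (same trials, different event) or across
  the cued item's presentation side (independent trial sets).  A stable
  coding scheme generalises; a condition-specific one does not.
* *Categorical decoding* classifies a binary state (which impulse, or which
  side was cued) from the distance difference between the test pattern and
  the two class templates; positive differences are hits, and percent hits
  is compared against the 50% chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf

from .decoder import (
    ReconstructionResult,
    _chol_precision,
    _mahal_distances,
    _stratified_folds,
    reconstruct,
    train_test_reconstruct,
)
from .features import FeatureMatrix


@dataclass
class CategoricalResult:
    """Trial-wise hits/misses of a binary state decoder."""

    hits: np.ndarray  # 0/1 per scored pattern
    accuracy: float  # percent hits
    chance: float = 50.0


def cross_impulse_reconstruct(
    features_imp1: FeatureMatrix,
    features_imp2: FeatureMatrix,
    orientations,
    n_repeats: int = 100,
    rng=None,
) -> tuple[ReconstructionResult, ReconstructionResult]:
    """Orientation reconstruction training on one impulse epoch and testing
    on the other.

    Both directions use the standard stratified 8-fold machinery on the
    shared trial indexing: the 7 training folds supply rows from the *other*
    epoch, and the held-out fold is scored in the test epoch, so a trial
    never contributes to its own templates in either epoch.  Returns the
    (trained-on-impulse-1 / tested-on-impulse-2, and vice versa) results.
    """
    if features_imp1.values.shape[0] != features_imp2.values.shape[0]:
        raise ValueError("impulse epochs must index the same trials")
    rng = np.random.default_rng(rng)
    r12 = reconstruct(
        features_imp2, orientations, n_repeats=n_repeats, rng=rng,
        train_features=features_imp1,
    )
    r21 = reconstruct(
        features_imp1, orientations, n_repeats=n_repeats, rng=rng,
        train_features=features_imp2,
    )
    return r12, r21


def cross_location_reconstruct(
    features: FeatureMatrix,
    orientations,
    cue_side,
    n_repeats: int = 100,
    rng=None,
) -> ReconstructionResult:
    """Orientation reconstruction across the cued item's presentation side.

    Left and right trials are independent sets, so no cross-validation is
    used: the decoder is trained on all left trials and tested on all right
    trials, and vice versa.  Training bins are balanced by random
    subsampling, repeated ``n_repeats`` times.  The returned result covers
    every trial (each scored in the direction where it was in the test set).
    """
    rng = np.random.default_rng(rng)
    side = np.asarray(cue_side)
    ori = np.asarray(orientations, dtype=float)
    n = ori.size
    left = np.flatnonzero(side == "left")
    right = np.flatnonzero(side == "right")
    if left.size < 16 or right.size < 16:
        raise ValueError("each side needs at least 16 usable trials")

    profiles = np.zeros((n, 16))
    accuracies = np.zeros(n)
    n_samples = 0
    for train_idx, test_idx in ((left, right), (right, left)):
        res = train_test_reconstruct(
            features.select_trials(train_idx),
            ori[train_idx],
            features.select_trials(test_idx),
            ori[test_idx],
            n_repeats=n_repeats,
            rng=rng,
        )
        profiles[test_idx] = res.profiles
        accuracies[test_idx] = res.accuracies
        n_samples = res.n_samples_per_trial
    return ReconstructionResult(profiles, accuracies, n_samples)


def decode_impulse_loo(
    features_imp1: FeatureMatrix,
    features_imp2: FeatureMatrix,
) -> CategoricalResult:
    """Leave-one-out decoding of impulse identity (1 vs 2).

    For each trial and epoch, the pattern's Mahalanobis distances to the
    mean of the remaining same-epoch trials and to the mean of the other
    epoch's remaining trials are compared; the covariance is estimated from
    the concatenated remaining trials of both epochs.  ``different - same >
    0`` is a hit (ties count as misses), and accuracy is percent hits over
    all trial x epoch patterns.
    """
    x1 = np.asarray(features_imp1.values, dtype=float)
    x2 = np.asarray(features_imp2.values, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("impulse epochs must index the same trials")
    n = x1.shape[0]
    if n < 3:
        raise ValueError("leave-one-out decoding needs at least 3 trials")

    sum1 = x1.sum(axis=0)
    sum2 = x2.sum(axis=0)
    hits = np.empty(2 * n)
    for i in range(n):
        rest = np.concatenate([np.delete(x1, i, axis=0), np.delete(x2, i, axis=0)])
        cov, _ = ledoit_wolf(rest)
        chol_l = _chol_precision(cov)
        m1 = (sum1 - x1[i]) / (n - 1)
        m2 = (sum2 - x2[i]) / (n - 1)
        d = _mahal_distances(np.vstack([x1[i], x2[i]]), np.vstack([m1, m2]), chol_l)
        # rows: the trial's two epoch patterns; cols: the two epoch means
        hits[2 * i] = 1.0 if d[0, 1] - d[0, 0] > 0 else 0.0
        hits[2 * i + 1] = 1.0 if d[1, 0] - d[1, 1] > 0 else 0.0
    return CategoricalResult(hits=hits, accuracy=100.0 * hits.mean())


def decode_category_kfold(
    features: FeatureMatrix,
    labels,
    n_folds: int = 8,
    rng=None,
) -> CategoricalResult:
    """8-fold cross-validated decoding of a binary trial label.

    Per test trial, the distance-difference score ``d(other-class mean) -
    d(own-class mean)`` is computed using the training folds' class means
    and shrinkage covariance; positive scores are hits.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(features.values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} trials, got {counts}"
        )
    y = (labels == classes[1]).astype(int)
    folds = _stratified_folds(y, n_folds, rng)
    hits = np.empty(x.shape[0])
    for f in range(n_folds):
        test = folds == f
        xtr, ytr = x[~test], y[~test]
        cov, _ = ledoit_wolf(xtr)
        chol_l = _chol_precision(cov)
        means = np.vstack([xtr[ytr == 0].mean(axis=0), xtr[ytr == 1].mean(axis=0)])
        d = _mahal_distances(x[test], means, chol_l)
        yt = y[test]
        score = d[np.arange(d.shape[0]), 1 - yt] - d[np.arange(d.shape[0]), yt]
        hits[test] = (score > 0).astype(float)
    return CategoricalResult(hits=hits, accuracy=100.0 * hits.mean())
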