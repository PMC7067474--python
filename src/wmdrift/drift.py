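"""Response-coupled drift of the neural orientation representation.

If the remembered orientation performs a random walk during the delay, the
neural code measured late in the delay should be displaced in the direction
of the eventual (bias-adjusted) report error.  Two complementary analyses
quantify this displacement from similarity profiles:

* **Response-dependent averaging** (approach A): per participant, average
  the trial-wise similarity profiles separately for CW and CCW responses,
  mirror the CCW average (so that positive orientation differences point
  towards the response), and average the two.  A rightward shift of the
  aligned profile indicates the code leans towards the response.
* **Response-split training and testing** (approach B): train the
  orientation decoder only on CW trials and test it on CCW trials, and
  vice versa.  Training and testing sets are displaced in *opposite*
  directions, so a true shift appears doubled in the reconstruction,
  making this the more sensitive probe.

Shift magnitude is summarised at the group level by the circular mean of
the aligned profile and at the participant level by an asymmetry score:
similarity towards the response (at +22.5, +45, +67.5 degrees) minus
similarity away from it (at -22.5, -45, -67.5 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import (
    DELTA_AXIS,
    circular_mean_profile,
    flip_profile,
    train_test_reconstruct,
)
from .features import FeatureMatrix, average_features

#: profile positions entering the asymmetry score
_POS_IDX = [np.flatnonzero(np.isclose(DELTA_AXIS, d))[0] for d in (22.5, 45.0, 67.5)]
_NEG_IDX = [np.flatnonzero(np.isclose(DELTA_AXIS, d))[0] for d in (-22.5, -45.0, -67.5)]


@dataclass
class DriftResult:
    """Aligned profiles and shift statistics for a cohort of participants."""

    aligned_profiles: np.ndarray  # n_participants x 16
    asymmetry_scores: np.ndarray  # n_participants
    group_shift: float  # circular mean of the group-average profile, degrees
    approach: str  # "average_split" or "train_test_split"


def asymmetry_score(aligned_profile) -> float:
    """Similarity towards minus similarity away from the response.

    Uses exactly the six orientation differences +-22.5, +-45 and +-67.5
    degrees; the entries at 0, +-11.25, +-33.75, +-56.25, +-78.75 and 90 do
    not enter.  Positive scores mean the profile leans towards the response.
    """
    p = np.asarray(aligned_profile, dtype=float)
    if p.shape[-1] != 16:
        raise ValueError("aligned profile must have 16 entries")
    return float(p[..., _POS_IDX].sum(axis=-1) - p[..., _NEG_IDX].sum(axis=-1)) if p.ndim == 1 else (
        p[..., _POS_IDX].sum(axis=-1) - p[..., _NEG_IDX].sum(axis=-1)
    )


def align_by_response(cw_profile, ccw_profile) -> np.ndarray:
    """Average a CW-response profile with the mirrored CCW-response profile.

    After the flip, positive orientation differences of the result point
    towards the behavioural response for both response classes.
    """
    return 0.5 * (np.asarray(cw_profile, float) + flip_profile(ccw_profile))


def response_aligned_average(
    profiles: np.ndarray,
    classes,
    participants=None,
) -> DriftResult:
    """Approach A: response-dependent averaging of trial-wise profiles.

    Parameters
    ----------
    profiles
        Trial-wise similarity profiles (n_trials x 16) from the standard
        cross-validated reconstruction.
    classes
        Per-trial response class; only ``CW`` and ``CCW`` trials enter.
    participants
        Per-trial participant id; default a single participant.
    """
    profiles = np.asarray(profiles, dtype=float)
    classes = np.asarray(classes)
    if participants is None:
        participants = np.zeros(len(classes), dtype=int)
    participants = np.asarray(participants)

    aligned, scores = [], []
    for p in np.unique(participants):
        cw = (participants == p) & (classes == "CW")
        ccw = (participants == p) & (classes == "CCW")
        if not cw.any() or not ccw.any():
            raise ValueError(f"participant {p}: a response class is empty")
        prof = align_by_response(profiles[cw].mean(axis=0), profiles[ccw].mean(axis=0))
        aligned.append(prof)
        scores.append(asymmetry_score(prof))
    aligned = np.asarray(aligned)
    return DriftResult(
        aligned_profiles=aligned,
        asymmetry_scores=np.asarray(scores),
        group_shift=circular_mean_profile(aligned.mean(axis=0)),
        approach="average_split",
    )


def response_split_train_test(
    test_features: FeatureMatrix,
    orientations,
    classes,
    train_features: FeatureMatrix | None = None,
    n_repeats: int = 100,
    rng=None,
) -> np.ndarray:
    """Approach B aligned profile for one participant and one test epoch.

    Trains on CW trials only and tests on CCW trials, and vice versa; the
    CCW-tested reconstruction is mirrored before averaging, so a genuine
    drift appears as a doubled positive shift.  ``train_features``
    (typically the impulse-averaged epoch) defaults to ``test_features``;
    training rows are always drawn from it, test rows from
    ``test_features``.

    Returns the 16-point aligned profile.
    """
    rng = np.random.default_rng(rng)
    if train_features is None:
        train_features = test_features
    ori = np.asarray(orientations, dtype=float)
    classes = np.asarray(classes)
    cw = np.flatnonzero(classes == "CW")
    ccw = np.flatnonzero(classes == "CCW")
    if cw.size < 16 or ccw.size < 16:
        raise ValueError("each response class needs at least 16 trials")

    # train on CW, test on CCW: a +s drift shifts this profile by -2s
    res_ccw = train_test_reconstruct(
        train_features.select_trials(cw), ori[cw],
        test_features.select_trials(ccw), ori[ccw],
        n_repeats=n_repeats, rng=rng,
    )
    # train on CCW, test on CW: shifted by +2s
    res_cw = train_test_reconstruct(
        train_features.select_trials(ccw), ori[ccw],
        test_features.select_trials(cw), ori[cw],
        n_repeats=n_repeats, rng=rng,
    )
    return align_by_response(
        res_cw.profiles.mean(axis=0), res_ccw.profiles.mean(axis=0)
    )


def drift_analysis_train_test(
    features_by_participant,
    n_repeats: int = 100,
    rng=None,
) -> DriftResult:
    """Approach B over a cohort.

    ``features_by_participant`` is an iterable of ``(test_features,
    orientations, classes, train_features)`` tuples, one per participant
    (``train_features`` may be None).
    """
    rng = np.random.default_rng(rng)
    aligned = []
    for test_f, ori, classes, train_f in features_by_participant:
        aligned.append(
            response_split_train_test(
                test_f, ori, classes, train_features=train_f,
                n_repeats=n_repeats, rng=rng,
            )
        )
    aligned = np.asarray(aligned)
    scores = np.array([asymmetry_score(p) for p in aligned])
    return DriftResult(
        aligned_profiles=aligned,
        asymmetry_scores=scores,
        group_shift=circular_mean_profile(aligned.mean(axis=0)),
        approach="train_test_split",
    )


def impulse_training_features(
    features_imp1: FeatureMatrix, features_imp2: FeatureMatrix
) -> FeatureMatrix:
    """Impulse-averaged training epoch (per-trial mean of the two impulse
    responses), used to improve reconstruction when testing on either
    impulse separately."""
    return average_features(features_imp1, features_imp2)
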