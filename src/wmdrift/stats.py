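"""Permutation, sign-flip and bootstrap inference.

Group-level significance is assessed non-parametrically:

* ``permutation_t_test`` compares the observed group t statistic with a
  null distribution of t statistics built from label-permuted re-analyses
  (one null statistic per participant per permutation).
* ``signflip_circmean_test`` tests whether the group-average aligned
  similarity profile is shifted to the right: each participant's profile is
  mirrored with probability 1/2 and the circular mean of the group average
  recomputed many times.
* ``bootstrap_ci`` gives percentile confidence intervals of the group mean
  by resampling participants.

All p-values use the ``(1 + #extreme) / (1 + n)`` convention, so p is never
exactly zero and the smallest attainable value is ``1 / (n + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .decoder import circular_mean_profile, flip_profile


@dataclass
class NullDistribution:
    """A permutation-style null with its observed statistic and p-value."""

    statistics: np.ndarray
    observed: float
    p: float
    sidedness: str  # "one" or "two"
    n_permutations: int


def _one_sample_t(values, mu0):
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    if sd == 0:
        return np.inf * np.sign(values.mean() - mu0) if values.mean() != mu0 else 0.0
    return (values.mean() - mu0) / (sd / np.sqrt(n))


def permutation_t_test(
    observed,
    nulls,
    mu0: float = 0.0,
    sidedness: str = "one",
) -> NullDistribution:
    """Group-level permutation t test.

    Parameters
    ----------
    observed
        One statistic per participant (e.g. decoding accuracy).
    nulls
        Array of shape (n_participants, n_permutations): each participant's
        statistics from analyses re-run with randomised condition labels.
        Permutation b combines every participant's b-th null value into one
        group t statistic, preserving exchangeability.
    mu0
        Chance value the t statistics are computed against.
    sidedness
        ``"one"``: the alternative is observed > mu0.  ``"two"``: absolute
        t values are compared.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim != 2 or nulls.shape[0] != observed.size:
        raise ValueError(
            "nulls must be (n_participants, n_permutations) matching observed"
        )
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    t_obs = _one_sample_t(observed, mu0)
    t_null = np.array([_one_sample_t(nulls[:, b], mu0) for b in range(nulls.shape[1])])
    if sidedness == "one":
        extreme = np.sum(t_null >= t_obs)
    else:
        extreme = np.sum(np.abs(t_null) >= np.abs(t_obs))
    n = t_null.size
    p = (1.0 + extreme) / (1.0 + n)
    return NullDistribution(t_null, float(t_obs), float(p), sidedness, n)


def permutation_t_test_difference(
    observed_a,
    observed_b,
    nulls_a,
    nulls_b,
    sidedness: str = "two",
) -> NullDistribution:
    """Permutation t test of a paired difference between two analyses.

    The paired null statistics are subtracted permutation-wise before the
    group t statistics are formed.
    """
    obs = np.asarray(observed_a, float) - np.asarray(observed_b, float)
    nulls = np.asarray(nulls_a, float) - np.asarray(nulls_b, float)
    return permutation_t_test(obs, nulls, mu0=0.0, sidedness=sidedness)


def signflip_circmean_test(
    aligned_profiles,
    n_iter: int = 100_000,
    rng=None,
) -> NullDistribution:
    """Sign-flip test of the group-level circular-mean shift.

    Each iteration mirrors every participant's aligned profile
    independently with probability 1/2, averages over participants, and
    records the circular mean; the one-sided p-value is the proportion of
    null circular means at least as positive as the observed one.
    """
    rng = np.random.default_rng(rng)
    profiles = np.asarray(aligned_profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need aligned profiles from at least 2 participants")
    if np.allclose(profiles, 0.0):
        raise ValueError("all-zero profiles: circular mean undefined")
    n_part = profiles.shape[0]
    observed = circular_mean_profile(profiles.mean(axis=0))
    flipped = flip_profile(profiles)
    null = np.empty(n_iter)
    for i in range(n_iter):
        flip = rng.random(n_part) < 0.5
        avg = np.where(flip[:, None], flipped, profiles).mean(axis=0)
        null[i] = circular_mean_profile(avg)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    return NullDistribution(null, float(observed), float(p), "one", n_iter)


def bootstrap_ci(
    values,
    n_boot: int = 100_000,
    level: float = 0.95,
    rng=None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean.

    Resampling is over participants (the unit of group-level CIs).  Values
    are sorted before resampling, so the interval depends only on the
    multiset of values, not their order.
    """
    rng = np.random.default_rng(rng)
    values = np.sort(np.asarray(values, dtype=float))
    if values.size < 2:
        raise ValueError("need at least 2 values")
    idx = rng.integers(values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def t_test_summary(values, mu0: float = 0.0) -> dict:
    """Plain one-sample t test (descriptive companion to the permutation
    machinery)."""
    values = np.asarray(values, dtype=float)
    t, p = sps.ttest_1samp(values, mu0)
    return {"mean": float(values.mean()), "t": float(t), "p_two_sided": float(p)}
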