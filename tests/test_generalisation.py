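import numpy as np
import pytest

import wmdrift as wd
from wmdrift.features import FeatureMatrix, average_features
from wmdrift.generalisation import (
    cross_impulse_reconstruct,
    cross_location_reconstruct,
    decode_category_kfold,
    decode_impulse_loo,
)
from wmdrift.synth import SynthConfig, generate_dataset


def as_features(x, event="toy"):
    x = np.asarray(x, dtype=float)
    return FeatureMatrix(x, x.shape[1], 1, (0.0, 0.0), event)


@pytest.fixture(scope="module")
def located_dataset():
    cfg = SynthConfig(n_participants=1, n_trials=240, n_channels=8, seed=21)
    epochs, table, truth = generate_dataset(cfg)
    feats = {ev: wd.featurize(epochs[ev]) for ev in wd.EVENTS}
    return cfg, feats, table, truth


# ------------------------------------------------------------- impulse LOO

def test_impulse_loo_separable_means():
    """A large impulse-specific pattern makes the classifier near-perfect."""
    rng = np.random.default_rng(0)
    base = rng.standard_normal((40, 6))
    offset = rng.standard_normal(6) * 4
    r = decode_impulse_loo(as_features(base), as_features(base + offset))
    assert r.accuracy > 95.0


def test_impulse_loo_exchangeable_epochs_at_chance():
    """Identically distributed epochs decode at ~50% on average."""
    rng = np.random.default_rng(1)
    accs = [
        decode_impulse_loo(
            as_features(rng.standard_normal((30, 6))),
            as_features(rng.standard_normal((30, 6))),
        ).accuracy
        for _ in range(20)
    ]
    accs = np.asarray(accs)
    se = accs.std(ddof=1) / np.sqrt(accs.size)
    assert abs(accs.mean() - 50.0) < 3 * se + 1e-9


def test_impulse_loo_symmetric_under_epoch_swap():
    rng = np.random.default_rng(2)
    a = as_features(rng.standard_normal((25, 5)))
    b = as_features(rng.standard_normal((25, 5)) + 0.3)
    assert decode_impulse_loo(a, b).accuracy == decode_impulse_loo(b, a).accuracy


def test_impulse_loo_tie_is_miss():
    # identical data in both epochs: every distance difference is exactly 0
    x = np.tile(np.arange(12.0)[:, None], (1, 4))
    r = decode_impulse_loo(as_features(x), as_features(x.copy()))
    assert r.accuracy == 0.0


def test_impulse_loo_requires_trials():
    x = np.zeros((2, 3))
    with pytest.raises(ValueError, match="3 trials"):
        decode_impulse_loo(as_features(x), as_features(x))


# ------------------------------------------------------------ k-fold binary

def test_kfold_permuted_labels_at_chance(located_dataset):
    _, feats, table, _ = located_dataset
    rng = np.random.default_rng(3)
    labels = rng.permutation(table["cue_side"].to_numpy())
    r = decode_category_kfold(average_features(feats["impulse1"], feats["impulse2"]),
                              labels, rng=0)
    # permuted labels carry no signal; binomial 3-sigma band around 50%
    assert abs(r.accuracy - 50.0) < 3 * 50.0 / np.sqrt(r.hits.size)


def test_kfold_decodes_cued_location(located_dataset):
    _, feats, table, _ = located_dataset
    r = decode_category_kfold(average_features(feats["impulse1"], feats["impulse2"]),
                              table["cue_side"].to_numpy(), rng=0)
    assert r.accuracy > 90.0  # strong lateralised trace in the generator


def test_kfold_rejects_degenerate_labels():
    x = np.zeros((20, 3))
    with pytest.raises(ValueError, match="2 classes"):
        decode_category_kfold(as_features(x), ["A"] * 20)
    with pytest.raises(ValueError, match="at least 8"):
        decode_category_kfold(as_features(x), ["A"] * 16 + ["B"] * 4)


# ----------------------------------------------------- orientation x-impulse

def test_cross_impulse_matches_within_for_exchangeable_epochs():
    """With no impulse-specific pattern and no drift the two epochs are
    exchangeable, so cross-impulse decoding equals within-impulse decoding
    up to dataset-level noise (checked across independent datasets)."""
    diffs, crosses = [], []
    for seed in (21, 22, 23, 25):
        cfg = SynthConfig(n_participants=1, n_trials=240, n_channels=8,
                          seed=seed, impulse_offset_gain=0.0,
                          drift_sd_impulse1=0.0, drift_step_sd=0.0)
        epochs, table, _ = generate_dataset(cfg)
        ori = table["cued_orientation"].to_numpy()
        f1 = wd.featurize(epochs["impulse1"])
        f2 = wd.featurize(epochs["impulse2"])
        r12, r21 = cross_impulse_reconstruct(f1, f2, ori, n_repeats=1, rng=seed)
        cross = (r12.accuracies + r21.accuracies) / 2
        within = wd.reconstruct(f2, ori, n_repeats=1, rng=seed).accuracies
        diffs.append(cross.mean() - within.mean())
        crosses.append(cross.mean())
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    assert np.mean(crosses) > 0.02  # the code clearly generalises
    assert abs(diffs.mean()) < 3 * se


def test_cross_impulse_near_within_under_study_conditions(located_dataset):
    """With the default impulse-specific pattern and drift, the stable
    orientation code still carries most of its strength across epochs."""
    _, feats, table, _ = located_dataset
    ori = table["cued_orientation"].to_numpy()
    r12, r21 = cross_impulse_reconstruct(feats["impulse1"], feats["impulse2"],
                                         ori, n_repeats=2, rng=4)
    cross = (r12.accuracies + r21.accuracies) / 2
    within = wd.reconstruct(feats["impulse2"], ori, n_repeats=2, rng=4).accuracies
    assert within.mean() > 0.02
    assert cross.mean() > 0.7 * within.mean()


def test_cross_impulse_fails_for_dynamic_code():
    """With independent tuning maps per impulse there is nothing to
    generalise: cross-impulse accuracy is ~0 while within stays positive."""
    cfg = SynthConfig(n_participants=1, n_trials=240, n_channels=8, seed=22,
                      impulse_offset_gain=0.0)
    epochs, table, _ = generate_dataset(cfg)
    ori = table["cued_orientation"].to_numpy()
    f1 = wd.featurize(epochs["impulse1"])
    # a fresh, unrelated dataset's impulse epoch stands in for an impulse
    # with its own private tuning maps
    cfg2 = SynthConfig(n_participants=1, n_trials=240, n_channels=8, seed=23,
                       impulse_offset_gain=0.0)
    epochs2, _, _ = generate_dataset(cfg2)
    f2alt = wd.featurize(epochs2["impulse2"])
    r12, r21 = cross_impulse_reconstruct(f1, f2alt, ori, n_repeats=2, rng=5)
    cross = (r12.accuracies + r21.accuracies) / 2
    within = wd.reconstruct(f1, ori, n_repeats=2, rng=5).accuracies
    se = cross.std(ddof=1) / np.sqrt(cross.size)
    assert abs(cross.mean()) < 3 * se
    assert within.mean() > 3 * within.std(ddof=1) / np.sqrt(within.size)


# ---------------------------------------------------- orientation x-location

def test_cross_location_null_within_positive(located_dataset):
    """Location-specific tuning maps do not cross-generalise: the
    cross-location accuracy is zero on average over independent datasets
    while within-location decoding stays clearly positive."""
    means = []
    for seed in (31, 32, 33, 34, 35):
        cfg = SynthConfig(n_participants=1, n_trials=320, n_channels=8,
                          seed=seed, drift_sd_impulse1=0.0, drift_step_sd=0.0)
        epochs, table, _ = generate_dataset(cfg)
        f2 = wd.featurize(epochs["impulse2"])
        rx = cross_location_reconstruct(
            f2, table["cued_orientation"].to_numpy(),
            table["cue_side"].to_numpy(), n_repeats=5, rng=1000 + seed,
        )
        means.append(rx.accuracies.mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(means.size)
    assert abs(means.mean()) < 3 * se
    # within-location decoding on the shared fixture stays clearly positive
    _, feats, table, _ = located_dataset
    rw = wd.reconstruct(feats["impulse2"],
                        table["cued_orientation"].to_numpy(), n_repeats=2,
                        rng=6)
    assert rw.accuracies.mean() > 0.01


def test_cross_location_generalises_with_shared_maps():
    cfg = SynthConfig(n_participants=1, n_trials=240, n_channels=8, seed=24,
                      location_specific=False)
    epochs, table, _ = generate_dataset(cfg)
    f2 = wd.featurize(epochs["impulse2"])
    ori = table["cued_orientation"].to_numpy()
    rx = cross_location_reconstruct(f2, ori, table["cue_side"].to_numpy(),
                                    n_repeats=5, rng=7)
    se = rx.accuracies.std(ddof=1) / np.sqrt(rx.accuracies.size)
    assert rx.accuracies.mean() > 3 * se


def test_cross_location_needs_both_sides():
    x = np.zeros((40, 3))
    with pytest.raises(ValueError, match="16 usable"):
        cross_location_reconstruct(as_features(x), np.linspace(0, 179, 40),
                                   np.array(["left"] * 35 + ["right"] * 5))
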