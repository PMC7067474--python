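"""Synthetic impulse-response EEG with a drifting orientation code.

The generator emulates the statistical structure of a retro-cue orientation
working-memory experiment in which task-neutral visual impulses are flashed
during the delay:

* each trial carries a cued grating orientation ``theta`` in [0, 180);
* the evoked response encodes the *currently held* orientation through a pair
  of participant-specific tuning maps (channels x samples) driving the
  doubled-angle components ``sin 2(theta + delta)`` and ``cos 2(theta +
  delta)``;
* the coding subspace is location specific by default: the left- and
  right-presentation items use distinct tuning-map pairs, so a decoder
  trained on one side does not generalise to the other;
* each impulse additionally evokes a fixed "time stamp" pattern, constant
  across trials but different between impulse 1 and impulse 2; by default it
  is orthogonalised against the orientation subspace, so the temporal axis
  and the mnemonic code occupy independent dimensions;
* each presentation side additionally leaves a fixed additive trace
  (``location_offset_gain``), emulating the lateralised component of the
  evoked response that makes the cued location itself decodable;
* the remembered orientation performs a two-point random walk: the code is
  veridical at encoding, displaced by ``delta1 ~ N(0, drift_sd_impulse1^2)``
  at impulse 1, and by ``delta2 = delta1 + N(0, drift_step_sd^2)`` at
  impulse 2; the behavioural report error couples to ``delta2``, plus a
  cardinal-repulsion bias ``cardinal_bias_amp * sin(4 theta)`` and motor
  noise;
* sensor noise is Gaussian, independent over samples, with a random
  participant-specific SPD channel covariance.

Default sizes match the source experiment's scale (26 participants, 1,100
trials each); analyses and tests pass smaller sizes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._circular import wrap_diff, wrap_orientation
from .io import EpochSet, EVENTS

#: the 17 posterior channels used for decoding in this paradigm
POSTERIOR_17 = [
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic experiment.

    Amplitudes are in arbitrary voltage units, angles and SDs in degrees.
    """

    n_participants: int = 26
    n_trials: int = 1100
    n_channels: int = 17
    sample_rate: float = 500.0
    epoch_window: tuple[float, float] = (0.0, 400.0)
    tuning_gain: float = 1.0
    location_specific: bool = True
    impulse_offset_gain: float = 1.0
    location_offset_gain: float = 1.0
    orthogonal_time_axis: bool = True
    drift_sd_impulse1: float = 5.0
    drift_step_sd: float = 7.0
    report_coupling: float = 1.0
    motor_noise_sd: float = 8.0
    cardinal_bias_amp: float = 5.0
    noise_cov_scale: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "tuning_gain",
            "impulse_offset_gain",
            "location_offset_gain",
            "drift_sd_impulse1",
            "drift_step_sd",
            "motor_noise_sd",
            "noise_cov_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_trials < 64:
            raise ValueError(
                "n_trials must be at least 64 so that stratified 8-fold "
                "cross-validation over 16 orientation bins is feasible"
            )
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        lo, hi = self.epoch_window
        if not (lo <= 100.0 and hi >= 400.0):
            raise ValueError("epoch_window must cover at least 100-400 ms")


@dataclass
class GroundTruth:
    """Latent state of a generated dataset.

    ``theta``, ``delta1``, ``delta2`` are per-trial (concatenated over
    participants, aligned with the trial table).  ``tuning_maps[p][side]``
    is the (W_sin, W_cos) pair of channels x samples maps of participant p;
    ``impulse_patterns[p][event]`` the additive time-stamp pattern.
    """

    theta: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    tuning_maps: list[dict[str, tuple[np.ndarray, np.ndarray]]]
    impulse_patterns: list[dict[str, np.ndarray]]


def _participant_patterns(rng, cfg, n_samples):
    """Draw one participant's tuning maps, impulse patterns and noise chol."""
    shape = (cfg.n_channels, n_samples)
    w_left = (rng.standard_normal(shape), rng.standard_normal(shape))
    if cfg.location_specific:
        w_right = (rng.standard_normal(shape), rng.standard_normal(shape))
    else:
        w_right = w_left
    maps = {"left": w_left, "right": w_right}

    patterns = {
        "impulse1": rng.standard_normal(shape),
        "impulse2": rng.standard_normal(shape),
    }
    side_patterns = {"left": rng.standard_normal(shape),
                     "right": rng.standard_normal(shape)}
    if cfg.orthogonal_time_axis:
        # project the impulse patterns onto the orthogonal complement of the
        # span of the tuning maps, so the time axis cannot mimic orientation
        basis = [w.ravel() for pair in (w_left, w_right) for w in pair]
        q, _ = np.linalg.qr(np.column_stack(basis))
        for ev, m in patterns.items():
            v = m.ravel()
            patterns[ev] = (v - q @ (q.T @ v)).reshape(shape)

    # random SPD channel covariance, scaled to unit mean variance
    a = rng.standard_normal((cfg.n_channels, cfg.n_channels))
    cov = a @ a.T / cfg.n_channels
    cov *= cfg.noise_cov_scale**2 / np.mean(np.diag(cov)) if cfg.noise_cov_scale > 0 else 0.0
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cfg.n_channels))
    return maps, patterns, side_patterns, chol


def generate_dataset(
    config: SynthConfig,
) -> tuple[dict[str, EpochSet], pd.DataFrame, GroundTruth]:
    """Generate epoched data for the three events plus behaviour and truth.

    Returns ``(epochs, trial_table, ground_truth)`` where ``epochs`` maps
    each of ``memory_array``, ``impulse1``, ``impulse2`` to an
    :class:`~wmdrift.io.EpochSet` whose trials are concatenated over
    participants in trial-table order.  Identical configs (same seed)
    produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.epoch_window
    step = 1000.0 / config.sample_rate
    times = lo + step * np.arange(int(round((hi - lo) / step)))
    n_samples = times.size
    if config.n_channels == 17:
        channels = list(POSTERIOR_17)
    else:
        channels = [f"ch{i + 1:02d}" for i in range(config.n_channels)]

    n_total = config.n_participants * config.n_trials
    data = {ev: np.empty((n_total, config.n_channels, n_samples)) for ev in EVENTS}
    rows = []
    theta_all = np.empty(n_total)
    d1_all = np.empty(n_total)
    d2_all = np.empty(n_total)
    all_maps, all_patterns = [], []

    for p in range(config.n_participants):
        maps, patterns, side_patterns, noise_chol = _participant_patterns(
            rng, config, n_samples
        )
        all_maps.append(maps)
        all_patterns.append(patterns)
        sl = slice(p * config.n_trials, (p + 1) * config.n_trials)

        ori_left = rng.uniform(0.0, 180.0, size=config.n_trials)
        ori_right = rng.uniform(0.0, 180.0, size=config.n_trials)
        cue_side = np.where(rng.random(config.n_trials) < 0.5, "left", "right")
        theta = np.where(cue_side == "left", ori_left, ori_right)
        delta1 = rng.normal(0.0, config.drift_sd_impulse1, size=config.n_trials)
        delta2 = delta1 + rng.normal(0.0, config.drift_step_sd, size=config.n_trials)

        deltas = {"memory_array": np.zeros(config.n_trials),
                  "impulse1": delta1, "impulse2": delta2}
        for ev in EVENTS:
            coded = np.deg2rad(2.0 * (theta + deltas[ev]))
            block = np.empty((config.n_trials, config.n_channels, n_samples))
            for side in ("left", "right"):
                idx = np.flatnonzero(cue_side == side)
                if idx.size == 0:
                    continue
                w_sin, w_cos = maps[side]
                block[idx] = config.tuning_gain * (
                    np.sin(coded[idx])[:, None, None] * w_sin
                    + np.cos(coded[idx])[:, None, None] * w_cos
                ) + config.location_offset_gain * side_patterns[side]
            if ev in ("impulse1", "impulse2"):
                block += config.impulse_offset_gain * patterns[ev]
            noise = rng.standard_normal((config.n_trials, config.n_channels, n_samples))
            block += np.einsum("ij,tjs->tis", noise_chol, noise)
            data[ev][sl] = block

        bias = config.cardinal_bias_amp * np.sin(np.deg2rad(4.0 * theta))
        motor = rng.normal(0.0, config.motor_noise_sd, size=config.n_trials)
        error = wrap_diff(config.report_coupling * delta2 + bias + motor)

        theta_all[sl], d1_all[sl], d2_all[sl] = theta, delta1, delta2
        rows.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "orientation_left": wrap_orientation(ori_left),
                    "orientation_right": wrap_orientation(ori_right),
                    "cue_side": cue_side,
                    "cued_orientation": wrap_orientation(theta),
                    "report_error": error,
                }
            )
        )

    epochs = {
        ev: EpochSet(data[ev], times, channels, ev, config.sample_rate)
        for ev in EVENTS
    }
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(theta_all, d1_all, d2_all, all_maps, all_patterns)
    return epochs, table, truth


def config_dict(config: SynthConfig) -> dict:
    """Plain-dict view of a config (for result metadata)."""
    return asdict(config)
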