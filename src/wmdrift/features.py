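"""Multivariate feature extraction from epoched data.

An evoked impulse response is treated as a single multivariate pattern
pooled over channels *and* time: the window of interest is demeaned per
trial and channel (isolating the dynamic, impulse-evoked signal from slower
state differences), down-sampled to 100 Hz by averaging consecutive 10-ms
blocks, and flattened to one vector per trial.  With the canonical 17
posterior channels and the [100, 400) ms window at 500 Hz this yields
30 time bins per channel and 510 feature dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochSet

BIN_MS = 10.0


@dataclass
class FeatureMatrix:
    """Flattened trials x (channels * timebins) feature vectors."""

    values: np.ndarray
    n_channels: int
    n_timebins: int
    window: tuple[float, float]
    source_event: str

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_trials(self, index) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[index],
            self.n_channels,
            self.n_timebins,
            self.window,
            self.source_event,
        )


def featurize(
    epochs: EpochSet,
    window: tuple[float, float] = (100.0, 400.0),
    channels: list[str] | None = None,
) -> FeatureMatrix:
    """Extract demeaned, 10-ms-binned feature vectors from one event.

    Parameters
    ----------
    epochs
        Epoched voltage data.
    window
        Half-open [start, stop) interval in ms relative to event onset.
        Its length must be a whole multiple of 10 ms, and 10 ms must
        correspond to an integer number of samples.
    channels
        Channel names to keep (in the epoch's own order); default all.

    Notes
    -----
    The per-trial, per-channel mean over the window is removed *before*
    down-sampling, so adding any constant offset to a trial/channel leaves
    the output unchanged and each trial/channel's bins average to zero.
    """
    if channels is None:
        channels = list(epochs.channels)
    unknown = [c for c in channels if c not in epochs.channels]
    if unknown:
        raise ValueError(f"unknown channels: {unknown}")
    ch_idx = [epochs.channels.index(c) for c in channels]

    lo, hi = window
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if epochs.times.size == 0 or lo < epochs.times[0] or hi > epochs.times[-1] + 1000.0 / epochs.sample_rate:
        raise ValueError(
            f"window [{lo}, {hi}) not covered by epoch time axis "
            f"[{epochs.times[0]}, {epochs.times[-1]}]"
        )
    block = BIN_MS * epochs.sample_rate / 1000.0
    if abs(block - round(block)) > 1e-9:
        raise ValueError(
            f"10 ms is not an integer number of samples at {epochs.sample_rate} Hz"
        )
    block = int(round(block))
    n_samples = int(mask.sum())
    if n_samples % block != 0:
        raise ValueError(
            f"window length {hi - lo} ms is not a whole number of 10-ms blocks"
        )
    n_bins = n_samples // block

    x = epochs.data[:, ch_idx][:, :, mask]
    x = x - x.mean(axis=2, keepdims=True)
    x = x.reshape(x.shape[0], x.shape[1], n_bins, block).mean(axis=3)
    values = x.reshape(x.shape[0], len(ch_idx) * n_bins)
    return FeatureMatrix(values, len(ch_idx), n_bins, (lo, hi), epochs.event)


def average_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Per-trial average of two feature matrices over the same trials."""
    if a.values.shape != b.values.shape:
        raise ValueError("feature matrices must share shape to be averaged")
    return FeatureMatrix(
        (a.values + b.values) / 2.0,
        a.n_channels,
        a.n_timebins,
        a.window,
        f"mean({a.source_event},{b.source_event})",
    )
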