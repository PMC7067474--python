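"""Behavioural quality control and response-class labelling.

Three steps prepare the trial table for the neural drift analyses:

1. ``exclude_guesses`` drops, per participant, trials whose report error
   lies more than 3 circular standard deviations from that participant's
   circular mean error — such trials likely reflect complete guesses.
2. ``adjust_bias`` removes the systematic, orientation-dependent report
   bias (a repulsion from the cardinal axes) by subtracting the median
   error within 11.25-degree orientation bins, isolating random from
   systematic errors.
3. ``label_response_class`` labels each trial clockwise (CW) or
   counterclockwise (CCW) by the sign of the adjusted error.  Because the
   per-bin median of the adjusted error is zero, CW and CCW trials are
   balanced within every orientation bin, which the response-conditioned
   decoding analyses require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._circular import circ_mean_error, circ_sd_error, signed_diff

N_BIAS_BINS = 16
BIAS_BIN_WIDTH = 180.0 / N_BIAS_BINS  # 11.25 degrees


@dataclass
class BiasModel:
    """Per-orientation-bin median report error (the systematic bias).

    Medians are estimated separately per participant (the analysis unit);
    ``median_error_per_bin`` has one row per entry of ``participants``.
    """

    bin_edges: np.ndarray  # 17 edges tiling [0, 180]
    median_error_per_bin: np.ndarray  # (n_participants, 16), degrees
    participants: list


def orientation_bin(orientations) -> np.ndarray:
    """Fixed 11.25-degree bin index (0..15) of each orientation, bins
    anchored at 0 degrees."""
    ori = np.asarray(orientations, dtype=float) % 180.0
    return np.minimum((ori // BIAS_BIN_WIDTH).astype(int), N_BIAS_BINS - 1)


def exclude_guesses(table: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Flag trials whose report error is a circular outlier.

    Per participant, the circular mean and circular SD of the report error
    are computed on doubled angles; trials farther than ``n_sd`` circular
    SDs from the mean get ``include = False``.  Returns a copy with the
    ``include`` column set.
    """
    if "report_error" not in table.columns:
        raise ValueError("report_error column required")
    out = table.copy()
    include = np.ones(len(out), dtype=bool)
    for _, idx in out.groupby("participant").groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError("need at least 2 trials per participant")
        err = out.loc[idx, "report_error"].to_numpy(dtype=float)
        mu = circ_mean_error(err)
        sd = circ_sd_error(err)
        dev = np.abs(signed_diff(err, mu))
        include[idx] = dev <= n_sd * sd
    out["include"] = include
    return out


def adjust_bias(table: pd.DataFrame) -> tuple[pd.DataFrame, BiasModel]:
    """Remove the orientation-dependent median report bias.

    Within each of 16 fixed 11.25-degree bins of the cued orientation
    (included trials only, separately per participant), the median report
    error is subtracted, so every participant's per-bin median adjusted
    error is exactly zero.  Excluded trials get a NaN adjusted error.
    Raises if an orientation bin holds no included trials.
    """
    out = table.copy()
    if "include" not in out.columns:
        out["include"] = True
    inc = out["include"].to_numpy(dtype=bool)
    bins = orientation_bin(out["cued_orientation"])
    err = out["report_error"].to_numpy(dtype=float)
    adjusted = np.full(len(out), np.nan)
    participants = sorted(out["participant"].unique())
    medians = np.full((len(participants), N_BIAS_BINS), np.nan)
    for pi, (p, idx) in enumerate(
        sorted(out.groupby("participant").groups.items(), key=lambda kv: kv[0])
    ):
        idx = np.asarray(idx)
        for b in range(N_BIAS_BINS):
            sel = idx[inc[idx] & (bins[idx] == b)]
            if sel.size == 0:
                lo = b * BIAS_BIN_WIDTH
                raise ValueError(
                    f"participant {p}: no included trials in orientation bin "
                    f"[{lo}, {lo + BIAS_BIN_WIDTH})"
                )
            medians[pi, b] = np.median(err[sel])
        keep = idx[inc[idx]]
        adjusted[keep] = signed_diff(err[keep], medians[pi, bins[keep]])
    out["adjusted_error"] = adjusted
    model = BiasModel(
        bin_edges=BIAS_BIN_WIDTH * np.arange(N_BIAS_BINS + 1),
        median_error_per_bin=medians,
        participants=participants,
    )
    return out, model


def label_response_class(table: pd.DataFrame) -> pd.DataFrame:
    """Label trials CW/CCW by the sign of the adjusted report error.

    Adjusted errors of exactly zero (the per-bin median trials) are labelled
    ``excluded``: a deterministic tie rule that keeps the two classes
    unbiased.  Excluded/NaN trials are also labelled ``excluded``.
    """
    if "adjusted_error" not in table.columns:
        raise ValueError("run adjust_bias first: adjusted_error column required")
    out = table.copy()
    adj = out["adjusted_error"].to_numpy(dtype=float)
    cls = np.where(adj > 0, "CW", np.where(adj < 0, "CCW", "excluded"))
    cls[~np.isfinite(adj)] = "excluded"
    out["response_class"] = cls
    return out


def prepare_behaviour(table: pd.DataFrame) -> tuple[pd.DataFrame, BiasModel]:
    """Full behavioural pipeline: exclusion, bias adjustment, CW/CCW labels."""
    out = exclude_guesses(table)
    out, model = adjust_bias(out)
    out = label_response_class(out)
    return out, model
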