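"""Circular arithmetic for orientations with a 180-degree period.

Grating orientation is an axial quantity: theta and theta + 180 are the same
stimulus.  All circular statistics therefore operate on the doubled angle
2*theta (period 360), and results are halved back to orientation space.
"""

from __future__ import annotations

import numpy as np

ORI_PERIOD = 180.0


def wrap_orientation(theta):
    """Wrap orientation(s) into [0, 180)."""
    w = np.asarray(theta, dtype=float) % ORI_PERIOD
    # float rounding can yield exactly 180.0 for tiny negative inputs
    return np.where(w >= ORI_PERIOD, w - ORI_PERIOD, w)


def wrap_diff(delta):
    """Wrap signed orientation difference(s) into (-90, 90]."""
    half = ORI_PERIOD / 2
    return half - ((half - np.asarray(delta, dtype=float)) % ORI_PERIOD)


def signed_diff(a, b):
    """Signed circular difference a - b in (-90, 90] (degrees)."""
    return wrap_diff(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circ_mean_error(errors):
    """Circular mean of signed report errors (degrees in (-90, 90]).

    Computed on doubled angles so that -90 and +90 are identified.
    """
    z = np.exp(1j * np.deg2rad(2.0 * np.asarray(errors, dtype=float)))
    return float(np.rad2deg(np.angle(np.mean(z))) / 2.0)


def circ_sd_error(errors):
    """Circular standard deviation of signed report errors, in degrees.

    Uses the doubled-angle mapping and the standard definition
    sd = sqrt(-2 ln R) on the doubled circle, halved back to orientation
    units.  Zero when all errors coincide.
    """
    z = np.exp(1j * np.deg2rad(2.0 * np.asarray(errors, dtype=float)))
    r = np.abs(np.mean(z))
    r = min(r, 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r)) if r > 0 else np.inf) / 2.0)
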