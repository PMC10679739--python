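"""Circular helpers.

All public angles in this package are degrees in [0, 360), with 0° pointing
up and positive angles running clockwise. Radians are used internally where
trigonometry demands it.
"""

from __future__ import annotations

import numpy as np

DEG2RAD = np.pi / 180.0
RAD2DEG = 180.0 / np.pi

#: Default reconstruction grid: 1°..360° in steps of 1°.
DEFAULT_GRID = np.arange(1.0, 361.0)


def wrap_deg(theta):
    """Wrap angles into [0, 360)."""
    return np.mod(np.asarray(theta, dtype=float), 360.0)


def signed_error_deg(theta_ref, theta):
    """Signed circular difference ``theta - theta_ref`` wrapped to (-180, 180]."""
    d = np.mod(np.asarray(theta, dtype=float) - np.asarray(theta_ref, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circdist_deg(a, b):
    """Shortest-arc circular distance in degrees, in [0, 180]."""
    return np.abs(signed_error_deg(a, b))
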