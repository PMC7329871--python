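"""Angle conventions used throughout the package.

All directions are horizontal-plane bearings in degrees in the chamber
frame: the along-aisle X-axis is 0 deg, the lateral Y-axis is +90 deg.
Angles are wrapped to the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # map -180 -> 180 so the interval is half-open on the left
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def signed_diff_deg(a, b):
    """Signed minimal angular difference a - b, in (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def abs_diff_deg(a, b):
    """Absolute minimal angular difference |a - b| in [0, 180]."""
    return np.abs(signed_diff_deg(a, b))


def bearing_deg(dx, dy):
    """Bearing of a displacement (dx, dy) in the chamber frame."""
    return wrap_deg(np.degrees(np.arctan2(dy, dx)))
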