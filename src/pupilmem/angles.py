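"""Circular (angular) helpers shared across the package.

All recall errors live on the circle.  The package-wide convention is a
signed error in degrees on the half-open interval (-180, 180]; the +180
boundary is kept (not mapped to -180) so that an exactly-opposite response
has a well-defined sign.
"""

from __future__ import annotations

import numpy as np


def wrap_signed_deg(angle_deg):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180].

    Accepts scalars or arrays; returns the same shape.  Adding any multiple
    of 360 degrees to the input leaves the result unchanged.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    out = a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return float(out) if out.ndim == 0 else out


def wrap_positive_deg(angle_deg):
    """Wrap angle(s) in degrees to (0, 360] (stimulus-angle convention)."""
    a = np.asarray(angle_deg, dtype=float)
    out = a - 360.0 * np.ceil((a - 360.0) / 360.0)
    return float(out) if out.ndim == 0 else out


def deg_to_rad(angle_deg):
    return np.deg2rad(angle_deg)


def rad_to_deg(angle_rad):
    return np.rad2deg(angle_rad)
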