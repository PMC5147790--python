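"""Compass-angle helpers shared by the virtual surveyor and the corrections.

Compass azimuths are measured clockwise from north in [0, 360).  Survey
records store bearings as a quadrant (NE/SE/SW/NW) plus an angle in [0, 90]
within the quadrant (e.g. N30E = compass 30, S45E = compass 135).
"""
from __future__ import annotations

import numpy as np

QUADRANTS = ("NE", "SE", "SW", "NW")
CARDINALS = np.array([0.0, 90.0, 180.0, 270.0])


def circular_distance(a, b):
    """Minimal angular separation in degrees between compass angles."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def pair_angle(az1, az2):
    """Angle in [0, 180] between the bearings of two trees at a corner."""
    return circular_distance(az1, az2)


def compass_to_quadrant(az):
    """Compass azimuth -> (quadrant, angle-in-quadrant in [0, 90])."""
    az = float(az) % 360.0
    if az < 90.0:
        return "NE", az
    if az < 180.0:
        return "SE", 180.0 - az
    if az < 270.0:
        return "SW", az - 180.0
    return "NW", 360.0 - az


def quadrant_to_compass(quadrant, angle):
    """(quadrant, angle-in-quadrant) -> compass azimuth in [0, 360)."""
    angle = float(angle)
    if not 0.0 <= angle <= 90.0:
        raise ValueError(f"angle within quadrant must be in [0, 90], got {angle}")
    if quadrant == "NE":
        return angle % 360.0
    if quadrant == "SE":
        return (180.0 - angle) % 360.0
    if quadrant == "SW":
        return (180.0 + angle) % 360.0
    if quadrant == "NW":
        return (360.0 - angle) % 360.0
    raise ValueError(f"unknown quadrant {quadrant!r}")


def in_window(az, center, width):
    """True where compass angle az lies within ±width/2 of center."""
    return circular_distance(az, center) <= width / 2.0
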