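"""Surveyor (link, inch) and metric unit conventions.

Public Land Survey distances were chained in Gunter's links
(1 link = 0.201168 m) and diameters recorded in inches.
"""
from __future__ import annotations

import numpy as np

LINK_M = 0.201168  # 1 Gunter's link, exactly 0.66 ft
INCH_CM = 2.54
DIAMETER_LIMIT_IN = 8.0
DIAMETER_LIMIT_CM = DIAMETER_LIMIT_IN * INCH_CM  # 20.32 cm


def links_to_m(links):
    """Convert distances in links to meters. Rejects negative input."""
    links = np.asarray(links, dtype=float)
    if np.any(links[np.isfinite(links)] < 0):
        raise ValueError("distance in links must be non-negative")
    out = links * LINK_M
    return float(out) if out.ndim == 0 else out


def m_to_links(m):
    m = np.asarray(m, dtype=float)
    if np.any(m[np.isfinite(m)] < 0):
        raise ValueError("distance in meters must be non-negative")
    out = m / LINK_M
    return float(out) if out.ndim == 0 else out


def inches_to_cm(inches):
    """Convert diameters in inches to centimeters. Rejects negative input."""
    inches = np.asarray(inches, dtype=float)
    if np.any(inches[np.isfinite(inches)] < 0):
        raise ValueError("diameter in inches must be non-negative")
    out = inches * INCH_CM
    return float(out) if out.ndim == 0 else out


def cm_to_inches(cm):
    cm = np.asarray(cm, dtype=float)
    if np.any(cm[np.isfinite(cm)] < 0):
        raise ValueError("diameter in cm must be non-negative")
    out = cm / INCH_CM
    return float(out) if out.ndim == 0 else out


def convert_units(distance_links, dbh_inches):
    """Convert a (distance in links, dbh in inches) pair to (m, cm)."""
    return links_to_m(distance_links), inches_to_cm(dbh_inches)
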