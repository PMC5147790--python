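"""Cleaning and standardization of raw survey corner records.

Raw Public Land Survey corner records carry up to four bearing trees per
corner, with quadrant bearings (0–90° within NE/NW/SE/SW), distances in
links, diameters in inches and free-text surveyor taxon names.  This module

* converts units (links → m, inches → cm),
* maps surveyor names to genus-level taxa via a shipped lookup table,
* keeps only the closest two tree records per corner and applies the
  validity rules (different quadrants, valid azimuths and diameters, no
  oversized or transcription-suspect trees),
* reports every rejection with a machine-readable reason code.

Corners are never silently dropped: kept + rejected counts always sum to
the input count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._angles import QUADRANTS, quadrant_to_compass
from .units import INCH_CM, LINK_M

logger = logging.getLogger(__name__)

SENTINEL_TAXA = ("NonTree", "Water", "Unknown")
MAX_DBH_IN = 100.0  # larger diameters are treated as transcription errors

REJECT_REASONS = (
    "too_few_records",
    "same_quadrant",
    "invalid_azimuth",
    "invalid_distance",
    "invalid_diameter",
    "oversize_dbh",
    "duplicate_link_trees",
    "zero_distance_azimuth",
)

_RAW_COLUMNS = [
    "point_id",
    "quadrant",
    "azimuth_in_quadrant",
    "distance_links",
    "diameter_in",
    "taxon_raw",
]


def _normalize(name) -> str:
    return " ".join(str(name).strip().lower().split())


def load_taxon_lookup(path=None) -> dict:
    """Load a raw-name → genus lookup (normalized keys).

    Without ``path`` the table shipped with the package is used; a user CSV
    (columns raw_name, genus) extends/overrides it.
    """
    with resources.files("plssrecon.data").joinpath("taxon_lookup.csv").open() as fh:
        table = pd.read_csv(fh)
    lookup = {_normalize(r): g for r, g in zip(table["raw_name"], table["genus"])}
    if path is not None:
        extra = pd.read_csv(path)
        lookup.update(
            {_normalize(r): g for r, g in zip(extra["raw_name"], extra["genus"])}
        )
    return lookup


_DEFAULT_LOOKUP: dict | None = None


def _default_lookup() -> dict:
    global _DEFAULT_LOOKUP
    if _DEFAULT_LOOKUP is None:
        _DEFAULT_LOOKUP = load_taxon_lookup()
    return _DEFAULT_LOOKUP


def standardize_taxa(taxon_raw, lookup: dict | None = None) -> str:
    """Map a surveyor taxon string to a genus label or sentinel.

    Matching is case- and whitespace-insensitive.  Unmatched names map to
    ``'Unknown'`` with a logged warning — never silently dropped.
    """
    lookup = lookup or _default_lookup()
    if taxon_raw is None or (isinstance(taxon_raw, float) and np.isnan(taxon_raw)):
        return "Unknown"
    key = _normalize(taxon_raw)
    if key in lookup:
        return lookup[key]
    logger.warning("unmatched surveyor taxon %r mapped to Unknown", taxon_raw)
    return "Unknown"


@dataclass
class StandardizedBatch:
    """Output of :func:`standardize_corners`.

    ``points``: one row per input corner with status ('kept'/'rejected'),
    reason code, and point_class ('tree', 'mixed', 'nontree', 'water').
    ``trees``: the kept records (two per kept corner, sentinels included)
    with standardized units and taxa alongside the raw columns.
    """

    points: pd.DataFrame
    trees: pd.DataFrame


def _tree_sort_key(rec):
    d = rec["distance_links"]
    return float(d) if np.isfinite(d) else np.inf


def _validate_point(grp: pd.DataFrame, lookup: dict):
    """Return (status, reason, point_class, kept_records)."""
    recs = grp.to_dict("records")
    if len(recs) < 2:
        return "rejected", "too_few_records", None, []

    for r in recs:
        r["taxon"] = standardize_taxa(r.get("taxon_raw"), lookup)
    # Unknown records carry measurements and are treated as trees; only
    # NonTree/Water are positional sentinels.
    real = [r for r in recs if r["taxon"] not in ("NonTree", "Water")]
    water = [r for r in recs if r["taxon"] == "Water"]
    sentinels = [r for r in recs if r["taxon"] in ("NonTree", "Water")]

    for r in real:
        r["distance_links"] = _coerce(r.get("distance_links"))
        r["diameter_in"] = _coerce(r.get("diameter_in"))
        r["azimuth_in_quadrant"] = _coerce(r.get("azimuth_in_quadrant"))

    real.sort(key=_tree_sort_key)

    if len(real) >= 2:
        chosen, point_class = real[:2], "tree"
    elif len(real) == 1 and sentinels:
        chosen = [real[0], sentinels[0]]
        point_class = "water" if sentinels[0]["taxon"] == "Water" else "mixed"
    else:
        chosen, point_class = sentinels[:2], (
            "water" if water else "nontree"
        )

    chosen_real = [r for r in chosen if r["taxon"] not in ("NonTree", "Water")]

    # transcription screen: several large trees all at exactly 1 link
    big_at_link = [
        r
        for r in real
        if np.isfinite(r["distance_links"])
        and r["distance_links"] == 1.0
        and np.isfinite(r["diameter_in"])
        and r["diameter_in"] >= 8.0
    ]
    if len(big_at_link) >= 2:
        return "rejected", "duplicate_link_trees", point_class, []

    for r in chosen_real:
        az = r["azimuth_in_quadrant"]
        if r.get("quadrant") not in QUADRANTS or not np.isfinite(az) or not 0 <= az <= 90:
            return "rejected", "invalid_azimuth", point_class, []
        if not np.isfinite(r["distance_links"]) or r["distance_links"] < 0:
            return "rejected", "invalid_distance", point_class, []
        dbh = r["diameter_in"]
        if not np.isfinite(dbh) or dbh <= 0:
            return "rejected", "invalid_diameter", point_class, []
        if dbh > MAX_DBH_IN:
            return "rejected", "oversize_dbh", point_class, []
        if r["distance_links"] == 0.0 and np.isfinite(az):
            return "rejected", "zero_distance_azimuth", point_class, []

    if len(chosen_real) == 2 and chosen_real[0]["quadrant"] == chosen_real[1]["quadrant"]:
        return "rejected", "same_quadrant", point_class, []

    return "kept", None, point_class, chosen


def _coerce(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return np.nan


def standardize_corners(
    records: pd.DataFrame, lookup: dict | None = None
) -> StandardizedBatch:
    """Validate and standardize a batch of raw corner records.

    ``records`` is long-format: one row per recorded tree (or sentinel) with
    at least the columns point_id, quadrant, azimuth_in_quadrant,
    distance_links, diameter_in, taxon_raw; point-level metadata columns
    (x, y, corner_kind, line_kind, year, design_class, ...) are carried
    through.  Re-running on the output's trees table is a no-op.
    """
    lookup = lookup or _default_lookup()
    missing = [c for c in _RAW_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")

    meta_cols = [
        c
        for c in records.columns
        if c not in _RAW_COLUMNS + ["tree_index", "distance_m", "dbh_cm", "taxon", "azimuth_compass"]
    ]

    point_rows, tree_rows = [], []
    for pid, grp in records.groupby("point_id", sort=False):
        status, reason, point_class, chosen = _validate_point(grp, lookup)
        meta = {c: grp.iloc[0][c] for c in meta_cols}
        point_rows.append(
            dict(meta, point_id=pid, status=status, reason=reason, point_class=point_class)
        )
        for t_idx, r in enumerate(chosen):
            is_tree = r["taxon"] not in ("NonTree", "Water")
            d_links = r.get("distance_links", np.nan)
            dbh_in = r.get("diameter_in", np.nan)
            az = r.get("azimuth_in_quadrant", np.nan)
            quadrant = r.get("quadrant", np.nan)
            tree_rows.append(
                dict(
                    meta,
                    point_id=pid,
                    tree_index=t_idx,
                    quadrant=quadrant,
                    azimuth_in_quadrant=az,
                    azimuth_compass=(
                        quadrant_to_compass(quadrant, az)
                        if is_tree and quadrant in QUADRANTS and np.isfinite(_coerce(az))
                        else np.nan
                    ),
                    distance_links=_coerce(d_links),
                    distance_m=_coerce(d_links) * LINK_M if is_tree else np.nan,
                    diameter_in=_coerce(dbh_in),
                    dbh_cm=_coerce(dbh_in) * INCH_CM if is_tree else np.nan,
                    taxon_raw=r.get("taxon_raw"),
                    taxon=r["taxon"],
                )
            )

    points = pd.DataFrame(point_rows)
    trees = pd.DataFrame(tree_rows)
    return StandardizedBatch(points=points, trees=trees)


@dataclass
class RejectionSummary:
    table: pd.DataFrame  # columns: reason, n
    kept_fraction: float  # NaN (flagged undefined) for empty input


def summarize_rejections(points: pd.DataFrame) -> RejectionSummary:
    """Counts per rejection reason plus the kept fraction.

    Kept + per-reason counts always sum to the input point count; an empty
    batch returns an empty table with kept_fraction NaN.
    """
    if len(points) == 0:
        return RejectionSummary(
            table=pd.DataFrame(columns=["reason", "n"]), kept_fraction=float("nan")
        )
    rejected = points[points["status"] == "rejected"]
    counts = rejected["reason"].value_counts()
    table = pd.DataFrame({"reason": counts.index, "n": counts.to_numpy()})
    kept = int((points["status"] == "kept").sum())
    assert kept + int(table["n"].sum()) == len(points)
    return RejectionSummary(table=table, kept_fraction=kept / len(points))
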