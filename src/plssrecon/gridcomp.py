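"""Aggregation of point and plot data to an 8 × 8 km grid.

Point-level density/basal-area/biomass estimates and tree records are
binned into 64 km² cells (half-open binning from a grid origin).  Per cell
the module computes composition vectors on a stem-count and a basal-area
basis, structural means/SDs in a "full" and a "reported" variant (the
reported variant drops points above the global 97.5th density percentile,
because plotless estimates are heavy-tailed near-tree artifacts), the
prairie/savanna/forest cover class, and the density:biomass structure
ratio.  Modern fixed-radius inventory plots are expanded to per-hectare
values from the subplot area and averaged per cell.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .structure import stem_basal_area

CELL_SIZE_M = 8000.0
#: stem-density cover-class thresholds (stems/ha); the savanna upper bound
#: is inclusive
PRAIRIE_MAX = 0.5
SAVANNA_MAX = 47.0
SENTINELS = ("NonTree", "Water", "Unknown")


def assign_cells(
    df: pd.DataFrame,
    origin=(0.0, 0.0),
    cell_size: float = CELL_SIZE_M,
) -> pd.DataFrame:
    """Add half-open grid indices (cell_i, cell_j, cell_id) to a table
    with planar x/y columns in meters."""
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates")
    i = np.floor((x - origin[0]) / cell_size).astype(int)
    j = np.floor((y - origin[1]) / cell_size).astype(int)
    out = df.copy()
    out["cell_i"] = i
    out["cell_j"] = j
    out["cell_id"] = [f"{a}_{b}" for a, b in zip(i, j)]
    return out


def cell_composition(trees: pd.DataFrame, genus_col: str = "taxon") -> dict:
    """Composition vectors per cell on stem-count and basal-area bases.

    ``trees`` must carry cell_id, a genus column and dbh_cm.  Sentinel
    records are excluded from both bases.  Returns
    {'stem': DataFrame, 'ba': DataFrame, 'empty_cells': list} with rows
    summing to 1; cells with no real trees are listed as empty.
    """
    t = trees[~trees[genus_col].isin(SENTINELS)].copy()
    all_cells = trees["cell_id"].unique()
    if len(t):
        stem = pd.crosstab(t["cell_id"], t[genus_col])
        stem = stem.div(stem.sum(axis=1), axis=0)
        t["ba"] = stem_basal_area(t["dbh_cm"].to_numpy(dtype=float))
        ba = t.pivot_table(
            index="cell_id", columns=genus_col, values="ba", aggfunc="sum", fill_value=0.0
        )
        ba = ba.div(ba.sum(axis=1), axis=0)
    else:
        stem = pd.DataFrame()
        ba = pd.DataFrame()
    empty = sorted(set(all_cells) - set(stem.index))
    return {"stem": stem, "ba": ba, "empty_cells": empty}


def cell_structure(
    point_values: pd.DataFrame,
    trim: float = 0.025,
    per_cell: bool = False,
) -> dict:
    """Cell means and SDs of density, basal area and biomass.

    ``point_values`` needs cell_id, density (stems/ha), basal_area (m²/ha),
    biomass (Mg/ha).  Two variants are returned: 'full' (all points) and
    'reported' (points above the global (1 - trim) density percentile
    excluded; per-cell trimming behind ``per_cell=True``).
    """
    cols = {"density", "basal_area", "biomass"} & set(point_values.columns)
    if "density" not in cols:
        raise ValueError("point_values must have a density column")

    def _summarize(pv):
        g = pv.groupby("cell_id")
        out = g.size().to_frame("n_points")
        for c in sorted(cols):
            out[f"{c}_mean"] = g[c].mean()
            out[f"{c}_sd"] = g[c].std(ddof=1)
        return out

    full = _summarize(point_values)
    if trim <= 0:
        reported = full.copy()
    elif per_cell:
        def _trim_group(g):
            cut = np.percentile(g["density"], 100 * (1 - trim))
            return g[g["density"] <= cut]
        reported = _summarize(
            point_values.groupby("cell_id", group_keys=False)[point_values.columns].apply(_trim_group)
        )
    else:
        cut = np.percentile(point_values["density"], 100 * (1 - trim))
        reported = _summarize(point_values[point_values["density"] <= cut])
    return {"full": full, "reported": reported}


def classify_cover(density_stems_ha):
    """Prairie (< 0.5), savanna (0.5–47, inclusive) or forest (> 47)."""
    d = np.asarray(density_stems_ha, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    out = np.where(d < PRAIRIE_MAX, "prairie", np.where(d <= SAVANNA_MAX, "savanna", "forest"))
    return str(out) if out.ndim == 0 else out


def aggregate_fia(
    plots: pd.DataFrame,
    min_dbh: float = 20.32,
    subplot_radius: float = 7.2,
    origin=(0.0, 0.0),
    cell_size: float = CELL_SIZE_M,
) -> pd.DataFrame:
    """Cell-level structure from fixed-radius inventory plots.

    Each plot expands to per-hectare values over its sampled area
    (4 × pi × subplot_radius² m²); only live trees with dbh > ``min_dbh``
    count.  Cell values are plot means; cells without plots are absent
    (no-data).
    """
    area_m2 = 4.0 * np.pi * subplot_radius**2
    if area_m2 <= 0:
        raise ValueError("zero subplot area")
    rows = []
    for pid, grp in plots.groupby("plot_id", sort=False):
        live = grp[grp.get("live", True) & grp["dbh_cm"].notna()]
        qual = live[live["dbh_cm"] > min_dbh]
        n = len(qual)
        rows.append(
            {
                "plot_id": pid,
                "x": grp["x"].iloc[0],
                "y": grp["y"].iloc[0],
                "density": n / area_m2 * 1e4,
                "basal_area": stem_basal_area(qual["dbh_cm"].to_numpy()).sum()
                / area_m2
                * 1e4
                if n
                else 0.0,
                "mean_dbh": qual["dbh_cm"].mean() if n else np.nan,
            }
        )
    per_plot = assign_cells(pd.DataFrame(rows), origin=origin, cell_size=cell_size)
    g = per_plot.groupby("cell_id")
    cells = g.agg(
        n_plots=("plot_id", "size"),
        density_mean=("density", "mean"),
        basal_area_mean=("basal_area", "mean"),
        mean_dbh=("mean_dbh", "mean"),
        cell_i=("cell_i", "first"),
        cell_j=("cell_j", "first"),
    ).reset_index()
    cells["era"] = "FIA"
    return cells


def density_biomass_ratio(cells: pd.DataFrame) -> pd.DataFrame:
    """Stem density : biomass ratio per cell (stems/ha per Mg/ha).

    The orientation is density over biomass (high = dense small-stem
    stands); cells with zero biomass are flagged undefined, not dropped.
    """
    out = cells.copy()
    dens = out["density_mean"].to_numpy(dtype=float)
    biom = out["biomass_mean"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(biom > 0, dens / biom, np.nan)
    out["density_per_biomass"] = ratio
    out["ratio_undefined"] = ~(biom > 0)
    return out
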