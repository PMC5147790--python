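"""Analog analysis between eras: novel, lost and remnant forests.

Compositional dissimilarity between 64 km² cells uses Bray–Curtis distance
on proportional composition (relative basal area by default).  Each cell is
matched to its most similar cell within its own era and within the other
era, keeping only the minimum.  Modern cells whose best historical analog
exceeds the 95th percentile of within-historical-era minima are *novel*;
historical cells with no close modern analog are *lost*; modern cells below
the 25th percentile are *remnant*.  A binomial GLM relates novelty to
distance from the nearest remnant cell per historical forest type (types
from k-medoids on the dissimilarity matrix), with a permutation null that
reshuffles the between-era minima across cells.  Transect β diversity and
Moran's I quantify homogenization of ecotones.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import cdist

# ---------------------------------------------------------------------------
# Bray–Curtis


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1].

    Vectors are non-negative compositions on the union of taxa (missing
    taxa are zeros).  Two all-zero vectors are undefined -> NaN, flagged
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("compositions must be non-negative")
    denom = np.sum(x + y)
    if denom == 0:
        warnings.warn("Bray-Curtis undefined for two all-zero vectors", stacklevel=2)
        return float("nan")
    return float(np.sum(np.abs(x - y)) / denom)


def dissimilarity_matrix(comps: pd.DataFrame, other: pd.DataFrame | None = None) -> np.ndarray:
    """Pairwise Bray–Curtis matrix between rows of composition tables."""
    a = comps.to_numpy(dtype=float)
    b = a if other is None else other.reindex(columns=comps.columns, fill_value=0.0).to_numpy(dtype=float)
    num = np.abs(a[:, None, :] - b[None, :, :]).sum(axis=2)
    den = (a[:, None, :] + b[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def min_dissimilarity(
    focal: pd.DataFrame,
    reference: pd.DataFrame,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Minimum Bray–Curtis distance from each focal cell to a reference set.

    Brute-force over the full matrix; ties break to the lowest reference
    cell_id.  ``exclude_self`` (required for within-era analyses on the same
    table) forbids a cell from matching itself.
    """
    if len(focal) == 0 or len(reference) == 0:
        raise ValueError("empty cell set")
    reference = reference.sort_index()  # lowest cell_id wins ties via argmin
    d = dissimilarity_matrix(focal, reference)
    if exclude_self:
        if len(reference) < 2:
            raise ValueError("reference empty after self-exclusion")
        shared = focal.index.get_indexer(reference.index)
        for j, i in enumerate(shared):
            if i >= 0:
                d[i, j] = np.inf
    best = np.argmin(d, axis=1)
    return pd.DataFrame(
        {
            "min_dissim": d[np.arange(len(focal)), best],
            "matched_cell_id": reference.index.to_numpy()[best],
        },
        index=focal.index,
    )


# ---------------------------------------------------------------------------
# Thresholds and classification


def novelty_thresholds(
    within_pls: Sequence[float],
    within_fia: Sequence[float],
    novel_pct: float = 95.0,
    remnant_pct: float = 25.0,
    min_values: int = 20,
) -> dict:
    """Novel/lost/remnant cutoffs from within-era minimum dissimilarities.

    novel_cut / remnant_cut are the 95th / 25th percentiles of within-
    historical-era minima; lost_cut is the 95th percentile of within-modern
    minima (the symmetric reading).  Percentiles use linear interpolation.
    """
    wp = np.asarray(within_pls, dtype=float)
    wf = np.asarray(within_fia, dtype=float)
    if wp.size < min_values or wf.size < min_values:
        raise ValueError(f"need at least {min_values} within-era minima per era")
    return {
        "novel_cut": float(np.percentile(wp, novel_pct)),
        "remnant_cut": float(np.percentile(wp, remnant_pct)),
        "lost_cut": float(np.percentile(wf, novel_pct)),
    }


def classify_cells(
    fia_to_pls_min: pd.Series,
    pls_to_fia_min: pd.Series,
    cuts: dict,
) -> dict:
    """Novel/remnant flags for modern cells and lost flags for historical."""
    return {
        "novel": fia_to_pls_min > cuts["novel_cut"],
        "remnant": fia_to_pls_min <= cuts["remnant_cut"],
        "lost": pls_to_fia_min > cuts["lost_cut"],
    }


# ---------------------------------------------------------------------------
# k-medoids (PAM) forest types


def _pam_build(d: np.ndarray, k: int) -> list:
    n = len(d)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def kmedoid_types(
    comps: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Forest types by k-medoids (PAM build + swap) on Bray–Curtis.

    Deterministic given the data (the seed only breaks exact cost ties).
    Cluster labels are named from the medoid's dominant taxa
    ('Hemlock-Cedar-Birch-Maple' style: taxa with share >= 0.1, up to 4).
    """
    n = len(comps)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    d = dissimilarity_matrix(comps)
    np.fill_diagonal(d, 0.0)
    medoids = _pam_build(d, k)

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = [m for j, m in enumerate(medoids) if j != mi]
            for h in range(n):
                if h in medoids:
                    continue
                trial = others + [h]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    medoids = sorted(trial)
                    best_cost = c
                    improved = True
        if not improved:
            break

    assign = np.argmin(d[:, medoids], axis=1)
    names = []
    for m in medoids:
        row = comps.iloc[m].sort_values(ascending=False)
        top = [t for t, v in row.items() if v >= 0.1][:4] or [row.index[0]]
        names.append("-".join(top))
    return pd.DataFrame(
        {
            "forest_type": [names[a] for a in assign],
            "medoid_cell_id": [comps.index[medoids[a]] for a in assign],
            "is_medoid": [i in medoids for i in range(n)],
        },
        index=comps.index,
    )


# ---------------------------------------------------------------------------
# Distance to remnant and the novelty GLM


def distance_to_remnant(coords: pd.DataFrame, remnant: pd.Series) -> pd.Series:
    """Euclidean center-to-center distance (km) to the nearest remnant cell."""
    if not remnant.any():
        raise ValueError("no remnant cells")
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    rem_xy = xy[remnant.reindex(coords.index).to_numpy(dtype=bool)]
    d = cdist(xy, rem_xy).min(axis=1) / 1000.0
    return pd.Series(d, index=coords.index, name="distance_to_remnant_km")


@dataclass
class NoveltyModelFit:
    forest_type: str
    intercept: float = np.nan
    slope: float = np.nan  # per km
    d50: float = np.nan  # km at fitted probability 0.5
    n: int = 0
    n_novel: int = 0
    flag: str | None = None  # 'too_few', 'one_class', 'saturated', 'separation'
    null_d50_range: tuple | None = None
    n_permutations: int = 0


def fit_novelty_glm(
    novel: pd.Series,
    distance_km: pd.Series,
    forest_type: pd.Series | None = None,
    min_cells: int = 20,
) -> dict:
    """Binomial GLM of novelty on distance to remnant, per forest type.

    Types with < ``min_cells`` cells or only one class are flagged
    non-estimable (an all-novel type mirrors a saturated, flat-at-one fit).
    d50 = -intercept/slope is reported only for positive slopes.
    """
    if forest_type is None:
        forest_type = pd.Series("all", index=novel.index)
    fits = {}
    for ftype, idx in novel.groupby(forest_type).groups.items():
        y = novel.loc[idx].astype(float)
        x = distance_km.loc[idx].astype(float)
        fit = NoveltyModelFit(forest_type=str(ftype), n=len(y), n_novel=int(y.sum()))
        if len(y) < min_cells:
            fit.flag = "too_few"
        elif y.nunique() < 2:
            fit.flag = "saturated" if y.iloc[0] == 1.0 else "one_class"
        else:
            X = sm.add_constant(x.to_numpy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(y.to_numpy(), X, family=sm.families.Binomial()).fit()
                    fit.intercept = float(res.params[0])
                    fit.slope = float(res.params[1])
                    if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 1e3:
                        fit.flag = "separation"
                    elif fit.slope > 0:
                        fit.d50 = -fit.intercept / fit.slope
                except Exception:
                    fit.flag = "separation"
        fits[str(ftype)] = fit
    return fits


def _shuffle_minima(minima: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Permute the nearest-neighbor dissimilarities across cells without
    replacement (the multiset of values is preserved exactly)."""
    return pd.Series(rng.permutation(minima.to_numpy()), index=minima.index)


def permutation_null(
    between_min: pd.Series,
    coords: pd.DataFrame,
    cuts: dict,
    forest_type: pd.Series | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Null distance-to-novelty ranges under spatially random dissimilarity.

    Each permutation reshuffles the between-era minimum dissimilarities
    across cells, recomputes remnant/novel flags, distances to remnant and
    the per-type GLM d50; the min/max (and quartiles) of the null d50 per
    forest type are returned.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    null_d50 = {}
    for _ in range(n_perm):
        shuffled = _shuffle_minima(between_min, rng)
        flags = classify_cells(shuffled, shuffled, cuts)
        if not flags["remnant"].any():
            continue
        dist = distance_to_remnant(coords, flags["remnant"])
        fits = fit_novelty_glm(flags["novel"], dist, forest_type)
        for ftype, fit in fits.items():
            if np.isfinite(fit.d50):
                null_d50.setdefault(ftype, []).append(fit.d50)
    out = {}
    for ftype, vals in null_d50.items():
        v = np.asarray(vals)
        out[ftype] = {
            "null_min": float(v.min()),
            "null_max": float(v.max()),
            "null_q25": float(np.percentile(v, 25)),
            "null_q75": float(np.percentile(v, 75)),
            "n_valid": int(v.size),
        }
    return out


# ---------------------------------------------------------------------------
# Ecotone structure


@dataclass
class TransectBeta:
    delta_beta: float  # mean adjacent dissimilarity, era2 - era1
    beta_era1: float
    beta_era2: float
    t_stat: float
    p_value: float
    n_pairs: int
    restricted: bool  # True when eras were restricted to shared cells


def transect_beta(era1: pd.DataFrame, era2: pd.DataFrame) -> TransectBeta:
    """Change in adjacent-cell β diversity along an ordered transect.

    Rows must be ordered along the path; the analysis restricts to cells
    present in both eras (flagged when that drops any).  Δβ < 0 means the
    modern era is more homogeneous.
    """
    shared = era1.index.intersection(era2.index)
    restricted = len(shared) < max(len(era1), len(era2))
    e1 = era1.loc[shared]
    e2 = era2.reindex(columns=era1.columns, fill_value=0.0).loc[shared]
    if len(shared) < 3:
        raise ValueError("transect needs at least 3 shared cells")
    b1 = np.array([bray_curtis(e1.iloc[i], e1.iloc[i + 1]) for i in range(len(e1) - 1)])
    b2 = np.array([bray_curtis(e2.iloc[i], e2.iloc[i + 1]) for i in range(len(e2) - 1)])
    if np.allclose(b1, b2):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(b2, b1)
    return TransectBeta(
        delta_beta=float(b2.mean() - b1.mean()),
        beta_era1=float(b1.mean()),
        beta_era2=float(b2.mean()),
        t_stat=float(t),
        p_value=float(p),
        n_pairs=len(b1),
        restricted=restricted,
    )


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class SpatialStats:
    morans_I: float
    expected_I: float
    p_value: float
    n: int
    weights_spec: str
    n_permutations: int


def _contiguity_weights(coords: pd.DataFrame, cell_size: float, scheme: str) -> np.ndarray:
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    dx = np.abs(xy[:, None, 0] - xy[None, :, 0]) / cell_size
    dy = np.abs(xy[:, None, 1] - xy[None, :, 1]) / cell_size
    if scheme == "queen":
        w = (np.maximum(dx, dy) <= 1.001) & ~np.eye(len(xy), dtype=bool)
    elif scheme == "rook":
        w = (dx + dy <= 1.001) & ~np.eye(len(xy), dtype=bool)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    return w.astype(float)


def morans_i(
    values: pd.Series,
    coords: pd.DataFrame,
    weights: str = "queen",
    cell_size: float = 8000.0,
    row_standardize: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> SpatialStats:
    """Moran's I with contiguity weights and a permutation p-value.

    Default queen contiguity on the cell grid, row-standardized; the
    p-value is one-sided (positive autocorrelation) over ``n_perm``
    random relabelings.  Constant values are undefined -> rejected.
    """
    y = values.reindex(coords.index).to_numpy(dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 cells")
    if np.ptp(y) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = _contiguity_weights(coords, cell_size, weights)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs

    def _I(v):
        z = v - v.mean()
        return n / w.sum() * (z @ w @ z) / (z @ z)

    obs = _I(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _I(rng.permutation(y)) >= obs:
            exceed += 1
    return SpatialStats(
        morans_I=float(obs),
        expected_I=-1.0 / (n - 1),
        p_value=(exceed + 1) / (n_perm + 1),
        n=n,
        weights_spec=f"{weights}, row_standardized={row_standardize}",
        n_permutations=n_perm,
    )
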