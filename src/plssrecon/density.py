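"""Morisita plotless density estimation with surveyor-bias corrections.

The per-point two-tree Morisita estimator is

    lambda_M = 2 / (pi * (r1^2 + r2^2))        [stems per m^2]

with r1, r2 the distances to the two recorded trees.  For a homogeneous
Poisson stand sampled point-halves (nearest tree in each 180° semicircle)
this estimator is exactly unbiased: the squared nearest-tree distance in a
sector of angle 2*pi/k is exponential with rate lambda*pi/k, so the sum of
two such squares is Gamma(2, rate lambda*pi/2) and E[1/sum] = lambda*pi/2.

Surveyors did not all follow the point-halves geometry, and they avoided
trees near cardinal bearings and below the 8-inch reporting size.  Four
multiplicative factors repair the estimate:

* kappa — fixed design constant (point_quarter/point_halves 1,
  two_nearest_quadrants 0.857, interior_half 2);
* theta — sector bias, 180° / effective sector span, estimated from the
  empirical pair-angle distribution between the two bearings;
* zeta  — azimuthal censoring, the ratio of the proportion of trees in the
  allowed region (p) to the fraction of the circle it occupies (alpha);
* phi   — fraction of trees at or above the diameter limit (20.32 cm);
  corrected densities refer to trees >= that limit.

    lambda_corrected = kappa * theta * zeta * phi * lambda_M

Factors are estimated separately per stratum (region/year/line/corner
kind/design); sparse strata fall back to the pooled factors with a flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._angles import CARDINALS, circular_distance, pair_angle
from .units import DIAMETER_LIMIT_CM

KAPPA = {
    "point_quarter": 1.0,
    "point_halves": 1.0,
    "two_nearest_quadrants": 0.857,
    "interior_half": 2.0,
}

PHI_TYPICAL_RANGE = (0.6, 0.95)


# ---------------------------------------------------------------------------
# Morisita estimators


def morisita_two_tree(r1, r2) -> float:
    """Per-point two-tree Morisita density (stems per m^2)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("distances must be positive")
    out = 2.0 / (np.pi * (r1**2 + r2**2))
    return float(out) if out.ndim == 0 else out


def morisita_k_sector(distances: Sequence[float], k: int) -> float:
    """Per-point k-sector Morisita density, k(k-1) / (pi * sum r_j^2).

    Requires exactly one nearest-tree distance per sector.  Reduces to
    :func:`morisita_two_tree` at k = 2.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    r = np.asarray(distances, dtype=float)
    if r.shape[-1] != k:
        raise ValueError(f"expected {k} distances, got {r.shape[-1]}")
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    return float(k * (k - 1) / (np.pi * np.sum(r**2)))


def kappa_for_design(design_class: str) -> float:
    """Cottam design correction kappa for a named sampling design."""
    try:
        return KAPPA[design_class]
    except KeyError:
        raise ValueError(f"unknown design_class {design_class!r}") from None


# ---------------------------------------------------------------------------
# Sector bias (theta)


def sector_correction(effective_sector_deg: float) -> float:
    """Sector-bias factor theta = p / alpha = 180 / effective sector span.

    For trees uniformly distributed over an effective sector of
    ``effective_sector_deg`` degrees evaluated against the 180° point-halves
    assumption, the observed proportion in the assumed sector over the
    circle-proportion of the effective sector reduces to 180/span.
    """
    s = float(effective_sector_deg)
    if not 0.0 < s <= 360.0:
        raise ValueError("effective sector must be in (0, 360] degrees")
    return 180.0 / s


def _pair_angle_cdf(a, span):
    """CDF of the angle between the two bearings under the sector model.

    Model: each tree's bearing is uniform on a sector of width ``span``
    centered on its own semicircle's midline (the two midlines are 180°
    apart).  span = 180 reproduces the exact point-halves law; wider spans
    push pair angles below 180 symmetrically.
    """
    a = np.asarray(a, dtype=float)
    s = float(span)
    c = s - 180.0
    lo = max(0.0, -c)  # support starts at 180 - s for narrow spans
    t = np.clip(a, lo, 180.0)
    if s <= 180.0:
        return ((s - 180.0 + t) / s) ** 2 * (a >= lo)
    first = ((c + t) ** 2 - c**2) / s**2
    second = (c**2 - (c - np.minimum(t, c)) ** 2) / s**2
    return first + second


@dataclass(frozen=True)
class SectorEstimate:
    span_deg: float
    theta: float
    at_bound: bool
    degenerate: bool


def estimate_effective_sector(
    pair_angles: Iterable[float],
    grid: tuple = (90.0, 360.0, 1.0),
    min_angles: int = 30,
) -> SectorEstimate:
    """Effective sector span best matching empirical pair-angle frequencies.

    Minimum Cramér–von Mises distance between the empirical pair-angle CDF
    and the sector model over a candidate grid of spans.  Deterministic
    given inputs.  Zero-spread (degenerate) inputs pin to the grid's lower
    bound and are flagged.
    """
    a = np.sort(np.asarray(list(pair_angles), dtype=float))
    if a.size < min_angles:
        raise ValueError(
            f"need at least {min_angles} pair angles, got {a.size}"
        )
    if np.any((a < 0) | (a > 180)):
        raise ValueError("pair angles must be in [0, 180]")
    lo, hi, step = grid
    spans = np.arange(lo, hi + step / 2, step)
    if np.ptp(a) == 0.0:
        span = float(spans[0])
        return SectorEstimate(span, 180.0 / span, at_bound=True, degenerate=True)
    ecdf = (2 * np.arange(1, a.size + 1) - 1) / (2 * a.size)
    crit = np.array(
        [np.sum((_pair_angle_cdf(a, s) - ecdf) ** 2) for s in spans]
    )
    best = int(np.argmin(crit))
    span = float(spans[best])
    return SectorEstimate(
        span_deg=span,
        theta=180.0 / span,
        at_bound=best in (0, len(spans) - 1),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Azimuthal censoring (zeta)


def cardinal_censor_arcs(halfwidth_deg: float):
    """Censor arcs of ±halfwidth around each cardinal direction."""
    return [((c - halfwidth_deg) % 360.0, (c + halfwidth_deg) % 360.0) for c in CARDINALS]


def _arc_span(lo, hi):
    return (hi - lo) % 360.0 if hi != lo else 0.0


def _in_arcs(az, arcs):
    az = np.asarray(az, dtype=float) % 360.0
    hit = np.zeros(az.shape, dtype=bool)
    for lo, hi in arcs:
        lo, hi = lo % 360.0, hi % 360.0
        if lo <= hi:
            hit |= (az >= lo) & (az < hi)
        else:  # wraps midnight
            hit |= (az >= lo) | (az < hi)
    return hit


def azimuth_censoring_correction(azimuths, censor_arcs) -> float:
    """Censoring factor zeta = p / alpha (floored at 1).

    ``p`` is the proportion of recorded azimuths in the allowed region and
    ``alpha`` the fraction of the circle that region occupies; complete
    censoring of the arcs gives zeta = 360 / (360 - censored degrees).
    """
    az = np.asarray(azimuths, dtype=float)
    az = az[np.isfinite(az)]
    if az.size == 0:
        raise ValueError("no azimuths provided")
    total = sum(_arc_span(lo, hi) for lo, hi in censor_arcs)
    if total >= 360.0:
        raise ValueError("censor arcs cover the full circle")
    alpha = (360.0 - total) / 360.0
    p = float(np.mean(~_in_arcs(az, censor_arcs)))
    return max(p / alpha, 1.0)


def estimate_censor_halfwidth(azimuths, max_halfwidth: float = 40.0):
    """Estimate the censored halfwidth around the cardinals from azimuths.

    Under the complete-elimination model (no tree recorded within ±w of a
    cardinal bearing; azimuths otherwise uniform) the maximum-likelihood
    estimate of w is the smallest observed angular gap to any cardinal —
    the uniform-support MLE.  Uncensored data yield a gap near zero and
    zeta ≈ 1; partial (incomplete) avoidance is read as no censoring.
    Returns (halfwidth_deg, zeta, p, alpha).
    """
    az = np.asarray(azimuths, dtype=float)
    az = az[np.isfinite(az)]
    if az.size == 0:
        raise ValueError("no azimuths provided")
    gaps = circular_distance(az[:, None], CARDINALS[None, :]).min(axis=1)
    w = float(min(gaps.min(), max_halfwidth))
    alpha = (360.0 - 8.0 * w) / 360.0
    p = float(np.mean(~_in_arcs(az, cardinal_censor_arcs(w)))) if w > 0 else 1.0
    return w, max(p / alpha, 1.0), p, alpha


# ---------------------------------------------------------------------------
# Diameter limit (phi)


def diameter_limit_correction(dbhs, limit: float = DIAMETER_LIMIT_CM) -> float:
    """Fraction of trees with dbh >= limit (cm).

    Densities multiplied by phi refer to trees at or above the limit.
    Values outside the empirically typical range 0.6–0.95 are flagged with
    a warning.
    """
    d = np.asarray(dbhs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no diameters provided")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    phi = float(np.mean(d >= limit))
    lo, hi = PHI_TYPICAL_RANGE
    if not lo <= phi <= hi:
        warnings.warn(
            f"phi = {phi:.3f} outside the typical range [{lo}, {hi}]",
            stacklevel=2,
        )
    return phi


# ---------------------------------------------------------------------------
# Per-point estimates and stratified factors


def point_morisita(
    trees: pd.DataFrame,
    points: pd.DataFrame,
    mixed_policy: str = "zero",
) -> pd.DataFrame:
    """Uncorrected per-point Morisita density from a standardized batch.

    Corners with two trees get lambda_M = 2/(pi*(r1^2+r2^2)); 'No Tree'
    corners (and mixed one-tree corners under the default 'zero' policy)
    contribute 0 stems/m², the treatment of open vegetation; water corners
    are excluded entirely.
    """
    if mixed_policy not in ("zero", "exclude"):
        raise ValueError("mixed_policy must be 'zero' or 'exclude'")
    kept = points[points["status"] == "kept"]
    rows = []
    by_point = dict(tuple(trees.groupby("point_id", sort=False)))
    for _, pt in kept.iterrows():
        cls = pt["point_class"]
        if cls == "water":
            continue
        if cls == "nontree" or (cls == "mixed" and mixed_policy == "zero"):
            rows.append({"point_id": pt["point_id"], "lambda_M": 0.0, "n_trees": 0})
            continue
        if cls == "mixed":
            continue
        grp = by_point[pt["point_id"]]
        r = grp.loc[grp["taxon"].apply(lambda t: t not in ("NonTree", "Water")), "distance_m"]
        r = r.to_numpy(dtype=float)
        if len(r) != 2:
            continue
        rows.append(
            {
                "point_id": pt["point_id"],
                "lambda_M": morisita_two_tree(r[0], r[1]),
                "n_trees": 2,
            }
        )
    lam = pd.DataFrame(rows, columns=["point_id", "lambda_M", "n_trees"])
    meta_cols = [c for c in kept.columns if c not in ("status", "reason")]
    return lam.merge(kept[meta_cols], on="point_id", how="left")


def _factors_for_group(trees: pd.DataFrame, design_class: str) -> dict:
    """Raw correction factors (theta, zeta, phi and intermediates) for one
    pooled set of standardized tree records."""
    real = trees[~trees["taxon"].isin(["NonTree", "Water"])]
    az = real["azimuth_compass"].to_numpy(dtype=float)
    dbh = real["dbh_cm"].to_numpy(dtype=float)

    # pair angles: corners with exactly two real trees
    pairs = (
        real.groupby("point_id")["azimuth_compass"]
        .apply(lambda s: pair_angle(s.iloc[0], s.iloc[1]) if len(s) == 2 else np.nan)
        .dropna()
        .to_numpy()
    )
    out = {"kappa": kappa_for_design(design_class)}
    try:
        est = estimate_effective_sector(pairs)
        out.update(
            theta=est.theta,
            effective_sector_deg=est.span_deg,
            theta_at_bound=est.at_bound,
        )
    except ValueError:
        out.update(theta=np.nan, effective_sector_deg=np.nan, theta_at_bound=False)
    try:
        w, zeta, p, alpha = estimate_censor_halfwidth(az)
        out.update(zeta=zeta, censored_arc_deg=8.0 * w, zeta_p=p, zeta_alpha=alpha)
    except ValueError:
        out.update(zeta=np.nan, censored_arc_deg=np.nan, zeta_p=np.nan, zeta_alpha=np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["phi"] = diameter_limit_correction(dbh)
    except ValueError:
        out["phi"] = np.nan
    return out


def stratified_corrections(
    trees: pd.DataFrame,
    points: pd.DataFrame,
    strata: Sequence[str] = ("design_class",),
    min_points: int = 100,
) -> pd.DataFrame:
    """Correction factors per stratum of corner points.

    ``strata`` are column names on the points table (e.g. design_class,
    year, line_kind, corner_kind, region).  Strata with fewer than
    ``min_points`` kept corners inherit the pooled (all-data) factors and
    are flagged ``fallback``.  ``design_class`` must either be a stratum key
    or constant within each stratum (kappa is a per-design constant).
    """
    strata = list(strata)
    missing = [k for k in strata if k not in points.columns]
    if missing:
        raise ValueError(f"points table missing stratum keys: {missing}")
    kept = points[points["status"] == "kept"]
    tk = trees.merge(
        kept[["point_id"] + [k for k in strata if k not in trees.columns]],
        on="point_id",
        how="inner",
    )

    def _design_of(sub_points):
        if "design_class" in sub_points.columns:
            designs = sub_points["design_class"].unique()
            if len(designs) != 1:
                raise ValueError(
                    "design_class varies within a stratum; add it to the keys"
                )
            return designs[0]
        raise ValueError("points table must carry design_class")

    pooled = _factors_for_group(tk, _design_of(kept)) if len(kept) else {}

    rows = []
    for key, sub in kept.groupby(strata, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sub_trees = tk[tk["point_id"].isin(sub["point_id"])]
        if len(sub) < min_points:
            fac = dict(pooled, kappa=kappa_for_design(_design_of(sub)))
            fallback = True
        else:
            fac = _factors_for_group(sub_trees, _design_of(sub))
            fallback = False
        rows.append(
            dict(zip(strata, key), n_points=len(sub), fallback=fallback, **fac)
        )
    return pd.DataFrame(rows)


def corrected_density(
    point_estimates: pd.DataFrame,
    factors: pd.DataFrame,
    strata: Sequence[str] = ("design_class",),
) -> pd.DataFrame:
    """Apply lambda_corrected = kappa*theta*zeta*phi*lambda_M per stratum.

    ``point_estimates`` is the output of :func:`point_morisita` (it must
    carry the stratum key columns); ``factors`` the matching table from
    :func:`stratified_corrections`.  Points whose stratum has no factors
    are rejected.
    """
    strata = list(strata)
    fac_cols = strata + ["kappa", "theta", "zeta", "phi"]
    merged = point_estimates.merge(factors[fac_cols], on=strata, how="left", validate="many_to_one")
    if merged["kappa"].isna().any():
        bad = merged.loc[merged["kappa"].isna(), strata].drop_duplicates()
        raise ValueError(f"missing correction factors for strata:\n{bad}")
    merged["lambda_corrected"] = (
        merged["kappa"]
        * merged["theta"]
        * merged["zeta"]
        * merged["phi"]
        * merged["lambda_M"]
    )
    # open-vegetation corners stay exactly zero regardless of factors
    merged.loc[merged["lambda_M"] == 0.0, "lambda_corrected"] = 0.0
    return merged
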