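"""Synthetic stands, virtual surveyors, inventory plots and paired landscapes.

Every downstream stage of the reconstruction (standardization, Morisita
density with surveyor-bias corrections, gridding, analog analysis) is
exercised against data generated here, where the truth is known:

* :func:`generate_stand` draws a marked point pattern (a stem map) with a
  known true stem density — the ground truth for estimator calibration.
* :func:`survey_stand` walks a rectangular grid of corner points across the
  stand and records bearing trees the way a 19th-century surveyor would,
  under a configurable :class:`SurveyDesign` that can reproduce the known
  biases: sector restriction/widening, azimuthal censoring near the cardinal
  directions, and under-sampling of small-diameter trees.  Distances are
  emitted in links and diameters in inches to force the unit-conversion path.
* :func:`generate_fia_plots` emulates modern fixed-radius inventory plots
  (four 7.2 m subplots, trees > 12.7 cm dbh).
* :func:`generate_landscape_pair` builds two gridded composition tables with
  controlled compositional turnover and a known distance-to-novelty signal,
  the ground truth for the analog/novelty stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from ._angles import CARDINALS, circular_distance, compass_to_quadrant, in_window
from .units import DIAMETER_LIMIT_CM, INCH_CM, LINK_M

DESIGN_CLASSES = (
    "point_quarter",
    "point_halves",
    "two_nearest_quadrants",
    "interior_half",
)

#: default genus mix for synthetic stands (mixedwood, upper-Midwest flavored)
DEFAULT_COMPOSITION = {
    "Oak": 0.25,
    "Maple": 0.20,
    "Pine": 0.20,
    "Birch": 0.15,
    "Hemlock": 0.10,
    "Tamarack": 0.10,
}

HALF_MILE_M = 804.67  # PLSS corner spacing


@dataclass(frozen=True)
class StemMap:
    """A simulated mapped stand with known true density.

    ``trees`` has columns x, y (m), genus, dbh (cm); ``extent`` is
    (x0, y0, x1, y1) in planar meters; ``true_density`` is stems per m².
    """

    extent: tuple
    trees: pd.DataFrame
    true_density: float
    pattern: str
    seed: int

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class SurveyDesign:
    """How the virtual surveyor selects bearing trees at each corner.

    ``effective_sector_deg`` rescales each design sector's angular window
    (180 = the nominal point-halves assumption; 253 widens each semicircle
    to 253°, 141 narrows it).  ``censor_halfwidth_deg`` removes that many
    degrees on each side of each cardinal azimuth.  Trees below
    ``diameter_limit_cm`` are eligible with ``small_tree_sampling_prob``.
    """

    design_class: str = "point_halves"
    effective_sector_deg: float = 180.0
    censor_halfwidth_deg: float = 0.0
    small_tree_sampling_prob: float = 1.0
    diameter_limit_cm: float = DIAMETER_LIMIT_CM
    grid_spacing: float = HALF_MILE_M
    travel_axis: str = "NS"
    max_radius: float = 100.0

    def __post_init__(self):
        if self.design_class not in DESIGN_CLASSES:
            raise ValueError(f"unknown design_class {self.design_class!r}")
        if not 0.0 < self.effective_sector_deg <= 360.0:
            raise ValueError("effective_sector_deg must be in (0, 360]")
        if self.censor_halfwidth_deg < 0 or 8 * self.censor_halfwidth_deg >= 360:
            raise ValueError("censor arcs must leave part of the circle open")
        if not 0.0 <= self.small_tree_sampling_prob <= 1.0:
            raise ValueError("small_tree_sampling_prob must be in [0, 1]")
        if self.travel_axis not in ("NS", "EW"):
            raise ValueError("travel_axis must be 'NS' or 'EW'")


def generate_stand(
    intensity: float,
    extent,
    pattern: str = "poisson",
    composition: Mapping[str, float] | None = None,
    dbh_median: float = 25.0,
    dbh_sigma: float = 0.5,
    dbh_min: float = 2.5,
    cluster_parent_intensity: float | None = None,
    cluster_sigma: float = 15.0,
    seed: int = 0,
) -> StemMap:
    """Generate a marked point pattern with expected density ``intensity``.

    ``pattern='poisson'`` is homogeneous; ``'clustered'`` is a Thomas
    process (Poisson parents, Gaussian offspring with scale
    ``cluster_sigma`` m) with the same expected intensity.  Genus marks are
    i.i.d. from ``composition``; dbh marks are lognormal with the given
    median (cm) and log-scale sigma, truncated below at ``dbh_min``.
    """
    x0, y0, x1, y1 = (float(v) for v in extent)
    area = (x1 - x0) * (y1 - y0)
    if intensity <= 0:
        raise ValueError("intensity must be positive (stems per m^2)")
    if area <= 0:
        raise ValueError("extent must have positive area")
    composition = dict(composition or DEFAULT_COMPOSITION)
    total = sum(composition.values())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"composition must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    if pattern == "poisson":
        n = rng.poisson(intensity * area)
        xs = rng.uniform(x0, x1, n)
        ys = rng.uniform(y0, y1, n)
    elif pattern == "clustered":
        parent_intensity = cluster_parent_intensity or intensity / 40.0
        mean_offspring = intensity / parent_intensity
        pad = 4.0 * cluster_sigma
        parea = (x1 - x0 + 2 * pad) * (y1 - y0 + 2 * pad)
        n_parents = rng.poisson(parent_intensity * parea)
        px = rng.uniform(x0 - pad, x1 + pad, n_parents)
        py = rng.uniform(y0 - pad, y1 + pad, n_parents)
        n_off = rng.poisson(mean_offspring, n_parents)
        xs = np.repeat(px, n_off) + rng.normal(0.0, cluster_sigma, n_off.sum())
        ys = np.repeat(py, n_off) + rng.normal(0.0, cluster_sigma, n_off.sum())
        inside = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
        xs, ys = xs[inside], ys[inside]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    n = len(xs)
    taxa = np.array(list(composition))
    probs = np.array([composition[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    genus = rng.choice(taxa, size=n, p=probs)
    dbh = _truncated_lognormal(rng, n, dbh_median, dbh_sigma, dbh_min)
    trees = pd.DataFrame({"x": xs, "y": ys, "genus": genus, "dbh": dbh})
    return StemMap(
        extent=(x0, y0, x1, y1),
        trees=trees,
        true_density=float(intensity),
        pattern=pattern,
        seed=int(seed),
    )


def _truncated_lognormal(rng, n, median, sigma, lower):
    mu = np.log(median)
    out = rng.lognormal(mu, sigma, n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
        bad = out < lower
    return out


def _sector_windows(design: SurveyDesign):
    """(center, width) compass windows the design samples, in record order."""
    scale = design.effective_sector_deg / 180.0
    if design.design_class == "point_halves":
        centers = (90.0, 270.0) if design.travel_axis == "NS" else (0.0, 180.0)
        return [(c, 180.0 * scale) for c in centers]
    quarter_centers = (45.0, 135.0, 225.0, 315.0)
    if design.design_class in ("point_quarter", "two_nearest_quadrants"):
        return [(c, 90.0 * scale) for c in quarter_centers]
    # interior_half: both quadrants on one side of the travel line
    centers = (45.0, 135.0) if design.travel_axis == "NS" else (315.0, 45.0)
    return [(c, 90.0 * scale) for c in centers]


def survey_stand(
    stand: StemMap,
    design: SurveyDesign,
    seed: int = 0,
    margin: float = 50.0,
    year: int = 1850,
    max_neighbors: int = 80,
) -> pd.DataFrame:
    """Record witness trees at a grid of corner points across a stand.

    Corners are placed at ``design.grid_spacing`` on a rectangular grid at
    least ``margin`` m inside the stand boundary, so nearest-tree searches
    never truncate at the edge.  Returns one row per recorded tree (or
    'No Tree' sentinel) in raw survey units: quadrant bearing, distance in
    links, diameter in inches, lower-case surveyor taxon string.
    """
    if len(stand.trees) == 0:
        raise ValueError("stand has no trees")
    x0, y0, x1, y1 = stand.extent
    xs = np.arange(x0 + margin, x1 - margin + 1e-9, design.grid_spacing)
    ys = np.arange(y0 + margin, y1 - margin + 1e-9, design.grid_spacing)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("stand too small for the grid spacing and margin")
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])

    tree_xy = stand.trees[["x", "y"]].to_numpy()
    dbh_cm = stand.trees["dbh"].to_numpy()
    genus = stand.trees["genus"].to_numpy()
    tree = cKDTree(tree_xy)
    k = min(len(tree_xy), max_neighbors)
    dist, idx = tree.query(points, k=k, distance_upper_bound=design.max_radius)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    rng = np.random.default_rng(seed)
    windows = _sector_windows(design)
    nx = xs.size
    rows = []
    for p in range(len(points)):
        ok = np.isfinite(dist[p])
        d = dist[p][ok]
        ti = idx[p][ok]
        dx = tree_xy[ti, 0] - points[p, 0]
        dy = tree_xy[ti, 1] - points[p, 1]
        az = np.degrees(np.arctan2(dx, dy)) % 360.0

        eligible = np.ones(len(ti), dtype=bool)
        if design.censor_halfwidth_deg > 0:
            near_cardinal = circular_distance(az[:, None], CARDINALS[None, :])
            eligible &= near_cardinal.min(axis=1) >= design.censor_halfwidth_deg
        if design.small_tree_sampling_prob < 1.0:
            small = dbh_cm[ti] < design.diameter_limit_cm
            sampled = rng.random(len(ti)) < design.small_tree_sampling_prob
            eligible &= ~small | sampled

        selected = []
        taken = np.zeros(len(ti), dtype=bool)  # a tree is recorded once only
        for center, width in windows:
            hit = eligible & ~taken & in_window(az, center, width)
            if hit.any():
                j = int(np.flatnonzero(hit)[0])  # KD distances are sorted
                taken[j] = True
                selected.append((d[j], az[j], ti[j]))
            else:
                selected.append(None)
        if design.design_class == "two_nearest_quadrants":
            found = sorted((s for s in selected if s is not None), key=lambda s: s[0])
            selected = found[:2] + [None] * max(0, 2 - len(found))

        ix, iy = p % nx, p // nx
        meta = {
            "point_id": f"p{p:06d}",
            "x": points[p, 0],
            "y": points[p, 1],
            "corner_kind": "section" if (ix + iy) % 2 == 0 else "quarter_section",
            "line_kind": (
                "external"
                if ix in (0, nx - 1) or iy in (0, ys.size - 1)
                else "internal"
            ),
            "year": year,
            "design_class": design.design_class,
        }
        for t_idx, s in enumerate(selected):
            row = dict(meta, tree_index=t_idx)
            if s is None:
                row.update(
                    quadrant=np.nan,
                    azimuth_in_quadrant=np.nan,
                    distance_links=np.nan,
                    diameter_in=np.nan,
                    taxon_raw="No Tree",
                )
            else:
                sd, saz, sti = s
                quadrant, angle = compass_to_quadrant(saz)
                # surveyors chained whole links and called whole inches;
                # the discretization is part of the record format (and the
                # cleaning rules assume it: a tree inside half a link of
                # the stake is recorded at distance 0)
                row.update(
                    quadrant=quadrant,
                    azimuth_in_quadrant=angle,
                    distance_links=round(sd / LINK_M),
                    diameter_in=max(round(dbh_cm[sti] / INCH_CM), 1),
                    taxon_raw=str(genus[sti]).lower(),
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Modern inventory plots

SUBPLOT_OFFSET_M = 36.58  # distance from plot center to outer subplots


def generate_fia_plots(
    stand: StemMap,
    n_plots: int,
    subplot_radius: float = 7.2,
    min_dbh: float = 12.7,
    seed: int = 0,
    centers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample fixed-radius inventory plots from a stand.

    Each plot is four ``subplot_radius`` m subplots: one at the plot center
    and three at ``SUBPLOT_OFFSET_M`` m along azimuths 0/120/240.  Every tree
    with dbh > ``min_dbh`` inside any subplot is recorded with exact genus
    and dbh (cm).  Plot centers are uniform within the extent shrunk so all
    subplots fit; user-supplied ``centers`` are validated against that.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if len(stand.trees) == 0:
        raise ValueError("stand has no trees")
    x0, y0, x1, y1 = stand.extent
    reach = SUBPLOT_OFFSET_M + subplot_radius
    if centers is None:
        rng = np.random.default_rng(seed)
        if x1 - x0 <= 2 * reach or y1 - y0 <= 2 * reach:
            raise ValueError("stand extent too small to place whole plots")
        cx = rng.uniform(x0 + reach, x1 - reach, n_plots)
        cy = rng.uniform(y0 + reach, y1 - reach, n_plots)
        centers = np.column_stack([cx, cy])
    else:
        centers = np.asarray(centers, dtype=float)
        if len(centers) != n_plots:
            raise ValueError("centers must match n_plots")
        bad = (
            (centers[:, 0] < x0 + reach)
            | (centers[:, 0] > x1 - reach)
            | (centers[:, 1] < y0 + reach)
            | (centers[:, 1] > y1 - reach)
        )
        if bad.any():
            raise ValueError("plot (sub)plots fall outside the stand extent")

    offsets = np.array(
        [[0.0, 0.0]]
        + [
            [
                SUBPLOT_OFFSET_M * np.sin(np.radians(a)),
                SUBPLOT_OFFSET_M * np.cos(np.radians(a)),
            ]
            for a in (0.0, 120.0, 240.0)
        ]
    )
    tree_xy = stand.trees[["x", "y"]].to_numpy()
    dbh = stand.trees["dbh"].to_numpy()
    genus = stand.trees["genus"].to_numpy()
    kd = cKDTree(tree_xy)

    rows = []
    for p in range(n_plots):
        plot_id = f"f{p:05d}"
        seen = set()
        for s, off in enumerate(offsets):
            center = centers[p] + off
            for j in kd.query_ball_point(center, subplot_radius):
                if j in seen or dbh[j] <= min_dbh:
                    continue
                seen.add(j)
                rows.append(
                    {
                        "plot_id": plot_id,
                        "x": centers[p, 0],
                        "y": centers[p, 1],
                        "subplot": s,
                        "genus": genus[j],
                        "dbh_cm": dbh[j],
                        "live": True,
                    }
                )
        if not seen:  # keep empty plots in the table so they count as zeros
            rows.append(
                {
                    "plot_id": plot_id,
                    "x": centers[p, 0],
                    "y": centers[p, 1],
                    "subplot": -1,
                    "genus": None,
                    "dbh_cm": np.nan,
                    "live": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired-era landscapes

ARCHETYPE_TAXA = (
    "Oak",
    "Pine",
    "Maple",
    "Birch",
    "Hemlock",
    "Tamarack",
    "Spruce",
    "Cedar",
    "Basswood",
    "Elm",
)
#: taxa concentrated in the homogenized (post-disturbance) composition;
#: absent from the era-1 archetypes so fully perturbed cells have no analog
NOVEL_TAXA = ("Poplar", "Ash")
HOMOGENIZED = {"Poplar": 0.45, "Ash": 0.30, "Maple": 0.15, "Birch": 0.10}


def _solve_intercept(target: float, offsets: np.ndarray) -> float:
    """b0 with mean(expit(b0 + offsets)) = target (bisection; monotone)."""
    if target >= 1.0:
        return 40.0
    if target <= 0.0:
        return -40.0
    lo, hi = -40.0, 40.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + offsets))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class LandscapePair:
    """Two gridded composition tables with known turnover structure."""

    era1: pd.DataFrame  # cells x taxa, era-1 (historical) composition
    era2: pd.DataFrame  # same cells, era-2 (modern) composition
    coords: pd.DataFrame  # cell_id, x, y (m)
    remnant: pd.Series  # True where era-2 kept the era-1 composition patch
    novel_true: pd.Series  # True where era-2 was perturbed
    zone: pd.Series  # generating archetype label per cell
    seed: int
    params: dict = field(default_factory=dict)


def generate_landscape_pair(
    n_cells: int,
    k_types: int,
    turnover: float,
    distance_effect: float = 0.0,
    perturbation: float = 1.0,
    remnant_fraction: float = 0.25,
    cell_size: float = 8000.0,
    concentration: float = 75.0,
    drift_concentration: float = 300.0,
    seed: int = 0,
) -> LandscapePair:
    """Paired era-1/era-2 composition tables with controlled turnover.

    Era-1 cells draw from ``k_types`` Dirichlet-centered archetypes arranged
    in spatially coherent zones.  ``remnant_fraction`` of the cells, grown
    as patches around the zone centers, keep their era-1 composition in
    era 2.  Each remaining cell is perturbed toward a common homogenized
    composition with probability expit(b0 + distance_effect * d), d its
    distance (km) to the nearest remnant cell and b0 solved so the expected
    perturbed fraction among non-remnant cells equals ``turnover``
    (b0 = logit(turnover) when distance_effect is 0).  ``perturbation`` is
    the homogenized mixing weight in perturbed cells (1 = full
    replacement).  turnover=0 returns an identical era 2 (all cells
    remnant); turnover=1 perturbs every cell (no remnants).
    """
    if not 0.0 <= turnover <= 1.0:
        raise ValueError("turnover must be in [0, 1]")
    if k_types < 2:
        raise ValueError("k_types must be >= 2")
    if n_cells <= k_types:
        raise ValueError("need more cells than archetypes")
    if not 0.0 <= perturbation <= 1.0:
        raise ValueError("perturbation must be in [0, 1]")

    rng = np.random.default_rng(seed)
    base_taxa = list(ARCHETYPE_TAXA[: max(k_types + 2, 5)])
    taxa = base_taxa + [t for t in NOVEL_TAXA if t not in base_taxa]

    nx = int(np.ceil(np.sqrt(n_cells)))
    ij = np.array([(i, j) for j in range(nx) for i in range(nx)][:n_cells])
    xy = (ij + 0.5) * cell_size
    cell_id = np.array([f"c{i:04d}" for i in range(n_cells)])

    # spatially coherent zones around random archetype centers
    centers = xy[rng.choice(n_cells, size=k_types, replace=False)]
    zone = np.argmin(
        np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2), axis=1
    )

    arch = np.zeros((k_types, len(taxa)))
    for t in range(k_types):
        arch[t, : len(base_taxa)] = 1.0
        arch[t, t % len(base_taxa)] = 8.0
    arch /= arch.sum(axis=1, keepdims=True)

    alpha = arch[zone] * concentration + 0.02
    era1 = np.vstack([rng.dirichlet(a) for a in alpha])

    if turnover == 0.0:
        era2 = era1.copy()
        remnant = np.ones(n_cells, dtype=bool)
        perturbed = np.zeros(n_cells, dtype=bool)
    else:
        n_rem = 0 if turnover == 1.0 else int(round(remnant_fraction * n_cells))
        remnant = np.zeros(n_cells, dtype=bool)
        if n_rem > 0:
            d_seed = np.linalg.norm(
                xy[:, None, :] - centers[None, :, :], axis=2
            ).min(axis=1)
            remnant[np.argsort(d_seed, kind="stable")[:n_rem]] = True
        if remnant.any():
            rem_xy = xy[remnant]
            d_km = (
                np.linalg.norm(xy[:, None, :] - rem_xy[None, :, :], axis=2).min(axis=1)
                / 1000.0
            )
        else:
            d_km = np.zeros(n_cells)
        p_perturb = expit(
            _solve_intercept(turnover, distance_effect * d_km[~remnant])
            + distance_effect * d_km
        )
        perturbed = ~remnant & (rng.random(n_cells) < p_perturb)

        homog = np.array([HOMOGENIZED.get(t, 0.0) for t in taxa])
        homog = homog / homog.sum()
        era2 = era1.copy()
        for i in np.flatnonzero(perturbed):
            target = rng.dirichlet(homog * concentration + 0.02)
            era2[i] = (1.0 - perturbation) * era1[i] + perturbation * target
        # unperturbed non-remnant cells drift a little: real forests that
        # kept their type did not stay compositionally identical
        for i in np.flatnonzero(~remnant & ~perturbed):
            era2[i] = rng.dirichlet(era1[i] * drift_concentration + 0.02)

    idx = pd.Index(cell_id, name="cell_id")
    return LandscapePair(
        era1=pd.DataFrame(era1, index=idx, columns=taxa),
        era2=pd.DataFrame(era2, index=idx, columns=taxa),
        coords=pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}, index=idx),
        remnant=pd.Series(remnant, index=idx, name="remnant"),
        novel_true=pd.Series(perturbed, index=idx, name="novel_true"),
        zone=pd.Series([f"type{z}" for z in zone], index=idx, name="zone"),
        seed=int(seed),
        params={
            "n_cells": n_cells,
            "k_types": k_types,
            "turnover": turnover,
            "distance_effect": distance_effect,
            "perturbation": perturbation,
            "remnant_fraction": remnant_fraction,
            "cell_size": cell_size,
        },
    )
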