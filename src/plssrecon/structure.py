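"""Per-point basal area and aboveground biomass from witness-tree diameters.

Individual-tree aboveground dry biomass uses the national group-level
allometry  m = exp(beta0 + beta1 * ln(dbh))  with dbh in cm and m in kg;
the genus → group assignment and coefficients ship as a CSV (all maples go
to the generic Mixed Hardwood group because separate soft/hard maple curves
exist and the survey taxa are genus-level).

Per corner point, the mean stem basal area / mean tree biomass over the two
recorded trees is multiplied by the corrected point density to give
m² ha⁻¹ and Mg ha⁻¹.  'No Tree' corners are 0 by the density-zero
convention; sentinel records contribute 0 to the within-point mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

SENTINELS = ("NonTree", "Water", "Unknown")


@dataclass(frozen=True)
class AllometricGroup:
    name: str
    beta0: float
    beta1: float
    taxa: tuple


def _load_allometry():
    with resources.files("plssrecon.data").joinpath("allometry.csv").open() as fh:
        table = pd.read_csv(fh)
    groups = {}
    genus_to_group = {}
    for name, sub in table.groupby("group", sort=False):
        grp = AllometricGroup(
            name=name,
            beta0=float(sub["beta0"].iloc[0]),
            beta1=float(sub["beta1"].iloc[0]),
            taxa=tuple(sub["genus"]),
        )
        groups[name] = grp
        for g in grp.taxa:
            genus_to_group[g] = grp
    return groups, genus_to_group


GROUPS, _GENUS_TO_GROUP = _load_allometry()
GENUS_TAXA = tuple(_GENUS_TO_GROUP)  # the 28 genus-level taxa


def jenkins_group(genus: str) -> AllometricGroup | None:
    """Allometric group for a genus; None (zero contribution) for sentinels."""
    if genus in SENTINELS:
        return None
    try:
        return _GENUS_TO_GROUP[genus]
    except KeyError:
        raise ValueError(f"no allometric group for genus {genus!r}") from None


def tree_biomass(dbh_cm, group: AllometricGroup) -> float:
    """Aboveground dry biomass (kg) of one tree, exp(b0 + b1 ln dbh)."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be positive (cm)")
    out = np.exp(group.beta0 + group.beta1 * np.log(dbh))
    return float(out) if out.ndim == 0 else out


def stem_basal_area(dbh_cm):
    """Cross-sectional stem area (m²) at breast height, pi*(dbh/200)^2."""
    dbh = np.asarray(dbh_cm, dtype=float)
    out = np.pi * (dbh / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def _point_mean(values, taxa):
    """Mean over the two point records; sentinels contribute 0."""
    vals = []
    for v, t in zip(values, taxa):
        vals.append(0.0 if t in SENTINELS or not np.isfinite(v) else v)
    return float(np.mean(vals)) if vals else 0.0


def point_basal_area(dbh_cms, taxa, density_stems_m2: float) -> float:
    """Point basal area (m² ha⁻¹): mean stem area × density × 10⁴."""
    if density_stems_m2 == 0.0:
        return 0.0
    areas = [stem_basal_area(d) if np.isfinite(d) else np.nan for d in dbh_cms]
    return _point_mean(areas, taxa) * density_stems_m2 * 1e4


def point_biomass(dbh_cms, taxa, density_stems_m2: float) -> float:
    """Point aboveground biomass (Mg ha⁻¹): mean tree kg × density × 10."""
    if density_stems_m2 == 0.0:
        return 0.0
    masses = []
    for d, t in zip(dbh_cms, taxa):
        if t in SENTINELS or not np.isfinite(d):
            masses.append(0.0)
        else:
            masses.append(tree_biomass(d, jenkins_group(t)))
    return _point_mean(masses, taxa) * density_stems_m2 * 1e4 / 1000.0


def point_structure(trees: pd.DataFrame, point_density: pd.DataFrame) -> pd.DataFrame:
    """Per-point basal area and biomass table.

    ``trees`` is the standardized tree table, ``point_density`` the output
    of density estimation with a ``lambda_corrected`` (or ``lambda_M``)
    column in stems/m².  Returns point_id, basal_area_m2ha, biomass_Mgha.
    """
    lam_col = (
        "lambda_corrected" if "lambda_corrected" in point_density.columns else "lambda_M"
    )
    by_point = dict(tuple(trees.groupby("point_id", sort=False)))
    rows = []
    for _, pt in point_density.iterrows():
        lam = pt[lam_col]
        grp = by_point.get(pt["point_id"])
        if grp is None or lam == 0.0:
            rows.append(
                {"point_id": pt["point_id"], "basal_area_m2ha": 0.0, "biomass_Mgha": 0.0}
            )
            continue
        dbh = grp["dbh_cm"].to_numpy(dtype=float)
        taxa = grp["taxon"].tolist()
        rows.append(
            {
                "point_id": pt["point_id"],
                "basal_area_m2ha": point_basal_area(dbh, taxa, lam),
                "biomass_Mgha": point_biomass(dbh, taxa, lam),
            }
        )
    return pd.DataFrame(rows)
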