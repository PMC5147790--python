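"""Shared fixtures: small synthetic stands and surveys reused across tests."""
import numpy as np
import pandas as pd
import pytest

import plssrecon as pr

TRUE_INTENSITY = 0.02  # stems per m^2 (200 stems/ha)


@pytest.fixture(scope="session")
def poisson_stand():
    """1 km² homogeneous Poisson stand at 200 stems/ha."""
    return pr.generate_stand(TRUE_INTENSITY, (0, 0, 1000, 1000), seed=11)


@pytest.fixture(scope="session")
def halves_survey(poisson_stand):
    """Unbiased point-halves survey (~900 corners) on the Poisson stand."""
    design = pr.SurveyDesign(design_class="point_halves", grid_spacing=30.0)
    return pr.survey_stand(poisson_stand, design, seed=12)


@pytest.fixture(scope="session")
def halves_batch(halves_survey):
    return pr.standardize_corners(halves_survey)


@pytest.fixture()
def raw_corner():
    """A single valid two-tree corner record in raw survey units."""

    def make(**overrides):
        base = pd.DataFrame(
            {
                "point_id": ["p0", "p0"],
                "x": [100.0, 100.0],
                "y": [100.0, 100.0],
                "corner_kind": ["section"] * 2,
                "line_kind": ["internal"] * 2,
                "year": [1850] * 2,
                "design_class": ["point_halves"] * 2,
                "quadrant": ["NE", "SW"],
                "azimuth_in_quadrant": [30.0, 45.0],
                "distance_links": [20.0, 35.0],
                "diameter_in": [10.0, 14.0],
                "taxon_raw": ["oak", "pine"],
            }
        )
        for col, vals in overrides.items():
            base[col] = vals
        return base

    return make
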