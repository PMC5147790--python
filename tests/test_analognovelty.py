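"""Dissimilarity, analogs, clustering, novelty GLM, permutation null,
transect beta diversity and Moran's I."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_bc

import plssrecon as pr
from plssrecon import analognovelty as an


def _comp_df(arr, prefix="c"):
    arr = np.asarray(arr, dtype=float)
    idx = pd.Index([f"{prefix}{i:03d}" for i in range(len(arr))], name="cell_id")
    return pd.DataFrame(arr, index=idx, columns=[f"t{j}" for j in range(arr.shape[1])])


class TestBrayCurtis:
    def test_identity(self):
        assert an.bray_curtis([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_supports(self):
        assert an.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_worked_example(self):
        assert an.bray_curtis([0.5, 0.5, 0.0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_all_zero_flagged_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(an.bray_curtis([0.0, 0.0], [0.0, 0.0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            an.bray_curtis([-0.1, 1.1], [0.5, 0.5])

    @given(
        st.lists(st.floats(0.0, 10.0), min_size=3, max_size=8).filter(
            lambda v: sum(v) > 0
        ),
        st.lists(st.floats(0.0, 10.0), min_size=3, max_size=8).filter(
            lambda v: sum(v) > 0
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_and_axioms(self, x, y):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n]), np.asarray(y[:n])
        d = an.bray_curtis(x, y)
        assert abs(d - scipy_bc(x, y)) < 1e-12
        assert d == an.bray_curtis(y, x)
        assert 0.0 <= d <= 1.0


class TestMinDissimilarity:
    def test_identical_cells_within_era(self):
        comps = _comp_df([[0.5, 0.5], [0.5, 0.5], [0.2, 0.8]])
        out = an.min_dissimilarity(comps, comps, exclude_self=True)
        assert out.loc["c000", "min_dissim"] == 0.0
        assert out.loc["c000", "matched_cell_id"] == "c001"

    def test_between_era_exact_match(self):
        focal = _comp_df([[0.3, 0.7]])
        ref = _comp_df([[0.6, 0.4], [0.3, 0.7]], prefix="r")
        out = an.min_dissimilarity(focal, ref)
        assert out["min_dissim"].iloc[0] == 0.0
        assert out["matched_cell_id"].iloc[0] == "r001"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        focal = _comp_df(rng.dirichlet(np.ones(6), 50), prefix="f")
        ref = _comp_df(rng.dirichlet(np.ones(6), 50), prefix="r")
        out = an.min_dissimilarity(focal, ref)
        for i, (cid, row) in enumerate(out.iterrows()):
            dists = [scipy_bc(focal.iloc[i], ref.iloc[j]) for j in range(len(ref))]
            assert row["min_dissim"] == pytest.approx(min(dists), abs=1e-12)
            assert row["matched_cell_id"] == ref.index[int(np.argmin(dists))]

    def test_self_exclusion_requires_second_cell(self):
        comps = _comp_df([[1.0, 0.0]])
        with pytest.raises(ValueError):
            an.min_dissimilarity(comps, comps, exclude_self=True)


class TestThresholds:
    def test_percentiles_linear_interpolation(self):
        vals = np.arange(0.01, 1.001, 0.01)
        cuts = an.novelty_thresholds(vals, vals)
        assert cuts["novel_cut"] == pytest.approx(np.percentile(vals, 95))
        assert cuts["novel_cut"] == pytest.approx(0.95, abs=0.01)
        assert cuts["remnant_cut"] == pytest.approx(0.25, abs=0.01)

    def test_constant_distribution(self):
        vals = np.full(30, 0.4)
        cuts = an.novelty_thresholds(vals, vals)
        assert cuts["novel_cut"] == cuts["remnant_cut"] == cuts["lost_cut"] == 0.4

    def test_classification(self):
        cuts = {"novel_cut": 0.95, "remnant_cut": 0.25, "lost_cut": 0.95}
        fia = pd.Series([0.99, 0.5, 0.1], index=list("abc"))
        pls = pd.Series([0.96, 0.2], index=list("xy"))
        flags = an.classify_cells(fia, pls, cuts)
        assert flags["novel"].tolist() == [True, False, False]
        assert flags["remnant"].tolist() == [False, False, True]
        assert flags["lost"].tolist() == [True, False]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            an.novelty_thresholds([0.1] * 5, [0.1] * 30)


class TestKMedoids:
    def test_recovers_two_archetype_groups(self):
        rng = np.random.default_rng(23)
        a = rng.dirichlet([40, 4, 1], 30)
        b = rng.dirichlet([1, 4, 40], 30)
        comps = _comp_df(np.vstack([a, b]))
        out = an.kmedoid_types(comps, k=2)
        labels = out["forest_type"].to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_k_one_rejected(self):
        comps = _comp_df(np.eye(3))
        with pytest.raises(ValueError):
            an.kmedoid_types(comps, k=1)

    def test_k_too_large_rejected(self):
        comps = _comp_df(np.eye(3))
        with pytest.raises(ValueError):
            an.kmedoid_types(comps, k=3)

    def test_stable_under_duplication(self):
        rng = np.random.default_rng(29)
        base = np.vstack([rng.dirichlet([30, 3, 1], 10), rng.dirichlet([1, 3, 30], 10)])
        one = an.kmedoid_types(_comp_df(base), k=2)
        two = an.kmedoid_types(_comp_df(np.vstack([base, base])), k=2)
        m1 = sorted(set(one["medoid_cell_id"].str.slice(1).astype(int) % 20))
        m2 = sorted(set(two["medoid_cell_id"].str.slice(1).astype(int) % 20))
        assert m1 == m2

    def test_names_reflect_dominant_taxa(self):
        comps = _comp_df([[0.6, 0.3, 0.1], [0.58, 0.32, 0.1], [0.05, 0.05, 0.9], [0.06, 0.04, 0.9]])
        out = an.kmedoid_types(comps, k=2)
        names = set(out["forest_type"])
        assert any(n.startswith("t0-t1") for n in names)
        assert any(n.startswith("t2") for n in names)


class TestDistanceToRemnant:
    def _coords(self, n=5):
        idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
        return pd.DataFrame({"x": np.arange(n) * 8000.0, "y": 0.0}, index=idx)

    def test_remnant_cell_distance_zero(self):
        coords = self._coords()
        rem = pd.Series([True, False, False, False, False], index=coords.index)
        d = an.distance_to_remnant(coords, rem)
        assert d.iloc[0] == 0.0

    def test_one_grid_step_is_eight_km(self):
        coords = self._coords()
        rem = pd.Series([True, False, False, False, False], index=coords.index)
        assert an.distance_to_remnant(coords, rem).iloc[1] == pytest.approx(8.0)

    def test_matches_brute_force_on_lattice(self):
        rng = np.random.default_rng(5)
        n = 49
        idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
        xy = np.array([(i % 7, i // 7) for i in range(n)]) * 8000.0
        coords = pd.DataFrame(xy, columns=["x", "y"], index=idx)
        rem = pd.Series(rng.random(n) < 0.2, index=idx)
        rem.iloc[0] = True
        d = an.distance_to_remnant(coords, rem)
        for i in range(n):
            brute = min(
                np.hypot(*(xy[i] - xy[j])) / 1000.0 for j in np.flatnonzero(rem)
            )
            assert d.iloc[i] == pytest.approx(brute)

    def test_no_remnants_rejected(self):
        coords = self._coords()
        with pytest.raises(ValueError):
            an.distance_to_remnant(coords, pd.Series(False, index=coords.index))


class TestNoveltyGLM:
    def _simulate(self, slope=0.1, intercept=-3.0, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 60, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(intercept + slope * d)))
        idx = pd.Index([f"c{i}" for i in range(n)])
        return pd.Series(y, index=idx), pd.Series(d, index=idx)

    def test_parameter_recovery(self):
        novel, dist = self._simulate(seed=1)
        fit = an.fit_novelty_glm(novel, dist)["all"]
        X = sm.add_constant(dist.to_numpy())
        ci = sm.GLM(novel.to_numpy().astype(float), X, family=sm.families.Binomial()).fit().conf_int()
        assert ci[1][0] <= 0.1 <= ci[1][1]
        assert fit.d50 == pytest.approx(30.0, abs=3.0)

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        idx = pd.Index([f"c{i}" for i in range(2000)])
        novel = pd.Series(rng.random(2000) < 0.3, index=idx)
        dist = pd.Series(rng.uniform(0, 60, 2000), index=idx)
        X = sm.add_constant(dist.to_numpy())
        ci = sm.GLM(novel.to_numpy().astype(float), X, family=sm.families.Binomial()).fit().conf_int()
        assert ci[1][0] <= 0.0 <= ci[1][1]

    def test_all_novel_type_flagged_saturated(self):
        idx = pd.Index([f"c{i}" for i in range(30)])
        novel = pd.Series(True, index=idx)
        dist = pd.Series(np.linspace(0, 50, 30), index=idx)
        fit = an.fit_novelty_glm(novel, dist)["all"]
        assert fit.flag == "saturated"
        assert np.isnan(fit.d50)

    def test_small_type_flagged(self):
        idx = pd.Index([f"c{i}" for i in range(10)])
        novel = pd.Series([True, False] * 5, index=idx)
        dist = pd.Series(np.linspace(0, 50, 10), index=idx)
        assert an.fit_novelty_glm(novel, dist)["all"].flag == "too_few"


class TestPermutationNull:
    def test_shuffle_preserves_multiset(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.random(100), index=[f"c{i}" for i in range(100)])
        shuffled = an._shuffle_minima(vals, rng)
        assert sorted(shuffled) == sorted(vals)
        assert list(shuffled.index) == list(vals.index)

    def test_reproducible_with_seed(self):
        pair = pr.generate_landscape_pair(200, 3, turnover=0.5, seed=6)
        bet = an.min_dissimilarity(pair.era2, pair.era1)["min_dissim"]
        w1 = an.min_dissimilarity(pair.era1, pair.era1, exclude_self=True)["min_dissim"]
        cuts = an.novelty_thresholds(w1, w1)
        a = an.permutation_null(bet, pair.coords, cuts, n_perm=10, seed=9)
        b = an.permutation_null(bet, pair.coords, cuts, n_perm=10, seed=9)
        assert a == b

    def test_nperm_lower_bound(self):
        pair = pr.generate_landscape_pair(100, 2, turnover=0.5, seed=6)
        bet = an.min_dissimilarity(pair.era2, pair.era1)["min_dissim"]
        with pytest.raises(ValueError):
            an.permutation_null(bet, pair.coords, {"novel_cut": 0.5, "remnant_cut": 0.1}, n_perm=1)


class TestTransectBeta:
    def _gradient(self, n=30, taxa=4, seed=0):
        rng = np.random.default_rng(seed)
        base = np.linspace(0, 1, n)[:, None]
        arr = np.hstack(
            [np.maximum(1 - base, 0), base * 0.5, base * 0.3, base * 0.2]
        )[:, :taxa]
        arr = arr + rng.uniform(0, 0.15, arr.shape)
        return _comp_df(arr / arr.sum(axis=1, keepdims=True))

    def test_identical_eras_delta_zero(self):
        era = self._gradient()
        out = an.transect_beta(era, era.copy())
        assert out.delta_beta == 0.0 and out.t_stat == 0.0

    def test_smoothed_era_two_more_homogeneous(self):
        era1 = self._gradient(seed=4)
        smoothed = era1.rolling(5, center=True, min_periods=1).mean()
        smoothed = smoothed.div(smoothed.sum(axis=1), axis=0)
        out = an.transect_beta(era1, smoothed)
        assert out.delta_beta < 0
        assert out.p_value < 0.05

    def test_too_short_rejected(self):
        era = self._gradient(n=2)
        with pytest.raises(ValueError):
            an.transect_beta(era, era)

    def test_restriction_to_shared_cells_flagged(self):
        era1 = self._gradient(n=20, seed=7)
        era2 = self._gradient(n=20, seed=8).iloc[:15]
        out = an.transect_beta(era1, era2)
        assert out.restricted and out.n_pairs == 14


class TestMoransI:
    def _lattice(self, n=6):
        idx = pd.Index([f"c{i}" for i in range(n * n)], name="cell_id")
        xy = np.array([(i % n, i // n) for i in range(n * n)]) * 8000.0
        return pd.DataFrame(xy, columns=["x", "y"], index=idx)

    def _direct_I(self, y, w):
        # independent implementation of the statistic as an oracle
        z = y - y.mean()
        num = sum(
            w[i, j] * z[i] * z[j] for i in range(len(y)) for j in range(len(y))
        )
        return len(y) / w.sum() * num / (z @ z)

    def test_checkerboard_negative_and_matches_oracle(self):
        coords = self._lattice()
        y = pd.Series(
            [(i + i // 6) % 2 * 2.0 - 1.0 for i in range(36)], index=coords.index
        )
        out = an.morans_i(y, coords, weights="rook", n_perm=99, seed=1)
        assert out.morans_I == pytest.approx(-1.0)
        w = an._contiguity_weights(coords, 8000.0, "rook")
        w = w / w.sum(axis=1, keepdims=True)
        assert out.morans_I == pytest.approx(self._direct_I(y.to_numpy(), w))

    def test_gradient_positive(self):
        coords = self._lattice()
        y = pd.Series(coords["x"] + coords["y"], index=coords.index)
        out = an.morans_i(y, coords, n_perm=199, seed=2)
        assert out.morans_I > 0.5
        assert out.p_value < 0.01

    def test_constant_rejected(self):
        coords = self._lattice()
        with pytest.raises(ValueError):
            an.morans_i(pd.Series(1.0, index=coords.index), coords)

    def test_null_mean_near_expected(self):
        coords = self._lattice()
        rng = np.random.default_rng(11)
        w = an._contiguity_weights(coords, 8000.0, "queen")
        w = w / w.sum(axis=1, keepdims=True)
        y = rng.normal(size=36)
        sims = []
        for _ in range(300):
            sims.append(self._direct_I(rng.permutation(y), w))
        sem = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - (-1 / 35)) < 4 * sem


class TestPipelineProperties:
    def test_zero_turnover_zero_novelty_zero_delta_beta(self):
        pair = pr.generate_landscape_pair(150, 3, turnover=0.0, seed=13)
        w1 = an.min_dissimilarity(pair.era1, pair.era1, exclude_self=True)["min_dissim"]
        bet = an.min_dissimilarity(pair.era2, pair.era1)["min_dissim"]
        cuts = an.novelty_thresholds(w1, w1)
        flags = an.classify_cells(bet, bet, cuts)
        assert not flags["novel"].any()
        assert flags["remnant"].all()
        row = pair.coords[pair.coords["y"] == pair.coords["y"].iloc[0]].index
        out = an.transect_beta(pair.era1.loc[row], pair.era2.loc[row])
        assert out.delta_beta == 0.0

    def test_full_turnover_full_novelty(self):
        pair = pr.generate_landscape_pair(150, 3, turnover=1.0, seed=13)
        w1 = an.min_dissimilarity(pair.era1, pair.era1, exclude_self=True)["min_dissim"]
        bet = an.min_dissimilarity(pair.era2, pair.era1)["min_dissim"]
        cuts = an.novelty_thresholds(w1, w1)
        assert (bet > cuts["novel_cut"]).all()
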