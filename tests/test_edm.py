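"""Delay embedding and S-map forecasting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recruitcast as rc
from recruitcast.edm import (
    CANDIDATE_COORDS,
    DelayBlock,
    EmbeddingError,
    EmbeddingSpec,
    SMapConfig,
    best_edm_rho,
    build_block,
    enumerate_embeddings,
    loo_smap_rho,
    optimize_theta,
    smap_predict,
)


def _series(R, S=None):
    n = len(R)
    return rc.StockRecruitSeries(
        "t", "x", np.arange(1960, 1960 + n), np.ones(n) if S is None else S, R
    )


class TestEnumeration:
    def test_all_63_subsets_once(self):
        specs = enumerate_embeddings()
        assert len(specs) == 63
        seen = {frozenset(s.coordinates) for s in specs}
        assert len(seen) == 63
        assert frozenset({("R", 1)}) in seen

    def test_concurrent_mode_drops_lag0_recruitment(self):
        specs = enumerate_embeddings(include_lag0_R=False)
        assert len(specs) == 31
        assert all(("R", 0) not in s.coordinates for s in specs)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            EmbeddingSpec((("R", 0), ("R", 0)))


class TestBuildBlock:
    def test_row_count_with_lags_and_horizon(self):
        s = _series(np.linspace(1, 2, 25))
        spec = EmbeddingSpec((("R", 0), ("R", 2), ("S", 1)))
        block = build_block(s, spec, horizon=1)
        assert block.n_rows == 22
        assert block.base_times[0] == 2 and block.base_times[-1] == 23

    def test_concurrent_single_coordinate_keeps_all_rows(self):
        S = np.linspace(1, 3, 25)
        s = _series(2 * S, S)
        block = build_block(s, EmbeddingSpec((("S", 0),)), horizon=0)
        assert block.n_rows == 25
        np.testing.assert_array_equal(block.X[:, 0], S)
        np.testing.assert_array_equal(block.y, s.R)

    def test_too_short_series_raises(self):
        with pytest.raises(EmbeddingError, match="too short"):
            build_block(_series([1.0, 2.0]), EmbeddingSpec((("R", 2),)), horizon=1)

    def test_lagged_columns_align(self):
        R = np.arange(10.0) + 1
        block = build_block(_series(R), EmbeddingSpec((("R", 0), ("R", 2))), horizon=1)
        np.testing.assert_array_equal(block.X[:, 0] - block.X[:, 1], np.full(7, 2.0))
        np.testing.assert_array_equal(block.y, block.X[:, 0] + 1)


@pytest.fixture(scope="module")
def noisy_block():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.5, 40)
    return DelayBlock(
        X=X, y=y, base_times=np.arange(40),
        spec=EmbeddingSpec((("R", 0), ("R", 1), ("S", 0))), horizon=1,
    )


class TestSMap:

    def test_theta_zero_equals_global_ols(self, noisy_block):
        """At theta = 0 the S-map is one global linear regression."""
        import statsmodels.api as sm

        block = noisy_block
        for row in (0, 13, 39):
            lib = np.setdiff1d(np.arange(block.n_rows), [row])
            got = smap_predict(block, 0.0, row, lib)
            fit = sm.OLS(block.y[lib], sm.add_constant(block.X[lib])).fit()
            want = fit.predict(np.concatenate([[1.0], block.X[row]]))[0]
            assert got == pytest.approx(want, abs=1e-8)

    def test_exact_linear_map_recovered_at_any_theta(self):
        x = np.linspace(-2, 3, 30)
        block = DelayBlock(
            X=x[:, None], y=2 * x + 1, base_times=np.arange(30),
            spec=EmbeddingSpec((("R", 0),)), horizon=1,
        )
        lib = np.arange(1, 30)
        for theta in (0.0, 0.5, 4.0):
            assert smap_predict(block, theta, 0, lib) == pytest.approx(
                2 * x[0] + 1, abs=1e-8
            )

    def test_prediction_invariant_to_column_rescaling(self, noisy_block):
        """With z-scored coordinates, rescaling predictors changes nothing."""
        block = noisy_block
        scaled = DelayBlock(
            X=block.X * [100.0, 0.01, 7.0], y=block.y,
            base_times=block.base_times, spec=block.spec, horizon=block.horizon,
        )
        lib = np.arange(1, block.n_rows)
        for theta in (0.0, 1.0, 4.0):
            a = smap_predict(block, theta, 0, lib, normalize=True)
            b = smap_predict(scaled, theta, 0, lib, normalize=True)
            assert a == pytest.approx(b, rel=1e-10)

    def test_target_never_in_library(self, noisy_block):
        with pytest.raises(ValueError, match="own library"):
            smap_predict(noisy_block, 1.0, 5, np.arange(noisy_block.n_rows))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        theta1=st.floats(0.0, 4.0),
        dtheta=st.floats(0.01, 4.0),
        seed=st.integers(0, 100),
    )
    def test_weights_localize_monotonically(self, theta1, dtheta, seed):
        """Larger theta never favors a farther point over a nearer one more."""
        rng = np.random.default_rng(seed)
        d = np.sort(rng.uniform(0.0, 5.0, 10))
        dbar = d.mean()
        w1 = np.exp(-theta1 * d / dbar)
        w2 = np.exp(-(theta1 + dtheta) * d / dbar)
        assert np.all((0 < w1) & (w1 <= 1.0)) and np.all((0 < w2) & (w2 <= 1.0))
        # ratio w[far]/w[near] shrinks as theta grows
        assert np.all(w2[1:] / w2[:-1] <= w1[1:] / w1[:-1] + 1e-12)

    def test_weight_one_iff_zero_distance_or_theta(self):
        block = DelayBlock(
            X=np.array([[0.0], [0.0], [1.0], [2.0]]), y=np.array([1.0, 1.0, 2.0, 3.0]),
            base_times=np.arange(4), spec=EmbeddingSpec((("R", 0),)), horizon=1,
        )
        # duplicate predictee rows are retained with weight exp(0) = 1
        assert np.isfinite(smap_predict(block, 2.0, 0, np.array([1, 2, 3])))


class TestLooRho:
    def test_noiseless_linear_ar_map_is_learnable(self, linear_ar_series):
        block = build_block(linear_ar_series, EmbeddingSpec((("R", 0),)), 1)
        rho, preds = loo_smap_rho(block, 0.0, np.arange(block.n_rows))
        assert rho > 0.999
        assert len(preds) == block.n_rows

    def test_rho_independent_of_target_order(self, chaotic_series):
        block = build_block(chaotic_series, EmbeddingSpec((("R", 0), ("R", 1))), 1)
        rows = np.arange(block.n_rows)
        rho_fwd, p_fwd = loo_smap_rho(block, 2.0, rows)
        rho_rev, p_rev = loo_smap_rho(block, 2.0, rows[::-1])
        assert rho_fwd == pytest.approx(rho_rev, abs=1e-12)
        np.testing.assert_allclose(p_fwd, p_rev[::-1])


class TestOptimizeTheta:
    def test_linear_dynamics_tie_break_to_zero(self, linear_ar_series):
        """A noiseless linear map is fit exactly at every theta; ties -> 0."""
        block = build_block(linear_ar_series, EmbeddingSpec((("R", 0),)), 1)
        theta, rho = optimize_theta(block, np.arange(block.n_rows))
        assert theta == 0.0
        assert rho > 0.999

    def test_chaotic_dynamics_prefer_local_maps(self, chaotic_series):
        block = build_block(chaotic_series, EmbeddingSpec((("R", 0),)), 1)
        rows = np.arange(block.n_rows)
        theta, rho = optimize_theta(block, rows)
        rho0, _ = loo_smap_rho(block, 0.0, rows)
        assert theta > 0
        assert rho > rho0

    def test_never_below_global_linear(self, chaotic_series):
        block = build_block(chaotic_series, EmbeddingSpec((("R", 0), ("S", 1))), 1)
        rows = np.arange(block.n_rows)
        _, rho = optimize_theta(block, rows)
        rho0, _ = loo_smap_rho(block, 0.0, rows)
        assert rho >= rho0


class TestBestEdm:
    def test_dominates_univariate_singleton(self, small_series):
        series = small_series[0]
        result = best_edm_rho(series)
        block = build_block(series, EmbeddingSpec((("R", 0),)), 1)
        # same evaluation targets as the full search, mapped onto this block
        rows = np.array(
            [np.where(block.target_times == t)[0][0]
             for t in result.target_times if t in block.target_times]
        )
        _, rho_single = optimize_theta(block, rows)
        assert result.rho >= rho_single - 1e-12

    def test_deterministic_given_input(self, small_series):
        a = best_edm_rho(small_series[1])
        b = best_edm_rho(small_series[1])
        assert a.rho == b.rho and a.best_theta == b.best_theta
        assert a.best_spec == b.best_spec
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_spawner_driven_dynamics_select_spawner_coordinates(self):
        """When R is a (dome-shaped) function of S only, S coordinates win."""
        rng = np.random.default_rng(21)
        n = 60
        z = np.empty(n)
        z[0] = 0.0
        for t in range(n - 1):
            z[t + 1] = 0.9 * z[t] + 0.3 * rng.normal()
        S = np.exp(z)
        R = 2.0 * S * np.exp(-1.5 * S) * np.exp(rng.normal(0, 0.05, n))
        series = _series(R, S)
        result = best_edm_rho(series, horizon=0)
        assert any(var == "S" for var, _ in result.best_spec.coordinates)
        # derived check: S-containing embeddings outperform R-only ones
        config = SMapConfig()
        rhos = {}
        for spec in enumerate_embeddings(include_lag0_R=False):
            block = build_block(series, spec, 0)
            _, rho = optimize_theta(block, np.arange(block.n_rows), config)
            rhos[spec.coordinates] = rho
        best_with_S = max(r for c, r in rhos.items() if any(v == "S" for v, _ in c))
        best_R_only = max(r for c, r in rhos.items() if all(v == "R" for v, _ in c))
        assert best_with_S > best_R_only

    def test_rho_matches_stored_pairs(self, small_series):
        result = best_edm_rho(small_series[2])
        assert result.rho == pytest.approx(
            rc.pearson_rho(result.observed, result.predicted), abs=1e-12
        )

    def test_candidate_coordinates_are_R_and_S_to_lag_2(self):
        assert set(CANDIDATE_COORDS) == {
            ("R", 0), ("R", 1), ("R", 2), ("S", 0), ("S", 1), ("S", 2),
        }
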