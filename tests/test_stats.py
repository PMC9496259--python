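import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dagvalid import (
    EstimationConfig,
    InsufficientDataError,
    bca_ci,
    fisher_z_ci,
    partial_correlation,
    rank_correlation_matrix,
    spearman_rho,
)
from dagvalid import test_conditional as run_conditional_test
from dagvalid import test_marginal as run_marginal_test
from dagvalid.stats import _bca_adjusted_alphas, _partial_correlation_recursive


def _bivariate(rng, n, rho):
    cov = [[1, rho], [rho, 1]]
    x, y = rng.multivariate_normal([0, 0], cov, size=n).T
    return x, y


class TestSpearman:
    def test_hand_computed_value(self):
        # d^2 = (1,1,1,1): rho = 1 - 6*4/(4*15) = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_perfect_monotone(self):
        x = np.arange(1.0, 11.0)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = _bivariate(rng, 30, 0.4)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, y**3) == pytest.approx(base)
        assert spearman_rho(2 * x + 7, y) == pytest.approx(base)

    def test_complete_case_removal(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 1, 3, 5, 4]
        assert spearman_rho(x, y) == spearman_rho([1, 2, 4, 5], [2, 1, 5, 4])

    @pytest.mark.parametrize("x, y", [([1, 1, 1, 1], [1, 2, 3, 4]), ([1, 2], [3, 4])])
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(InsufficientDataError):
            spearman_rho(x, y)


class TestBcaBootstrap:
    def test_zero_bias_zero_acceleration_is_percentile(self):
        lo, hi = _bca_adjusted_alphas(0.0, 0.0, 0.025)
        assert (lo, hi) == pytest.approx((0.025, 0.975), abs=1e-12)

    def test_same_seed_reproduces_different_seed_close(self, rng):
        x, y = _bivariate(rng, 60, 0.5)
        a = bca_ci(x, y, replicates=2000, seed=7)
        b = bca_ci(x, y, replicates=2000, seed=7)
        c = bca_ci(x, y, replicates=2000, seed=8)
        assert a == b
        assert abs(a[0] - c[0]) < 0.05 and abs(a[1] - c[1]) < 0.05

    def test_degenerate_resamples_flagged(self):
        x = np.arange(10.0)
        lo, hi, flags = bca_ci(x, 2 * x, replicates=200, seed=0)
        assert (lo, hi) == pytest.approx((1.0, 1.0))
        assert "degenerate" in flags

    def test_matches_scipy_bca_cross_check(self, rng):
        x, y = _bivariate(rng, 40, 0.6)
        lo, hi, flags = bca_ci(x, y, replicates=6000, seed=3)
        assert flags == ()

        def stat(xs, ys):
            return sps.spearmanr(xs, ys).statistic

        ref = sps.bootstrap(
            (x, y), stat, paired=True, vectorized=False, n_resamples=6000,
            confidence_level=0.95, method="BCa", rng=np.random.default_rng(3),
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.04)
        assert hi == pytest.approx(ref.high, abs=0.04)

    def test_interval_narrows_with_n(self, rng):
        widths = []
        for n in (20, 80, 320):
            ws = []
            for rep in range(5):
                x, y = _bivariate(rng, n, 0.4)
                lo, hi, _ = bca_ci(x, y, replicates=500, seed=rep)
                ws.append(hi - lo)
            widths.append(np.median(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_parameter_validation(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="replicates"):
            bca_ci(x, x[::-1], replicates=50)
        with pytest.raises(ValueError, match="level"):
            bca_ci(x, x[::-1], level=1.5)


class TestPartialCorrelation:
    def test_identity_matrix_gives_zero(self):
        corr = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        assert partial_correlation(corr, "a", "b", {"c", "d"}) == pytest.approx(0.0)

    def test_hand_computed_equicorrelated(self):
        corr = pd.DataFrame(
            [[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]],
            index=list("xyz"), columns=list("xyz"),
        )
        # (0.5 - 0.25) / (1 - 0.25) = 1/3
        assert partial_correlation(corr, "x", "y", {"z"}) == pytest.approx(1 / 3)

    def test_empty_conditioning_returns_marginal_entry(self):
        corr = pd.DataFrame(
            [[1, 0.37], [0.37, 1]], index=["x", "y"], columns=["x", "y"]
        )
        assert partial_correlation(corr, "x", "y") == 0.37

    @given(st.integers(0, 2**31 - 1), st.integers(3, 6))
    @settings(max_examples=50, deadline=None)
    def test_inversion_agrees_with_recursion(self, seed, p):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(p + 3, p))
        cov = a.T @ a + 0.1 * np.eye(p)
        sd = np.sqrt(np.diag(cov))
        names = [f"v{i}" for i in range(p)]
        corr = pd.DataFrame(cov / np.outer(sd, sd), index=names, columns=names)
        z = names[2:]
        direct = partial_correlation(corr, names[0], names[1], z)
        recursive = _partial_correlation_recursive(corr, names[0], names[1], z)
        assert direct == pytest.approx(recursive, abs=1e-10)

    def test_agrees_with_residual_regression_oracle(self, rng):
        """Partialling out Z equals correlating least-squares residuals."""
        n = 400
        z = rng.normal(size=(n, 2))
        x = z @ [0.8, -0.4] + rng.normal(size=n)
        y = z @ [0.3, 0.6] + 0.5 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        pearson = df.corr(method="pearson")
        got = partial_correlation(pearson, "x", "y", {"z1", "z2"})
        zmat = np.column_stack([np.ones(n), z])
        rx = x - zmat @ np.linalg.lstsq(zmat, x, rcond=None)[0]
        ry = y - zmat @ np.linalg.lstsq(zmat, y, rcond=None)[0]
        assert got == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-8)

    def test_singular_submatrix_rejected(self):
        corr = pd.DataFrame(np.ones((3, 3)), index=list("xyz"), columns=list("xyz"))
        with pytest.raises(InsufficientDataError):
            partial_correlation(corr, "x", "y", {"z"})


class TestFisherZ:
    def test_hand_computed_interval(self):
        lo, hi = fisher_z_ci(0.5, n=28, k=0, level=0.95)
        assert lo == pytest.approx(0.156, abs=2e-3)
        assert hi == pytest.approx(0.736, abs=2e-3)

    def test_symmetric_about_zero(self):
        lo, hi = fisher_z_ci(0.0, n=30)
        assert lo == pytest.approx(-hi)

    def test_width_decreases_in_n(self):
        widths = [np.subtract(*fisher_z_ci(0.4, n)[::-1]) for n in (10, 30, 100, 1000)]
        assert all(np.diff([abs(w) for w in widths]) < 0)

    def test_conditioning_cost_degrees_of_freedom(self):
        plain = fisher_z_ci(0.3, n=20, k=0)
        partial = fisher_z_ci(0.3, n=20, k=3)
        assert partial[1] - partial[0] > plain[1] - plain[0]

    def test_insufficient_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            fisher_z_ci(0.3, n=5, k=2)


class TestMatrixAndTests:
    def test_matrix_consistent_with_pairwise_calls(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        m = rank_correlation_matrix(df)
        assert np.allclose(np.diag(m), 1.0)
        for i, j in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert m.loc[i, j] == pytest.approx(spearman_rho(df[i], df[j]))
            assert m.loc[i, j] == m.loc[j, i]

    def test_duplicated_column_unit_correlation(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20)})
        df["b"] = df["a"]
        assert rank_correlation_matrix(df).loc["a", "b"] == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.raises(InsufficientDataError, match="constant"):
            rank_correlation_matrix(df)

    def test_marginal_estimate_records_complete_cases(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df.loc[:4, "x"] = np.nan
        est = run_marginal_test(df, ("x", "y"), EstimationConfig(replicates=200, seed=1))
        assert est.n_effective == 25
        assert est.method == "spearman_bootstrap"
        assert -1 <= est.ci_low <= est.ci_high <= 1

    def test_conditional_estimate_near_zero_on_faithful_data(self, bone_study_large):
        est = run_conditional_test(
            bone_study_large.data,
            ("formation", "resorption", {"unloading"}),
            EstimationConfig(replicates=200, seed=1),
        )
        assert abs(est.rho) < 0.05
        assert est.method == "partial_fisher_z"
        assert est.n_effective == len(bone_study_large.data)

    def test_conditional_minimum_sample_boundary(self, rng):
        # k + 3 complete cases is one short of the k + 4 minimum
        df = pd.DataFrame(rng.normal(size=(4, 3)), columns=["x", "y", "z"])
        with pytest.raises(InsufficientDataError):
            run_conditional_test(df, ("x", "y", {"z"}), EstimationConfig(replicates=200))

    def test_missing_column_raises(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(KeyError):
            run_marginal_test(df, ("x", "nope"), EstimationConfig(replicates=200))
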