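"""IQR scaling, OLS associations, BH control, two-pollutant models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from peilink.association import (
    bh_adjust,
    compute_iqr,
    fit_single_pollutant,
    fit_two_pollutant,
    pearson_screen,
    report,
    run_associations,
)
from peilink.covariates import ADJUSTMENT_COLUMNS


def brute_iqr(values):
    """Sorted linear-interpolation quantiles, written out by hand."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.75) - q(0.25)


def random_covariates(n, rng):
    race = rng.dirichlet([4, 4, 2, 1], size=n)
    return pd.DataFrame({
        "pct_female": rng.normal(50, 1, n),
        "pct_less_than_hs": rng.uniform(5, 35, n),
        "pct_unmarried": rng.uniform(20, 60, n),
        "race_hispanic": race[:, 0],
        "race_native_american": race[:, 2],
        "race_other": race[:, 3],
    })


class TestIQR:
    def test_one_to_five(self):
        assert compute_iqr([1, 2, 3, 4, 5]) == 2.0

    def test_constant_vector_zero(self):
        assert compute_iqr([7.0] * 9) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            v = rng.normal(size=rng.integers(2, 40)) * rng.lognormal()
            assert compute_iqr(v) == pytest.approx(brute_iqr(v), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_iqr([])


class TestSinglePollutant:
    def test_matches_normal_equations(self):
        """OLS effect and p-value agree with a hand normal-equations solve."""
        rng = np.random.default_rng(1)
        from scipy import stats as sps

        for _ in range(100):
            n = int(rng.integers(30, 80))
            x = rng.lognormal(size=n)
            covs = random_covariates(n, rng)
            y = rng.normal(9, 1, n)
            res = fit_single_pollutant(x, y, covs, chemical="test")
            X = np.column_stack([np.ones(n), x / brute_iqr(x)]
                                + [covs[c].to_numpy() for c in ADJUSTMENT_COLUMNS])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            dof = n - X.shape[1]
            sigma2 = resid @ resid / dof
            cov_b = sigma2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(cov_b[1, 1])
            assert res.effect == pytest.approx(beta[1], abs=1e-8)
            tcrit = sps.t.ppf(0.975, dof)
            assert res.ci_low == pytest.approx(beta[1] - tcrit * se, abs=1e-8)
            p = 2 * sps.t.sf(abs(beta[1] / se), dof)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_wald_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=60)
        y = 9 + 0.3 * x / compute_iqr(x) + rng.normal(0, 0.5, 60)
        res = fit_single_pollutant(x, y, chemical="m")
        assert res.effect == pytest.approx((res.ci_low + res.ci_high) / 2, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=50)
        covs = random_covariates(50, rng)
        y = rng.normal(9, 1, 50)
        a = fit_single_pollutant(x, y, covs)
        b = fit_single_pollutant(1000.0 * x, y, covs)
        assert a.effect == pytest.approx(b.effect, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_orthogonal_covariate_leaves_effect(self):
        rng = np.random.default_rng(4)
        n = 80
        x = rng.lognormal(size=n)
        y = 9 + 0.4 * x / compute_iqr(x) + rng.normal(0, 0.4, n)
        base = fit_single_pollutant(x, y)
        # residualize a random column against [1, x/iqr] to force orthogonality
        z = rng.normal(size=n)
        D = np.column_stack([np.ones(n), x / compute_iqr(x)])
        z = z - D @ np.linalg.lstsq(D, z, rcond=None)[0]
        import statsmodels.api as sm

        X = np.column_stack([D, z])
        fit = sm.OLS(y, X).fit()
        assert fit.params[1] == pytest.approx(base.effect, abs=1e-10)

    def test_type_one_error_rate(self):
        """Permuted exposure: CI covers zero at the nominal 95% rate.

        With B replicates the binomial SD of the coverage count is
        sqrt(B * 0.95 * 0.05); the assertion allows three SDs below nominal
        so a correct implementation fails with probability ~1e-3.
        """
        rng = np.random.default_rng(5)
        n = 108
        B = 400
        x = rng.lognormal(size=n)
        covs = random_covariates(n, rng)
        y = 9 + 0.5 * covs["pct_less_than_hs"].to_numpy() / 10 + rng.normal(0, 0.6, n)
        covered = 0
        for _ in range(B):
            xp = rng.permutation(x)
            res = fit_single_pollutant(xp, y, covs)
            covered += res.ci_low <= 0.0 <= res.ci_high
        floor = 0.95 * B - 3 * np.sqrt(B * 0.95 * 0.05)
        assert covered >= floor

    def test_iqr_zero_rejected(self):
        with pytest.raises(ValueError, match="IQR"):
            fit_single_pollutant(np.ones(30), np.random.default_rng(0).normal(9, 1, 30))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(6)
        n = 40
        covs = random_covariates(n, rng)
        covs["race_other"] = covs["race_hispanic"]  # exact duplicate
        covs["race_native_american"] = 0.0
        x = covs["race_hispanic"].to_numpy()  # also collinear with exposure
        with pytest.raises(ValueError, match="collinear"):
            fit_single_pollutant(x, rng.normal(9, 1, n), covs)

    def test_too_few_areas_rejected(self):
        rng = np.random.default_rng(7)
        covs = random_covariates(6, rng)
        with pytest.raises(ValueError, match="areas"):
            fit_single_pollutant(rng.lognormal(size=6), rng.normal(9, 1, 6), covs)


class TestBH:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(3, 25))
            ours = bh_adjust(p, fdr=0.05)
            ref_sig, ref_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(ours["significant"].to_numpy(), ref_sig)
            np.testing.assert_allclose(ours["p_bh"], ref_adj, atol=1e-12)

    def test_all_ones_none_significant(self):
        out = bh_adjust(np.ones(10))
        assert not out["significant"].any()

    def test_single_test_reduces_to_threshold(self):
        assert bool(bh_adjust([0.04], fdr=0.05)["significant"][0])
        assert not bool(bh_adjust([0.06], fdr=0.05)["significant"][0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
           st.floats(0.005, 0.2), st.floats(0.005, 0.2))
    def test_monotone_in_fdr(self, ps, f1, f2):
        """Lowering the FDR never adds discoveries."""
        lo, hi = sorted((f1, f2))
        s_lo = bh_adjust(ps, fdr=lo)["significant"]
        s_hi = bh_adjust(ps, fdr=hi)["significant"]
        assert (s_hi | ~s_lo).all()  # discoveries at lo are a subset of hi


class TestPearsonScreen:
    def test_identical_columns_excluded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        pairs = {(a, b) for a, b, _ in pearson_screen(df)}
        assert ("a", "b") not in pairs

    def test_independent_columns_admitted(self):
        rng = np.random.default_rng(10)
        admitted = 0
        for _ in range(200):
            df = pd.DataFrame(rng.normal(size=(108, 2)), columns=["a", "b"])
            admitted += len(pearson_screen(df)) == 1
        assert admitted >= 198  # null |r| < 0.5 at n=108 is near-certain

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x, y = rng.normal(size=(2, 30))
            df = pd.DataFrame({"x": x, "y": y})
            pairs = pearson_screen(df, threshold=2.0)
            r = pairs[0][2]
            manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert r == pytest.approx(manual, abs=1e-10)

    def test_strong_negative_correlation_excluded(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": -x + rng.normal(0, 0.1, 60)})
        assert pearson_screen(df) == []


class TestTwoPollutant:
    def test_orthogonal_copollutant_preserves_effect(self):
        rng = np.random.default_rng(13)
        n = 90
        x1 = rng.lognormal(size=n)
        # co-pollutant residualized against [1, x1] so designs are orthogonal
        z = rng.normal(size=n)
        D = np.column_stack([np.ones(n), x1 / compute_iqr(x1)])
        z = z - D @ np.linalg.lstsq(D, z, rcond=None)[0]
        y = 9 + 0.4 * x1 / compute_iqr(x1) + rng.normal(0, 0.5, n)
        single = fit_single_pollutant(x1, y)
        double = fit_two_pollutant(x1, z - z.min() + 0.1, y)
        assert double.effect == pytest.approx(single.effect, abs=1e-10)

    def test_noise_copollutant_widens_ci_mildly(self):
        rng = np.random.default_rng(14)
        n = 108
        x1 = rng.lognormal(size=n)
        noise = rng.lognormal(size=n)
        y = 9 + 0.4 * x1 / compute_iqr(x1) + rng.normal(0, 0.5, n)
        single = fit_single_pollutant(x1, y)
        double = fit_two_pollutant(x1, noise, y)
        w1 = single.ci_high - single.ci_low
        w2 = double.ci_high - double.ci_low
        assert w2 < 1.10 * w1

    def test_joint_noiseless_recovery(self):
        rng = np.random.default_rng(15)
        n = 60
        x1 = rng.lognormal(size=n)
        x2 = rng.lognormal(size=n)
        y = 9 + 0.43 * x1 / compute_iqr(x1) + 0.63 * x2 / compute_iqr(x2)
        res = fit_two_pollutant(x1, x2, y, primary_name="hg", co_name="cr")
        assert res.effect == pytest.approx(0.43, abs=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            fit_two_pollutant(np.ones(30), np.arange(30.0), np.arange(30.0))


class TestReport:
    def _results(self):
        rng = np.random.default_rng(16)
        n = 60
        y = rng.normal(9, 1, n)
        exp = pd.DataFrame({c: rng.lognormal(size=n) for c in
                            ["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"]})
        return run_associations(exp, pd.DataFrame({"lbw_rate": y}))

    def test_sorted_by_p_and_complete(self, tmp_path):
        results = self._results()
        df = report(results, csv_path=tmp_path / "assoc.csv")
        assert len(df) == 10
        assert df["p"].is_monotonic_increasing

    def test_csv_round_trip_byte_identical(self, tmp_path):
        results = self._results()
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        report(results, csv_path=p1)
        from peilink.io import read_table

        parsed = read_table(p1, ("chemical", "effect_pct_per_iqr", "p"))
        parsed.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_significance_matches_bh(self):
        results = self._results()
        flags = bh_adjust([r.p_value for r in results])["significant"]
        assert [r.significant_after_bh for r in results] == flags.tolist()
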