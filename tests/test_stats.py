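import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pigdom.stats import (
    BEHAVIOR_COVARIATES,
    index_correlations,
    multiple_regression,
    partial_correlation,
    sex_contrast,
)


class TestIndexCorrelations:
    def test_identical_columns_give_rho_one(self):
        elo = np.arange(20.0)
        table = pd.DataFrame({"elo": elo, "elo2": elo})
        out = index_correlations(table)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_perfect_hierarchy_gives_unit_magnitude(self):
        # rank 1 = most dominant, so rank correlates -1 with ratings
        table = pd.DataFrame({
            "isi_rank": [1, 2, 3, 4, 5],
            "elo": [1200, 1100, 1000, 900, 800],
            "glicko": [2500, 2400, 2300, 2200, 2100],
        })
        out = index_correlations(table)
        assert np.allclose(out["abs_rho"], 1.0)
        signed = dict(zip(zip(out["index_a"], out["index_b"]), out["rho"]))
        assert signed[("isi_rank", "elo")] == pytest.approx(-1.0)
        assert signed[("elo", "glicko")] == pytest.approx(1.0)

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        out = index_correlations(table)
        rho, p = sps.spearmanr(table["a"], table["b"])
        assert out.loc[0, "rho"] == pytest.approx(rho)
        assert out.loc[0, "p_value"] == pytest.approx(p)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = partial_correlation(x, y)
        rr, pp = sps.pearsonr(x, y)
        assert r == pytest.approx(rr, abs=1e-12)
        assert p == pytest.approx(pp, abs=1e-12)

    def test_known_partial_correlation_recovered(self):
        # X,Y,Z trivariate normal engineered so that partial corr(X,Y|Z)=0.5
        rng = np.random.default_rng(2)
        n = 10000
        z = rng.normal(size=n)
        e1, e2 = rng.normal(size=n), rng.normal(size=n)
        x = z + e1
        y = z + (e1 + np.sqrt(3.0) * e2) / 2.0  # corr(e1, e2')=0.5
        r, p = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert r == pytest.approx(0.5, abs=0.03)
        assert p < 1e-6

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("xyzw"))
        r, p = partial_correlation(df["x"], df["y"], df[["z", "w"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z", "w"])
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-9)

    def test_covariate_identical_to_y_reported_missing(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        r, p = partial_correlation(x, z, pd.DataFrame({"z": z}))
        assert np.isnan(r) and np.isnan(p)

    def test_singular_covariates_rejected_by_name(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        Z = pd.DataFrame({"z1": z, "z2": 2 * z})
        with pytest.raises(ValueError, match="z1.*z2"):
            partial_correlation(rng.normal(size=30), rng.normal(size=30), Z)


class TestMultipleRegression:
    @staticmethod
    def _summary(n=40, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=BEHAVIOR_COVARIATES
        )
        coefs = np.array([2.0, -1.0, 0.5, 0.0, 3.0, -2.0])
        df["y"] = 1.5 + df[BEHAVIOR_COVARIATES] @ coefs + noise * rng.normal(size=n)
        return df, coefs

    def test_noiseless_response_recovered_exactly(self):
        df, coefs = self._summary()
        fit = multiple_regression(df, "y")
        assert fit.loc[BEHAVIOR_COVARIATES, "B"].to_numpy() == pytest.approx(
            coefs, abs=1e-8
        )
        assert fit.loc["const", "B"] == pytest.approx(1.5, abs=1e-8)
        assert (fit.loc[BEHAVIOR_COVARIATES, "SE"] < 1e-7).all()

    def test_matches_normal_equations(self):
        df, _ = self._summary(noise=1.0, seed=6)
        fit = multiple_regression(df, "y")
        X = np.column_stack([np.ones(len(df)), df[BEHAVIOR_COVARIATES]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
        resid = df["y"] - X @ beta
        sigma2 = resid @ resid / (len(df) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert fit["B"].to_numpy() == pytest.approx(beta, abs=1e-8)
        assert fit["SE"].to_numpy() == pytest.approx(se, abs=1e-8)
        assert fit["t"].to_numpy() == pytest.approx(beta / se, abs=1e-6)

    def test_residuals_orthogonal_to_design(self):
        df, _ = self._summary(noise=2.0, seed=7)
        fit = multiple_regression(df, "y")
        X = np.column_stack([np.ones(len(df)), df[BEHAVIOR_COVARIATES]])
        resid = df["y"] - X @ fit["B"].to_numpy()
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_pure_noise_p_values_roughly_uniform(self):
        ps = []
        for seed in range(40):
            df, _ = self._summary(n=30, seed=100 + seed)
            rng = np.random.default_rng(seed)
            df["y"] = rng.normal(size=30)  # response unrelated to covariates
            fit = multiple_regression(df, "y")
            ps.extend(fit.loc[BEHAVIOR_COVARIATES, "p"])
        # uniform on [0,1]: mean 0.5, ~5% below 0.05
        assert np.mean(ps) == pytest.approx(0.5, abs=0.07)
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_too_small_n_rejected(self):
        df, _ = self._summary(n=7)
        with pytest.raises(ValueError, match="too small"):
            multiple_regression(df, "y")


class TestSexContrast:
    @staticmethod
    def _table(n=100, shift=15.0, sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.5, "female", "barrow")
        base = 24.0 + sd * rng.normal(size=n)
        return pd.DataFrame({
            "stability_h": base + shift * (sex == "barrow"),
            "sex": sex,
            "parity": rng.integers(1, 6, n),
            "sire_id": rng.choice(["S1", "S2", "S3"], n),
            "initial_bw_kg": rng.normal(9, 1, n),
        })

    def test_identical_groups_give_p_near_one(self):
        t = self._table(shift=0.0, sd=0.0)
        t["stability_h"] = 24.0
        res = sex_contrast(t, with_covariates=False)
        assert res.diff == pytest.approx(0.0, abs=1e-9)

    def test_simulated_shift_recovered_within_two_se(self):
        res = sex_contrast(self._table(shift=15.0))
        assert abs(res.diff - 15.0) < 2 * res.se_diff
        assert res.p_value < 1e-6
        assert res.mean_barrow > res.mean_female

    def test_no_covariates_equals_two_sample_t(self):
        t = self._table(n=60, shift=8.0, seed=3)
        res = sex_contrast(t, with_covariates=False)
        f = t.loc[t["sex"] == "female", "stability_h"]
        b = t.loc[t["sex"] == "barrow", "stability_h"]
        tt = sps.ttest_ind(b, f, equal_var=True)
        assert res.p_value == pytest.approx(tt.pvalue, abs=1e-12)
        assert res.diff == pytest.approx(b.mean() - f.mean(), abs=1e-9)
        assert res.mean_female == pytest.approx(f.mean(), abs=1e-9)

    def test_single_sex_rejected(self):
        t = self._table()
        t["sex"] = "female"
        with pytest.raises(ValueError, match="both sexes"):
            sex_contrast(t)
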