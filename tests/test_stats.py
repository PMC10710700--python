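"""Statistical layer: scaling, screening, thinning, GLMM, averaging, R2."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from soarflight.stats import (
    ModelSpec,
    chi_square_counts,
    collinearity_screen,
    compare_metrics,
    dredge_average,
    fit_glmm,
    fit_model,
    kfold_accuracy,
    nakagawa_r2,
    orthogonal_poly,
    standardize,
    thin_30s,
)
from soarflight.synthetic import SimConfig, simulate_soaring_dataset


class TestStandardize:
    def test_basic_scaling(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scaling = standardize(df, ["x"])
        assert out["x"].tolist() == [-1.0, 0.0, 1.0]
        assert scaling.loc["x", "mean"] == 2.0 and scaling.loc["x", "sd"] == 1.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(3, 2, 100)})
        once, _ = standardize(df, ["x"])
        twice, _ = standardize(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)


class TestCollinearityScreen:
    def test_cloud_correlated_with_delta_T_dropped(self):
        rng = np.random.default_rng(0)
        dT = rng.normal(0, 1, 2000)
        df = pd.DataFrame(
            {
                "tailwind": rng.normal(0, 1, 2000),
                "delta_T": dT,
                "cloud": 0.9 * dT + rng.normal(0, 0.55, 2000),
            }
        )
        r = df["delta_T"].corr(df["cloud"])
        assert r == pytest.approx(0.83, abs=0.03)  # the regime of interest
        retained, report = collinearity_screen(df, ["tailwind", "delta_T", "cloud"])
        assert retained == ["tailwind", "delta_T"]
        assert report["dropped"].tolist() == ["cloud"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (10_000, 4)), columns=list("abcd"))
        retained, report = collinearity_screen(df, list("abcd"))
        assert retained == list("abcd") and report.empty

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 500)
        df = pd.DataFrame({"tailwind": x, "copy": x})
        retained, _ = collinearity_screen(df, ["tailwind", "copy"])
        assert retained == ["tailwind"]


class TestThinning:
    def make_fixes(self, n, tailwind=None):
        return pd.DataFrame(
            {
                "bird_id": "A",
                "burst_id": 0,
                "timestamp": pd.date_range("2020-10-01 06:00:00", periods=n, freq="s"),
                "behavior": ["soaring"] * n,
                "tailwind": np.ones(n) if tailwind is None else tailwind,
            }
        )

    def test_150_fixes_five_blocks(self):
        assert len(thin_30s(self.make_fixes(150))) == 5

    def test_incomplete_block_dropped(self):
        assert len(thin_30s(self.make_fixes(29))) == 0
        assert len(thin_30s(self.make_fixes(59))) == 1

    def test_constant_covariates_unchanged(self):
        out = thin_30s(self.make_fixes(90))
        assert np.allclose(out["tailwind"], 1.0)

    def test_thinning_reduces_residual_autocorrelation(self):
        # 1 Hz response driven by covariate + unmodeled smooth AR(1) process
        rng = np.random.default_rng(3)
        frames = []
        for burst in range(40):
            n = 300
            x = rng.normal(0, 1)
            latent = np.empty(n)
            latent[0] = rng.normal(0, 1)
            for i in range(1, n):
                latent[i] = 0.98 * latent[i - 1] + rng.normal(0, 0.2)
            p = 1 / (1 + np.exp(-(x + latent)))
            f = pd.DataFrame(
                {
                    "bird_id": "A",
                    "burst_id": burst,
                    "timestamp": pd.date_range("2020-10-01", periods=n, freq="s"),
                    "behavior": (rng.random(n) < p).astype(int),
                    "tailwind": np.full(n, x) + rng.normal(0, 0.05, n),
                }
            )
            frames.append(f)
        hz1 = pd.concat(frames, ignore_index=True)
        thinned = thin_30s(hz1)
        thinned["behavior"] = thinned["behavior"].astype(int)

        def lag1_resid_acf(df):
            spec = ModelSpec("behavior", ["tailwind"], group=None)
            res = fit_model(spec, df)
            _, X = spec.design(df)
            p = res.predict_marginal(X)
            pearson = (df["behavior"].to_numpy() - p) / np.sqrt(p * (1 - p))
            acfs = []
            for _, g in df.groupby("burst_id"):
                r = pearson[g.index]
                if len(r) > 2:
                    acfs.append(np.corrcoef(r[:-1], r[1:])[0, 1])
            return np.nanmean(acfs)

        assert lag1_resid_acf(thinned) < lag1_resid_acf(hz1)


class TestGLMM:
    def test_zero_re_data_matches_plain_logistic(self):
        cfg = SimConfig(seed=6, re_sd=0.0)
        df = simulate_soaring_dataset(cfg, 1500)
        spec = ModelSpec("soaring", ["tailwind", "sidewind", "delta_T", "tailwind:delta_T"])
        mixed = fit_model(spec, df)
        glm = fit_model(ModelSpec("soaring", spec.terms, group=None), df)
        assert np.allclose(mixed.params, glm.params, atol=0.01)

    def test_needs_two_groups(self):
        df = simulate_soaring_dataset(SimConfig(seed=1), 100, n_birds=1)
        with pytest.raises(ValueError, match="2 groups"):
            fit_model(ModelSpec("soaring", ["tailwind"]), df)

    def test_matches_lme4_reference(self, tmp_path):
        """Same fixed effects and SEs as the standard R mixed-model fitter."""
        cfg = SimConfig(seed=12)
        df = simulate_soaring_dataset(cfg, 800, n_birds=8)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fit.csv"
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(soaring ~ tailwind + delta_T + (1 | bird_id),
                       family = binomial, data = d,
                       control = glmerControl(check.conv.singular = "ignore"), nAGQ = 25)
            co <- summary(m)$coefficients
            write.csv(data.frame(est = co[, 1], se = co[, 2]), "{out}")
            """
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(out, index_col=0)
        res = fit_model(ModelSpec("soaring", ["tailwind", "delta_T"]), df)
        assert np.allclose(res.params.to_numpy(), ref["est"].to_numpy(), atol=0.02)
        assert np.allclose(res.bse.to_numpy(), ref["se"].to_numpy(), rtol=0.1)

    def test_orthogonal_poly_matches_r_convention(self):
        x = np.arange(10.0)
        Z = orthogonal_poly(x, 2)
        assert np.allclose(Z.T @ Z, np.eye(2), atol=1e-10)
        assert abs(Z.sum(axis=0)).max() < 1e-10
        assert np.corrcoef(Z[:, 0], x)[0, 1] > 0.999


class TestDredgeAverage:
    def test_single_term_averaging_is_that_model(self):
        cfg = SimConfig(seed=8, soaring_logit=(0, 2.0, 0, 0, 0))
        df = simulate_soaring_dataset(cfg, 1200)
        spec = ModelSpec("soaring", ["tailwind"])
        result = dredge_average(spec, df)
        single = fit_model(spec, df, subset=("tailwind",))
        if result.n_models_averaged == 1:
            assert result.table.loc["tailwind", "estimate"] == pytest.approx(
                single.params["tailwind"], abs=1e-9
            )
        assert result.model_table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_strong_effects_best_model_is_full(self):
        cfg = SimConfig(seed=9)
        df = simulate_soaring_dataset(cfg, 2000)
        spec = ModelSpec("soaring", ["tailwind", "sidewind", "delta_T", "tailwind:delta_T"])
        result = dredge_average(spec, df)
        assert set(result.best_terms) == set(spec.terms)

    def test_marginality_respected_in_subsets(self):
        cfg = SimConfig(seed=10)
        df = simulate_soaring_dataset(cfg, 300)
        spec = ModelSpec("soaring", ["tailwind", "delta_T", "tailwind:delta_T"])
        result = dredge_average(spec, df)
        for terms in result.model_table["terms"]:
            if "tailwind:delta_T" in terms:
                assert "tailwind" in terms and "delta_T" in terms

    def test_poly_terms_kept_as_unit(self):
        cfg = SimConfig(seed=10)
        df = simulate_soaring_dataset(cfg, 400)
        spec = ModelSpec("soaring", ["poly(tailwind,2)", "delta_T"])
        result = dredge_average(spec, df)
        assert {"(Intercept)", "poly(tailwind,2)1", "poly(tailwind,2)2", "delta_T"} == set(
            result.table.index
        )
        assert len(result.model_table) == 4  # {}, {poly}, {dT}, {poly, dT}


class TestModelQuality:
    def test_nakagawa_null_model_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "bird_id": np.repeat([f"b{i}" for i in range(8)], 100),
                "x": rng.normal(0, 1, 800),
                "y": rng.integers(0, 2, 800),
            }
        )
        res = fit_model(ModelSpec("y", ["x"]), df)
        r2m, r2c = nakagawa_r2(res, df[["x"]])
        assert r2m == pytest.approx(0.0, abs=0.01)
        assert r2c == pytest.approx(r2m, abs=0.05)

    def test_r2m_increases_with_effect_size(self):
        vals = []
        for beta in (0.5, 1.5, 3.0):
            cfg = SimConfig(seed=4, soaring_logit=(0, beta, 0, 0, 0), re_sd=0.3)
            df = simulate_soaring_dataset(cfg, 1500)
            res = fit_model(ModelSpec("soaring", ["tailwind"]), df)
            vals.append(nakagawa_r2(res, df[["tailwind"]])[0])
        assert vals[0] < vals[1] < vals[2]

    def test_kfold_separable_data_near_one(self):
        cfg = SimConfig(seed=5, soaring_logit=(0, 12, 0, 0, 0), re_sd=0.0)
        df = simulate_soaring_dataset(cfg, 1000)
        acc = kfold_accuracy(ModelSpec("soaring", ["tailwind"]), df, k=5, seed=0)
        assert acc > 0.95

    def test_kfold_noise_data_near_chance(self):
        cfg = SimConfig(seed=6, soaring_logit=(0, 0, 0, 0, 0), re_sd=0.0)
        df = simulate_soaring_dataset(cfg, 2000)
        acc = kfold_accuracy(ModelSpec("soaring", ["tailwind"]), df, k=10, seed=0)
        assert acc == pytest.approx(0.5, abs=0.05)


class TestGroupComparisons:
    def test_identical_groups_u_statistic_central(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 80)
        rep = compare_metrics(a, a.copy())
        assert rep["mannwhitney_U"] == pytest.approx(80 * 80 / 2, rel=0.01)
        assert rep["mannwhitney_p"] > 0.9

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(30):
            a = rng.normal(0, 1, 100)
            b = rng.normal(2.0, 1, 100)
            hits += compare_metrics(a, b)["mannwhitney_p"] < 0.05
        assert hits == 30

    def test_balanced_contingency_chi2_zero(self):
        rep = chi_square_counts([[50, 50], [50, 50]])
        assert rep["chi2"] == 0.0
        assert rep["p"] == 1.0
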