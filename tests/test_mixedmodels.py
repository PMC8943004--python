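"""Mixed models: frame assembly, GLMM fitting, reductions, LRT, contrasts."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from nocmig import mixedmodels as mm


def simulate_glmm(
    rng, n_ind=6, n_per=300, dusk_eff=0.7, night_eff=0.0, dawn_eff=0.0, sigma=0.5,
    prev_eff=0.5,
):
    rows = []
    for i in range(n_ind):
        u = rng.normal(0, sigma)
        period = rng.choice(["dusk", "night", "dawn"], n_per)
        cat = rng.choice(["hospitable", "barrier"], n_per)
        prev = rng.binomial(1, 0.3, n_per).astype(float)
        eta = -1.0 + u + prev_eff * prev
        eta = eta + 1.0 * (period == "night") - 0.5 * (period == "dawn")
        eta = eta + np.where(
            cat == "barrier",
            np.select(
                [period == "dusk", period == "night", period == "dawn"],
                [dusk_eff, night_eff, dawn_eff],
            ),
            0.0,
        )
        y = rng.binomial(1, special.expit(eta)).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": f"id{i}",
                    "outcome": y,
                    "biome_category": cat,
                    "period": period,
                    "prev_state": prev,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestBuildModelFrame:
    def _records(self):
        t = pd.date_range("2018-09-01 20:00", periods=6, freq="5min")
        return pd.DataFrame(
            {
                "individual_id": "a",
                "timestamp": t,
                "migrating": [0, 1, 1, 0, 0, 1],
                "period": ["dusk"] * 3 + ["night"] * 2 + ["day"],
                "biome_category": "barrier",
                "date": pd.Timestamp("2018-09-01").date(),
            }
        )

    def test_lagged_outcome(self):
        frame = mm.build_model_frame(self._records())
        # row following a migrating interval has prev_state 1
        assert frame["prev_state"].iloc[2] == 1.0

    def test_first_interval_dropped_and_day_excluded(self):
        frame = mm.build_model_frame(self._records())
        assert len(frame) == 4  # 6 - first row - day row
        assert "day" not in set(frame["period"])

    def test_stopover_days_excluded(self):
        rec = self._records()
        frame = mm.build_model_frame(
            rec, stopover_dates={"a": {pd.Timestamp("2018-09-01").date()}}
        )
        assert len(frame) == 0

    def test_matches_hand_built_frame(self):
        frame = mm.build_model_frame(self._records())
        expect_outcome = [1.0, 1.0, 0.0, 0.0]
        expect_prev = [0.0, 1.0, 1.0, 0.0]
        assert list(frame["outcome"]) == expect_outcome
        assert list(frame["prev_state"]) == expect_prev

    def test_missing_columns_reported(self):
        with pytest.raises(KeyError, match="biome_category"):
            mm.build_model_frame(self._records().drop(columns=["biome_category"]))


class TestBinomialGLMM:
    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(10)
        frame = simulate_glmm(rng, n_ind=10, n_per=600)
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        assert res.converged
        truth = {
            "category[T.barrier]": 0.7,
            "period[T.night]": 1.0,
            "period[T.dawn]": -0.5,
            "prev_state": 0.5,
            "category[T.barrier]:period[T.night]": -0.7,
            "category[T.barrier]:period[T.dawn]": -0.7,
        }
        for term, b in truth.items():
            assert abs(res.params[term] - b) < 3 * res.bse[term]

    def test_all_zero_outcome_is_separation_error(self):
        frame = simulate_glmm(np.random.default_rng(1), n_ind=3, n_per=50)
        frame["outcome"] = 0.0
        with pytest.raises(ValueError, match="separation"):
            mm.BinomialRandomInterceptModel.from_frame(frame).fit()

    def test_constant_cell_named_in_error(self):
        frame = simulate_glmm(np.random.default_rng(2), n_ind=3, n_per=200)
        cell = (frame["biome_category"] == "barrier") & (frame["period"] == "dusk")
        frame.loc[cell, "outcome"] = 1.0
        with pytest.raises(ValueError, match="barrier.*dusk"):
            mm.BinomialRandomInterceptModel.from_frame(frame)

    def test_variance_pinned_matches_plain_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        frame = simulate_glmm(rng, n_ind=5, n_per=400, sigma=0.0)
        model = mm.BinomialRandomInterceptModel.from_frame(frame)
        res = model.fit(fix_variance=0.0)
        glm = sm.GLM(model.y, model.X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-4)
        assert res.group_var == 0.0

    def test_zero_variance_data_estimates_near_zero_variance(self):
        rng = np.random.default_rng(4)
        frame = simulate_glmm(rng, n_ind=8, n_per=500, sigma=0.0)
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        assert res.group_var < 0.05

    def test_relabelling_individuals_changes_nothing(self):
        rng = np.random.default_rng(6)
        frame = simulate_glmm(rng, n_ind=5, n_per=300)
        a = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        relab = frame.copy()
        relab["individual_id"] = relab["individual_id"].map(
            {f"id{i}": f"zz{9 - i}" for i in range(5)}
        )
        b = mm.BinomialRandomInterceptModel.from_frame(relab).fit()
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_glmmtmb_reference(self, tmp_path):
        rng = np.random.default_rng(42)
        frame = simulate_glmm(rng, n_ind=6, n_per=300)
        frame.to_csv(tmp_path / "fixture.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(glmmTMB))
            d <- read.csv(file.path(commandArgs(TRUE)[1], "fixture.csv"))
            d$biome_category <- factor(d$biome_category, c("hospitable", "barrier"))
            d$period <- factor(d$period, c("dusk", "night", "dawn"))
            m <- glmmTMB(outcome ~ biome_category * period + prev_state +
                         (1 | individual_id), family = binomial, data = d)
            co <- summary(m)$coefficients$cond
            write.csv(data.frame(term = rownames(co), est = co[, 1], se = co[, 2]),
                      file.path(commandArgs(TRUE)[1], "ref.csv"), row.names = FALSE)
            cat(logLik(m), "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        ref = pd.read_csv(tmp_path / "ref.csv")
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        r_llf = float(out.stdout.strip().split()[-1])
        assert res.llf == pytest.approx(r_llf, abs=0.05)
        mapping = {
            "(Intercept)": "Intercept",
            "biome_categorybarrier": "category[T.barrier]",
            "periodnight": "period[T.night]",
            "perioddawn": "period[T.dawn]",
            "prev_state": "prev_state",
            "biome_categorybarrier:periodnight": "category[T.barrier]:period[T.night]",
            "biome_categorybarrier:perioddawn": "category[T.barrier]:period[T.dawn]",
        }
        for _, row in ref.iterrows():
            term = mapping[row["term"]]
            assert res.params[term] == pytest.approx(row["est"], abs=0.02)
            assert res.bse[term] == pytest.approx(row["se"], abs=0.02)


class TestGaussianMixed:
    def _frame(self, rng, sigma_u=30.0, n_ind=8, n_per=60, effect=500.0):
        rows = []
        for i in range(n_ind):
            u = rng.normal(0, sigma_u)
            cat = rng.choice(["hospitable", "barrier"], n_per)
            y = 800.0 + u + effect * (cat == "barrier") + rng.normal(0, 150, n_per)
            rows.append(
                pd.DataFrame(
                    {"individual_id": f"id{i}", "outcome": y, "biome_category": cat,
                     "period": "night"}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_effect_recovery(self):
        rng = np.random.default_rng(7)
        frame = self._frame(rng)
        res = mm.GaussianMixedModel.from_frame(frame).fit()
        assert abs(res.params["category[T.barrier]"] - 500.0) < 3 * res.bse["category[T.barrier]"]

    def test_variance_pinned_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        frame = self._frame(rng, sigma_u=0.0)
        model = mm.GaussianMixedModel.from_frame(frame)
        res = model.fit(fix_variance=0.0)
        ols = sm.OLS(model.y, model.X).fit()
        assert np.allclose(res.params.to_numpy(), ols.params, atol=1e-6)

    def test_single_individual_falls_back_to_ols(self):
        rng = np.random.default_rng(9)
        frame = self._frame(rng, n_ind=1)
        with pytest.warns(UserWarning, match="single individual"):
            res = mm.GaussianMixedModel.from_frame(frame).fit()
        assert res.n_groups == 1 and res.converged


class TestZeroInflated:
    def _frame(self, rng, zero_frac=0.3, n=600):
        cat = rng.choice(["hospitable", "barrier"], n)
        y = 600.0 + 500.0 * (cat == "barrier") + rng.normal(0, 100, n)
        zero = rng.random(n) < zero_frac
        y = np.where(zero, 0.0, np.maximum(y, 1.0))
        return pd.DataFrame(
            {
                "individual_id": rng.choice([f"id{i}" for i in range(5)], n),
                "outcome": y,
                "biome_category": cat,
                "period": "night",
            }
        )

    def test_inflation_probability_recovered(self):
        rng = np.random.default_rng(11)
        res = mm.ZeroInflatedMixedModel.from_frame(self._frame(rng)).fit()
        pi = special.expit(res.params["zero_inflation[logit]"])
        assert abs(pi - 0.30) < 0.05

    def test_no_zeros_reduces_with_warning(self):
        rng = np.random.default_rng(12)
        frame = self._frame(rng, zero_frac=0.0)
        with pytest.warns(UserWarning, match="no zeros"):
            res = mm.ZeroInflatedMixedModel.from_frame(frame).fit()
        assert "zero_inflation[logit]" not in res.params.index

    def test_loglik_beats_uninflated_on_inflated_data(self):
        rng = np.random.default_rng(13)
        frame = self._frame(rng)
        zi = mm.ZeroInflatedMixedModel.from_frame(frame).fit()
        plain = mm.GaussianMixedModel.from_frame(frame).fit()
        assert zi.llf > plain.llf

    def test_negative_outcome_rejected(self):
        frame = pd.DataFrame(
            {"individual_id": ["a", "a"], "outcome": [-1.0, 2.0],
             "biome_category": ["barrier", "hospitable"], "period": ["night", "night"]}
        )
        with pytest.raises(ValueError, match="nonnegative"):
            mm.ZeroInflatedMixedModel.from_frame(frame)


class TestLikelihoodRatio:
    def test_identical_models(self):
        rng = np.random.default_rng(14)
        frame = simulate_glmm(rng, n_ind=4, n_per=100)
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        chi2, df, p = mm.likelihood_ratio_test(res, res)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi2_equals_twice_delta_ll(self):
        rng = np.random.default_rng(15)
        frame = simulate_glmm(rng, n_ind=5, n_per=200)
        full = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        reduced = mm.BinomialRandomInterceptModel.from_frame(frame, interaction=False).fit()
        chi2, df, p = mm.likelihood_ratio_test(full, reduced)
        assert chi2 == pytest.approx(2 * (full.llf - reduced.llf))
        assert df == 2

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(16)
        frame = simulate_glmm(rng, n_ind=4, n_per=100)
        full = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        reduced = mm.BinomialRandomInterceptModel.from_frame(frame, interaction=False).fit()
        with pytest.raises(ValueError, match="nested"):
            mm.likelihood_ratio_test(reduced, full)

    def test_type_I_error_rate_under_null(self):
        # no interaction effect: the LRT on the interaction rejects at ~alpha
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            frame = simulate_glmm(
                rng, n_ind=4, n_per=60, dusk_eff=0.4, night_eff=0.4, dawn_eff=0.4,
                sigma=0.3,
            )
            try:
                full = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
                reduced = mm.BinomialRandomInterceptModel.from_frame(
                    frame, interaction=False
                ).fit()
            except ValueError:  # occasional separation at this small size
                continue
            _, _, p = mm.likelihood_ratio_test(full, reduced)
            if p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.08


class TestTukeyContrasts:
    def test_single_contrast_unadjusted(self):
        rng = np.random.default_rng(18)
        frame = simulate_glmm(rng, n_ind=5, n_per=300)
        frame = frame[frame["period"] == "dusk"]
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        cons = mm.tukey_contrasts(res, periods=("dusk",))
        assert len(cons) == 1
        t = cons[0]
        p_raw = 2 * stats.t.sf(abs(t.t_ratio), t.df)
        assert t.p_value == pytest.approx(p_raw, rel=1e-6)

    def test_t_ratio_consistency_and_adjustment_bounds(self):
        rng = np.random.default_rng(19)
        frame = simulate_glmm(rng, n_ind=6, n_per=400)
        res = mm.BinomialRandomInterceptModel.from_frame(frame).fit()
        cons = mm.tukey_contrasts(res)
        assert [c.label for c in cons] == ["dusk", "night", "dawn"]
        for c in cons:
            assert c.t_ratio == pytest.approx(c.estimate / c.se)
            p_raw = 2 * stats.t.sf(abs(c.t_ratio), c.df)
            assert c.p_value >= p_raw - 1e-9
            assert c.p_value <= min(1.0, 3 * p_raw + 0.02)

    def test_unconverged_fit_rejected(self):
        res = mm.MixedModelResults(
            params=pd.Series({"category[T.barrier]": 1.0}),
            bse=pd.Series({"category[T.barrier]": 0.5}),
            cov_params=pd.DataFrame([[0.25]], index=["category[T.barrier]"],
                                    columns=["category[T.barrier]"]),
            group_var=0.1, llf=-10.0, n_obs=100, n_groups=5, n_params=2,
            converged=False,
        )
        with pytest.raises(ValueError, match="unconverged"):
            mm.tukey_contrasts(res)
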