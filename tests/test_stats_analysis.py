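import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalnoise import (
    ShoalResponseModel,
    apply_transform,
    dispersion_check,
    effect_size_of_change,
)
from shoalnoise._nbglmm import NBGLMMError, fit_nbglmm
from shoalnoise.stats import invert_transform


def make_table(rng, J=20, F=4, effects=None, sd=1.0, response="median_speed",
               sigma_trial=0.5, sigma_fish=0.3):
    """Balanced two-treatment, two-half summary table with known effects.

    ``effects`` = (treat, half, interaction) additive shifts.
    """
    bt, bh, bi = effects if effects is not None else (0.0, 0.0, 0.0)
    rows = []
    for j in range(J):
        treat = j % 2
        a_j = rng.normal(0, sigma_trial)
        for f in range(F):
            b_f = rng.normal(0, sigma_fish)
            for h in (0, 1):
                y = (
                    10.0 + bt * treat + bh * h + bi * treat * h
                    + a_j + b_f + rng.normal(0, sd)
                )
                rows.append(
                    {
                        "trial": f"T{j:02d}",
                        "fish": f,
                        "treatment": "pile_driving" if treat else "ambient",
                        "half": "second" if h else "first",
                        response: y,
                        "median_speed": y if response == "median_speed"
                        else 10.0 + rng.normal(0, 0.5),
                    }
                )
    return pd.DataFrame(rows)


class TestTransforms:
    def test_paper_examples(self):
        assert apply_transform(np.array([0.9]), "log10_one_minus")[0] == pytest.approx(-1.0)
        assert apply_transform(np.array([1.0]), "log10")[0] == pytest.approx(0.0)

    def test_domain_errors_name_rows(self):
        with pytest.raises(ValueError, match="rows: \\[1\\]"):
            apply_transform(np.array([0.5, 1.0]), "log10_one_minus")
        with pytest.raises(ValueError, match="positive"):
            apply_transform(np.array([0.0]), "log10")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(1e-6, 1e6), r=st.floats(-5.0, 1.0 - 1e-9))
    def test_round_trip_identity(self, x, r):
        assert invert_transform(
            apply_transform(np.array([x]), "log10"), "log10"
        )[0] == pytest.approx(x, rel=1e-12)
        assert invert_transform(
            apply_transform(np.array([r]), "log10_one_minus"), "log10_one_minus"
        )[0] == pytest.approx(r, rel=1e-9, abs=1e-12)


class TestLMM:
    def test_forced_interaction_detected(self):
        rng = np.random.default_rng(0)
        df = make_table(rng, effects=(0.0, 0.0, 3.0), sd=0.0,
                        sigma_trial=0.0, sigma_fish=0.0)
        res = ShoalResponseModel(df, "median_speed", family="lmm").fit()
        assert not res.pruned
        assert res.interaction_p < 1e-6

    def test_null_interaction_pruned_and_refit(self):
        rng = np.random.default_rng(1)
        df = make_table(rng, effects=(1.0, 1.0, 0.0))
        res = ShoalResponseModel(df, "median_speed", family="lmm").fit()
        assert res.pruned
        assert "inter" not in set(res.params["term"])
        assert res.params.set_index("term").loc["half2", "p"] < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        df = make_table(rng, effects=(0.5, 0.5, 0.5))
        r1 = ShoalResponseModel(df, "median_speed", family="lmm").fit()
        r2 = ShoalResponseModel(df, "median_speed", family="lmm").fit()
        pd.testing.assert_frame_equal(r1.params, r2.params)
        assert r1.interaction_stat == r2.interaction_stat

    def test_closed_form_agrees_with_iterative_mixedlm(self):
        """Dual route: the balanced-design ANOVA/REML path must match the
        general iterative mixed-model fit (statsmodels MixedLM)."""
        rng = np.random.default_rng(3)
        df = make_table(rng, J=12, effects=(0.6, 0.4, 2.0))
        model = ShoalResponseModel(df, "median_speed", family="lmm")
        frame = model._frame()
        frame["y"] = frame["median_speed"]
        fast = model._fit_lmm_balanced(frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slow = model._fit_lmm_mixedlm(frame)
        assert fast.interaction_stat == pytest.approx(slow.interaction_stat, rel=1e-3)
        f = fast.params.set_index("term")
        s = slow.params.set_index("term")
        for term in ("treat", "half2", "inter"):
            assert f.loc[term, "estimate"] == pytest.approx(
                s.loc[term, "estimate"], rel=1e-6, abs=1e-9
            )
            assert f.loc[term, "se"] == pytest.approx(s.loc[term, "se"], rel=1e-2)
        for k in ("trial", "fish(trial)", "residual"):
            assert fast.vc[k] == pytest.approx(slow.vc[k], rel=0.05, abs=1e-3)

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(4)
        df = make_table(rng)
        with pytest.raises(ValueError, match="one row per half"):
            ShoalResponseModel(df.iloc[:-1], "median_speed")

    def test_speed_covariate_refit_runs(self):
        rng = np.random.default_rng(5)
        df = make_table(rng, effects=(0.5, 0.5, 1.0), response="max_dir_corr")
        df["max_dir_corr"] = 1.0 - 10 ** (-(df["max_dir_corr"] - 5.0) / 5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ShoalResponseModel(
                df, "max_dir_corr", family="lmm", covariate_speed=True
            ).fit()
        assert "speed_c" in set(res.params["term"])


class TestNBGLMM:
    @staticmethod
    def simulate_counts(rng, beta, k, s2t=0.03, s2f=0.02, J=30, F=4):
        trial = np.repeat(np.arange(J), F * 2)
        fish = np.repeat(np.arange(J * F), 2)
        treat = (trial % 2).astype(float)
        half = np.tile([0.0, 1.0], J * F)
        X = np.column_stack([np.ones(trial.size), treat, half, treat * half])
        u_t = rng.normal(0, np.sqrt(s2t), J)
        u_f = rng.normal(0, np.sqrt(s2f), J * F)
        mu = np.exp(X @ beta + u_t[trial] + u_f[fish])
        y = rng.negative_binomial(k, k / (k + mu))
        return y, X, trial, fish, treat, half

    def test_shape_recovery_within_30pct(self):
        rng = np.random.default_rng(10)
        ks = []
        for _ in range(3):
            y, X, trial, fish, _, _ = self.simulate_counts(
                rng, np.array([3.0, 0.0, 0.0, 0.0]), k=5.0
            )
            ks.append(fit_nbglmm(y, X, trial, fish).k)
        assert abs(np.median(ks) - 5.0) / 5.0 < 0.30

    def test_interaction_power_when_mean_doubles(self):
        """Half-2 mean doubled in one treatment only: the LRT must flag the
        interaction in every scaled-down replicate."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 8
        for _ in range(n_rep):
            beta = np.array([3.0, 0.0, 0.0, np.log(2.0)])
            y, X, trial, fish, treat, half = self.simulate_counts(rng, beta, k=8.0)
            df = pd.DataFrame(
                {
                    "trial": trial,
                    "fish": fish,
                    "treatment": np.where(treat == 1, "pile_driving", "ambient"),
                    "half": np.where(half == 1, "second", "first"),
                    "mean_heading_diff": y.astype(float),
                }
            )
            res = ShoalResponseModel(df, "mean_heading_diff", family="nb_glmm").fit()
            hits += res.interaction_p < 0.05
        assert hits == n_rep

    def test_all_zero_response_rejected(self):
        rng = np.random.default_rng(12)
        _, X, trial, fish, _, _ = self.simulate_counts(
            rng, np.array([1.0, 0.0, 0.0, 0.0]), k=5.0
        )
        with pytest.raises(NBGLMMError, match="all-zero"):
            fit_nbglmm(np.zeros(X.shape[0]), X, trial, fish)

    def test_matches_glmmtmb_oracle(self, tmp_path):
        """Independent cross-check: our Laplace ML fit must agree with the
        R glmmTMB fit (same model, same data) on loglik, coefficients and
        the NB shape."""
        rng = np.random.default_rng(13)
        y, X, trial, fish, treat, half = self.simulate_counts(
            rng, np.array([2.5, 0.2, 0.1, 0.0]), k=6.0, J=16
        )
        res = fit_nbglmm(y, X, trial, fish)
        data = pd.DataFrame(
            {"y": y, "trial": trial, "fish": fish, "treat": treat, "half": half}
        )
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            d$trial <- factor(d$trial); d$fish <- factor(d$fish)
            m <- glmmTMB(y ~ treat*half + (1|trial) + (1|fish),
                         family = nbinom2, data = d)
            cat(as.numeric(logLik(m)), fixef(m)$cond, sigma(m), sep = "\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        ll_r, beta_r, k_r = vals[0], np.array(vals[1:5]), vals[5]
        assert res.loglik == pytest.approx(ll_r, abs=1e-2)
        np.testing.assert_allclose(res.beta, beta_r, atol=5e-3)
        assert res.k == pytest.approx(k_r, rel=0.02)


class TestDispersionCheck:
    @staticmethod
    def table_from_counts(y, trial, fish, treat, half):
        return pd.DataFrame(
            {
                "trial": trial,
                "fish": fish,
                "treatment": np.where(treat == 1, "pile_driving", "ambient"),
                "half": np.where(half == 1, "second", "first"),
                "mean_heading_diff": y.astype(float),
            }
        )

    def test_well_specified_passes(self):
        rng = np.random.default_rng(20)
        passes = 0
        n_rep = 30
        for _ in range(n_rep):
            y, X, trial, fish, treat, half = TestNBGLMM.simulate_counts(
                rng, np.array([3.2, 0.1, 0.1, 0.0]), k=6.0
            )
            df = self.table_from_counts(y, trial, fish, treat, half)
            _, ok = dispersion_check(df, "mean_heading_diff")
            passes += ok
        assert passes >= int(0.9 * n_rep)

    def test_misspecified_variance_fails(self):
        """Variance patterns the NB mean-variance function mu(1 + mu/k)
        cannot represent must trip the fail flag.  (With the shape estimated
        by maximum likelihood, global overdispersion is absorbed into k, so
        misspecification surfaces through the band's other side.)"""
        rng = np.random.default_rng(21)
        _, X, trial, fish, treat, half = TestNBGLMM.simulate_counts(
            rng, np.array([3.0, 0.0, 0.0, 0.0]), k=5.0
        )
        n = trial.size
        # same mean in both halves but wildly different variance
        y = np.where(
            half == 0, rng.poisson(20.0, n), np.where(rng.random(n) < 0.5, 0, 40)
        ).astype(float)
        disp, ok = dispersion_check(
            self.table_from_counts(y, trial, fish, treat, half), "mean_heading_diff"
        )
        assert not ok and (disp <= 0.5 or disp >= 2.0)
        # near-deterministic counts: far less variable than any NB law
        y2 = np.full(n, 20.0)
        y2[::11] = 21.0
        disp2, ok2 = dispersion_check(
            self.table_from_counts(y2, trial, fish, treat, half), "mean_heading_diff"
        )
        assert not ok2 and disp2 < 0.5


class TestEffectSize:
    def test_identical_deltas_give_zero(self):
        rng = np.random.default_rng(30)
        df = make_table(rng, effects=(0.0, 1.0, 0.0), sd=0.0,
                        sigma_trial=0.0, sigma_fish=0.0)
        assert effect_size_of_change(df, "median_speed") == pytest.approx(0.0)

    def test_one_pooled_sd_shift(self):
        # trial-level deltas shifted by exactly one pooled SD -> d ~ 1
        rng = np.random.default_rng(31)
        ds = []
        for rep in range(40):
            # per-fish delta sd = sqrt(2)*sd; trial-level (4 fish) delta sd
            # = 0.5, so an interaction shift of 0.5 is one pooled SD
            df = make_table(rng, J=30, effects=(0.0, 0.0, 0.5), sd=np.sqrt(2.0) / 2,
                            sigma_trial=0.0, sigma_fish=0.0)
            ds.append(effect_size_of_change(df, "median_speed"))
        assert np.mean(ds) == pytest.approx(1.0, abs=0.15)

    def test_sign_convention(self):
        rng = np.random.default_rng(32)
        df = make_table(rng, effects=(0.0, 0.0, 2.0), sd=0.5)
        assert effect_size_of_change(df, "median_speed") > 0
        df2 = make_table(rng, effects=(0.0, 0.0, -2.0), sd=0.5)
        assert effect_size_of_change(df2, "median_speed") < 0

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(33)
        df = make_table(rng, J=3)
        with pytest.raises(ValueError):
            effect_size_of_change(df, "median_speed")
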