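"""Mixed-model inference on the per-fish-per-half response table.

Every response is modelled with treatment (between subjects) and trial
half (within subjects) as fixed effects, their interaction (dropped and
the model refitted with main effects only when non-significant), and
random intercepts for trial and for fish nested within trial.

Two families are used, matching the distributional character of the
responses: right-skewed positive responses (offsets, bearings, heading
difference) get a negative-binomial GLMM with variance mu * (1 + mu / k);
the remaining responses get a Gaussian LMM (REML), after log10 or
log10(1 - r) transforms where the raw scale is skewed or bounded.

The public surface follows the Model/Results convention: build a
:class:`ShoalResponseModel` from the summary table, call ``fit()`` and
read estimates, tests and diagnostics off the returned
:class:`ShoalResponseResults` (or print ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._nbglmm import NBGLMMError, fit_nbglmm

__all__ = [
    "TRANSFORM_MAP",
    "NB_RESPONSES",
    "LMM_RESPONSES",
    "apply_transform",
    "ShoalResponseModel",
    "ShoalResponseResults",
    "dispersion_check",
    "effect_size_of_change",
    "analyse_all_responses",
]

# response -> LMM transform (the GLMM responses are analysed untransformed)
TRANSFORM_MAP = {
    "mean_centroid_dist": "log10",
    "modal_nnd": "log10",
    "median_speed": "none",
    "max_speed_corr": "log10_one_minus",
    "max_dir_corr": "log10_one_minus",
    "dir_delay_s": "none",
}
LMM_RESPONSES = list(TRANSFORM_MAP)

# right-skewed positive responses analysed with the NB GLMM; the count
# integerization unit is 1 degree for angles and 1 mm for offsets
NB_RESPONSES = {
    "mean_perp": 10.0,           # cm -> mm
    "mean_para": 10.0,
    "mean_bearing_front": 1.0,   # degrees
    "mean_bearing_behind": 1.0,
    "mean_heading_diff": 1.0,
}


def apply_transform(values: np.ndarray | pd.Series, transform: str) -> np.ndarray:
    """Element-wise response transform with domain checking."""
    x = np.asarray(values, dtype=float)
    if transform == "none":
        return x
    if transform == "log10":
        bad = np.flatnonzero(~(x > 0))
        if bad.size:
            raise ValueError(f"log10 requires positive values; offending rows: {bad.tolist()}")
        return np.log10(x)
    if transform == "log10_one_minus":
        bad = np.flatnonzero(~(x < 1))
        if bad.size:
            raise ValueError(
                f"log10(1-r) requires values < 1; offending rows: {bad.tolist()}"
            )
        return np.log10(1.0 - x)
    raise ValueError(f"unknown transform {transform!r}")


def invert_transform(values: np.ndarray, transform: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if transform == "none":
        return x
    if transform == "log10":
        return 10.0**x
    if transform == "log10_one_minus":
        return 1.0 - 10.0**x
    raise ValueError(f"unknown transform {transform!r}")


def _validate_table(data: pd.DataFrame, response: str) -> pd.DataFrame:
    required = {"trial", "fish", "treatment", "half", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    df = data.copy()
    df["unit"] = df["trial"].astype(str) + "/" + df["fish"].astype(str)
    counts = df.groupby("unit")["half"].nunique()
    if (counts != 2).any() or (df.groupby("unit").size() != 2).any():
        raise ValueError("each fish must contribute exactly one row per half")
    per_treat = df.groupby("treatment")["trial"].nunique()
    if (per_treat < 2).any() or per_treat.size != 2:
        raise ValueError("need >= 2 trials in each of the two treatments")
    if df[response].isna().any():
        # a fish with a missing value in either half drops out entirely
        drop = df.loc[df[response].isna(), "unit"].unique()
        df = df[~df["unit"].isin(drop)]
    return df


@dataclass
class ShoalResponseResults:
    """Fitted mixed-model results for one response."""

    response: str
    family: str                      # "lmm" | "nb_glmm"
    transform: str
    params: pd.DataFrame             # term, estimate, se, stat, df..., p
    interaction_stat: float
    interaction_p: float
    interaction_df: tuple
    pruned: bool
    vc: dict
    k: Optional[float] = None
    dispersion: Optional[float] = None
    dispersion_ok: Optional[bool] = None
    df_method: str = "containment"
    stat_label: str = "F"
    converged: bool = True
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.interaction_p <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def summary(self) -> str:
        lines = [
            f"Response: {self.response}   family: {self.family}   "
            f"transform: {self.transform}",
            f"Interaction treatment x half: {self.stat_label} = "
            f"{self.interaction_stat:.3f}, df = {self.interaction_df}, "
            f"p = {self.interaction_p:.4g} "
            f"({'dropped' if self.pruned else 'kept'})",
        ]
        if self.family == "nb_glmm":
            lines.append(
                f"NB shape k = {self.k:.3g}; dispersion = {self.dispersion:.3f} "
                f"({'ok' if self.dispersion_ok else 'OUT OF (0.5, 2)'})"
            )
        lines.append(
            "Random-effect variances: "
            + ", ".join(f"{k} = {v:.4g}" for k, v in self.vc.items())
        )
        lines.append(self.params.to_string(index=False))
        if self.notes:
            lines.append("Notes: " + "; ".join(self.notes))
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat record for the combined model-summary CSV."""
        row = {
            "response": self.response,
            "family": self.family,
            "transform": self.transform,
            "stat_label": self.stat_label,
            "interaction_stat": self.interaction_stat,
            "interaction_p": self.interaction_p,
            "interaction_df": str(self.interaction_df),
            "pruned": self.pruned,
            "df_method": self.df_method,
            "k": self.k,
            "dispersion": self.dispersion,
            "converged": self.converged,
        }
        for _, r in self.params.iterrows():
            row[f"b_{r['term']}"] = r["estimate"]
            row[f"p_{r['term']}"] = r["p"]
        return row


class ShoalResponseModel:
    """Treatment x trial-half mixed model for one response measure.

    Parameters
    ----------
    data : tidy per-fish-per-half summary table (two rows per fish).
    response : column to analyse.
    family : "lmm", "nb_glmm" or None to pick the family the response
        conventionally gets.
    covariate_speed : add the fish's median speed as an extra main effect
        (used for the correlation/delay responses, which co-vary with
        swimming speed).
    alpha_prune : significance level below which the interaction is kept.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        family: Optional[str] = None,
        transform: Optional[str] = None,
        covariate_speed: bool = False,
        alpha_prune: float = 0.05,
    ):
        if family is None:
            family = "nb_glmm" if response in NB_RESPONSES else "lmm"
        if family not in ("lmm", "nb_glmm"):
            raise ValueError("family must be 'lmm' or 'nb_glmm'")
        self.response = response
        self.family = family
        self.covariate_speed = covariate_speed
        self.alpha_prune = alpha_prune
        if transform is None:
            transform = TRANSFORM_MAP.get(response, "none") if family == "lmm" else "none"
        self.transform = transform
        self.data = _validate_table(data, response)
        if covariate_speed and "median_speed" not in data.columns:
            raise ValueError("covariate_speed requires a median_speed column")

    @classmethod
    def from_summaries(cls, data: pd.DataFrame, response: str, **kwargs) -> "ShoalResponseModel":
        return cls(data, response, **kwargs)

    # ---- design helpers -------------------------------------------------
    def _frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df["treat"] = (df["treatment"] == "pile_driving").astype(float)
        df["half2"] = (df["half"] == "second").astype(float)
        df["inter"] = df["treat"] * df["half2"]
        if self.covariate_speed:
            df["speed_c"] = df["median_speed"] - df["median_speed"].mean()
        return df

    def _containment_df(self, df: pd.DataFrame, n_within: int) -> int:
        n_obs = len(df)
        n_fish = df["unit"].nunique()
        return n_obs - n_fish - n_within

    # ---- fitting --------------------------------------------------------
    def fit(self) -> ShoalResponseResults:
        if self.family == "lmm":
            return self._fit_lmm()
        return self._fit_nbglmm()

    def _mixedlm(self, df: pd.DataFrame, rhs: str):
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                f"y ~ {rhs}",
                data=df,
                groups="trial",
                re_formula="1",
                vc_formula={"fish": "0 + C(fish)"},
            )
            res = model.fit(reml=True)
        msgs = sorted({str(w.message) for w in wlist})
        return res, msgs

    def _wald_f(self, res, term: str, ddf: int) -> tuple[float, float]:
        t = res.params[term] / res.bse[term]
        f = float(t * t)
        return f, float(sps.f.sf(f, 1, max(ddf, 1)))

    def _is_balanced(self, df: pd.DataFrame) -> bool:
        fish_per_trial = df.groupby("trial")["unit"].nunique()
        return fish_per_trial.nunique() == 1

    def _fit_lmm(self) -> ShoalResponseResults:
        df = self._frame()
        df["y"] = apply_transform(df[self.response].to_numpy(), self.transform)
        if not self.covariate_speed and self._is_balanced(df):
            return self._fit_lmm_balanced(df)
        return self._fit_lmm_mixedlm(df)

    def _fit_lmm_balanced(self, df: pd.DataFrame) -> ShoalResponseResults:
        """Closed-form REML for the balanced split-plot design.

        With complete, balanced data the ANOVA stratum estimators coincide
        with REML, and the treatment x half interaction test is the exact
        F-test in the within-fish stratum; this path is therefore both
        faster and numerically exact.  (Cross-checked against the iterative
        mixed-model fit in the test-suite.)
        """
        J = df["trial"].nunique()
        F_fish = df.groupby("trial")["unit"].nunique().iloc[0]
        cell = df.groupby(["treat", "half2"])["y"].mean()
        m_a1, m_a2 = cell[(0.0, 0.0)], cell[(0.0, 1.0)]
        m_p1, m_p2 = cell[(1.0, 0.0)], cell[(1.0, 1.0)]
        J_a = df.loc[df.treat == 0, "trial"].nunique()
        J_p = J - J_a

        trial_means = df.groupby(["trial", "treat"])["y"].mean().reset_index()
        treat_means = trial_means.groupby("treat")["y"].transform("mean")
        ss_trial = 2 * F_fish * ((trial_means["y"] - treat_means) ** 2).sum()
        ms_trial = ss_trial / (J - 2)
        fish_means = df.groupby(["trial", "unit"])["y"].mean().reset_index()
        tm = fish_means.groupby("trial")["y"].transform("mean")
        ss_fish = 2 * ((fish_means["y"] - tm) ** 2).sum()
        ms_fish = ss_fish / (J * (F_fish - 1))
        # within-fish residuals after removing fish means and the (treatment-
        # specific) half effects: exactly the full interaction model residuals
        dfm = df.merge(
            fish_means.rename(columns={"y": "fish_mean"}), on=["trial", "unit"]
        )
        half_eff = dfm.groupby(["treat", "half2"])["y"].transform("mean") - dfm.groupby(
            "treat"
        )["y"].transform("mean")
        resid = dfm["y"] - dfm["fish_mean"] - half_eff
        df_res = J * F_fish - 2
        ms_res = float((resid**2).sum() / df_res)

        sigma2 = ms_res
        sigma2_f = max((ms_fish - ms_res) / 2.0, 0.0)
        sigma2_t = max((ms_trial - ms_fish) / (2.0 * F_fish), 0.0)
        notes = []
        if ms_fish < ms_res or ms_trial < ms_fish:
            notes.append("variance component estimated at boundary (0)")

        inter = (m_p2 - m_p1) - (m_a2 - m_a1)
        se_inter = np.sqrt(2 * sigma2 * (1.0 / (J_a * F_fish) + 1.0 / (J_p * F_fish)))
        if se_inter == 0.0:
            # degenerate zero-residual input: any nonzero contrast is exact
            f_int = np.inf if inter != 0 else 0.0
        else:
            f_int = float((inter / se_inter) ** 2)
        p_int = float(sps.f.sf(f_int, 1, df_res))
        pruned = p_int >= self.alpha_prune

        var_trial_half_mean = sigma2_t + (sigma2_f + sigma2) / F_fish
        rows = []
        if pruned:
            # main-effects model: half effect pooled over treatments
            m1 = (J_a * m_a1 + J_p * m_p1) / J
            m2 = (J_a * m_a2 + J_p * m_p2) / J
            half = float(m2 - m1)
            se_half = np.sqrt(2 * sigma2 / (J * F_fish))
            df_res_m = J * F_fish - 1
            treat = float((m_p1 + m_p2) / 2 - (m_a1 + m_a2) / 2)
            v_treat_mean = sigma2_t + sigma2_f / F_fish + sigma2 / (2 * F_fish)
            se_treat = np.sqrt(v_treat_mean * (1 / J_a + 1 / J_p))
            terms = [
                ("Intercept", float((m_a1 + m_a2) / 2 - 0.5 * half), np.nan, J - 2),
                ("treat", treat, se_treat, J - 2),
                ("half2", half, se_half, df_res_m),
            ]
        else:
            half = float(m_a2 - m_a1)
            se_half = np.sqrt(2 * sigma2 / (J_a * F_fish))
            treat = float(m_p1 - m_a1)
            se_treat = np.sqrt(var_trial_half_mean * (1 / J_a + 1 / J_p))
            terms = [
                ("Intercept", float(m_a1), np.nan, J - 2),
                ("treat", treat, se_treat, J - 2),
                ("half2", half, se_half, df_res),
                ("inter", float(inter), se_inter, df_res),
            ]
        for name, est, se, ddf in terms:
            if np.isnan(se):
                rows.append(
                    {"term": name, "estimate": est, "se": np.nan, "stat": np.nan,
                     "df_num": 1, "df_den": ddf, "p": np.nan}
                )
            else:
                if se == 0.0:
                    fstat = np.inf if est != 0 else 0.0
                else:
                    fstat = float((est / se) ** 2)
                rows.append(
                    {"term": name, "estimate": est, "se": float(se), "stat": fstat,
                     "df_num": 1, "df_den": ddf, "p": float(sps.f.sf(fstat, 1, ddf))}
                )
        return ShoalResponseResults(
            response=self.response,
            family="lmm",
            transform=self.transform,
            params=pd.DataFrame(rows),
            interaction_stat=f_int,
            interaction_p=p_int,
            interaction_df=(1, df_res),
            pruned=pruned,
            vc={"trial": sigma2_t, "fish(trial)": sigma2_f, "residual": sigma2},
            stat_label="F",
            converged=True,
            notes=notes,
        )

    def _fit_lmm_mixedlm(self, df: pd.DataFrame) -> ShoalResponseResults:
        extra = " + speed_c" if self.covariate_speed else ""
        n_within_full = 2 + (1 if self.covariate_speed else 0)
        res_full, msgs = self._mixedlm(df, "treat + half2 + inter" + extra)
        ddf_w = self._containment_df(df, n_within_full)
        f_int, p_int = self._wald_f(res_full, "inter", ddf_w)
        pruned = p_int >= self.alpha_prune
        notes = [m for m in msgs if "converge" in m.lower() or "singular" in m.lower()]
        if pruned:
            res, msgs2 = self._mixedlm(df, "treat + half2" + extra)
            notes += [m for m in msgs2 if "converge" in m.lower() or "singular" in m.lower()]
            n_within = n_within_full - 1
        else:
            res = res_full
            n_within = n_within_full
        ddf_w = self._containment_df(df, n_within)
        ddf_b = df["trial"].nunique() - 2
        rows = []
        for term in res.params.index:
            if term in ("Group Var", "fish Var") or term.endswith("Var"):
                continue
            ddf = ddf_b if term == "treat" else ddf_w
            if term == "Intercept":
                ddf = ddf_b
            fstat, p = self._wald_f(res, term, ddf)
            rows.append(
                {
                    "term": term,
                    "estimate": float(res.params[term]),
                    "se": float(res.bse[term]),
                    "stat": fstat,
                    "df_num": 1,
                    "df_den": ddf,
                    "p": p,
                }
            )
        vc = {
            "trial": float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0,
            "fish(trial)": float(res.vcomp[0]) if res.vcomp.size else 0.0,
            "residual": float(res.scale),
        }
        return ShoalResponseResults(
            response=self.response,
            family="lmm",
            transform=self.transform,
            params=pd.DataFrame(rows),
            interaction_stat=f_int,
            interaction_p=p_int,
            interaction_df=(1, self._containment_df(df, n_within_full)),
            pruned=pruned,
            vc=vc,
            stat_label="F",
            converged=bool(getattr(res, "converged", True)),
            notes=notes,
        )

    def _design(self, df: pd.DataFrame, interaction: bool) -> tuple[np.ndarray, list]:
        cols = [np.ones(len(df)), df["treat"].to_numpy(), df["half2"].to_numpy()]
        names = ["Intercept", "treat", "half2"]
        if interaction:
            cols.append(df["inter"].to_numpy())
            names.append("inter")
        if self.covariate_speed:
            cols.append(df["speed_c"].to_numpy())
            names.append("speed_c")
        return np.column_stack(cols), names

    def _fit_nbglmm(self) -> ShoalResponseResults:
        df = self._frame()
        scale = NB_RESPONSES.get(self.response, 1.0)
        y = np.round(df[self.response].to_numpy() * scale)
        if np.any(y < 0):
            raise ValueError("NB GLMM requires a non-negative response")
        X_full, names_full = self._design(df, interaction=True)
        X_red, names_red = self._design(df, interaction=False)
        full = fit_nbglmm(y, X_full, df["trial"].to_numpy(), df["unit"].to_numpy(), names_full)
        red = fit_nbglmm(y, X_red, df["trial"].to_numpy(), df["unit"].to_numpy(), names_red)
        lrt = max(0.0, 2.0 * (full.loglik - red.loglik))
        p_int = float(sps.chi2.sf(lrt, 1))
        pruned = p_int >= self.alpha_prune
        chosen, names = (red, names_red) if pruned else (full, names_full)
        rows = []
        for i, term in enumerate(names):
            z, p = chosen.wald(i)
            rows.append(
                {
                    "term": term,
                    "estimate": float(chosen.beta[i]),
                    "se": float(chosen.se[i]),
                    "stat": float(z * z),
                    "df_num": 1,
                    "df_den": np.inf,
                    "p": p,
                }
            )
        disp, disp_ok = dispersion_check(self.data, self.response, self.covariate_speed)
        notes = []
        if not (full.converged and red.converged):
            notes.append("outer optimiser reported imperfect convergence")
        if chosen.k <= 0:
            raise NBGLMMError("estimated NB shape k <= 0")
        return ShoalResponseResults(
            response=self.response,
            family="nb_glmm",
            transform="none",
            params=pd.DataFrame(rows),
            interaction_stat=float(lrt),
            interaction_p=p_int,
            interaction_df=(1,),
            pruned=pruned,
            vc={"trial": chosen.sigma2_trial, "fish(trial)": chosen.sigma2_fish},
            k=chosen.k,
            dispersion=disp,
            dispersion_ok=disp_ok,
            stat_label="chi2",
            converged=full.converged and red.converged,
            notes=notes
            + [f"response integerised at {1.0 / scale:g} cm units" if scale != 1.0 else "response integerised in degrees"],
        )


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    covariate_speed: bool = False,
    alpha_prune: float = 0.05,
) -> ShoalResponseResults:
    """Functional wrapper: LMM with the conventional transform for ``response``."""
    return ShoalResponseModel(
        data, response, family="lmm", covariate_speed=covariate_speed,
        alpha_prune=alpha_prune,
    ).fit()


def fit_nb_glmm(
    data: pd.DataFrame, response: str, alpha_prune: float = 0.05
) -> ShoalResponseResults:
    """Functional wrapper for the negative-binomial GLMM path."""
    return ShoalResponseModel(
        data, response, family="nb_glmm", alpha_prune=alpha_prune
    ).fit()


def dispersion_check(
    data: pd.DataFrame, response: str, covariate_speed: bool = False
) -> tuple[float, bool]:
    """Overdispersion check for the NB family.

    Fits the same fixed-effect structure as the GLMM but without random
    effects (a plain NB GLM with ML-estimated shape) and returns the
    Pearson chi-square / df statistic with its pass flag
    (0.5 < dispersion < 2).
    """
    df = _validate_table(data, response)
    df["treat"] = (df["treatment"] == "pile_driving").astype(float)
    df["half2"] = (df["half"] == "second").astype(float)
    df["inter"] = df["treat"] * df["half2"]
    cols = ["treat", "half2", "inter"]
    if covariate_speed:
        df["speed_c"] = df["median_speed"] - df["median_speed"].mean()
        cols.append("speed_c")
    scale = NB_RESPONSES.get(response, 1.0)
    y = np.round(df[response].to_numpy() * scale)
    X = sm.add_constant(df[cols].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        res = model.fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("NB GLM for the dispersion check did not converge")
    mu = np.exp(X @ res.params[:-1])
    alpha = max(float(res.params[-1]), 1e-12)
    pearson = float(np.sum((y - mu) ** 2 / (mu * (1.0 + alpha * mu))))
    ddf = y.size - X.shape[1] - 1
    disp = pearson / ddf
    return disp, bool(0.5 < disp < 2.0)


def effect_size_of_change(data: pd.DataFrame, response: str) -> float:
    """Cohen's d comparing the playback-induced change between treatments.

    The change score is (2nd-half value - 1st-half value) per fish,
    averaged to trial level to respect the non-independence of fish within
    a trial; d is the between-treatment difference of mean changes over the
    pooled trial-level SD.  Positive d means the response increased more
    (or decreased less) under pile-driving than ambient playback.
    """
    df = _validate_table(data, response)
    wide = df.pivot_table(
        index=["trial", "treatment", "unit"], columns="half", values=response
    ).reset_index()
    if not {"first", "second"} <= set(wide.columns):
        raise ValueError("both trial halves required")
    wide["delta"] = wide["second"] - wide["first"]
    trial_means = wide.groupby(["trial", "treatment"])["delta"].mean().reset_index()
    groups = {
        t: g["delta"].to_numpy() for t, g in trial_means.groupby("treatment")
    }
    if set(groups) != {"ambient", "pile_driving"}:
        raise ValueError("need both treatments")
    a, p = groups["ambient"], groups["pile_driving"]
    if a.size < 2 or p.size < 2:
        raise ValueError("need >= 2 trials per treatment")
    s_pool = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (p.size - 1) * p.var(ddof=1))
        / (a.size + p.size - 2)
    )
    diff = p.mean() - a.mean()
    if s_pool == 0.0:
        # degenerate noiseless input: identical deltas -> no effect
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / s_pool)


def analyse_all_responses(
    data: pd.DataFrame,
    alpha_prune: float = 0.05,
    speed_covariate_refits: bool = True,
) -> tuple[list[ShoalResponseResults], pd.DataFrame, pd.DataFrame]:
    """Run the full inference battery on a summary table.

    LMM responses and NB-GLMM responses are fitted with their conventional
    families/transforms; the correlation and delay responses are refitted
    with median speed as a covariate (they co-vary with swimming speed);
    effect sizes of change are computed for every response.  Returns
    (results list, model-summary table, effect-size table).
    """
    results: list[ShoalResponseResults] = []
    for resp in LMM_RESPONSES:
        if resp == "dir_delay_s" and data[resp].isna().all():
            continue
        results.append(
            ShoalResponseModel(data, resp, family="lmm", alpha_prune=alpha_prune).fit()
        )
    for resp in NB_RESPONSES:
        results.append(
            ShoalResponseModel(data, resp, family="nb_glmm", alpha_prune=alpha_prune).fit()
        )
    if speed_covariate_refits:
        for resp in ("max_speed_corr", "max_dir_corr", "dir_delay_s"):
            r = ShoalResponseModel(
                data, resp, family="lmm", covariate_speed=True, alpha_prune=alpha_prune
            ).fit()
            r.notes.append("speed-covariate refit")
            r.response = resp + "+speed"
            results.append(r)
    summary = pd.DataFrame([r.to_row() for r in results])
    effect_rows = []
    for resp in LMM_RESPONSES + list(NB_RESPONSES):
        try:
            d = effect_size_of_change(data, resp)
        except ValueError:
            d = np.nan
        effect_rows.append({"response": resp, "cohens_d_change": d})
    effects = pd.DataFrame(effect_rows)
    return results, summary, effects
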