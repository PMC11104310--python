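"""Reinforcement-learning analysis of daily activity-diary (GOAL form) data.

Each diary entry records, for one planned activity: the reward and
punishment expected when it was planned (R_pre, P_pre), the reward and
punishment experienced on completion (r, p), and a fresh prediction for a
hypothetical repeat (R_post1, P_post1).  Prediction errors (delta_R = r -
R_pre) should, under delta-rule learning, drive both the immediate
prediction change dR1 = R_post1 - R_pre and the longer-horizon change dR2 =
R_pre(next planning of the same activity) - R_pre, and recent reinforcement
should raise the odds of repeating an activity the next day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

GOAL_COLUMNS = ["subject_id", "day", "activity_id", "category", "R_pre", "P_pre", "r", "p", "R_post1", "P_post1"]

PE_OUTCOMES = ("dR1", "dP1", "dR2", "dP2")
PE_PREDICTORS = ("delta_R", "delta_P")


def derive_pe_table(entries: pd.DataFrame) -> pd.DataFrame:
    """Prediction errors and prediction changes, one row per completed activity.

    dR2/dP2 pair successive plannings of the same (subject, activity):
    the change is attached to the earlier planning, whose prediction error
    is the natural regressor for it; each planning is used at most once.
    ``repeat_next_day`` flags activities planned again on the following day.
    """
    dup = entries.duplicated(subset=["subject_id", "day", "activity_id"], keep=False)
    if dup.any():
        rows = entries.index[dup].tolist()
        raise ValueError(f"duplicate (subject, day, activity) entries at rows {rows}")
    df = entries.sort_values(["subject_id", "day"], kind="stable").copy()
    df["delta_R"] = df["r"] - df["R_pre"]
    df["delta_P"] = df["p"] - df["P_pre"]
    df["dR1"] = df["R_post1"] - df["R_pre"]
    df["dP1"] = df["P_post1"] - df["P_pre"]
    g = df.groupby(["subject_id", "activity_id"], sort=False)
    df["dR2"] = g["R_pre"].shift(-1) - df["R_pre"]
    df["dP2"] = g["P_pre"].shift(-1) - df["P_pre"]
    next_day = g["day"].shift(-1)
    df["repeat_next_day"] = (next_day == df["day"] + 1).fillna(False).astype(bool)
    return df


@dataclass
class MixedFitResult:
    estimate: float
    se: float
    z: float
    p: float
    term: str
    random_structure: str
    n_obs: int
    n_subjects: int
    fixed_effects: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    flags: list = field(default_factory=list)
    p_bonferroni: float | None = None


def _slope_variance_positive(res, slope_name: str) -> bool:
    cov_re = np.asarray(res.cov_re)
    names = list(getattr(res.model.data, "exog_re_names", None) or [])
    if slope_name in names:
        i = names.index(slope_name)
        return bool(cov_re[i, i] > 1e-8)
    return True  # vc-structured fit: slope variance reported elsewhere


def _mixedlm_with_fallback(formula: str, data: pd.DataFrame, re_formula: str):
    """Random intercept + slope mixed fit with a robust convergence chain.

    Tries the correlated intercept+slope structure under several optimizers,
    then an uncorrelated (variance-components) slope, and only then drops to
    intercept-only — whose standard errors ignore between-subject slope
    variance and are therefore a last resort.
    """
    slope_name = re_formula.lstrip("~ ")
    groups = data["subject_id"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in (None, "powell", "nm"):
            try:
                model = smf.mixedlm(formula, data, groups=groups, re_formula=re_formula)
                res = model.fit(reml=True) if method is None else model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and np.isfinite(res.bse.iloc[:2]).all() and _slope_variance_positive(res, slope_name):
                return res, f"intercept+slope ({re_formula})", []
        # uncorrelated random intercept and slope
        try:
            model = smf.mixedlm(
                formula, data, groups=groups,
                vc_formula={"slope": f"0 + {slope_name}"},
            )
            res = model.fit(reml=True)
            if res.converged and np.isfinite(res.bse.iloc[:2]).all():
                return res, f"intercept+uncorrelated slope ({re_formula})", [
                    "random intercept-slope correlation dropped (convergence)"]
        except (np.linalg.LinAlgError, ValueError):
            pass
        res = smf.mixedlm(formula, data, groups=groups).fit(reml=True)
    return res, "intercept-only", ["random slope dropped (insufficient within-subject variance)"]


def fit_pe_update(table: pd.DataFrame, outcome: str = "dR1", predictor: str = "delta_R") -> MixedFitResult:
    """Mixed model: prediction change ~ prediction error, random intercept+slope.

    Returns the fixed-effect slope with its Wald z and p.
    """
    if outcome not in PE_OUTCOMES or predictor not in PE_PREDICTORS:
        raise ValueError(f"outcome must be in {PE_OUTCOMES} and predictor in {PE_PREDICTORS}")
    data = table.dropna(subset=[outcome, predictor])
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    res, structure, flags = _mixedlm_with_fallback(f"{outcome} ~ {predictor}", data, f"~{predictor}")
    fe = pd.DataFrame({"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues})
    return MixedFitResult(
        estimate=float(res.params[predictor]),
        se=float(res.bse[predictor]),
        z=float(res.tvalues[predictor]),
        p=float(res.pvalues[predictor]),
        term=predictor,
        random_structure=structure,
        n_obs=len(data),
        n_subjects=data["subject_id"].nunique(),
        fixed_effects=fe,
        flags=flags,
    )


@dataclass
class RepeatChoiceResult:
    reward_estimate: float
    reward_z: float
    reward_p: float
    punishment_estimate: float
    punishment_z: float
    punishment_p: float
    method: str
    n_obs: int
    flags: list = field(default_factory=list)


def fit_repeat_choice(table: pd.DataFrame) -> RepeatChoiceResult:
    """Clustered logistic regression of next-day repetition on reported r and p.

    Within-subject dependence is handled by generalized estimating equations
    with an exchangeable working correlation and cluster-robust standard
    errors, which stay calibrated at small cluster counts where
    subject-specific logistic mixed fits are unstable.  Degenerate outcomes
    (repetition constant) are flagged; estimation failure falls back to a
    penalized plain logistic fit.
    """
    data = table.dropna(subset=["repeat_next_day", "r", "p"]).copy()
    data["repeat"] = data["repeat_next_day"].astype(int)
    flags = []
    if data["repeat"].nunique() < 2:
        flags.append("degenerate outcome: repetition is constant (complete separation)")
        return RepeatChoiceResult(*(np.nan,) * 6, method="degenerate", n_obs=len(data), flags=flags)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE.from_formula(
                "repeat ~ r + p",
                groups="subject_id",
                data=data,
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
        if not np.isfinite(res.params[["r", "p"]]).all() or not np.isfinite(res.bse[["r", "p"]]).all():
            raise np.linalg.LinAlgError("non-finite GEE fit")
        return RepeatChoiceResult(
            reward_estimate=float(res.params["r"]),
            reward_z=float(res.tvalues["r"]),
            reward_p=float(res.pvalues["r"]),
            punishment_estimate=float(res.params["p"]),
            punishment_z=float(res.tvalues["p"]),
            punishment_p=float(res.pvalues["p"]),
            method="gee_exchangeable_logistic",
            n_obs=len(data),
            flags=flags,
        )
    except (np.linalg.LinAlgError, ValueError):
        flags.append("clustered logistic failed; penalized plain logistic fallback")
    X = sm.add_constant(data[["r", "p"]])
    res = sm.Logit(data["repeat"], X).fit_regularized(alpha=1.0, disp=False)
    # approximate SEs from the unpenalized information at the penalized estimate
    cov = sm.Logit(data["repeat"], X).hessian(res.params)
    se = np.sqrt(np.diag(np.linalg.inv(-cov)))
    zr = res.params["r"] / se[1]
    zp_ = res.params["p"] / se[2]
    return RepeatChoiceResult(
        reward_estimate=float(res.params["r"]),
        reward_z=float(zr),
        reward_p=float(2 * stats.norm.sf(abs(zr))),
        punishment_estimate=float(res.params["p"]),
        punishment_z=float(zp_),
        punishment_p=float(2 * stats.norm.sf(abs(zp_))),
        method="penalized_logit",
        n_obs=len(data),
        flags=flags,
    )


def fit_item_interaction(
    table: pd.DataFrame,
    item_change: pd.Series,
    outcome: str = "dR1",
    predictor: str = "delta_R",
    bonferroni_factor: int = 2,
) -> MixedFitResult:
    """Does a symptom-item change moderate prediction-error updating?

    Fixed effects: predictor, per-subject item change (between-subject) and
    their interaction; random intercept and predictor slope per subject.
    The interaction p-value is Bonferroni corrected for ``bonferroni_factor``
    hypotheses (default 2: items 19 and 21).  Sign convention: item change =
    end - start, so symptom improvements are negative changes.
    """
    if item_change.index.has_duplicates:
        raise ValueError("item_change must hold one value per subject")
    data = table.dropna(subset=[outcome, predictor]).copy()
    data["item_change"] = data["subject_id"].map(item_change)
    data = data.dropna(subset=["item_change"])
    if np.isclose(data.groupby("subject_id")["item_change"].first().std(), 0.0):
        return MixedFitResult(
            estimate=np.nan, se=np.nan, z=np.nan, p=np.nan,
            term=f"{predictor}:item_change", random_structure="n/a",
            n_obs=len(data), n_subjects=data["subject_id"].nunique(),
            flags=["item change constant across subjects: interaction inestimable"],
            p_bonferroni=np.nan,
        )
    formula = f"{outcome} ~ {predictor} * item_change"
    res, structure, flags = _mixedlm_with_fallback(formula, data, f"~{predictor}")
    term = f"{predictor}:item_change"
    fe = pd.DataFrame({"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues})
    p = float(res.pvalues[term])
    return MixedFitResult(
        estimate=float(res.params[term]),
        se=float(res.bse[term]),
        z=float(res.tvalues[term]),
        p=p,
        term=term,
        random_structure=structure,
        n_obs=len(data),
        n_subjects=data["subject_id"].nunique(),
        fixed_effects=fe,
        flags=flags,
        p_bonferroni=float(min(1.0, bonferroni_factor * p)),
    )


def fit_baseline_control(
    table: pd.DataFrame,
    baseline: pd.Series,
    outcome: str = "dR1",
    predictor: str = "delta_R",
    bonferroni_factor: int = 2,
) -> MixedFitResult:
    """Moderation by the baseline item score instead of its change (control model)."""
    res = fit_item_interaction(table, baseline, outcome=outcome, predictor=predictor,
                               bonferroni_factor=bonferroni_factor)
    res.flags = res.flags + ["moderator is the baseline item score"]
    return res


def subject_update_slopes(table: pd.DataFrame, outcome: str = "dR1", predictor: str = "delta_R") -> pd.Series:
    """Per-subject OLS slope of prediction change on prediction error."""
    out = {}
    for sid, g in table.dropna(subset=[outcome, predictor]).groupby("subject_id"):
        x = g[predictor].to_numpy()
        if len(g) < 3 or np.isclose(x.std(), 0.0):
            out[sid] = np.nan
            continue
        out[sid] = float(np.polyfit(x, g[outcome].to_numpy(), 1)[0])
    return pd.Series(out, name="update_slope")


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False


def correlate_learning_rates(task_alpha: pd.Series, diary_slopes: pd.Series) -> CorrelationResult:
    """Pearson and Spearman correlation of task learning rates with diary update slopes."""
    merged = pd.concat([task_alpha.rename("alpha"), diary_slopes.rename("slope")], axis=1).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 subjects with both values")
    if np.isclose(merged["alpha"].std(), 0.0) or np.isclose(merged["slope"].std(), 0.0):
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(merged), degenerate=True)
    pr, pp = stats.pearsonr(merged["alpha"], merged["slope"])
    sr, sp_ = stats.spearmanr(merged["alpha"], merged["slope"])
    return CorrelationResult(float(pr), float(pp), float(sr), float(sp_), len(merged))
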