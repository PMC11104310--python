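"""Mixed-effects regression of weekly depression scores on therapy phases.

Weekly IDS-SR totals are modelled as a per-subject random intercept plus
fixed effects for (i) a step improvement after the appetitive therapy phase
(week ``t3``), (ii) a step improvement after the aversive phase (week
``t7``), and (iii, iv) improvements proportional to each subject's change in
the appetitive and aversive Pavlovian parameters, gated by the same steps.
Negative Pavlovian-change coefficients mean larger parameter increases go
with larger symptom reductions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

DESIGN_COLUMNS = ["step3", "step7", "app_change", "av_change"]


def build_design(
    series: pd.DataFrame,
    changes: pd.DataFrame,
    t3_week: int = 4,
    t7_week: int = 7,
) -> pd.DataFrame:
    """Design matrix for the symptom regression.

    ``series`` needs subject_id, week and the outcome column(s); ``changes``
    needs subject_id, delta_pi_app, delta_pi_av.  Columns: step3 = 1[week >=
    t3_week], step7 = 1[week >= t7_week], app_change = delta_pi_app * step3,
    av_change = delta_pi_av * step7.  Subjects without change scores are
    dropped with a warning.
    """
    missing = set(series["subject_id"]) - set(changes["subject_id"])
    if missing:
        warnings.warn(f"subjects dropped (no parameter change scores): {sorted(missing)}", stacklevel=2)
    df = series.merge(changes[["subject_id", "delta_pi_app", "delta_pi_av"]], on="subject_id", how="inner")
    if df[["delta_pi_app", "delta_pi_av"]].isna().any().any():
        bad = df.loc[df[["delta_pi_app", "delta_pi_av"]].isna().any(axis=1), "subject_id"].unique()
        warnings.warn(f"subjects dropped (missing change scores): {sorted(bad)}", stacklevel=2)
        df = df.dropna(subset=["delta_pi_app", "delta_pi_av"])
    df = df.copy()
    df["step3"] = (df["week"] >= t3_week).astype(float)
    df["step7"] = (df["week"] >= t7_week).astype(float)
    df["app_change"] = df["delta_pi_app"] * df["step3"]
    df["av_change"] = df["delta_pi_av"] * df["step7"]
    return df


@dataclass
class SymptomFitResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    singular: bool
    method: str
    dropped_columns: list = field(default_factory=list)
    n_subjects: int = 0
    n_obs: int = 0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse, "p": self.pvalues})


def fit_symptom_model(design: pd.DataFrame, outcome: str = "ids_total") -> SymptomFitResult:
    """REML linear mixed model: outcome ~ steps + Pavlovian changes, random intercept.

    Wald z tests are reported per fixed effect.  Zero-variance design
    columns are dropped (flagged inestimable); near-zero residual variance
    falls back to OLS with subject fixed effects for stable point estimates.
    """
    if design["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    counts = design.groupby("subject_id")["week"].nunique()
    if (counts < 2).all():
        raise ValueError("need at least 2 weeks per subject")
    cols = [c for c in DESIGN_COLUMNS if c in design.columns]
    dropped = [c for c in cols if np.isclose(design[c].std(), 0.0)]
    if dropped:
        warnings.warn(f"zero-variance design columns dropped: {dropped}", stacklevel=2)
    cols = [c for c in cols if c not in dropped]
    exog = sm.add_constant(design[cols])
    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.MixedLM(design[outcome], exog, groups=design["subject_id"])
            res = model.fit(reml=True)
        converged = bool(res.converged)
        resid_var = float(res.scale)
        if not np.isfinite(res.params[cols]).all() or resid_var < 1e-10:
            raise np.linalg.LinAlgError("degenerate mixed fit")
        return SymptomFitResult(
            params=res.params[["const"] + cols],
            bse=res.bse[["const"] + cols],
            pvalues=res.pvalues[["const"] + cols],
            converged=converged,
            singular=bool(resid_var < 1e-8),
            method="mixedlm_reml",
            dropped_columns=dropped,
            n_subjects=design["subject_id"].nunique(),
            n_obs=len(design),
        )
    except (np.linalg.LinAlgError, ValueError):
        singular = True
    # fallback: subject fixed effects absorb the random intercepts
    dummies = pd.get_dummies(design["subject_id"], prefix="subj", drop_first=True, dtype=float)
    X = pd.concat([sm.add_constant(design[cols]), dummies], axis=1)
    ols = sm.OLS(design[outcome], X).fit()
    keep = ["const"] + cols
    return SymptomFitResult(
        params=ols.params[keep],
        bse=ols.bse[keep],
        pvalues=ols.pvalues[keep],
        converged=True,
        singular=singular,
        method="ols_subject_dummies",
        dropped_columns=dropped,
        n_subjects=design["subject_id"].nunique(),
        n_obs=len(design),
    )


def null_variant_fit(
    series: pd.DataFrame,
    alt_changes: pd.DataFrame,
    t3_week: int = 4,
    t7_week: int = 7,
    outcome: str = "ids_total",
) -> SymptomFitResult:
    """Same regression with substituted change scores (e.g. learning rate or noise).

    ``alt_changes`` must carry subject_id, delta_pi_app, delta_pi_av columns
    holding the alternative per-subject change scores (the column names are
    kept so the design construction is shared with the primary model).
    """
    design = build_design(series, alt_changes, t3_week=t3_week, t7_week=t7_week)
    return fit_symptom_model(design, outcome=outcome)
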