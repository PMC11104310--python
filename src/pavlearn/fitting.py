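"""Hierarchical empirical-Bayes fitting of the go/no-go model family.

Subjects share an independent Gaussian prior on the transformed parameters.
Fitting alternates subject-level MAP estimation with a Laplace approximation
of each posterior (E-step) and closed-form updates of the prior mean and
diagonal variance from the Laplace moments (M-step).  Model comparison uses
the integrated BIC: the group-level log marginal likelihood, estimated by
Monte-Carlo sampling of each subject's likelihood under the fitted prior,
penalized with 2 prior hyperparameters (mean and variance) per model
parameter times log(total number of choices).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import _likelihood
from .models import ModelSpec, prepare_arrays, untransform
from .task import CONDITIONS, OutcomeRule

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-6


class FittingError(RuntimeError):
    """All optimization restarts failed for a subject."""


@dataclass
class GroupPrior:
    """Independent Gaussian prior on transformed parameters (diagonal covariance)."""

    mean: np.ndarray
    variance: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean and variance must have the same shape")
        if np.any(self.variance <= 0):
            raise ValueError("prior variance must be strictly positive")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.sd * rng.standard_normal((n, self.mean.size))

    def log_density(self, theta: np.ndarray) -> float:
        z = (theta - self.mean) ** 2 / self.variance
        return float(-0.5 * np.sum(z + np.log(self.variance) + _LOG_2PI))


@dataclass
class SubjectFit:
    """MAP estimate with Laplace curvature for one subject."""

    subject_id: str
    map_estimate: np.ndarray
    hessian: np.ndarray
    nll_at_mode: float
    n_trials: int
    log_marginal_laplace: float
    converged: bool = True

    @property
    def posterior_variance(self) -> np.ndarray:
        return np.diag(np.linalg.inv(self.hessian))


@dataclass
class GroupFit:
    """Result of the EM scheme: fitted prior, subject fits, iBIC."""

    spec: ModelSpec
    prior: GroupPrior
    subjects: list
    log_marginal: float
    ibic: float
    em_iterations: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    def map_parameters(self) -> dict:
        return {s.subject_id: untransform(s.map_estimate, self.spec) for s in self.subjects}


def _penalized_nll(theta: np.ndarray, arrays, spec: ModelSpec, prior: GroupPrior) -> float:
    stim, act, out, admin = arrays
    try:
        params = untransform(theta, spec)
    except ValueError:
        return 1e10
    logp = _likelihood.trial_log_probs(stim, act, out, admin, params.resolve(spec))
    nll = -logp.sum()
    penalty = 0.5 * np.sum((theta - prior.mean) ** 2 / prior.variance)
    val = nll + penalty
    return float(val) if np.isfinite(val) else 1e10


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _regularize_pd(H: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    H = 0.5 * (H + H.T)
    w, v = np.linalg.eigh(H)
    if np.all(w > floor):
        return H
    logger.debug("Hessian regularized: eigenvalues clipped at %g (min was %g)", floor, w.min())
    w = np.clip(w, floor, None)
    return v @ np.diag(w) @ v.T


def fit_subject_map(
    data,
    prior: GroupPrior,
    spec: ModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    x0: np.ndarray | None = None,
    subject_id: str = "subject",
) -> SubjectFit:
    """MAP fit of one subject: minimize NLL - log prior over transformed parameters.

    Best of ``n_restarts`` random starts drawn from the prior (plus the prior
    mean and, if given, a warm start ``x0``); curvature from a central-difference
    Hessian at the mode, eigenvalue-clipped to positive definite.
    """
    arrays = data if isinstance(data, tuple) else prepare_arrays(data)
    rng = np.random.default_rng(seed)
    starts = [prior.mean.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    starts.extend(prior.sample(max(n_restarts - 1, 0), rng))

    def objective(theta):
        return _penalized_nll(theta, arrays, spec, prior)

    best = None
    any_success = False
    for start in starts:
        try:
            res = minimize(objective, start, method="L-BFGS-B", options={"maxiter": 500})
        except Exception:  # noqa: BLE001 - a failed restart is not fatal
            continue
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(
            f"all {len(starts)} restarts failed for subject {subject_id!r} "
            f"(model {spec.name}, {arrays[0].size} trials)"
        )
    H = _regularize_pd(_numerical_hessian(objective, best.x))
    n_trials = arrays[0].size
    k = best.x.size
    # Laplace: log p(D|prior) ~ -penalized_nll(mode) - 0.5 sum(log var) - k/2 log(2pi)
    #          + k/2 log(2pi) - 0.5 logdet(H)  [prior normalizer + Gaussian integral]
    sign, logdet = np.linalg.slogdet(H)
    log_marg = -best.fun - 0.5 * float(np.sum(np.log(prior.variance))) - 0.5 * logdet
    nll_mode = best.fun - 0.5 * float(np.sum((best.x - prior.mean) ** 2 / prior.variance))
    return SubjectFit(
        subject_id=str(subject_id),
        map_estimate=best.x,
        hessian=H,
        nll_at_mode=float(nll_mode),
        n_trials=int(n_trials),
        log_marginal_laplace=float(log_marg),
        converged=bool(any_success),
    )


def default_init_prior(spec: ModelSpec, variance: float = 2.0) -> GroupPrior:
    """Weakly informative starting prior for EM (transformed scale)."""
    from scipy.special import logit

    means = {
        "alpha": logit(0.3), "alpha_win": logit(0.3), "alpha_loss": logit(0.3),
        "beta": 0.0, "b": 0.0,
        "xi": logit(0.1), "xi_win": logit(0.1), "xi_loss": logit(0.1),
        "pi": 0.0, "pi_app": 0.0, "pi_av": 0.0, "pi_app_post": 0.0, "pi_av_post": 0.0,
    }
    names = spec.parameter_names()
    return GroupPrior(
        mean=np.array([means[n] for n in names]),
        variance=np.full(len(names), variance),
        names=names,
    )


def em_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-3,
    max_iter: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    ibic_samples: int = 2000,
    init_prior: GroupPrior | None = None,
) -> GroupFit:
    """Empirical-Bayes EM over a cohort: subject MAP+Laplace, then prior update.

    Stops when the largest prior-mean change falls below ``tol`` or after
    ``max_iter`` iterations.  The EM surrogate objective (sum of Laplace log
    marginals) is monitored each iteration; a decrease of more than 0.5 nats
    aborts with diagnostics.
    """
    subjects = sorted(data["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("em_fit requires at least 2 subjects")
    arrays = {s: prepare_arrays(data[data["subject_id"] == s]) for s in subjects}
    prior = init_prior if init_prior is not None else default_init_prior(spec)
    names = spec.parameter_names()
    rng = np.random.default_rng(seed)

    fits: dict = {}
    trace = []
    prev_objective = -np.inf
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        restarts = n_restarts if iteration == 1 else 2
        for s in subjects:
            warm = fits[s].map_estimate if s in fits else None
            fits[s] = fit_subject_map(
                arrays[s], prior, spec,
                n_restarts=restarts,
                seed=int(rng.integers(2**31)),
                x0=warm,
                subject_id=s,
            )
        objective = float(sum(f.log_marginal_laplace for f in fits.values()))
        if objective < prev_objective - 0.5:
            raise RuntimeError(
                f"EM objective decreased by {prev_objective - objective:.3f} nats at "
                f"iteration {iteration} (model {spec.name}); prior mean {prior.mean}"
            )
        prev_objective = objective

        m = np.vstack([fits[s].map_estimate for s in subjects])
        pv = np.vstack([np.clip(fits[s].posterior_variance, 0.0, None) for s in subjects])
        new_mean = m.mean(axis=0)
        new_var = (m**2 + pv).mean(axis=0) - new_mean**2
        if np.any(new_var < _VAR_FLOOR):
            warnings.warn(
                f"prior variance floored at {_VAR_FLOOR} for "
                f"{[n for n, v in zip(names, new_var) if v < _VAR_FLOOR]}",
                stacklevel=2,
            )
            new_var = np.clip(new_var, _VAR_FLOOR, None)
        delta = float(np.max(np.abs(new_mean - prior.mean)))
        trace.append({"iteration": iteration, "objective": objective, "max_delta_mean": delta})
        prior = GroupPrior(mean=new_mean, variance=new_var, names=names)
        if delta < tol:
            converged = True
            break

    total_trials = sum(f.n_trials for f in fits.values())
    log_marginal = _mc_log_marginal(
        prior, [arrays[s] for s in subjects], spec, ibic_samples, int(rng.integers(2**31))
    )
    ibic = -2.0 * log_marginal + 2.0 * len(names) * np.log(total_trials)
    fit = GroupFit(
        spec=spec,
        prior=prior,
        subjects=[fits[s] for s in subjects],
        log_marginal=log_marginal,
        ibic=float(ibic),
        em_iterations=iteration,
        converged=converged,
        trace=trace,
    )
    assert np.isclose(
        fit.ibic, -2.0 * fit.log_marginal + 2.0 * len(names) * np.log(total_trials)
    )
    return fit


def _mc_log_marginal(prior: GroupPrior, subject_arrays, spec: ModelSpec, n_samples: int, seed: int) -> float:
    if n_samples < 100:
        warnings.warn("fewer than 100 Monte-Carlo samples: marginal estimate has high variance", stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = prior.sample(n_samples, rng)
    resolved = np.vstack([untransform(theta, spec).resolve(spec) for theta in draws])
    total = 0.0
    for stim, act, out, admin in subject_arrays:
        logliks = np.empty(n_samples)
        for k in range(n_samples):
            logliks[k] = _likelihood.trial_log_probs(stim, act, out, admin, resolved[k]).sum()
        total += logsumexp(logliks) - np.log(n_samples)
    return float(total)


def integrated_bic(fit: GroupFit, data: pd.DataFrame, n_samples: int = 2000, seed: int = 0) -> float:
    """Recompute iBIC = -2 log p(data | prior) + 2 k log(total trials) by Monte Carlo."""
    subjects = sorted(data["subject_id"].unique())
    arrays = [prepare_arrays(data[data["subject_id"] == s]) for s in subjects]
    log_marginal = _mc_log_marginal(fit.prior, arrays, fit.spec, n_samples, seed)
    total_trials = sum(a[0].size for a in arrays)
    return float(-2.0 * log_marginal + 2.0 * fit.spec.n_parameters * np.log(total_trials))


def mean_choice_probability(fit: GroupFit, data: pd.DataFrame) -> float:
    """Average per-trial probability of the observed choice at subject MAPs."""
    probs = []
    for sf in fit.subjects:
        sub = data[data["subject_id"] == sf.subject_id]
        params = untransform(sf.map_estimate, fit.spec)
        stim, act, out, admin = prepare_arrays(sub)
        logp = _likelihood.trial_log_probs(stim, act, out, admin, params.resolve(fit.spec))
        probs.append(np.exp(logp))
    return float(np.concatenate(probs).mean())


def compare_models(
    specs: list,
    data: pd.DataFrame,
    tol: float = 1e-3,
    max_iter: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    ibic_samples: int = 2000,
) -> pd.DataFrame:
    """Fit every spec with EM and rank by iBIC (lowest = most parsimonious).

    Returns a table with iBIC, delta-iBIC to the best model, and the mean
    posterior choice probability per model; models that fail to fit are
    recorded with NaN and excluded from the ranking.
    """
    if len(specs) < 2:
        raise ValueError("compare_models requires at least 2 model specs")
    rows = []
    fits = {}
    for i, spec in enumerate(specs):
        try:
            fit = em_fit(
                data, spec, tol=tol, max_iter=max_iter, seed=seed + i,
                n_restarts=n_restarts, ibic_samples=ibic_samples,
            )
        except Exception as exc:  # noqa: BLE001 - failures are reported, not fatal
            warnings.warn(f"model {spec.name} failed to fit: {exc}", stacklevel=2)
            rows.append({"model": spec.name, "ibic": np.nan, "mean_choice_prob": np.nan,
                         "converged": False, "failed": True})
            continue
        fits[spec.name] = fit
        rows.append({
            "model": spec.name,
            "ibic": fit.ibic,
            "mean_choice_prob": mean_choice_probability(fit, data),
            "converged": fit.converged,
            "failed": False,
        })
    table = pd.DataFrame(rows)
    best = table.loc[~table["failed"], "ibic"].min()
    table["delta_ibic"] = table["ibic"] - best
    table = table.sort_values("ibic", na_position="last").reset_index(drop=True)
    table.attrs["fits"] = fits
    table.attrs["best_model"] = table.iloc[0]["model"]
    return table


def posterior_predictive(
    fit: GroupFit,
    data: pd.DataFrame,
    n_sims: int = 20,
    seed: int = 0,
    rule: OutcomeRule | None = None,
):
    """Observed vs model-simulated go-rate learning curves per condition.

    For each subject, the observed condition sequences are replayed
    ``n_sims`` times through the model at the subject's MAP parameters
    (outcomes redrawn from *rule* — pass the rule that generated the data;
    the default matches the synthetic cohort generator).  Curves aggregate
    go-rate by condition and within-condition trial position across
    subjects and administrations.
    """
    rule = rule if rule is not None else OutcomeRule.conventional()
    rule_probs = rule.prob_array()
    rng = np.random.default_rng(seed)

    obs_frames = []
    pred_frames = []
    for sf in fit.subjects:
        sub = data[data["subject_id"] == sf.subject_id]
        stim, act, out, admin = prepare_arrays(sub)
        p10 = untransform(sf.map_estimate, fit.spec).resolve(fit.spec)
        # within-condition position per administration
        pos = np.empty(stim.size, dtype=np.int64)
        for a in np.unique(admin):
            mask = admin == a
            for c in range(4):
                cm = mask & (stim == c)
                pos[cm] = np.arange(1, cm.sum() + 1)
        obs_frames.append(pd.DataFrame({"condition": stim, "position": pos, "go": (act == 0).astype(float)}))
        for _ in range(n_sims):
            sim_act, _ = _likelihood.simulate_actions(stim, admin, p10, rule_probs, int(rng.integers(2**31)))
            pred_frames.append(
                pd.DataFrame({"condition": stim, "position": pos, "go": (sim_act == 0).astype(float)})
            )

    def _curve(frames):
        df = pd.concat(frames, ignore_index=True)
        cur = df.groupby(["condition", "position"])["go"].mean().reset_index(name="go_rate")
        cur["condition"] = [CONDITIONS[c].name for c in cur["condition"]]
        return cur

    return _curve(obs_frames), _curve(pred_frames)


def learning_curve_mad(observed: pd.DataFrame, predicted: pd.DataFrame) -> dict:
    """Mean absolute deviation between observed and predicted curves, per condition."""
    merged = observed.merge(predicted, on=["condition", "position"], suffixes=("_obs", "_pred"))
    mad = merged.groupby("condition").apply(
        lambda g: float(np.mean(np.abs(g["go_rate_obs"] - g["go_rate_pred"]))),
        include_groups=False,
    )
    return mad.to_dict()
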