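"""Ground-truth generators for every pipeline input.

Task cohorts are drawn from a Gaussian prior over transformed model
parameters and simulated through the generative go/no-go agents; diary
cohorts hold latent per-activity reward/punishment expectations updated by
prediction errors and drive next-day activity choice; symptom cohorts follow
the step + parameter-change design of the symptom regression.  Every
generator is deterministic under its seed and returns a truth object
sufficient to regenerate the data and to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit, softmax

from .fitting import GroupPrior
from .models import Agent, ModelSpec, untransform
from .symptoms import build_design
from .task import OutcomeRule, generate_schedule, records_to_frame, simulate_session


def default_task_prior(spec: ModelSpec) -> GroupPrior:
    """Realistic group prior on the transformed scale (SD 0.5 per parameter).

    Means: alpha 0.2, beta 3, go bias 0.3, lapse 0.05, Pavlovian weights 0.5
    rising to 1.0 after their respective therapy phases.  These produce the
    canonical accuracy ordering (congruent > incongruent, worst no-go-to-win).
    """
    means = {
        "alpha": logit(0.2), "alpha_win": logit(0.2), "alpha_loss": logit(0.2),
        "beta": np.log(3.0), "b": 0.3,
        "xi": logit(0.05), "xi_win": logit(0.05), "xi_loss": logit(0.05),
        "pi": 0.5, "pi_app": 0.5, "pi_av": 0.5,
        "pi_app_post": 1.0, "pi_av_post": 1.0,
    }
    names = spec.parameter_names()
    return GroupPrior(
        mean=np.array([means[n] for n in names]),
        variance=np.full(len(names), 0.25),
        names=names,
    )


def _default_rt_sampler(rng: np.random.Generator) -> float:
    return float(np.clip(rng.lognormal(mean=np.log(0.55), sigma=0.25), 0.15, 2.5))


@dataclass
class CohortTruth:
    """Everything needed to regenerate a task cohort and score recovery."""

    spec: ModelSpec
    prior: GroupPrior
    seed: int
    theta: np.ndarray = field(repr=False)  # n_subjects x n_params, transformed scale
    subject_ids: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def parameters(self) -> dict:
        return {sid: untransform(t, self.spec) for sid, t in zip(self.subject_ids, self.theta)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.to_dict(),
                "prior": {"mean": self.prior.mean.tolist(), "variance": self.prior.variance.tolist(),
                          "names": self.prior.names},
                "seed": self.seed,
                "theta": self.theta.tolist(),
                "subject_ids": self.subject_ids,
                "settings": self.settings,
            },
            indent=2,
        )


def gen_task_cohort(
    n_subjects: int = 12,
    prior: GroupPrior | None = None,
    spec: ModelSpec | None = None,
    n_administrations: int = 5,
    n_per_condition: int = 60,
    seed: int = 0,
    rule: OutcomeRule | None = None,
    with_rt: bool = True,
):
    """Simulate a cohort through repeated task administrations.

    Subjects are drawn from *prior* (default :func:`default_task_prior`);
    session-varying Pavlovian weights take effect per administration.  The
    default outcome rule is the ``conventional`` coding (win stimuli deliver
    reward/nothing, loss stimuli loss/nothing): it is the coding under which
    win stimuli accumulate positive Pavlovian value and the canonical
    accuracy ordering (worst condition no-go-to-win) emerges.  Under the
    ``paper_text`` coding, wrong go responses at win stimuli are punished
    with losses, the stimulus value turns negative, and the Pavlovian
    conflict largely disappears.
    Returns (trials DataFrame, CohortTruth).
    """
    spec = spec if spec is not None else ModelSpec.from_name("RW+noise+bias+2Pav+session")
    prior = prior if prior is not None else default_task_prior(spec)
    rule = rule if rule is not None else OutcomeRule.conventional()
    rng = np.random.default_rng(seed)
    theta = prior.sample(n_subjects, rng)
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    frames = []
    rt_sampler = _default_rt_sampler if with_rt else None
    for sid, t in zip(subject_ids, theta):
        params = untransform(t, spec)
        for admin in range(1, n_administrations + 1):
            schedule = generate_schedule(n_per_condition, seed=int(rng.integers(2**31)))
            agent = Agent(params, spec, administration=admin)
            records = simulate_session(
                agent, schedule, rule,
                seed=int(rng.integers(2**31)),
                subject_id=sid,
                administration=admin,
                rt_sampler=rt_sampler,
            )
            frames.append(records_to_frame(records))
    trials = pd.concat(frames, ignore_index=True)
    truth = CohortTruth(
        spec=spec, prior=prior, seed=seed, theta=theta, subject_ids=subject_ids,
        settings={"n_administrations": n_administrations, "n_per_condition": n_per_condition,
                  "outcome_rule_variant": rule.variant, "dominant_prob": rule.dominant_prob},
    )
    return trials, truth


@dataclass
class GoalTruth:
    seed: int
    update_rates: pd.Series
    true_reward: np.ndarray = field(repr=False)
    true_punishment: np.ndarray = field(repr=False)
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "update_rates": self.update_rates.to_dict(),
                "true_reward": self.true_reward.tolist(),
                "true_punishment": self.true_punishment.tolist(),
                "settings": self.settings,
            },
            indent=2,
        )


def gen_goal_cohort(
    n_subjects: int = 12,
    n_days: int = 56,
    n_activities: int = 14,
    update_rate_mean: float = 0.7,
    update_rate_sd: float = 0.1,
    rating_noise_sd: float = 0.25,
    experience_noise_sd: float = 1.5,
    choice_temperature: float = 1.0,
    scale: tuple = (0, 10),
    seed: int = 0,
    item_change: pd.Series | None = None,
    item_coupling: float = 0.0,
    choice_mode: str = "softmax",
    repeat_coeffs: tuple = (-1.0, 0.4, 0.0),
    round_ratings: bool = True,
):
    """Simulate activity diaries with delta-rule expectation updating.

    Each agent holds latent expectations R_a, P_a per activity (initialized
    mid-scale), reports a noisy clipped/rounded reading of them before and
    after each completion, experiences outcomes around fixed latent activity
    values, and updates by ``R_a += rho * (r - R_a)`` with per-subject update
    rate rho ~ N(update_rate_mean + item_coupling * item_change, sd).  The
    next day's activity is chosen by softmax over R_a (``choice_mode =
    'softmax'``) or by a stay/switch rule whose stay probability is
    ``logistic(c0 + c_r * r + c_p * p)`` (``'repeat_logistic'``).
    Returns (diary DataFrame, GoalTruth).
    """
    if choice_mode not in ("softmax", "repeat_logistic"):
        raise ValueError("choice_mode must be 'softmax' or 'repeat_logistic'")
    rng = np.random.default_rng(seed)
    lo, hi = scale
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    categories = ["emotional", "mental", "physical", "pleasure", "sensory", "social", "spiritual"]
    if item_change is None:
        item_change = pd.Series(0.0, index=subject_ids)
    rates = np.clip(
        update_rate_mean
        + item_coupling * item_change.reindex(subject_ids).to_numpy()
        + update_rate_sd * rng.standard_normal(n_subjects),
        0.02, 1.0,
    )
    true_R = rng.uniform(lo + 1, hi - 1, size=(n_subjects, n_activities))
    true_P = rng.uniform(lo + 1, hi - 4, size=(n_subjects, n_activities))

    def report(x):
        noisy = x + rating_noise_sd * rng.standard_normal()
        if round_ratings:
            noisy = np.round(noisy)
        return float(np.clip(noisy, lo, hi))

    rows = []
    mid = (lo + hi) / 2.0
    for si, sid in enumerate(subject_ids):
        R = np.full(n_activities, mid)
        P = np.full(n_activities, mid)
        rho = rates[si]
        act = int(rng.integers(n_activities))
        for day in range(1, n_days + 1):
            R_pre, P_pre = report(R[act]), report(P[act])
            r_latent = true_R[si, act] + experience_noise_sd * rng.standard_normal()
            p_latent = true_P[si, act] + experience_noise_sd * rng.standard_normal()
            r_obs, p_obs = report(r_latent), report(p_latent)
            R[act] += rho * (r_obs - R[act])
            P[act] += rho * (p_obs - P[act])
            rows.append(
                {
                    "subject_id": sid, "day": day,
                    "activity_id": f"A{act:02d}",
                    "category": categories[act % len(categories)],
                    "R_pre": R_pre, "P_pre": P_pre, "r": r_obs, "p": p_obs,
                    "R_post1": report(R[act]), "P_post1": report(P[act]),
                }
            )
            if choice_mode == "softmax":
                probs = softmax(R / max(choice_temperature, 1e-6))
                act = int(rng.choice(n_activities, p=probs))
            else:
                c0, cr, cp = repeat_coeffs
                stay = 1.0 / (1.0 + np.exp(-(c0 + cr * r_obs + cp * p_obs)))
                if rng.random() >= stay:
                    others = [a for a in range(n_activities) if a != act]
                    act = int(rng.choice(others))
    diary = pd.DataFrame(rows)
    truth = GoalTruth(
        seed=seed,
        update_rates=pd.Series(rates, index=subject_ids, name="update_rate"),
        true_reward=true_R,
        true_punishment=true_P,
        settings={
            "n_days": n_days, "n_activities": n_activities, "scale": list(scale),
            "update_rate_mean": update_rate_mean, "update_rate_sd": update_rate_sd,
            "rating_noise_sd": rating_noise_sd, "experience_noise_sd": experience_noise_sd,
            "choice_mode": choice_mode, "choice_temperature": choice_temperature,
            "item_coupling": item_coupling,
        },
    )
    return diary, truth


@dataclass
class SymptomTruth:
    seed: int
    weights: np.ndarray
    intercepts: pd.Series
    changes: pd.DataFrame = field(repr=False)
    settings: dict = field(default_factory=dict)


def gen_symptom_cohort(
    n_subjects: int = 12,
    weeks: list | None = None,
    weights: tuple = (-5.0, -4.0, -2.0, -2.0),
    delta_pi: pd.DataFrame | None = None,
    noise_sd: float = 2.0,
    intercept_mean: float = 34.5,
    intercept_sd: float = 6.0,
    t3_week: int = 4,
    t7_week: int = 7,
    seed: int = 0,
    item_coupling_source: pd.Series | None = None,
):
    """Weekly IDS-SR totals from the step + Pavlovian-change design.

    ids_total = subject intercept + weights . (step3, step7, app_change,
    av_change) + Gaussian noise, clipped to the 0-84 instrument range.
    ``delta_pi`` supplies per-subject delta_pi_app / delta_pi_av (defaults to
    draws around the task-prior change of 0.5 with SD ~0.7).  Items 19/21
    are integer 0-3 series; if ``item_coupling_source`` (a per-subject
    score) is given, item changes track its ranking so interaction analyses
    have ground truth.
    Returns (symptom DataFrame, SymptomTruth).
    """
    weeks = list(weeks) if weeks is not None else list(range(10))
    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    if delta_pi is None:
        delta_pi = pd.DataFrame(
            {
                "subject_id": subject_ids,
                "delta_pi_app": 0.5 + np.sqrt(0.5) * rng.standard_normal(n_subjects),
                "delta_pi_av": 0.5 + np.sqrt(0.5) * rng.standard_normal(n_subjects),
            }
        )
    intercepts = pd.Series(
        intercept_mean + intercept_sd * rng.standard_normal(n_subjects), index=subject_ids
    )
    series = pd.DataFrame(
        [{"subject_id": sid, "week": w} for sid in subject_ids for w in weeks]
    )
    design = build_design(series, delta_pi, t3_week=t3_week, t7_week=t7_week)
    w = np.asarray(weights, dtype=float)
    X = design[["step3", "step7", "app_change", "av_change"]].to_numpy()
    ids = (
        design["subject_id"].map(intercepts).to_numpy()
        + X @ w
        + noise_sd * rng.standard_normal(len(design))
    )
    design = design.copy()
    design["ids_total"] = np.clip(ids, 0, 84)

    # anhedonia items: start moderate-severe, improve over weeks
    if item_coupling_source is not None:
        ranks = item_coupling_source.reindex(subject_ids).rank(pct=True).to_numpy()
    else:
        ranks = rng.uniform(size=n_subjects)
    improvement = pd.Series(np.round(3 * ranks), index=subject_ids)  # 0..3 drop over therapy
    frac = (design["week"] - design["week"].min()) / max(design["week"].max() - design["week"].min(), 1)
    base19 = 3.0
    item = np.clip(np.round(base19 - design["subject_id"].map(improvement) * frac), 0, 3)
    design["item19"] = item.astype(int)
    design["item21"] = item.astype(int)

    out = design[["subject_id", "week", "ids_total", "item19", "item21"]].copy()
    truth = SymptomTruth(
        seed=seed,
        weights=w,
        intercepts=intercepts,
        changes=delta_pi,
        settings={"weeks": weeks, "noise_sd": noise_sd, "t3_week": t3_week, "t7_week": t7_week},
    )
    return out, truth
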