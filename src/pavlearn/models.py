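"""The nested Rescorla-Wagner / Pavlovian model family for go/no-go choice.

Choice probabilities are a softmax over a go and a no-go action value,
optionally mixed with uniform noise (lapse rate xi).  Action values combine
an instrumental Q, learned per (action, stimulus) by a delta rule
``Q <- Q + alpha * (beta * r - Q)``, a fixed additive go bias ``b``, and a
Pavlovian term ``pi * V(s)`` added to the go value only, where the stimulus
value V follows the same delta rule irrespective of action.  The dual
variant carries separate appetitive (win-stimulus) and aversive
(loss-stimulus) Pavlovian weights, and the session-varying variant lets the
appetitive weight change from administration 3 and the aversive weight from
administration 4 onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import _likelihood
from .task import GO, MISSED, NOGO, Condition

PAVLOVIAN_MODES = ("none", "single", "dual")

#: Canonical nested family, simplest to richest.
MODEL_NAMES = (
    "RW",
    "RW+noise",
    "RW+noise+bias",
    "RW+noise+bias+Pav",
    "RW+noise+bias+2Pav",
    "RW+noise+bias+2Pav+session",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which model components are active; determines the free parameters."""

    has_noise: bool = True
    has_bias: bool = True
    pavlovian: str = "dual"
    session_varying: bool = False
    shared_learning_rate: bool = True
    valenced_noise: bool = False

    def __post_init__(self) -> None:
        if self.pavlovian not in PAVLOVIAN_MODES:
            raise ValueError(f"pavlovian must be one of {PAVLOVIAN_MODES}")
        if self.session_varying and self.pavlovian != "dual":
            raise ValueError("session_varying requires pavlovian='dual'")
        if self.valenced_noise and not self.has_noise:
            raise ValueError("valenced_noise requires has_noise")

    def parameter_names(self) -> list:
        names = ["alpha"] if self.shared_learning_rate else ["alpha_win", "alpha_loss"]
        names.append("beta")
        if self.has_bias:
            names.append("b")
        if self.has_noise:
            names.extend(["xi"] if not self.valenced_noise else ["xi_win", "xi_loss"])
        if self.pavlovian == "single":
            names.append("pi")
        elif self.pavlovian == "dual":
            names.extend(["pi_app", "pi_av"])
        if self.session_varying:
            names.extend(["pi_app_post", "pi_av_post"])
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names())

    @property
    def name(self) -> str:
        for key, spec in _CANONICAL.items():
            if spec == self:
                return key
        parts = ["RW"]
        if self.has_noise:
            parts.append("noise" if not self.valenced_noise else "2noise")
        if self.has_bias:
            parts.append("bias")
        if self.pavlovian == "single":
            parts.append("Pav")
        elif self.pavlovian == "dual":
            parts.append("2Pav")
        if self.session_varying:
            parts.append("session")
        if not self.shared_learning_rate:
            parts.append("2alpha")
        return "+".join(parts)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return _CANONICAL[name]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}") from None

    def to_dict(self) -> dict:
        return {
            "has_noise": self.has_noise,
            "has_bias": self.has_bias,
            "pavlovian": self.pavlovian,
            "session_varying": self.session_varying,
            "shared_learning_rate": self.shared_learning_rate,
            "valenced_noise": self.valenced_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


_CANONICAL = {
    "RW": ModelSpec(has_noise=False, has_bias=False, pavlovian="none"),
    "RW+noise": ModelSpec(has_noise=True, has_bias=False, pavlovian="none"),
    "RW+noise+bias": ModelSpec(has_noise=True, has_bias=True, pavlovian="none"),
    "RW+noise+bias+Pav": ModelSpec(has_noise=True, has_bias=True, pavlovian="single"),
    "RW+noise+bias+2Pav": ModelSpec(has_noise=True, has_bias=True, pavlovian="dual"),
    "RW+noise+bias+2Pav+session": ModelSpec(
        has_noise=True, has_bias=True, pavlovian="dual", session_varying=True
    ),
}


@dataclass
class Parameters:
    """Subject-level parameter values on their natural scales.

    ``pi_app`` doubles as the single Pavlovian weight for single-``pi``
    models.  Post-change values default to the pre values when absent.
    """

    alpha: float = 0.2
    beta: float = 3.0
    b: float = 0.0
    xi: float = 0.05
    pi_app: float = 0.0
    pi_av: float = 0.0
    pi_app_post: float | None = None
    pi_av_post: float | None = None
    alpha_loss: float | None = None
    xi_loss: float | None = None

    def resolve(self, spec: ModelSpec) -> np.ndarray:
        """Resolved 10-slot kernel vector (see ``_likelihood``), with inactive
        components at neutral values."""
        a_win = self.alpha
        a_loss = a_win if self.shared_alpha(spec) else self.alpha_loss
        xi_win = self.xi if spec.has_noise else 0.0
        xi_loss = xi_win if not spec.valenced_noise else self.xi_loss
        b = self.b if spec.has_bias else 0.0
        if spec.pavlovian == "none":
            pa = pv = 0.0
        elif spec.pavlovian == "single":
            pa = pv = self.pi_app
        else:
            pa, pv = self.pi_app, self.pi_av
        if spec.session_varying:
            pa_post = pa if self.pi_app_post is None else self.pi_app_post
            pv_post = pv if self.pi_av_post is None else self.pi_av_post
        else:
            pa_post, pv_post = pa, pv
        return np.array(
            [a_win, a_loss, self.beta, b, xi_win, xi_loss, pa, pv, pa_post, pv_post],
            dtype=float,
        )

    def shared_alpha(self, spec: ModelSpec) -> bool:
        return spec.shared_learning_rate or self.alpha_loss is None


# name -> (Parameters attribute, transform kind)
_PARAM_MAP = {
    "alpha": ("alpha", "logit"),
    "alpha_win": ("alpha", "logit"),
    "alpha_loss": ("alpha_loss", "logit"),
    "beta": ("beta", "log"),
    "b": ("b", "id"),
    "xi": ("xi", "logit"),
    "xi_win": ("xi", "logit"),
    "xi_loss": ("xi_loss", "logit"),
    "pi": ("pi_app", "id"),
    "pi_app": ("pi_app", "id"),
    "pi_av": ("pi_av", "id"),
    "pi_app_post": ("pi_app_post", "id"),
    "pi_av_post": ("pi_av_post", "id"),
}


def transform(params: Parameters, spec: ModelSpec) -> np.ndarray:
    """Map natural-scale parameters to the unconstrained fitting scale.

    Unit-interval parameters (alpha, xi) go through the logit, positive beta
    through the log; bias and Pavlovian weights are unconstrained already.
    """
    out = np.empty(spec.n_parameters)
    for i, name in enumerate(spec.parameter_names()):
        attr, kind = _PARAM_MAP[name]
        v = getattr(params, attr)
        if v is None or not np.isfinite(v):
            raise ValueError(f"parameter {name} is missing or non-finite")
        if kind == "logit":
            out[i] = logit(v)
        elif kind == "log":
            out[i] = np.log(v)
        else:
            out[i] = v
        if not np.isfinite(out[i]):
            raise ValueError(f"parameter {name}={v} maps to non-finite value")
    return out


def untransform(vector: np.ndarray, spec: ModelSpec) -> Parameters:
    """Inverse of :func:`transform` (exact bijection on the open domains)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (spec.n_parameters,):
        raise ValueError(f"expected vector of length {spec.n_parameters}, got {vector.shape}")
    if not np.all(np.isfinite(vector)):
        raise ValueError("non-finite values in parameter vector")
    params = Parameters(alpha=0.5, beta=1.0, b=0.0, xi=0.0, pi_app=0.0, pi_av=0.0)
    values = {}
    for name, x in zip(spec.parameter_names(), vector):
        attr, kind = _PARAM_MAP[name]
        if kind == "logit":
            values[attr] = float(expit(x))
        elif kind == "log":
            values[attr] = float(np.exp(x))
        else:
            values[attr] = float(x)
    return replace(params, **values)


def effective_pavlovian(params: Parameters, spec: ModelSpec, administration: int) -> tuple:
    """Appetitive/aversive Pavlovian weights in force at *administration*.

    The appetitive weight switches to its post value from administration 3,
    the aversive weight from administration 4; passthrough when the model is
    not session-varying.
    """
    if not 1 <= administration <= 5:
        raise ValueError(f"administration must be in 1..5, got {administration}")
    p = params.resolve(spec)
    pi_app = p[8] if administration >= 3 else p[6]
    pi_av = p[9] if administration >= 4 else p[7]
    return float(pi_app), float(pi_av)


@dataclass
class LearnerState:
    """Instrumental Q (action x stimulus) and Pavlovian V (stimulus) tables."""

    Q: np.ndarray
    V: np.ndarray

    @classmethod
    def zeros(cls) -> "LearnerState":
        return cls(Q=np.zeros((2, 4)), V=np.zeros(4))

    def copy(self) -> "LearnerState":
        return LearnerState(Q=self.Q.copy(), V=self.V.copy())


def action_values(
    state: LearnerState,
    stimulus: Condition,
    params: Parameters,
    spec: ModelSpec,
    administration: int = 1,
) -> tuple:
    """(go, nogo) action values: Q + bias + pi * V for go, plain Q for nogo."""
    p = params.resolve(spec)
    s = stimulus.value
    pi_app = p[8] if administration >= 3 else p[6]
    pi_av = p[9] if administration >= 4 else p[7]
    pi = pi_app if stimulus.valence == "win" else pi_av
    go_value = state.Q[0, s] + p[3] + pi * state.V[s]
    nogo_value = state.Q[1, s]
    return float(go_value), float(nogo_value)


def action_probabilities(values, xi: float = 0.0) -> np.ndarray:
    """Two-action softmax mixed with uniform noise: p*(1-xi) + xi/2.

    Overflow-guarded by max subtraction; each probability lies in
    [xi/2, 1 - xi/2] and the pair sums to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (2,) or not np.all(np.isfinite(v)):
        raise ValueError("values must be a finite pair")
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    e = np.exp(v - v.max())
    p = e / e.sum()
    return p * (1.0 - xi) + xi / 2.0


def update_state(
    state: LearnerState,
    stimulus: Condition,
    action: str,
    outcome: int,
    params: Parameters,
    spec: ModelSpec | None = None,
) -> LearnerState:
    """Delta-rule update of Q(action, stimulus) and V(stimulus); returns a new state.

    Missed actions leave the state untouched (callers that treat misses as
    no-go substitute the action before calling).
    """
    if action == MISSED:
        return state.copy()
    if action not in (GO, NOGO):
        raise ValueError(f"action must be go/nogo/missed, got {action!r}")
    spec = spec if spec is not None else ModelSpec()
    p = params.resolve(spec)
    alpha = p[0] if stimulus.valence == "win" else p[1]
    new = state.copy()
    ai = 0 if action == GO else 1
    s = stimulus.value
    target = p[2] * outcome
    new.Q[ai, s] += alpha * (target - new.Q[ai, s])
    new.V[s] += alpha * (target - new.V[s])
    return new


_ACTION_CODE = {GO: 0, NOGO: 1, MISSED: 1}


def prepare_arrays(data, missed_as_nogo: bool = True):
    """Convert trial data (DataFrame or TrialRecord list) to kernel arrays.

    Returns (stim, act, out, admin) int/float arrays ordered as given.
    Raises on data not grouped by administration with increasing trial_index.
    """
    if not isinstance(data, pd.DataFrame):
        from .task import records_to_frame

        data = records_to_frame(data)
    if len(data) == 0:
        raise ValueError("empty trial data")
    admin = data["administration"].to_numpy(dtype=np.int64)
    tidx = data["trial_index"].to_numpy(dtype=np.int64)
    # administrations must form contiguous blocks with increasing trial_index
    change = np.flatnonzero(np.diff(admin) != 0)
    seen = set()
    start = 0
    for c in list(change) + [len(admin) - 1]:
        a = admin[start]
        if a in seen:
            raise ValueError("trial data must be grouped by administration")
        seen.add(a)
        block = tidx[start : c + 1]
        if np.any(np.diff(block) <= 0):
            raise ValueError(f"trial_index must increase within administration {a}")
        start = c + 1
    cond = data["condition"]
    if cond.dtype == object and isinstance(cond.iloc[0], Condition):
        stim = np.array([c.value for c in cond], dtype=np.int64)
    else:
        stim = np.array([Condition[c].value for c in cond], dtype=np.int64)
    if not missed_as_nogo and (data["action"] == MISSED).any():
        keep = (data["action"] != MISSED).to_numpy()
        data = data[keep]
        return prepare_arrays(data, missed_as_nogo=True)
    act = np.array([_ACTION_CODE[a] for a in data["action"]], dtype=np.int64)
    out = data["outcome"].to_numpy(dtype=np.float64)
    return stim, act, out, admin


def trial_log_likelihoods(data, params: Parameters, spec: ModelSpec, missed_as_nogo: bool = True) -> np.ndarray:
    """Per-trial log probability of each observed action under the model."""
    stim, act, out, admin = prepare_arrays(data, missed_as_nogo=missed_as_nogo)
    return _likelihood.trial_log_probs(stim, act, out, admin, params.resolve(spec))


def negative_log_likelihood(data, params: Parameters, spec: ModelSpec, missed_as_nogo: bool = True) -> float:
    """-sum log p(action_t | state_t), with state reset at each administration."""
    return float(-trial_log_likelihoods(data, params, spec, missed_as_nogo).sum())


class Agent:
    """Stateful generative policy for :func:`pavlearn.task.simulate_session`.

    Mirrors the likelihood kernel trial-for-trial (tested for exact
    agreement): call to get action probabilities, ``observe`` to learn.
    """

    def __init__(self, params: Parameters, spec: ModelSpec, administration: int = 1):
        if not 1 <= administration <= 5:
            raise ValueError("administration must be in 1..5")
        self.params = params
        self.spec = spec
        self.administration = administration
        self._p = params.resolve(spec)
        self.state = LearnerState.zeros()

    def reset(self) -> None:
        self.state = LearnerState.zeros()

    def __call__(self, condition: Condition) -> np.ndarray:
        values = action_values(self.state, condition, self.params, self.spec, self.administration)
        xi = self._p[4] if condition.valence == "win" else self._p[5]
        return action_probabilities(values, xi)

    def observe(self, condition: Condition, action: str, outcome: int) -> None:
        if action == MISSED:
            action = NOGO
        self.state = update_state(self.state, condition, action, outcome, self.params, self.spec)


def make_agent(params: Parameters, spec: ModelSpec, administration: int = 1) -> Agent:
    """Generative agent sampling from the model's choice probabilities."""
    return Agent(params, spec, administration)
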