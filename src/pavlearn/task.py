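"""Orthogonalized Go/No-Go task: conditions, outcome rules, schedules, simulation.

The task crosses required action (go / no-go) with outcome valence (win /
avoid-loss) into four conditions, decorrelating action requirements from
outcome valence.  Feedback is probabilistic: the correct action yields the
better of the two possible outcomes with probability ``dominant_prob``
(default 0.8).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

GO = "go"
NOGO = "nogo"
MISSED = "missed"

#: Possible trial outcomes: loss, neutral, reward.
OUTCOMES = (-1, 0, 1)


class Condition(enum.Enum):
    """One of the four task conditions (2 valences x 2 correct actions)."""

    GO_WIN = 0
    NOGO_WIN = 1
    GO_AVOID = 2
    NOGO_AVOID = 3

    @property
    def valence(self) -> str:
        """'win' for reward conditions, 'loss' for loss-avoidance conditions."""
        return "win" if self.value < 2 else "loss"

    @property
    def correct_action(self) -> str:
        return GO if self in (Condition.GO_WIN, Condition.GO_AVOID) else NOGO

    @property
    def congruent(self) -> bool:
        """Pavlovian-congruent: go-to-win and no-go-to-avoid."""
        return self in (Condition.GO_WIN, Condition.NOGO_AVOID)


CONDITIONS = tuple(Condition)
CONDITION_NAMES = tuple(c.name for c in CONDITIONS)


@dataclass
class OutcomeRule:
    """Mapping (condition, action) -> distribution over outcomes {-1, 0, +1}.

    Two variants exist. ``paper_text``: in win conditions the wrong action
    yields a loss with the dominant probability (and a reward otherwise);
    ``conventional``: win conditions only ever deliver reward/nothing and
    loss conditions loss/nothing.
    """

    table: dict = field(repr=False)
    dominant_prob: float = 0.8
    variant: str = "paper_text"

    def __post_init__(self) -> None:
        for key, probs in self.table.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"outcome distribution for {key} must be 3 probabilities summing to 1")
            self.table[key] = probs
        for cond in CONDITIONS:
            for action in (GO, NOGO):
                if (cond, action) not in self.table:
                    raise ValueError(f"outcome rule missing entry for ({cond.name}, {action})")
        # correct action must yield its better outcome with dominant_prob
        for cond in CONDITIONS:
            probs = self.table[(cond, cond.correct_action)]
            best = 2 if cond.valence == "win" else 1  # +1 for win conds, 0 for loss conds
            if not np.isclose(probs[best], self.dominant_prob):
                raise ValueError(
                    f"correct action in {cond.name} must give the better outcome "
                    f"with probability {self.dominant_prob}"
                )

    @classmethod
    def paper_text(cls, dominant_prob: float = 0.8) -> "OutcomeRule":
        p, q = dominant_prob, 1.0 - dominant_prob
        table = {}
        for cond in CONDITIONS:
            wrong = NOGO if cond.correct_action == GO else GO
            if cond.valence == "win":
                table[(cond, cond.correct_action)] = [0.0, q, p]  # +1 w.p. p, 0 otherwise
                table[(cond, wrong)] = [p, 0.0, q]                # -1 w.p. p, +1 otherwise
            else:
                table[(cond, cond.correct_action)] = [q, p, 0.0]  # 0 w.p. p, -1 otherwise
                table[(cond, wrong)] = [p, q, 0.0]                # -1 w.p. p, 0 otherwise
        return cls(table=table, dominant_prob=dominant_prob, variant="paper_text")

    @classmethod
    def conventional(cls, dominant_prob: float = 0.8) -> "OutcomeRule":
        p, q = dominant_prob, 1.0 - dominant_prob
        table = {}
        for cond in CONDITIONS:
            wrong = NOGO if cond.correct_action == GO else GO
            if cond.valence == "win":
                table[(cond, cond.correct_action)] = [0.0, q, p]
                table[(cond, wrong)] = [0.0, p, q]
            else:
                table[(cond, cond.correct_action)] = [q, p, 0.0]
                table[(cond, wrong)] = [p, q, 0.0]
        return cls(table=table, dominant_prob=dominant_prob, variant="conventional")

    @classmethod
    def from_variant(cls, variant: str, dominant_prob: float = 0.8) -> "OutcomeRule":
        if variant == "paper_text":
            return cls.paper_text(dominant_prob)
        if variant == "conventional":
            return cls.conventional(dominant_prob)
        raise ValueError(f"unknown outcome rule variant {variant!r}")

    def prob_array(self) -> np.ndarray:
        """(4 conditions, 2 actions, 3 outcomes) probability array."""
        out = np.zeros((4, 2, 3))
        for cond in CONDITIONS:
            for ai, action in enumerate((GO, NOGO)):
                out[cond.value, ai] = self.table[(cond, action)]
        return out

    def sample(self, condition: Condition, action: str, rng: np.random.Generator) -> int:
        if action not in (GO, NOGO):
            raise ValueError(f"action must be 'go' or 'nogo', got {action!r}")
        probs = self.table[(condition, action)]
        return int(rng.choice(OUTCOMES, p=probs))

    def expected_outcome(self, condition: Condition, action: str) -> float:
        return float(np.dot(self.table[(condition, action)], OUTCOMES))


def sample_outcome(condition: Condition, action: str, rule: OutcomeRule, rng: np.random.Generator) -> int:
    """Draw one probabilistic outcome for (condition, action) under *rule*."""
    return rule.sample(condition, action, rng)


@dataclass
class TaskSchedule:
    """Ordered condition list for one administration (default 60 per condition)."""

    conditions: list
    n_per_condition: int = 60

    def __post_init__(self) -> None:
        if len(self.conditions) != 4 * self.n_per_condition:
            raise ValueError("schedule length must be 4 * n_per_condition")
        counts = {c: 0 for c in CONDITIONS}
        for c in self.conditions:
            counts[c] += 1
        if any(v != self.n_per_condition for v in counts.values()):
            raise ValueError("each condition must appear exactly n_per_condition times")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self) -> Iterator[Condition]:
        return iter(self.conditions)


def generate_schedule(n_per_condition: int = 60, seed: int = 0) -> TaskSchedule:
    """Pseudo-random interleaving of the four conditions, balanced in blocks of 4.

    Block randomization (a permutation of all four conditions per block of
    four trials) bounds local imbalance, which stabilizes binned learning
    curves.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    conds: list = []
    for _ in range(n_per_condition):
        conds.extend(CONDITIONS[i] for i in rng.permutation(4))
    return TaskSchedule(conditions=conds, n_per_condition=n_per_condition)


@dataclass
class TrialRecord:
    """One task trial within a subject x administration."""

    subject_id: str
    administration: int
    trial_index: int
    condition: Condition
    action: str
    outcome: int
    rt: float | None = None


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "administration": [r.administration for r in records],
            "trial_index": [r.trial_index for r in records],
            "condition": [r.condition.name for r in records],
            "action": [r.action for r in records],
            "outcome": [r.outcome for r in records],
            "rt": [np.nan if r.rt is None else r.rt for r in records],
        }
    )


def simulate_session(
    policy: Callable,
    schedule: TaskSchedule,
    rule: OutcomeRule,
    seed: int = 0,
    subject_id: str = "sim",
    administration: int = 1,
    rt_sampler: Callable | None = None,
) -> list:
    """Run *policy* through one session and return the trial records.

    ``policy(condition)`` must return a (p_go, p_nogo) pair; if the policy
    exposes ``observe(condition, action, outcome)`` it is called after every
    trial so the owner can update its learning state, and ``reset()`` is
    called once at session start.
    """
    rng = np.random.default_rng(seed)
    if hasattr(policy, "reset"):
        policy.reset()
    records = []
    for i, cond in enumerate(schedule, start=1):
        p = np.asarray(policy(cond), dtype=float)
        if p.shape != (2,) or not np.all(np.isfinite(p)) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"policy returned invalid action probabilities {p} at trial {i} ({cond.name})")
        action = GO if rng.random() < p[0] else NOGO
        outcome = rule.sample(cond, action, rng)
        rt = None
        if action == GO and rt_sampler is not None:
            rt = float(rt_sampler(rng))
        records.append(
            TrialRecord(
                subject_id=subject_id,
                administration=administration,
                trial_index=i,
                condition=cond,
                action=action,
                outcome=outcome,
                rt=rt,
            )
        )
        if hasattr(policy, "observe"):
            policy.observe(cond, action, outcome)
    return records
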