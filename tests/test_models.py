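"""Model family: transforms, action values, likelihood vs brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavlearn import (
    Agent,
    LearnerState,
    ModelSpec,
    Parameters,
    action_probabilities,
    action_values,
    effective_pavlovian,
    make_agent,
    negative_log_likelihood,
    transform,
    untransform,
    update_state,
)
from pavlearn.models import MODEL_NAMES, prepare_arrays, trial_log_likelihoods
from pavlearn.task import CONDITIONS, GO, NOGO, Condition, OutcomeRule, generate_schedule, simulate_session

from conftest import random_trial_frame


# ---------------------------------------------------------------------------
# independent reference: hand-unrolled likelihood, kept deliberately naive
# ---------------------------------------------------------------------------
def oracle_nll(df, params, spec):
    """Step-by-step likelihood using only dict bookkeeping and math formulas."""
    import math

    total = 0.0
    for admin in sorted(df["administration"].unique()):
        Q = {(a, s): 0.0 for a in (GO, NOGO) for s in range(4)}
        V = {s: 0.0 for s in range(4)}
        block = df[df["administration"] == admin]
        for _, row in block.iterrows():
            cond = Condition[row["condition"]]
            s = cond.value
            win = cond.valence == "win"
            alpha = params.alpha if (spec.shared_learning_rate or params.alpha_loss is None or win) else params.alpha_loss
            xi = params.xi if spec.has_noise else 0.0
            if spec.valenced_noise and not win:
                xi = params.xi_loss
            pi_app, pi_av = effective_pavlovian(params, spec, admin)
            pi = pi_app if win else pi_av
            if spec.pavlovian == "none":
                pi = 0.0
            go_val = Q[(GO, s)] + (params.b if spec.has_bias else 0.0) + pi * V[s]
            nogo_val = Q[(NOGO, s)]
            pg = math.exp(go_val) / (math.exp(go_val) + math.exp(nogo_val))
            pg = pg * (1 - xi) + xi / 2
            p = pg if row["action"] == GO else (1 - pg)
            total -= math.log(p)
            target = params.beta * row["outcome"]
            a = row["action"]
            Q[(a, s)] += alpha * (target - Q[(a, s)])
            V[s] += alpha * (target - V[s])
    return total


class TestTransforms:
    def test_logistic_midpoint_and_log_identity(self, full_spec):
        p = Parameters(alpha=0.5, beta=1.0, b=0.0, xi=0.5, pi_app=0.0, pi_av=0.0,
                       pi_app_post=0.0, pi_av_post=0.0)
        vec = transform(p, full_spec)
        names = full_spec.parameter_names()
        assert vec[names.index("alpha")] == pytest.approx(0.0)
        assert vec[names.index("beta")] == pytest.approx(0.0)
        back = untransform(vec, full_spec)
        assert back.alpha == pytest.approx(0.5)
        assert back.beta == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=8))
    def test_round_trip_bijection(self, vec):
        spec = ModelSpec.from_name("RW+noise+bias+2Pav+session")
        vec = np.asarray(vec)
        back = transform(untransform(vec, spec), spec)
        assert np.allclose(back, vec, atol=1e-10)

    def test_nonfinite_rejected(self, full_spec):
        with pytest.raises(ValueError):
            untransform(np.full(8, np.nan), full_spec)
        with pytest.raises(ValueError):
            transform(Parameters(alpha=1.0), ModelSpec.from_name("RW"))


class TestEffectivePavlovian:
    def test_switch_weeks(self, full_spec, generic_params):
        p = generic_params
        assert effective_pavlovian(p, full_spec, 2) == (p.pi_app, p.pi_av)
        assert effective_pavlovian(p, full_spec, 3) == (p.pi_app_post, p.pi_av)
        assert effective_pavlovian(p, full_spec, 4) == (p.pi_app_post, p.pi_av_post)
        assert effective_pavlovian(p, full_spec, 5) == (p.pi_app_post, p.pi_av_post)

    def test_passthrough_without_session_varying(self, dual_spec, generic_params):
        for admin in range(1, 6):
            assert effective_pavlovian(generic_params, dual_spec, admin) == (
                generic_params.pi_app, generic_params.pi_av)

    def test_out_of_range_administration(self, full_spec, generic_params):
        with pytest.raises(ValueError):
            effective_pavlovian(generic_params, full_spec, 6)


class TestActionValues:
    def test_zero_state(self, dual_spec):
        p = Parameters(alpha=0.2, beta=3.0, b=0.0, xi=0.1, pi_app=1.0, pi_av=1.0)
        assert action_values(LearnerState.zeros(), Condition.GO_WIN, p, dual_spec) == (0.0, 0.0)

    def test_direct_sum(self, dual_spec):
        state = LearnerState.zeros()
        state.Q[0, Condition.GO_WIN.value] = 0.2
        state.V[Condition.GO_WIN.value] = 0.5
        p = Parameters(alpha=0.2, beta=3.0, b=0.1, xi=0.1, pi_app=1.0, pi_av=1.0)
        go, nogo = action_values(state, Condition.GO_WIN, p, dual_spec)
        assert go == pytest.approx(0.8)
        assert nogo == pytest.approx(0.0)

    def test_dual_gating_by_valence(self, dual_spec):
        state = LearnerState.zeros()
        for cond in CONDITIONS:
            state.V[cond.value] = 1.0
        p = Parameters(alpha=0.2, beta=3.0, b=0.0, xi=0.0, pi_app=2.0, pi_av=-3.0)
        for cond in CONDITIONS:
            go, _ = action_values(state, cond, p, dual_spec)
            assert go == pytest.approx(2.0 if cond.valence == "win" else -3.0)


class TestActionProbabilities:
    def test_symmetry_and_noise_limits(self):
        assert np.allclose(action_probabilities((0.0, 0.0), xi=0.0), [0.5, 0.5])
        assert np.allclose(action_probabilities((37.0, -4.0), xi=1.0), [0.5, 0.5])

    def test_closed_form_softmax(self):
        p = action_probabilities((1.0, 0.0), xi=0.0)
        assert p[0] == pytest.approx(1 / (1 + np.exp(-1)))
        assert p[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(-200, 200), st.floats(-200, 200),
        st.floats(0, 1, exclude_max=True),
    )
    def test_bounds_and_sum(self, v1, v2, xi):
        p = action_probabilities((v1, v2), xi=xi)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= xi / 2 - 1e-12) and np.all(p <= 1 - xi / 2 + 1e-12)

    def test_overflow_guarded(self):
        p = action_probabilities((1e4, -1e4), xi=0.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestUpdateState:
    def test_delta_rule_values(self, dual_spec):
        p = Parameters(alpha=0.5, beta=2.0)
        s = update_state(LearnerState.zeros(), Condition.GO_WIN, GO, 1, p, dual_spec)
        assert s.Q[0, Condition.GO_WIN.value] == pytest.approx(1.0)  # 0 + 0.5*(2-0)
        p2 = Parameters(alpha=0.1, beta=1.0)
        s2 = update_state(LearnerState.zeros(), Condition.GO_AVOID, NOGO, -1, p2, dual_spec)
        assert s2.V[Condition.GO_AVOID.value] == pytest.approx(-0.1)

    def test_only_touched_entries_change(self, dual_spec):
        p = Parameters(alpha=0.3, beta=1.0)
        s = update_state(LearnerState.zeros(), Condition.NOGO_WIN, GO, 1, p, dual_spec)
        mask = np.zeros((2, 4), dtype=bool)
        mask[0, Condition.NOGO_WIN.value] = True
        assert np.all(s.Q[~mask] == 0)
        assert np.all(s.V[np.arange(4) != Condition.NOGO_WIN.value] == 0)

    def test_sequence_matches_iterative_oracle(self, dual_spec):
        rng = np.random.default_rng(7)
        p = Parameters(alpha=0.3, beta=2.0)
        state = LearnerState.zeros()
        q_oracle = 0.0
        for _ in range(60):
            r = int(rng.integers(-1, 2))
            state = update_state(state, Condition.GO_WIN, GO, r, p, dual_spec)
            q_oracle = q_oracle + 0.3 * (2.0 * r - q_oracle)
        assert state.Q[0, 0] == pytest.approx(q_oracle, abs=1e-12)


class TestLikelihood:
    def test_single_trial_is_log_two(self):
        df = random_trial_frame(np.random.default_rng(0), 1)
        p = Parameters(alpha=0.2, beta=3.0, b=0.0, xi=0.0, pi_app=0.0, pi_av=0.0)
        spec = ModelSpec.from_name("RW+noise+bias")
        assert negative_log_likelihood(df, p, spec) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_matches_bruteforce_oracle(self, name, generic_params):
        spec = ModelSpec.from_name(name)
        rng = np.random.default_rng(13)
        for n in (1, 2, 3, 8):
            df = random_trial_frame(rng, n, administrations=(1, 3))
            nll = negative_log_likelihood(df, generic_params, spec)
            assert nll == pytest.approx(oracle_nll(df, generic_params, spec), abs=1e-12)

    def test_unordered_data_rejected(self, dual_spec, generic_params):
        df = random_trial_frame(np.random.default_rng(1), 5)
        shuffled = df.sample(frac=1.0, random_state=2)
        if not shuffled["trial_index"].is_monotonic_increasing:
            with pytest.raises(ValueError):
                negative_log_likelihood(shuffled, generic_params, dual_spec)

    def test_interleaved_administrations_rejected(self, dual_spec, generic_params):
        df = pd.concat([
            random_trial_frame(np.random.default_rng(3), 2, administrations=(1,)),
            random_trial_frame(np.random.default_rng(4), 2, administrations=(2,)),
            random_trial_frame(np.random.default_rng(5), 2, administrations=(1,)),
        ], ignore_index=True)
        with pytest.raises(ValueError, match="grouped"):
            negative_log_likelihood(df, generic_params, dual_spec)

    def test_dual_with_zero_pis_equals_no_pavlovian(self, generic_params):
        rng = np.random.default_rng(21)
        df = random_trial_frame(rng, 40, administrations=(1, 2))
        p = Parameters(alpha=0.3, beta=2.0, b=0.2, xi=0.05, pi_app=0.0, pi_av=0.0)
        a = negative_log_likelihood(df, p, ModelSpec.from_name("RW+noise+bias+2Pav"))
        b = negative_log_likelihood(df, p, ModelSpec.from_name("RW+noise+bias"))
        assert a == pytest.approx(b, abs=1e-12)

    def test_finite_with_noise(self, full_spec):
        df = random_trial_frame(np.random.default_rng(6), 50)
        p = Parameters(alpha=0.9, beta=20.0, b=0.0, xi=0.01, pi_app=5.0, pi_av=-5.0,
                       pi_app_post=5.0, pi_av_post=-5.0)
        assert np.isfinite(negative_log_likelihood(df, p, full_spec))

    def test_missed_treated_as_nogo(self, dual_spec, generic_params):
        df = random_trial_frame(np.random.default_rng(8), 10)
        df.loc[3, "action"] = "missed"
        as_missed = negative_log_likelihood(df, generic_params, dual_spec)
        df.loc[3, "action"] = NOGO
        as_nogo = negative_log_likelihood(df, generic_params, dual_spec)
        assert as_missed == pytest.approx(as_nogo, abs=1e-12)


class TestAgent:
    def test_agent_probabilities_match_kernel(self, full_spec, generic_params):
        """Generative policy and likelihood kernel agree trial for trial."""
        rule = OutcomeRule.paper_text()
        sched = generate_schedule(20, seed=9)
        agent = make_agent(generic_params, full_spec, administration=4)
        records = simulate_session(agent, sched, rule, seed=3, administration=4)
        df = pd.DataFrame({
            "subject_id": "x", "administration": 4,
            "trial_index": [r.trial_index for r in records],
            "condition": [r.condition.name for r in records],
            "action": [r.action for r in records],
            "outcome": [r.outcome for r in records],
        })
        logp = trial_log_likelihoods(df, generic_params, full_spec)
        # replay through a fresh agent and compare chosen-action probabilities
        replay = make_agent(generic_params, full_spec, administration=4)
        for r, lp in zip(records, logp):
            probs = replay(r.condition)
            idx = 0 if r.action == GO else 1
            assert np.log(probs[idx]) == pytest.approx(lp, abs=1e-12)
            replay.observe(r.condition, r.action, r.outcome)

    def test_noise_ceiling_agent(self, dual_spec):
        p = Parameters(alpha=0.2, beta=3.0, b=0.0, xi=1.0, pi_app=0.0, pi_av=0.0)
        agent = make_agent(p, dual_spec)
        sched = generate_schedule(60, seed=10)
        go_rates = []
        for seed in range(50):
            recs = simulate_session(agent, sched, OutcomeRule.paper_text(), seed=seed)
            go_rates.append(np.mean([r.action == GO for r in recs]))
        assert np.mean(go_rates) == pytest.approx(0.5, abs=0.03)

    def test_no_learning_limit(self, dual_spec):
        p = Parameters(alpha=0.0, beta=3.0, b=0.4, xi=0.0, pi_app=0.0, pi_av=0.0)
        agent = make_agent(p, dual_spec)
        sched = generate_schedule(30, seed=11)
        recs = simulate_session(agent, sched, OutcomeRule.paper_text(), seed=0)
        expected = 1 / (1 + np.exp(-0.4))
        agent.reset()
        for cond in CONDITIONS:
            assert agent(cond)[0] == pytest.approx(expected)

    def test_appetitive_pavlovian_raises_nogo_win_go_rate(self, dual_spec):
        rule = OutcomeRule.paper_text()
        sched = generate_schedule(60, seed=12)

        def nogo_win_go_rate(pi_app, seed):
            p = Parameters(alpha=0.3, beta=3.0, b=0.0, xi=0.05, pi_app=pi_app, pi_av=0.0)
            recs = simulate_session(make_agent(p, dual_spec), sched, rule, seed=seed)
            mask = [r.condition is Condition.NOGO_WIN for r in recs]
            return np.mean([r.action == GO for r, m in zip(recs, mask) if m])

        strong = np.mean([nogo_win_go_rate(2.5, s) for s in range(200)])
        none = np.mean([nogo_win_go_rate(0.0, s) for s in range(200)])
        assert strong > none + 0.05


class TestModelSpec:
    def test_session_varying_requires_dual(self):
        with pytest.raises(ValueError):
            ModelSpec(pavlovian="single", session_varying=True)

    def test_parameter_names_deterministic(self):
        spec = ModelSpec.from_name("RW+noise+bias+2Pav+session")
        assert spec.parameter_names() == [
            "alpha", "beta", "b", "xi", "pi_app", "pi_av", "pi_app_post", "pi_av_post"]
        assert ModelSpec.from_name("RW").parameter_names() == ["alpha", "beta"]

    def test_name_round_trip(self):
        for name in MODEL_NAMES:
            spec = ModelSpec.from_name(name)
            assert spec.name == name
            assert ModelSpec.from_dict(spec.to_dict()) == spec
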