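"""JIT-compiled trial-likelihood kernel shared by fitting and simulation.

Parameters are passed as a resolved 10-slot vector so a single kernel serves
the whole nested model family (neutral values switch components off):

    0 alpha_win    learning rate, win-valence stimuli
    1 alpha_loss   learning rate, loss-valence stimuli
    2 beta         reward sensitivity (scales r inside the delta rule)
    3 go_bias      additive bias on the go action value
    4 xi_win       irreducible noise, win-valence stimuli
    5 xi_loss      irreducible noise, loss-valence stimuli
    6 pi_app_pre   appetitive Pavlovian weight, administrations 1-2
    7 pi_av_pre    aversive Pavlovian weight, administrations 1-3
    8 pi_app_post  appetitive Pavlovian weight from administration 3 on
    9 pi_av_post   aversive Pavlovian weight from administration 4 on

Stimuli are coded 0..3 in Condition order (0, 1 win-valence; 2, 3
loss-valence); actions 0 = go, 1 = nogo.  Q and V reset to zero whenever the
administration index changes (fresh stimuli per administration).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: floor on choice probabilities so log never returns -inf (xi = 0 saturation guard)
_P_FLOOR = 1e-300


@njit(cache=False)
def trial_log_probs(stim, act, out, admin, p):  # pragma: no cover - jitted
    n = stim.shape[0]
    logp = np.empty(n)
    Q = np.zeros((2, 4))
    V = np.zeros(4)
    prev_admin = -1
    for t in range(n):
        a_idx = admin[t]
        if a_idx != prev_admin:
            for i in range(4):
                Q[0, i] = 0.0
                Q[1, i] = 0.0
                V[i] = 0.0
            prev_admin = a_idx
        s = stim[t]
        win = s < 2
        alpha = p[0] if win else p[1]
        xi = p[4] if win else p[5]
        pi_app = p[8] if a_idx >= 3 else p[6]
        pi_av = p[9] if a_idx >= 4 else p[7]
        pi = pi_app if win else pi_av
        qg = Q[0, s] + p[3] + pi * V[s]
        qn = Q[1, s]
        m = qg if qg > qn else qn
        eg = math.exp(qg - m)
        en = math.exp(qn - m)
        z = eg + en
        pg = (eg / z) * (1.0 - xi) + xi / 2.0
        pn = (en / z) * (1.0 - xi) + xi / 2.0
        chosen = act[t]
        pa = pg if chosen == 0 else pn
        if pa < _P_FLOOR:
            pa = _P_FLOOR
        logp[t] = math.log(pa)
        delta_target = p[2] * out[t]
        Q[chosen, s] += alpha * (delta_target - Q[chosen, s])
        V[s] += alpha * (delta_target - V[s])
    return logp


@njit(cache=False)
def simulate_actions(stim, admin, p, rule_probs, seed):  # pragma: no cover - jitted
    """Sample actions/outcomes for a condition sequence under the model policy.

    rule_probs: (4 conditions, 2 actions, 3 outcomes) with outcomes (-1, 0, +1).
    Returns (actions, outcomes) arrays.
    """
    np.random.seed(seed)
    n = stim.shape[0]
    actions = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.float64)
    Q = np.zeros((2, 4))
    V = np.zeros(4)
    prev_admin = -1
    for t in range(n):
        a_idx = admin[t]
        if a_idx != prev_admin:
            for i in range(4):
                Q[0, i] = 0.0
                Q[1, i] = 0.0
                V[i] = 0.0
            prev_admin = a_idx
        s = stim[t]
        win = s < 2
        alpha = p[0] if win else p[1]
        xi = p[4] if win else p[5]
        pi_app = p[8] if a_idx >= 3 else p[6]
        pi_av = p[9] if a_idx >= 4 else p[7]
        pi = pi_app if win else pi_av
        qg = Q[0, s] + p[3] + pi * V[s]
        qn = Q[1, s]
        m = qg if qg > qn else qn
        eg = math.exp(qg - m)
        en = math.exp(qn - m)
        pg = (eg / (eg + en)) * (1.0 - xi) + xi / 2.0
        chosen = 0 if np.random.random() < pg else 1
        u = np.random.random()
        c = 0.0
        o = 1.0
        for k in range(3):
            c += rule_probs[s, chosen, k]
            if u < c:
                o = float(k - 1)
                break
        actions[t] = chosen
        outcomes[t] = o
        delta_target = p[2] * o
        Q[chosen, s] += alpha * (delta_target - Q[chosen, s])
        V[s] += alpha * (delta_target - V[s])
    return actions, outcomes
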