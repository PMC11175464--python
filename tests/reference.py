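"""Slow, independent reference implementations used as test oracles.

These are deliberately written in a plain dict-and-loop style, separate
from the package's compiled kernels, so that agreement between the two is
informative.
"""

import math


def _softmax_pair(u0, u1):
    e0, e1 = math.exp(u0), math.exp(u1)
    return e0 / (e0 + e1)


def reference_two_policy(trials, alpha, beta, rho, epsilon=0.0,
                         fixed_weight=None, counterfactual="counterfactual",
                         decay=0.0):
    """Trial-by-trial likelihood of the two-policy arbitration model.

    ``trials`` is a trial table (DataFrame) in the decision frame.  Returns
    ``(nll, latents)`` with per-trial lists of the internal quantities.
    """
    nll = 0.0
    latents = {"omega": [], "weight": [], "delta_correct": [],
               "delta_incorrect": [], "evidence": [], "p_chosen": [],
               "V_correct": [], "V_incorrect": []}
    state = None
    last_block = None
    for _, row in trials.iterrows():
        block_key = (row.get("run", 0), row["block"])
        if state is None or block_key != last_block:
            state = {
                "Vc": {(d, a): 0.0 for d in (1, 2) for a in (1, 2)},
                "Vi": {(d, a): 0.0 for d in (1, 2) for a in (1, 2)},
                "omega": 0.0,
                "prev": {1: None, 2: None},
            }
            last_block = block_key
        if fixed_weight is None:
            w = 1.0 / (1.0 + math.exp(-state["omega"]))
        else:
            w = fixed_weight
        latents["omega"].append(state["omega"] if fixed_weight is None
                                else math.log(w / (1 - w)) if 0 < w < 1
                                else (700.0 if w >= 1 else -700.0))
        latents["weight"].append(w)
        latents["V_correct"].append(dict(state["Vc"]))
        latents["V_incorrect"].append(dict(state["Vi"]))
        actions = {1: int(row["action_d1"]), 2: int(row["action_d2"])}
        rewards = {1: row["outcome_d1"] / 50.0 - 1.0,
                   2: row["outcome_d2"] / 50.0 - 1.0}
        p_chosen = {}
        for d in (1, 2):
            utils = {}
            for a in (1, 2):
                vnet = w * state["Vc"][(d, a)] + (1 - w) * state["Vi"][(d, a)]
                bonus = rho if state["prev"][d] == a else 0.0
                utils[a] = beta * vnet + bonus
            p1 = _softmax_pair(utils[1], utils[2])
            p_chosen[d] = p1 if actions[d] == 1 else 1.0 - p1
            nll -= math.log(p_chosen[d])
        latents["p_chosen"].append(p_chosen)
        # prediction errors against pre-update values; the incorrect policy
        # attributes the *other* decision's outcome to each decision
        dc = {d: rewards[d] - state["Vc"][(d, actions[d])] for d in (1, 2)}
        di = {d: rewards[3 - d] - state["Vi"][(d, actions[d])] for d in (1, 2)}
        latents["delta_correct"].append(dict(dc))
        latents["delta_incorrect"].append(dict(di))
        for d in (1, 2):
            a, other = actions[d], 3 - actions[d]
            state["Vc"][(d, a)] += alpha * dc[d]
            state["Vi"][(d, a)] += alpha * di[d]
            if counterfactual == "counterfactual":
                state["Vc"][(d, other)] -= alpha * dc[d]
                state["Vi"][(d, other)] -= alpha * di[d]
            elif counterfactual == "lr_decay":
                state["Vc"][(d, other)] *= (1.0 - alpha)
                state["Vi"][(d, other)] *= (1.0 - alpha)
            elif counterfactual == "free_decay":
                state["Vc"][(d, other)] *= (1.0 - decay)
                state["Vi"][(d, other)] *= (1.0 - decay)
            else:
                raise ValueError(counterfactual)
        ev_o1 = abs(di[2]) - abs(dc[1])
        ev_o2 = abs(di[1]) - abs(dc[2])
        latents["evidence"].append((ev_o1, ev_o2))
        if fixed_weight is None:
            state["omega"] += epsilon * (ev_o1 + ev_o2)
        state["prev"] = dict(actions)
    return nll, latents


def reference_single_policy_td(trials, alpha, beta, rho, which="relevant"):
    """A plain two-armed TD learner with counterfactual updating.

    Learns each decision from its relevant (own) or irrelevant (other
    decision's) outcome.  The arbitration model with the weight pinned at
    1 (resp. 0) must be likelihood-identical to this learner on any data.
    """
    nll = 0.0
    V = None
    last_block = None
    prev = None
    for _, row in trials.iterrows():
        block_key = (row.get("run", 0), row["block"])
        if V is None or block_key != last_block:
            V = {(d, a): 0.0 for d in (1, 2) for a in (1, 2)}
            prev = {1: None, 2: None}
            last_block = block_key
        actions = {1: int(row["action_d1"]), 2: int(row["action_d2"])}
        rewards = {1: row["outcome_d1"] / 50.0 - 1.0,
                   2: row["outcome_d2"] / 50.0 - 1.0}
        for d in (1, 2):
            u = {a: beta * V[(d, a)] + (rho if prev[d] == a else 0.0)
                 for a in (1, 2)}
            p1 = _softmax_pair(u[1], u[2])
            p = p1 if actions[d] == 1 else 1.0 - p1
            nll -= math.log(p)
        for d in (1, 2):
            source = rewards[d] if which == "relevant" else rewards[3 - d]
            delta = source - V[(d, actions[d])]
            V[(d, actions[d])] += alpha * delta
            V[(d, 3 - actions[d])] -= alpha * delta
        prev = actions
    return nll


def reference_joint_action(trials, alpha, beta, rho):
    """Scalar-prediction-error learner over the four joint actions."""
    nll = 0.0
    V = None
    last_block = None
    prev = None
    for _, row in trials.iterrows():
        block_key = (row.get("run", 0), row["block"])
        if V is None or block_key != last_block:
            V = {j: 0.0 for j in range(4)}
            prev = None
            last_block = block_key
        j = (int(row["action_d1"]) - 1) * 2 + (int(row["action_d2"]) - 1)
        rsum = (row["outcome_d1"] / 50.0 - 1.0) + (row["outcome_d2"] / 50.0 - 1.0)
        exps = {k: math.exp(beta * V[k] + (rho if k == prev else 0.0))
                for k in range(4)}
        total = sum(exps.values())
        nll -= math.log(exps[j] / total)
        V[j] += alpha * (rsum - V[j])
        prev = j
    return nll
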