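"""Arbitration-by-surprise-minimization model and its competitors.

The model family solves the structural credit assignment problem of the
multiple-bandits task.  Two temporal-difference policies learn action
values in parallel, one per candidate decision -> outcome mapping.  Each
policy's absolute prediction error is its surprise, read as negative model
evidence; the difference between the policies' surprises for the same
outcome is an evidence signal that is accumulated (at the assignment rate
epsilon) into a log-odds arbitration weight.  The inverse-logit of that
weight mixes the two policies' values for softmax action selection with
inverse temperature beta and perseveration bonus rho.

Competitor models: three fixed-weight variants (correct / incorrect /
random policy, arbitration weight pinned at 0.9 / 0.1 / 0.5) and a
joint-action model that treats each trial as a single 4-way choice scored
against the summed outcomes.

Every model runs in generative mode (``simulate``) and likelihood mode
(``negative_log_likelihood``), both with a full latent trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .task import TaskBlock, center_outcome, outcome_for_action, session_to_frame

__all__ = [
    "ModelParams",
    "ModelSpec",
    "LatentTrace",
    "JointLatentTrace",
    "MODEL_IDS",
    "get_model",
    "prediction_errors",
    "update_values",
    "surprise",
    "evidence",
    "update_arbitration",
    "net_values",
    "choice_probabilities",
    "joint_action_step",
    "simulate",
    "negative_log_likelihood",
    "trace_to_frame",
]

PARAM_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "rho": (-5.0, 5.0),
    "epsilon": (0.0, 1.0),
    "decay": (0.0, 1.0),
}

_CF_MODES = {"counterfactual": 0, "lr_decay": 1, "free_decay": 2}


@dataclass(frozen=True)
class ModelParams:
    """Free parameters: learning rate, inverse temperature, perseveration,
    and (surprise-minimization models only) the assignment rate epsilon.
    ``decay`` is used only by the free-decay variant."""

    alpha: float
    beta: float
    rho: float
    epsilon: float | None = None
    decay: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "rho", "epsilon", "decay"):
            value = getattr(self, name)
            if value is None:
                continue
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family to run.

    ``fixed_weight`` pins the arbitration weight (fixed-weight variants and
    the weight-1/0 validation simulations); ``None`` means dynamic
    surprise-minimization arbitration.  ``counterfactual_mode`` selects how
    unchosen options are updated.
    """

    model_id: str
    fixed_weight: float | None = None
    counterfactual_mode: str = "counterfactual"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.counterfactual_mode not in _CF_MODES:
            raise ValueError(f"unknown counterfactual_mode "
                             f"{self.counterfactual_mode!r}")
        fixed_family = self.model_id in ("correct_policy", "incorrect_policy",
                                         "random_policy")
        if (self.fixed_weight is not None) and not fixed_family:
            raise ValueError(f"{self.model_id} does not take a fixed weight")
        if fixed_family and self.fixed_weight is None:
            raise ValueError(f"{self.model_id} requires fixed_weight")
        if self.fixed_weight is not None and not 0.0 <= self.fixed_weight <= 1.0:
            raise ValueError("fixed_weight must lie in [0, 1]")

    @property
    def is_joint(self) -> bool:
        return self.model_id == "joint_action"

    @property
    def dynamic_weight(self) -> bool:
        return (not self.is_joint) and self.fixed_weight is None

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha", "beta", "rho"]
        if self.dynamic_weight:
            names.append("epsilon")
        if self.counterfactual_mode == "free_decay":
            names.append("decay")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def check_params(self, params: ModelParams) -> None:
        for name in self.param_names:
            if getattr(params, name) is None:
                raise ValueError(f"model {self.model_id} requires parameter "
                                 f"{name}")


#: Model identifiers and the fixed weight each implies (None = dynamic/joint).
MODEL_IDS = {
    "surprise_min": None,
    "correct_policy": 0.9,
    "incorrect_policy": 0.1,
    "random_policy": 0.5,
    "joint_action": None,
    "surprise_min_lrdecay": None,
    "surprise_min_freedecay": None,
}

#: The five-model comparison set.
DEFAULT_MODEL_SET = ("surprise_min", "correct_policy", "incorrect_policy",
                     "random_policy", "joint_action")


def get_model(model_id: str, fixed_weight: float | None = None) -> ModelSpec:
    """Construct a ModelSpec by id, with the conventional fixed weight.

    Pass ``fixed_weight`` explicitly for the weight-1/0 validation variants
    of the correct/incorrect policy models.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if fixed_weight is None:
        fixed_weight = MODEL_IDS[model_id]
    cf = "counterfactual"
    if model_id == "surprise_min_lrdecay":
        cf = "lr_decay"
    elif model_id == "surprise_min_freedecay":
        cf = "free_decay"
    return ModelSpec(model_id=model_id, fixed_weight=fixed_weight,
                     counterfactual_mode=cf)


# ---------------------------------------------------------------------------
# elementary model computations
#
# These pure functions spell out the individual steps of the recursion; the
# production simulate/likelihood paths run the same arithmetic inside
# compiled kernels.

def prediction_errors(V_correct, V_incorrect, rewards, actions):
    """Per-decision prediction errors of both policies.

    ``V_correct``/``V_incorrect`` have shape (2, 2) [decision, action],
    ``rewards`` are the centered rewards delivered by decision 1 and 2,
    ``actions`` the 0-based chosen actions.  The correct policy scores each
    decision against its own outcome; the incorrect policy scores it
    against the other decision's outcome.
    """
    a1, a2 = actions
    delta_c = np.array([rewards[0] - V_correct[0, a1],
                        rewards[1] - V_correct[1, a2]])
    delta_i = np.array([rewards[1] - V_incorrect[0, a1],
                        rewards[0] - V_incorrect[1, a2]])
    return delta_c, delta_i


def update_values(values, deltas, actions, alpha,
                  counterfactual_mode="counterfactual", decay=None):
    """Return the updated (2, 2) value table of one policy.

    Chosen option: V += alpha * delta.  Unchosen option: counterfactual
    mirror (V -= alpha * delta), learning-rate decay ((1 - alpha) * V), or
    free decay ((1 - decay) * V).
    """
    out = np.array(values, dtype=float, copy=True)
    for d in range(2):
        a = actions[d]
        out[d, a] += alpha * deltas[d]
        if counterfactual_mode == "counterfactual":
            out[d, 1 - a] -= alpha * deltas[d]
        elif counterfactual_mode == "lr_decay":
            out[d, 1 - a] *= (1.0 - alpha)
        elif counterfactual_mode == "free_decay":
            out[d, 1 - a] *= (1.0 - decay)
        else:
            raise ValueError(counterfactual_mode)
    return out


def surprise(delta):
    """Surprise = |prediction error| (negative model evidence)."""
    return np.abs(delta)


def evidence(surprise_correct, surprise_incorrect):
    """Evidence per outcome from the cross-decision surprise comparison.

    The same outcome is attributed to decision 1 by the correct mapping and
    to decision 2 by the incorrect one (and vice versa), hence
    delta(o1) = s_incorrect(d2) - s_correct(d1) and
    delta(o2) = s_incorrect(d1) - s_correct(d2).  Positive evidence favors
    the correct mapping.
    """
    return np.array([surprise_incorrect[1] - surprise_correct[0],
                     surprise_incorrect[0] - surprise_correct[1]])


def update_arbitration(omega, evidence_pair, epsilon):
    """Accumulate evidence into the log-odds arbitration weight."""
    return omega + epsilon * float(np.sum(evidence_pair))


def inverse_logit(omega):
    """Overflow-safe inverse logit; the arbitration weight on the correct
    policy."""
    x = np.clip(omega, -_kernels.CLAMP, _kernels.CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def net_values(V_correct, V_incorrect, weight):
    """Weighted mixture of the two policies' values."""
    return weight * np.asarray(V_correct) + (1.0 - weight) * np.asarray(V_incorrect)


def choice_probabilities(V_net, beta, rho, previous_actions=(-1, -1)):
    """Softmax choice probabilities, shape (2 decisions, 2 actions).

    ``previous_actions`` are the 0-based actions of the same decisions on
    the previous trial (-1 at a block start: no repetition bonus).
    """
    V_net = np.asarray(V_net, dtype=float)
    probs = np.empty((2, 2))
    for d in range(2):
        u = beta * V_net[d].copy()
        if previous_actions[d] in (0, 1):
            u[previous_actions[d]] += rho
        u -= u.max()
        e = np.exp(u)
        probs[d] = e / e.sum()
    return probs


def joint_action_step(values, rewards, joint_action, params,
                      previous_joint=-1):
    """One trial of the joint-action model.

    Returns (updated values over the 4 joint actions, choice probabilities
    computed from the pre-update values, scalar prediction error).
    """
    V = np.array(values, dtype=float, copy=True)
    u = params.beta * V
    if 0 <= previous_joint < 4:
        u[previous_joint] += params.rho
    u -= u.max()
    e = np.exp(u)
    probs = e / e.sum()
    delta = float(rewards[0] + rewards[1]) - V[joint_action]
    V[joint_action] += params.alpha * delta
    return V, probs, delta


# ---------------------------------------------------------------------------
# latent traces

@dataclass
class LatentTrace:
    """Trial-by-trial internals of a two-policy model.

    Value arrays hold the values *used at choice time* (pre-update);
    ``omega``/``weight`` likewise.  ``evidence[:, k]`` is the evidence for
    outcome o_{k+1} in the decision frame (o1 = outcome caused by
    decision 1).
    """

    block: np.ndarray
    trial: np.ndarray
    actions: np.ndarray            # (T, 2) 0-based
    rewards: np.ndarray            # (T, 2) centered, decision frame
    V_correct: np.ndarray          # (T, 2, 2)
    V_incorrect: np.ndarray        # (T, 2, 2)
    delta_correct: np.ndarray      # (T, 2)
    delta_incorrect: np.ndarray    # (T, 2)
    surprise_correct: np.ndarray   # (T, 2)
    surprise_incorrect: np.ndarray # (T, 2)
    evidence: np.ndarray           # (T, 2)
    omega: np.ndarray              # (T,)
    weight: np.ndarray             # (T,)
    p_action1: np.ndarray          # (T, 2) probability of action index 0
    p_chosen: np.ndarray           # (T, 2)

    #: log-odds weight after the final trial's evidence update (omega is
    #: otherwise recorded at choice time, i.e. before the update)
    _omega_end: float = field(default=0.0, repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.omega)

    def omega_end(self) -> float:
        """Log-odds arbitration weight after the final evidence update."""
        return float(self._omega_end)

    def final_weight(self) -> float:
        """Arbitration weight on the correct policy at the end of the run."""
        return float(inverse_logit(self._omega_end))


@dataclass
class JointLatentTrace:
    """Trial-by-trial internals of the joint-action model."""

    block: np.ndarray
    trial: np.ndarray
    joint_action: np.ndarray   # (T,) in 0..3
    rewards: np.ndarray        # (T, 2)
    V: np.ndarray              # (T, 4) pre-update
    delta: np.ndarray          # (T,)
    p: np.ndarray              # (T, 4)
    p_chosen: np.ndarray       # (T,)


def _alloc_trace(T: int, block: np.ndarray, trial: np.ndarray) -> LatentTrace:
    z2 = lambda: np.zeros((T, 2))
    return LatentTrace(
        block=block, trial=trial,
        actions=np.zeros((T, 2), dtype=np.int64), rewards=z2(),
        V_correct=np.zeros((T, 2, 2)), V_incorrect=np.zeros((T, 2, 2)),
        delta_correct=z2(), delta_incorrect=z2(),
        surprise_correct=z2(), surprise_incorrect=z2(),
        evidence=z2(), omega=np.zeros(T), weight=np.zeros(T),
        p_action1=z2(), p_chosen=z2(),
    )


def _kernel_args(spec: ModelSpec, params: ModelParams):
    spec.check_params(params)
    eps = params.epsilon if spec.dynamic_weight else 0.0
    fixed_w = spec.fixed_weight if spec.fixed_weight is not None else 0.5
    decay = params.decay if params.decay is not None else 0.0
    return (params.alpha, params.beta, params.rho, eps,
            spec.dynamic_weight, fixed_w,
            _CF_MODES[spec.counterfactual_mode], decay)


def _run_trace(spec, params, a1, a2, r1, r2, newblock, block, trial):
    T = len(a1)
    trace = _alloc_trace(T, block, trial)
    trace.actions[:, 0] = a1
    trace.actions[:, 1] = a2
    trace.rewards[:, 0] = r1
    trace.rewards[:, 1] = r2
    args = _kernel_args(spec, params)
    nll = _kernels.trace_two_policy(
        a1, a2, r1, r2, newblock, *args,
        trace.V_correct, trace.V_incorrect,
        trace.delta_correct, trace.delta_incorrect,
        trace.surprise_correct, trace.surprise_incorrect,
        trace.evidence, trace.omega, trace.weight,
        trace.p_action1, trace.p_chosen)
    if spec.dynamic_weight:
        trace._omega_end = trace.omega[-1] + params.epsilon * trace.evidence[-1].sum()
    else:
        trace._omega_end = trace.omega[-1]
    return nll, trace


def simulate(spec: ModelSpec, params: ModelParams,
             blocks: Sequence[TaskBlock], rng: np.random.Generator,
             run: int = 0):
    """Generate behavior from a model on task blocks.

    Per trial: choice probabilities from the current values and weight ->
    sample both actions -> realize both outcomes -> prediction errors from
    the pre-update values -> value update -> surprise and evidence ->
    arbitration update.  All state resets at block boundaries.

    Returns (trial table DataFrame, latent trace).
    """
    spec.check_params(params)
    T = sum(b.n_trials for b in blocks)
    a1 = np.empty(T, dtype=np.int64)
    a2 = np.empty(T, dtype=np.int64)
    # sample actions sequentially (choice probabilities depend on history)
    if spec.is_joint:
        aj = np.empty(T, dtype=np.int64)
    t0 = 0
    for blk in blocks:
        Tb = blk.n_trials
        if spec.is_joint:
            V = np.zeros(4)
            prev = -1
            for t in range(Tb):
                u = params.beta * V
                if prev >= 0:
                    u = u.copy()
                    u[prev] += params.rho
                u = u - u.max()
                e = np.exp(u)
                p = e / e.sum()
                j = int(rng.choice(4, p=p))
                aj[t0 + t] = j
                a1[t0 + t], a2[t0 + t] = j // 2, j % 2
                r1 = center_outcome(outcome_for_action(int(blk.P[t]), j // 2 + 1))
                r2 = center_outcome(outcome_for_action(int(blk.Q[t]), j % 2 + 1))
                V[j] += params.alpha * ((r1 + r2) - V[j])
                prev = j
        else:
            Vc = np.zeros((2, 2))
            Vi = np.zeros((2, 2))
            omega = 0.0
            prev = [-1, -1]
            for t in range(Tb):
                w = (inverse_logit(omega) if spec.dynamic_weight
                     else spec.fixed_weight)
                acts = []
                for d in range(2):
                    u0 = params.beta * (w * Vc[d, 0] + (1.0 - w) * Vi[d, 0])
                    u1 = params.beta * (w * Vc[d, 1] + (1.0 - w) * Vi[d, 1])
                    if prev[d] == 0:
                        u0 += params.rho
                    elif prev[d] == 1:
                        u1 += params.rho
                    m = max(u0, u1)
                    e0, e1 = np.exp(u0 - m), np.exp(u1 - m)
                    p0 = e0 / (e0 + e1)
                    acts.append(0 if rng.random() < p0 else 1)
                a1[t0 + t], a2[t0 + t] = acts
                r1 = center_outcome(outcome_for_action(int(blk.P[t]), acts[0] + 1))
                r2 = center_outcome(outcome_for_action(int(blk.Q[t]), acts[1] + 1))
                dc = [r1 - Vc[0, acts[0]], r2 - Vc[1, acts[1]]]
                di = [r2 - Vi[0, acts[0]], r1 - Vi[1, acts[1]]]
                for d in range(2):
                    a = acts[d]
                    Vc[d, a] += params.alpha * dc[d]
                    Vi[d, a] += params.alpha * di[d]
                    if spec.counterfactual_mode == "counterfactual":
                        Vc[d, 1 - a] -= params.alpha * dc[d]
                        Vi[d, 1 - a] -= params.alpha * di[d]
                    elif spec.counterfactual_mode == "lr_decay":
                        Vc[d, 1 - a] *= (1.0 - params.alpha)
                        Vi[d, 1 - a] *= (1.0 - params.alpha)
                    else:
                        Vc[d, 1 - a] *= (1.0 - params.decay)
                        Vi[d, 1 - a] *= (1.0 - params.decay)
                if spec.dynamic_weight:
                    ev = (abs(di[1]) - abs(dc[0])) + (abs(di[0]) - abs(dc[1]))
                    omega += params.epsilon * ev
                prev = acts
        t0 += Tb
    actions = np.stack([a1, a2], axis=1) + 1
    frame = session_to_frame(blocks, actions, run=run)
    _, trace = negative_log_likelihood(spec, params, frame, return_trace=True)
    return frame, trace


def _frame_arrays(trials: pd.DataFrame):
    a1 = trials["action_d1"].to_numpy(dtype=np.int64) - 1
    a2 = trials["action_d2"].to_numpy(dtype=np.int64) - 1
    if not (np.isin(a1, (0, 1)).all() and np.isin(a2, (0, 1)).all()):
        raise ValueError("actions must be coded 1/2")
    r1 = np.asarray(center_outcome(trials["outcome_d1"].to_numpy()))
    r2 = np.asarray(center_outcome(trials["outcome_d2"].to_numpy()))
    block = trials["block"].to_numpy(dtype=np.int64)
    trial = trials["trial"].to_numpy(dtype=np.int64)
    if "run" in trials:
        run_block = trials["run"].to_numpy(dtype=np.int64) * 10_000 + block
    else:
        run_block = block
    newblock = np.ones(len(trials), dtype=np.int64)
    newblock[1:] = (run_block[1:] != run_block[:-1]).astype(np.int64)
    newblock[0] = 1
    return a1, a2, r1, r2, newblock, block, trial


def negative_log_likelihood(spec: ModelSpec, params: ModelParams,
                            trials: pd.DataFrame, return_trace: bool = False):
    """Sum over trials and decisions of -log P(chosen action), with latents
    propagated exactly as in ``simulate``.

    Returns the scalar NLL, or ``(nll, trace)`` if ``return_trace``.
    """
    a1, a2, r1, r2, newblock, block, trial = _frame_arrays(trials)
    if spec.is_joint:
        spec.check_params(params)
        aj = a1 * 2 + a2
        rsum = r1 + r2
        if return_trace:
            T = len(aj)
            trace = JointLatentTrace(
                block=block, trial=trial, joint_action=aj,
                rewards=np.stack([r1, r2], axis=1),
                V=np.zeros((T, 4)), delta=np.zeros(T),
                p=np.zeros((T, 4)), p_chosen=np.zeros(T))
            nll = _kernels.trace_joint(aj, rsum, newblock, params.alpha,
                                       params.beta, params.rho,
                                       trace.V, trace.delta, trace.p,
                                       trace.p_chosen)
            return float(nll), trace
        return float(_kernels.nll_joint(aj, rsum, newblock, params.alpha,
                                        params.beta, params.rho))
    if return_trace:
        nll, trace = _run_trace(spec, params, a1, a2, r1, r2, newblock,
                                block, trial)
        return float(nll), trace
    args = _kernel_args(spec, params)
    return float(_kernels.nll_two_policy(a1, a2, r1, r2, newblock, *args))


def trace_to_frame(trace: LatentTrace) -> pd.DataFrame:
    """Flatten a latent trace to one row per trial x decision."""
    T = trace.n_trials
    rows = []
    for t in range(T):
        for d in range(2):
            rows.append({
                "block": trace.block[t], "trial": trace.trial[t],
                "decision": d + 1,
                "action": trace.actions[t, d] + 1,
                "reward": trace.rewards[t, d],
                "V_correct_a1": trace.V_correct[t, d, 0],
                "V_correct_a2": trace.V_correct[t, d, 1],
                "V_incorrect_a1": trace.V_incorrect[t, d, 0],
                "V_incorrect_a2": trace.V_incorrect[t, d, 1],
                "delta_correct": trace.delta_correct[t, d],
                "delta_incorrect": trace.delta_incorrect[t, d],
                "surprise_correct": trace.surprise_correct[t, d],
                "surprise_incorrect": trace.surprise_incorrect[t, d],
                "evidence_o": trace.evidence[t, d],
                "omega": trace.omega[t],
                "weight": trace.weight[t],
                "p_action1": trace.p_action1[t, d],
                "p_chosen": trace.p_chosen[t, d],
            })
    return pd.DataFrame(rows)
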