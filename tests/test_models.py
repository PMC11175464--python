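"""Model dynamics: recursion steps, likelihoods, and exact equivalences."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from creditassign import models
from creditassign.models import ModelParams, get_model, negative_log_likelihood
from creditassign.task import TaskConfig, generate_session

from .reference import (reference_joint_action, reference_single_policy_td,
                        reference_two_policy)


def random_trials(rng, n_trials=50, n_blocks=2, run=0):
    """Arbitrary (model-free) trial data: random actions and outcomes."""
    rows = []
    for b in range(n_blocks):
        for t in range(n_trials // n_blocks):
            rows.append({
                "run": run, "block": b, "trial": t,
                "action_d1": int(rng.integers(1, 3)),
                "action_d2": int(rng.integers(1, 3)),
                "outcome_d1": int(rng.integers(1, 100)),
                "outcome_d2": int(rng.integers(1, 100)),
                "mapping_d1": 1, "first_color": 1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary steps

def test_prediction_errors_substitution():
    V0 = np.zeros((2, 2))
    dc, di = models.prediction_errors(V0, V0, rewards=(0.5, -0.2),
                                      actions=(0, 1))
    assert dc == pytest.approx([0.5, -0.2])
    assert di == pytest.approx([-0.2, 0.5])
    # perfect prediction
    Vp = np.full((2, 2), 0.5)
    dc, _ = models.prediction_errors(Vp, V0, rewards=(0.5, 0.5),
                                     actions=(0, 0))
    assert dc == pytest.approx([0.0, 0.0])
    # nonzero expectation: V = 0.2, outcome 40 points -> delta = -0.4
    Vq = np.zeros((2, 2))
    Vq[0, 0] = 0.2
    dc, _ = models.prediction_errors(Vq, V0, rewards=(-0.2, 0.0),
                                     actions=(0, 0))
    assert dc[0] == pytest.approx(-0.4)


def test_update_values_modes():
    V = np.zeros((2, 2))
    # alpha = 0 leaves values unchanged
    out = models.update_values(V, deltas=(0.7, -0.3), actions=(0, 1),
                               alpha=0.0)
    assert np.all(out == 0)
    out = models.update_values(V, deltas=(0.5, 0.0), actions=(0, 0),
                               alpha=0.5)
    assert out[0, 0] == pytest.approx(0.25)
    assert out[0, 1] == pytest.approx(-0.25)
    # decay modes shrink the unchosen option instead of mirroring
    V2 = np.array([[0.4, 0.8], [0.0, 0.0]])
    out = models.update_values(V2, deltas=(0.0, 0.0), actions=(0, 0),
                               alpha=0.25, counterfactual_mode="lr_decay")
    assert out[0, 1] == pytest.approx(0.6)
    out = models.update_values(V2, deltas=(0.0, 0.0), actions=(0, 0),
                               alpha=0.25, counterfactual_mode="free_decay",
                               decay=0.5)
    assert out[0, 1] == pytest.approx(0.4)


@pytest.mark.parametrize("delta,expected", [(-0.4, 0.4), (0.0, 0.0),
                                            (0.98, 0.98)])
def test_surprise_is_absolute_prediction_error(delta, expected):
    assert models.surprise(delta) == pytest.approx(expected)


def test_evidence_cross_decision_pairing():
    # equal surprises cancel
    assert models.evidence((0.3, 0.3), (0.3, 0.3)) == pytest.approx([0, 0])
    # evidence for o1 compares the incorrect policy's d2 surprise with the
    # correct policy's d1 surprise
    ev = models.evidence((0.2, 0.1), (0.5, 0.6))
    assert ev[0] == pytest.approx(0.6 - 0.2)
    assert ev[1] == pytest.approx(0.5 - 0.1)
    # swapping the two policies' surprise tables negates the evidence
    swapped = models.evidence((0.5, 0.6), (0.2, 0.1))
    assert swapped == pytest.approx(-ev)


def test_update_arbitration():
    assert models.update_arbitration(1.3, (0.4, -0.2), 0.0) == 1.3
    omega = models.update_arbitration(0.0, (0.4, 0.2), 0.5)
    assert omega == pytest.approx(0.3)
    assert models.inverse_logit(omega) == pytest.approx(0.574442517)


def test_net_values_mixture():
    Vc = np.array([[0.4, -0.4], [0.2, -0.2]])
    Vi = np.array([[-0.2, 0.2], [0.0, 0.0]])
    assert models.net_values(Vc, Vi, 0.5) == pytest.approx((Vc + Vi) / 2)
    assert models.net_values(Vc, Vi, 1.0) == pytest.approx(Vc)
    assert models.net_values(Vc, Vi, 0.75)[0, 0] == pytest.approx(0.25)


def test_choice_probabilities():
    V = np.array([[0.98, -0.98], [0.0, 0.0]])
    p = models.choice_probabilities(V, beta=0.0, rho=0.0)
    assert p == pytest.approx(0.5 * np.ones((2, 2)))
    p = models.choice_probabilities(V, beta=20.0, rho=0.0)
    assert p[0, 0] == pytest.approx(1.0 / (1.0 + math.exp(-39.2)))
    # perseveration alone: previously chosen action gets inverse-logit(rho)
    p = models.choice_probabilities(np.zeros((2, 2)), beta=5.0, rho=1.0,
                                    previous_actions=(0, -1))
    assert p[0, 0] == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))
    assert p.sum(axis=1) == pytest.approx([1.0, 1.0])


def test_joint_action_step():
    params = ModelParams(alpha=0.3, beta=0.0, rho=0.0)
    V, probs, delta = models.joint_action_step(
        np.zeros(4), rewards=(0.5, -0.5), joint_action=2, params=params)
    assert probs == pytest.approx(0.25 * np.ones(4))
    assert delta == pytest.approx(0.0)          # 75 + 25 points cancel
    # outcomes 75 and 99 -> summed centered reward 1.48
    V, _, delta = models.joint_action_step(
        np.zeros(4), rewards=(0.5, 0.98), joint_action=1, params=params)
    assert delta == pytest.approx(1.48)
    assert V[1] == pytest.approx(0.444)


# ---------------------------------------------------------------------------
# invariants

@settings(max_examples=20, deadline=None, derandomize=True)
@given(alpha=st.floats(0.0, 1.0), beta=st.floats(0.0, 10.0),
       rho=st.floats(-2.0, 2.0), epsilon=st.floats(0.0, 1.0),
       seed=st.integers(0, 10_000))
def test_value_antisymmetry_and_normalization(alpha, beta, rho, epsilon, seed):
    """Counterfactual updating from zero initialization keeps the two
    actions' values exactly mirrored, and choice probabilities normalized,
    for every policy, decision and trial."""
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_blocks=1, n_trials_per_block=12)
    blocks = generate_session(cfg, rng)
    spec = get_model("surprise_min")
    params = ModelParams(alpha=alpha, beta=beta, rho=rho, epsilon=epsilon)
    _, trace = models.simulate(spec, params, blocks, rng)
    assert np.array_equal(trace.V_correct[:, :, 0], -trace.V_correct[:, :, 1])
    assert np.array_equal(trace.V_incorrect[:, :, 0],
                          -trace.V_incorrect[:, :, 1])
    assert np.all(trace.surprise_correct >= 0)
    assert np.all(trace.surprise_incorrect >= 0)
    assert np.all((trace.weight > 0) & (trace.weight < 1))
    assert np.all((trace.p_action1 >= 0) & (trace.p_action1 <= 1))


def test_state_resets_at_block_boundaries(simulated_agent):
    trace = simulated_agent["trace"]
    starts = np.flatnonzero(np.r_[1, np.diff(trace.block)] != 0)
    starts = np.r_[0, starts[starts > 0]]
    assert np.all(trace.omega[starts] == 0.0)
    assert np.all(trace.weight[starts] == 0.5)
    assert np.all(trace.V_correct[starts] == 0.0)


def test_uniform_policy_nll_is_2T_log2(rng):
    trials = random_trials(rng, n_trials=40)
    spec = get_model("surprise_min")
    params = ModelParams(alpha=0.5, beta=0.0, rho=0.0, epsilon=0.5)
    nll = negative_log_likelihood(spec, params, trials)
    assert nll == pytest.approx(2 * len(trials) * math.log(2), abs=1e-9)


def test_epsilon_zero_equals_random_policy(rng):
    """With the assignment rate at 0 the arbitration never moves off 0.5,
    so the full model is likelihood-identical to the random-policy model."""
    trials = random_trials(rng, n_trials=60)
    full = negative_log_likelihood(
        get_model("surprise_min"),
        ModelParams(alpha=0.37, beta=4.2, rho=-0.8, epsilon=0.0), trials)
    fixed = negative_log_likelihood(
        get_model("random_policy"),
        ModelParams(alpha=0.37, beta=4.2, rho=-0.8), trials)
    assert abs(full - fixed) < 1e-12


@pytest.mark.parametrize("weight,which", [(1.0, "relevant"),
                                          (0.0, "irrelevant")])
def test_pinned_weight_equals_single_policy_td(rng, weight, which):
    """Weight pinned at 1 (0) reduces the model to a plain TD learner on
    the relevant (irrelevant) outcomes, exactly, on arbitrary data."""
    trials = random_trials(rng, n_trials=60)
    model_id = "correct_policy" if weight == 1.0 else "incorrect_policy"
    nll = negative_log_likelihood(
        get_model(model_id, fixed_weight=weight),
        ModelParams(alpha=0.3, beta=6.0, rho=0.4), trials)
    ref = reference_single_policy_td(trials, alpha=0.3, beta=6.0, rho=0.4,
                                     which=which)
    assert abs(nll - ref) < 1e-12


@pytest.mark.parametrize("model_id,kwargs", [
    ("surprise_min", {"epsilon": 0.6}),
    ("correct_policy", {}),
    ("incorrect_policy", {}),
    ("random_policy", {}),
    ("surprise_min_lrdecay", {"epsilon": 0.6}),
    ("surprise_min_freedecay", {"epsilon": 0.6, "decay": 0.3}),
])
def test_likelihood_matches_slow_reference(rng, model_id, kwargs):
    trials = random_trials(rng, n_trials=50)
    params = ModelParams(alpha=0.45, beta=3.5, rho=0.7, **kwargs)
    spec = get_model(model_id)
    nll = negative_log_likelihood(spec, params, trials)
    ref, _ = reference_two_policy(
        trials, alpha=0.45, beta=3.5, rho=0.7,
        epsilon=kwargs.get("epsilon", 0.0),
        fixed_weight=spec.fixed_weight,
        counterfactual=spec.counterfactual_mode,
        decay=kwargs.get("decay", 0.0))
    assert nll == pytest.approx(ref, abs=1e-10)


def test_joint_likelihood_matches_slow_reference(rng):
    trials = random_trials(rng, n_trials=50)
    nll = negative_log_likelihood(get_model("joint_action"),
                                  ModelParams(alpha=0.4, beta=2.5, rho=0.6),
                                  trials)
    ref = reference_joint_action(trials, alpha=0.4, beta=2.5, rho=0.6)
    assert nll == pytest.approx(ref, abs=1e-10)


def test_latents_match_slow_reference(simulated_agent):
    """The latent trace replayed on simulated choices agrees with the
    independent trial-loop, variable by variable."""
    trials, trace = simulated_agent["trials"], simulated_agent["trace"]
    p = simulated_agent["params"]
    _, lat = reference_two_policy(trials, alpha=p.alpha, beta=p.beta,
                                  rho=p.rho, epsilon=p.epsilon)
    T = trace.n_trials
    for t in range(T):
        assert trace.omega[t] == pytest.approx(lat["omega"][t], abs=1e-12)
        assert trace.weight[t] == pytest.approx(lat["weight"][t], abs=1e-12)
        for d in (1, 2):
            assert trace.delta_correct[t, d - 1] == pytest.approx(
                lat["delta_correct"][t][d], abs=1e-12)
            assert trace.delta_incorrect[t, d - 1] == pytest.approx(
                lat["delta_incorrect"][t][d], abs=1e-12)
            assert trace.p_chosen[t, d - 1] == pytest.approx(
                lat["p_chosen"][t][d], abs=1e-12)
        assert trace.evidence[t, 0] == pytest.approx(lat["evidence"][t][0],
                                                     abs=1e-12)


def test_simulated_actions_consistent_with_trace(simulated_agent):
    trials, trace = simulated_agent["trials"], simulated_agent["trace"]
    assert np.array_equal(trials["action_d1"].to_numpy() - 1,
                          trace.actions[:, 0])
    assert np.array_equal(trials["action_d2"].to_numpy() - 1,
                          trace.actions[:, 1])


def test_generating_parameters_beat_distant_parameters(rng):
    """On average over simulated datasets, the generating parameters have a
    lower NLL than parameters perturbed far away."""
    spec = get_model("surprise_min")
    gen = ModelParams(alpha=0.4, beta=6.0, rho=0.0, epsilon=0.5)
    far = ModelParams(alpha=0.95, beta=0.5, rho=2.5, epsilon=0.05)
    diffs = []
    for _ in range(10):
        blocks = generate_session(TaskConfig(n_blocks=1,
                                             n_trials_per_block=80), rng)
        trials, _ = models.simulate(spec, gen, blocks, rng)
        diffs.append(negative_log_likelihood(spec, far, trials)
                     - negative_log_likelihood(spec, gen, trials))
    assert np.mean(diffs) > 0


def test_spec_params_mismatch_raises(rng):
    trials = random_trials(rng, n_trials=10)
    with pytest.raises(ValueError):
        negative_log_likelihood(get_model("surprise_min"),
                                ModelParams(alpha=0.4, beta=2.0, rho=0.0),
                                trials)
    with pytest.raises(ValueError):
        get_model("surprise_min", fixed_weight=0.7)


def test_trace_export_shape(simulated_agent):
    frame = models.trace_to_frame(simulated_agent["trace"])
    assert len(frame) == 2 * simulated_agent["trace"].n_trials
    assert {"decision", "delta_correct", "surprise_incorrect", "weight",
            "p_chosen"} <= set(frame.columns)
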