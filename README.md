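# creditassign

Structural credit assignment in multi-bandit tasks: when several decisions
produce several outcomes and the decision→outcome mapping is hidden, an
agent must infer *which outcome its own action caused* before ordinary
reinforcement learning can work. `creditassign` implements a complete,
tested pipeline for studying this problem with a surprise-minimization
arbitration model: task simulation, a family of candidate learning models,
MAP fitting with random-effects Bayesian model selection, the behavioral
statistics (win-stay/lose-shift, planned contrasts, chance tests), and
model-based single-trial EEG regression with cluster-based permutation
tests. It is written for computational cognitive neuroscientists who want
to simulate the paradigm, fit the models to behavioral data, or validate
latent-variable EEG analyses on synthetic ground truth.

## The task and the model

In the **multiple-bandits task**, each trial holds two independent
two-armed decisions. Decision 1 pays `P` points for one action and
`100 − P` for the other (anti-correlation); decision 2 pays `Q` /
`100 − Q`. `P` and `Q` follow independent bounded Gaussian random walks
(step SD 15, values 1–99, 3 blocks × 100 trials). Outcomes are
colour-coded, and the decision→colour mapping is hidden.

The **surprise-minimization model** runs two temporal-difference policies
in parallel, one per candidate mapping. With centered rewards
`r = points/50 − 1`, each policy computes per-decision prediction errors
(shown here for decision 1; decision 2 is analogous):

    δ_correct(d1)   = r(o1) − V_correct(d1, a)
    δ_incorrect(d1) = r(o2) − V_incorrect(d1, a)
    V(d, a) ← V(d, a) + α·δ            (chosen action)
    V(d, a') ← V(d, a') − α·δ          (unchosen action, counterfactual)

Surprise is `|δ|`, read as negative model evidence. Per outcome, the two
policies' surprises are compared across decisions to yield an evidence
signal, which is accumulated at the assignment rate ε into a log-odds
arbitration weight ω:

    Δ(o1) = surprise_incorrect(d2) − surprise_correct(d1)
    Δ(o2) = surprise_incorrect(d1) − surprise_correct(d2)
    ω ← ω + ε·(Δ(o1) + Δ(o2)),      w = logit⁻¹(ω)

Action selection is a softmax over weighted net values with inverse
temperature β and a perseveration bonus ρ for repeating the previous
action:

    V_net = w·V_correct + (1 − w)·V_incorrect
    P(a) ∝ exp(β·V_net(a) + ρ·rep(a))

Competitor models: the **correct / incorrect / random policy** variants
(ω pinned so that w = 0.9 / 0.1 / 0.5; ε removed) and a **joint-action**
model that treats each trial as one 4-way choice scored against the summed
outcomes. All models run generatively and in likelihood mode with a full
latent trace (values, prediction errors, surprises, evidence, weight,
choice probabilities).

## Worked example

```python
import numpy as np
from creditassign import (ModelParams, TaskConfig, generate_session,
                          get_model, simulate)

rng = np.random.default_rng(7)
params = ModelParams(alpha=0.4, beta=5.0, rho=0.3, epsilon=0.4)
blocks = generate_session(TaskConfig(), rng)
trials, trace = simulate(get_model("surprise_min"), params, blocks, rng)
print(round(trace.final_weight(), 4),
      round(trace.surprise_correct.mean(), 3),
      round(trace.surprise_incorrect.mean(), 3))
```

prints

```
1.0 0.235 0.347
```

— the arbitration weight has moved from 0.5 to 1.0 (full control to the
policy holding the true mapping), and the correct policy is on average
less surprised (0.235) than the incorrect one (0.347): the agent has
solved the credit assignment problem. The scripts in `examples/` walk
through each capability (task structure, arbitration dynamics, fitting
and model comparison, behavioral statistics, EEG regression) and print
annotated output.

A thin command-line layer exposes the end-to-end workflows:

```bash
creditassign simulate --runs 100 --seed 1 --out runs/sim
creditassign fit --data runs/sim/trials.tsv --out runs/fits
creditassign analyze-behavior --data runs/sim/trials.tsv --out runs/beh
creditassign validate --seed 1
```

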