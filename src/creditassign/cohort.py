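"""Synthetic cohorts: many agents playing the multiple-bandits task.

A cohort bundles, per agent, the generated task blocks, the trial table,
the latent trace, and the generating parameters — the synthetic stand-in
for a group of participants.  Transfer-task accuracy (an explicit-report
measure in the real experiment) is emulated as a binomial readout of each
block's final arbitration weight: an agent that has arbitrated fully to
the correct mapping reports it near-perfectly, an uncommitted agent is at
chance.  See docs/methods.md for what this emulates and what it does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import sample_params
from .models import ModelParams, ModelSpec, get_model, simulate
from .task import TaskConfig, generate_session

__all__ = ["Cohort", "simulate_cohort"]

TRANSFER_TRIALS_PER_BLOCK = 20


@dataclass
class Cohort:
    """A simulated group of agents."""

    trials: dict            # subject -> trial DataFrame
    traces: dict            # subject -> LatentTrace
    params: pd.DataFrame    # one row per subject, generating parameters
    transfer_acc: pd.Series # subject -> emulated transfer accuracy

    @property
    def subjects(self):
        return list(self.trials)

    def stacked_trials(self) -> pd.DataFrame:
        frames = []
        for subject, frame in self.trials.items():
            frames.append(frame.assign(subject=subject))
        return pd.concat(frames, ignore_index=True)


def _block_end_weights(trace, params: ModelParams, spec: ModelSpec
                       ) -> np.ndarray:
    """Arbitration weight after the last update of each block."""
    blocks = np.unique(trace.block)
    out = np.empty(len(blocks))
    for i, b in enumerate(blocks):
        idx = np.where(trace.block == b)[0]
        last = idx[-1]
        if spec.dynamic_weight:
            omega = trace.omega[last] + params.epsilon * trace.evidence[last].sum()
        else:
            omega = trace.omega[last]
        out[i] = 1.0 / (1.0 + np.exp(-np.clip(omega, -700, 700)))
    return out


def simulate_cohort(n_subjects: int,
                    model_id: str = "surprise_min",
                    config: TaskConfig | None = None,
                    rng: np.random.Generator | None = None,
                    params_list: list[ModelParams] | None = None,
                    fixed_weight: float | None = None) -> Cohort:
    """Simulate ``n_subjects`` agents with prior-drawn (or given)
    parameters on freshly generated task sessions."""
    if config is None:
        config = TaskConfig()
    if rng is None:
        rng = np.random.default_rng()
    spec = get_model(model_id, fixed_weight=fixed_weight)
    trials, traces, rows, transfer = {}, {}, [], {}
    for s in range(n_subjects):
        params = (params_list[s] if params_list is not None
                  else sample_params(spec, rng))
        blocks = generate_session(config, rng)
        frame, trace = simulate(spec, params, blocks, rng)
        trials[s] = frame
        traces[s] = trace
        rows.append({"subject": s,
                     **{n: getattr(params, n) for n in spec.param_names}})
        w_end = _block_end_weights(trace, params, spec)
        hits = rng.binomial(TRANSFER_TRIALS_PER_BLOCK, w_end)
        transfer[s] = hits.sum() / (TRANSFER_TRIALS_PER_BLOCK * len(w_end))
    return Cohort(trials=trials, traces=traces,
                  params=pd.DataFrame(rows),
                  transfer_acc=pd.Series(transfer, name="transfer_acc"))
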