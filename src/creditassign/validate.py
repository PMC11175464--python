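"""Monte-Carlo validation statistics of the arbitration model.

Three desk-scale statistics summarize whether the surprise-minimization
mechanism solves the credit assignment problem under the study conditions
(3 blocks x 100 trials, prior-drawn parameters):

* arbitration convergence — the fraction of runs whose final arbitration
  weight favors the correct policy;
* surprise separation — the paired signed-rank Z comparing each run's mean
  surprise under the correct vs the incorrect policy;
* walk stability — the mean number of consecutive trials an outcome walk
  stays on one side of the win/loss threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import signed_rank_z
from .fitting import sample_params
from .models import get_model, simulate
from .task import TaskConfig, generate_session, generate_walk

__all__ = [
    "run_convergence_sims",
    "arbitration_convergence",
    "surprise_separation",
    "walk_stability",
    "same_side_run_lengths",
]


def run_convergence_sims(n_runs: int = 1000,
                         config: TaskConfig | None = None,
                         rng: np.random.Generator | None = None,
                         model_id: str = "surprise_min") -> pd.DataFrame:
    """Simulate prior-drawn agents; one row per run with the final
    arbitration weight and the mean surprise under each policy."""
    if config is None:
        config = TaskConfig()
    if rng is None:
        rng = np.random.default_rng()
    spec = get_model(model_id)
    rows = []
    for r in range(n_runs):
        params = sample_params(spec, rng)
        blocks = generate_session(config, rng)
        _, trace = simulate(spec, params, blocks, rng)
        rows.append({
            "run": r,
            "final_weight": trace.final_weight(),
            "mean_surprise_correct": float(trace.surprise_correct.mean()),
            "mean_surprise_incorrect": float(trace.surprise_incorrect.mean()),
            **{n: getattr(params, n) for n in spec.param_names},
        })
    return pd.DataFrame(rows)


def arbitration_convergence(sims: pd.DataFrame, level: float = 0.95) -> dict:
    """Count of runs with final weight > 0.5, with a Clopper-Pearson CI."""
    n = len(sims)
    k = int((sims["final_weight"] > 0.5).sum())
    lo = stats.beta.ppf((1 - level) / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - (1 - level) / 2, k + 1, n - k) if k < n else 1.0
    return {"n_converged": k, "n_runs": n, "proportion": k / n,
            "ci_low": float(lo), "ci_high": float(hi)}


def surprise_separation(sims: pd.DataFrame) -> dict:
    """Paired Wilcoxon signed-rank Z (normal approximation) of per-run mean
    surprise, incorrect minus correct policy.  Positive Z means the correct
    policy was less surprised."""
    diff = (sims["mean_surprise_incorrect"]
            - sims["mean_surprise_correct"]).to_numpy()
    w_plus, z, p = signed_rank_z(diff)
    return {"z": z, "p": p, "w_plus": w_plus, "n": len(diff),
            "n_separated": int((diff > 0).sum())}


def same_side_run_lengths(walk: np.ndarray, threshold: int = 50) -> list[int]:
    """Lengths of the maximal runs a walk spends on one side of the
    threshold (values equal to the threshold count as the loss side)."""
    side = np.asarray(walk) > threshold
    lengths, current = [], 1
    for i in range(1, len(side)):
        if side[i] == side[i - 1]:
            current += 1
        else:
            lengths.append(current)
            current = 1
    lengths.append(current)
    return lengths


def walk_stability(n_blocks: int = 10_000,
                   config: TaskConfig | None = None,
                   rng: np.random.Generator | None = None) -> dict:
    """Mean same-side run length over many freshly simulated walks."""
    if config is None:
        config = TaskConfig()
    if rng is None:
        rng = np.random.default_rng()
    lengths = []
    for _ in range(n_blocks):
        walk = generate_walk(config.n_trials_per_block, config.walk_sd,
                             config.walk_bounds, rng, config.boundary)
        lengths.extend(same_side_run_lengths(walk, config.win_threshold))
    lengths = np.asarray(lengths, dtype=float)
    sem = lengths.std(ddof=1) / np.sqrt(len(lengths))
    return {"mean_run_length": float(lengths.mean()),
            "sem": float(sem), "n_runs": len(lengths),
            "n_blocks": n_blocks, "boundary": config.boundary}
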