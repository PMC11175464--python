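"""The multiple-bandits environment.

A block of the task consists of two independent two-armed bandits
("decisions").  Each decision pays out a point value in [1, 99]; within a
decision the two actions are perfectly anti-correlated (values P and
100 - P), and P drifts across trials as a bounded Gaussian random walk.
The two outcomes are colour-coded, and the decision -> colour mapping is
hidden from the agent: inferring it is the structural credit assignment
problem this package is about.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "TaskBlock",
    "generate_walk",
    "generate_block",
    "generate_session",
    "outcome_for_action",
    "center_outcome",
    "dichotomize",
    "session_to_frame",
    "write_trials",
    "read_trials",
    "write_config",
    "read_config",
]

#: Boundary-handling schemes for the random walk.  None of the bounded
#: schemes is singled out by the task description; "reflect" is the default
#: (see docs/methods.md for the comparison against the stability statistic).
BOUNDARY_SCHEMES = ("reflect", "clip", "resample")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the multiple-bandits task.

    Defaults are the study conditions: 3 blocks of 100 trials, walk step
    SD 15 points, outcomes bounded in [1, 99], win threshold 50.
    """

    n_blocks: int = 3
    n_trials_per_block: int = 100
    walk_sd: float = 15.0
    walk_bounds: tuple[int, int] = (1, 99)
    win_threshold: int = 50
    boundary: str = "reflect"
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if not (lo < hi):
            raise ValueError(f"degenerate walk_bounds {self.walk_bounds}")
        if self.n_trials_per_block < 2:
            raise ValueError("n_trials_per_block must be >= 2 "
                             "(stay/switch analysis needs a predecessor trial)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        if self.boundary not in BOUNDARY_SCHEMES:
            raise ValueError(f"unknown boundary scheme {self.boundary!r}; "
                             f"choose from {BOUNDARY_SCHEMES}")


@dataclass
class TaskBlock:
    """One block's latent walks and hidden structure.

    ``P`` drives decision 1, ``Q`` drives decision 2 (integer points per
    trial).  ``mapping`` is the hidden decision -> outcome-colour
    permutation: ``mapping[d]`` is the colour (1 or 2) of the outcome caused
    by decision d+1.  ``outcome_order`` gives, per trial, the order in which
    the two colours are presented (serial presentation); it tags events for
    EEG analyses and has no effect on model computations.
    """

    P: np.ndarray
    Q: np.ndarray
    mapping: tuple[int, int]
    outcome_order: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.P)


def generate_walk(
    n_trials: int,
    sd: float,
    bounds: tuple[int, int] = (1, 99),
    rng: np.random.Generator | None = None,
    boundary: str = "reflect",
) -> np.ndarray:
    """Bounded Gaussian random walk of integer point values.

    The first value is uniform over the integers in ``bounds``; each
    subsequent value adds a N(0, sd) step, is kept inside the bounds by the
    chosen scheme, and is rounded to the nearest integer.

    Schemes: ``reflect`` mirrors overshoots off the bounds, ``clip``
    saturates at the bounds, ``resample`` redraws the step until the value
    lands inside (a truncated-Gaussian step).
    """
    if rng is None:
        raise ValueError("generate_walk requires an explicit seeded Generator")
    lo, hi = bounds
    if not (lo < hi):
        raise ValueError(f"degenerate bounds {bounds}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if boundary not in BOUNDARY_SCHEMES:
        raise ValueError(f"unknown boundary scheme {boundary!r}")

    out = np.empty(n_trials, dtype=np.int64)
    value = float(rng.integers(lo, hi + 1))
    out[0] = value
    span = 2.0 * (hi - lo)
    for t in range(1, n_trials):
        x = value + rng.normal(0.0, sd)
        if boundary == "reflect":
            # fold into [lo, hi] by repeated mirroring
            x = (x - lo) % span
            if x > hi - lo:
                x = span - x
            x += lo
        elif boundary == "clip":
            x = min(float(hi), max(float(lo), x))
        else:  # resample
            while x < lo or x > hi:
                x = value + rng.normal(0.0, sd)
        value = float(np.round(x))
        value = min(float(hi), max(float(lo), value))  # rounding guard
        out[t] = value
    return out


def generate_block(config: TaskConfig, rng: np.random.Generator) -> TaskBlock:
    """Generate one block: two independent walks plus the hidden structure."""
    P = generate_walk(config.n_trials_per_block, config.walk_sd,
                      config.walk_bounds, rng, config.boundary)
    Q = generate_walk(config.n_trials_per_block, config.walk_sd,
                      config.walk_bounds, rng, config.boundary)
    mapping = (1, 2) if rng.random() < 0.5 else (2, 1)
    order = np.empty((config.n_trials_per_block, 2), dtype=np.int64)
    for t in range(config.n_trials_per_block):
        order[t] = (1, 2) if rng.random() < 0.5 else (2, 1)
    return TaskBlock(P=P, Q=Q, mapping=mapping, outcome_order=order)


def generate_session(config: TaskConfig, rng: np.random.Generator | None = None
                     ) -> list[TaskBlock]:
    """Generate ``config.n_blocks`` independent blocks."""
    if rng is None:
        if config.seed is None:
            raise ValueError("provide rng or set config.seed")
        rng = np.random.default_rng(config.seed)
    return [generate_block(config, rng) for _ in range(config.n_blocks)]


def outcome_for_action(walk_value: int, action: int) -> int:
    """Points delivered for an action: the walk value for action 1, its
    anti-correlated complement (100 - value) for action 2."""
    if not 1 <= walk_value <= 99:
        raise ValueError(f"walk value {walk_value} outside [1, 99]")
    if action == 1:
        return int(walk_value)
    if action == 2:
        return int(100 - walk_value)
    raise ValueError(f"action must be 1 or 2, got {action}")


def center_outcome(points):
    """Map points in [1, 99] to the centered reward r = points/50 - 1."""
    arr = np.asarray(points, dtype=float)
    if np.any(arr < 1) or np.any(arr > 99):
        raise ValueError("outcome points must lie in [1, 99]")
    result = arr / 50.0 - 1.0
    return result if result.ndim else float(result)


def dichotomize(points, threshold: int = 50):
    """Win (+1) / loss (-1) coding of an outcome value.

    A win is strictly more than the threshold; exact ties count as losses
    (deterministic tie rule).
    """
    arr = np.asarray(points)
    result = np.where(arr > threshold, 1, -1).astype(np.int64)
    return result if result.ndim else int(result)


# ---------------------------------------------------------------------------
# tabular I/O

#: Columns of the trial table.  Actions and outcomes are in the decision
#: frame (``outcome_d1`` is the value delivered by decision 1); ``mapping_d1``
#: records the hidden colour of decision 1's outcome, and ``first_color`` the
#: colour presented first on that trial.
TRIAL_COLUMNS = [
    "run", "block", "trial",
    "action_d1", "action_d2",
    "outcome_d1", "outcome_d2",
    "walk_P", "walk_Q",
    "mapping_d1", "first_color",
]


def session_to_frame(blocks: Sequence[TaskBlock],
                     actions: np.ndarray,
                     run: int = 0) -> pd.DataFrame:
    """Assemble a trial table from blocks and chosen actions.

    ``actions`` has shape (total_trials, 2) with entries in {1, 2}.
    """
    rows = []
    t0 = 0
    for b, blk in enumerate(blocks):
        T = blk.n_trials
        for t in range(T):
            a1, a2 = int(actions[t0 + t, 0]), int(actions[t0 + t, 1])
            rows.append({
                "run": run, "block": b, "trial": t,
                "action_d1": a1, "action_d2": a2,
                "outcome_d1": outcome_for_action(int(blk.P[t]), a1),
                "outcome_d2": outcome_for_action(int(blk.Q[t]), a2),
                "walk_P": int(blk.P[t]), "walk_Q": int(blk.Q[t]),
                "mapping_d1": blk.mapping[0],
                "first_color": int(blk.outcome_order[t, 0]),
            })
        t0 += T
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(frame: pd.DataFrame, path) -> None:
    """Write a trial table as tab-separated text (lossless round-trip)."""
    frame.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("block", "trial", "action_d1", "action_d2",
                           "outcome_d1", "outcome_d2") if c not in frame]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    return frame


def write_config(config: TaskConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["walk_bounds"] = list(config.walk_bounds)
    with open(path, "w") as fh:
        yaml.safe_dump({"task": data}, fh, sort_keys=False)


def read_config(path) -> TaskConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)["task"]
    data["walk_bounds"] = tuple(data["walk_bounds"])
    return TaskConfig(**data)
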