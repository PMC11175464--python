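"""Model-based single-trial EEG regression and cluster permutation tests.

Latent variables of the arbitration model (prediction errors of both
policies, the evidence signal, the arbitration weight) are regressed on
epoched EEG amplitude at every channel x time point, per participant
(mass-univariate GLM).  Standardized betas are then tested against zero
across participants with a two-tailed cluster-based sign-flip permutation
test that controls the family-wise error over the channel x time grid.

A synthetic-epochs generator plants known spatio-temporal effects of the
latents into autocorrelated noise, so the whole pipeline is exercisable
(and its error rates measurable) without recorded data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal, sparse, stats
from scipy.sparse import csgraph

__all__ = [
    "Epochs",
    "grid_montage",
    "build_design",
    "simulate_epochs",
    "mass_glm",
    "cluster_permutation",
    "ClusterResult",
    "downsample",
]


@dataclass
class Epochs:
    """Epoched EEG: events x channels x time, with per-event metadata.

    ``times`` are seconds relative to the lock event and must be uniformly
    spaced at 1/``sfreq``.  ``metadata`` has one row per event and links
    each epoch to its trial and latent variables.
    """

    data: np.ndarray
    channels: list[str]
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be events x channels x time")
        e, c, t = self.data.shape
        if c != len(self.channels) or t != len(self.times):
            raise ValueError("data shape does not match channels/times")
        if len(self.metadata) != e:
            raise ValueError("metadata must have one row per event")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or
                        not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6)):
            raise ValueError("times must increase uniformly at 1/sfreq")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    # -- disk round-trip (hierarchical array container) --------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.create_dataset("times", data=self.times)
            fh.attrs["sfreq"] = self.sfreq
            fh.create_dataset(
                "channels",
                data=np.array(self.channels, dtype=h5py.string_dtype()))
            meta = fh.create_group("metadata")
            for col in self.metadata.columns:
                values = self.metadata[col].to_numpy()
                if values.dtype.kind in "OU":
                    values = values.astype(h5py.string_dtype())
                meta.create_dataset(col, data=values)
            meta.attrs["columns"] = np.array(
                list(self.metadata.columns), dtype=h5py.string_dtype())

    @classmethod
    def load(cls, path) -> "Epochs":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            times = fh["times"][()]
            sfreq = float(fh.attrs["sfreq"])
            channels = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in fh["channels"][()]]
            cols = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in fh["metadata"].attrs["columns"]]
            meta = {}
            for col in cols:
                values = fh["metadata"][col][()]
                if values.dtype.kind in "SO":
                    values = np.array([v.decode() for v in values])
                meta[col] = values
        return cls(data=data, channels=channels, times=times, sfreq=sfreq,
                   metadata=pd.DataFrame(meta))

    @classmethod
    def from_arrays(cls, data, channels, times, metadata, sfreq=None
                    ) -> "Epochs":
        """Adapter for standard epoched exports (per-event channel x time
        matrices plus an event table)."""
        times = np.asarray(times, dtype=float)
        if sfreq is None:
            sfreq = 1.0 / float(np.median(np.diff(times)))
        return cls(data=np.asarray(data, dtype=float),
                   channels=list(channels), times=times, sfreq=sfreq,
                   metadata=pd.DataFrame(metadata).reset_index(drop=True))


def grid_montage(n_rows: int = 4, n_cols: int = 4):
    """A small synthetic montage: channels on a grid with rook adjacency.

    Returns ``(channel_names, adjacency)`` with a sparse boolean
    channel x channel adjacency matrix.
    """
    names = [f"g{r}{c}" for r in range(n_rows) for c in range(n_cols)]
    n = n_rows * n_cols
    A = sparse.lil_matrix((n, n), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if r + 1 < n_rows:
                A[i, i + n_cols] = A[i + n_cols, i] = True
            if c + 1 < n_cols:
                A[i, i + 1] = A[i + 1, i] = True
    return names, A.tocsr()


# ---------------------------------------------------------------------------
# design matrices

DESIGN_COLUMNS = ("pe_correct", "pe_incorrect", "evidence", "weight")


def build_design(trace, trials: pd.DataFrame, lock: str = "feedback",
                 response_evidence: str = "within_decision",
                 split_valence_surprise: bool = False):
    """Event-level design matrix of z-scored model latents.

    Feedback lock: two events per trial in presentation order; the event
    showing the outcome of colour c carries the correct-policy prediction
    error of the decision that caused it, the incorrect-policy prediction
    error of the decision the wrong mapping blames, and that outcome's
    evidence signal.  Response lock: two events per trial (decision 1, 2)
    with within-decision latents; the evidence recombination is
    ``within_decision`` (surprise_incorrect - surprise_correct of the same
    decision) or ``per_outcome`` (the feedback pairing).

    ``split_valence_surprise`` replaces each signed prediction-error column
    with its valence (sign) and surprise (magnitude) parts.

    Returns ``(design, events, dropped)``: the z-scored design (with
    intercept), the event table aligned to it, and the list of columns
    dropped for zero variance.
    """
    if lock not in ("feedback", "response"):
        raise ValueError("lock must be 'feedback' or 'response'")
    if len(trials) != trace.n_trials:
        raise ValueError("trial table and latent trace are misaligned")
    mapping_d1 = trials["mapping_d1"].to_numpy()
    first_color = (trials["first_color"].to_numpy()
                   if "first_color" in trials else np.ones(len(trials), int))
    ev_rows, meta_rows = [], []
    for t in range(trace.n_trials):
        if lock == "feedback":
            colors = (first_color[t], 3 - first_color[t])
            for slot, color in enumerate(colors):
                d_correct = 0 if mapping_d1[t] == color else 1   # caused it
                d_incorrect = 1 - d_correct                      # blamed for it
                ev_rows.append({
                    "pe_correct": trace.delta_correct[t, d_correct],
                    "pe_incorrect": trace.delta_incorrect[t, d_incorrect],
                    "evidence": trace.evidence[t, d_correct],
                    "weight": trace.weight[t],
                })
                meta_rows.append({"trial_index": t,
                                  "block": trace.block[t],
                                  "trial": trace.trial[t],
                                  "event": "outcome", "slot": slot + 1,
                                  "color": color,
                                  "decision": d_correct + 1})
        else:
            for d in range(2):
                if response_evidence == "within_decision":
                    ev = (trace.surprise_incorrect[t, d]
                          - trace.surprise_correct[t, d])
                else:
                    ev = trace.evidence[t, d]
                ev_rows.append({
                    "pe_correct": trace.delta_correct[t, d],
                    "pe_incorrect": trace.delta_incorrect[t, d],
                    "evidence": ev,
                    "weight": trace.weight[t],
                })
                meta_rows.append({"trial_index": t,
                                  "block": trace.block[t],
                                  "trial": trace.trial[t],
                                  "event": "response", "slot": d + 1,
                                  "color": 0, "decision": d + 1})
    design = pd.DataFrame(ev_rows)
    if split_valence_surprise:
        for col in ("pe_correct", "pe_incorrect"):
            design[f"{col}_valence"] = np.sign(design[col])
            design[f"{col}_surprise"] = np.abs(design[col])
            design = design.drop(columns=col)
    dropped = []
    for col in list(design.columns):
        sd = design[col].std(ddof=0)
        if sd < 1e-12:
            dropped.append(col)
            design = design.drop(columns=col)
            continue
        design[col] = (design[col] - design[col].mean()) / sd
    if dropped:
        warnings.warn(f"dropped constant design columns: {dropped}",
                      RuntimeWarning)
    design.insert(0, "intercept", 1.0)
    return design, pd.DataFrame(meta_rows), dropped


# ---------------------------------------------------------------------------
# synthetic epochs

def simulate_epochs(design: pd.DataFrame, events: pd.DataFrame,
                    effects: dict, channels: list[str], times: np.ndarray,
                    rng: np.random.Generator,
                    noise_sd: float = 1.0, noise_ar: float = 0.7,
                    spatial_smooth: float = 0.5,
                    adjacency: sparse.spmatrix | None = None,
                    sfreq: float | None = None):
    """Generate epochs with planted latent-variable effects.

    ``effects`` maps a design column to ``(amplitude, channel_profile,
    time_window)``: the column's z-scored value enters each event's signal
    as amplitude x channel_profile x boxcar(time_window seconds).  Noise is
    first-order autoregressive over time and (optionally) smoothed across
    neighbouring channels — white noise would overstate the power of the
    permutation test.

    Returns ``(epochs, truth)`` where ``truth`` holds the planted beta maps
    (regressors x channels x time).
    """
    times = np.asarray(times, dtype=float)
    n_ev, n_ch, n_t = len(design), len(channels), len(times)
    if len(events) != n_ev:
        raise ValueError("design and events are misaligned")
    truth = {}
    data = np.zeros((n_ev, n_ch, n_t))
    for col, (amp, ch_profile, window) in effects.items():
        if col not in design.columns:
            raise ValueError(f"effect on unknown design column {col!r}")
        ch_profile = np.asarray(ch_profile, dtype=float)
        if ch_profile.shape != (n_ch,):
            raise ValueError("channel profile must have one weight per channel")
        t_profile = ((times >= window[0]) & (times <= window[1])).astype(float)
        beta_map = amp * np.outer(ch_profile, t_profile)
        truth[col] = beta_map
        data += design[col].to_numpy()[:, None, None] * beta_map[None]
    # AR(1) noise over time
    white = rng.normal(0.0, 1.0, size=(n_ev, n_ch, n_t))
    noise = np.empty_like(white)
    noise[..., 0] = white[..., 0]
    scale = np.sqrt(1.0 - noise_ar ** 2)
    for t in range(1, n_t):
        noise[..., t] = noise_ar * noise[..., t - 1] + scale * white[..., t]
    if spatial_smooth > 0 and adjacency is not None:
        S = sparse.eye(n_ch) + spatial_smooth * adjacency.astype(float)
        S = np.asarray(S.todense())
        S /= S.sum(axis=1, keepdims=True)
        noise = np.einsum("ij,ejt->eit", S, noise)
    data += noise_sd * noise
    if sfreq is None:
        sfreq = 1.0 / float(np.median(np.diff(times)))
    epochs = Epochs(data=data, channels=list(channels), times=times,
                    sfreq=sfreq, metadata=events.copy())
    return epochs, truth


# ---------------------------------------------------------------------------
# mass-univariate GLM

def mass_glm(epochs: Epochs, design: pd.DataFrame,
             standardize: str = "se") -> np.ndarray:
    """Per-participant OLS at every channel x time point.

    Returns betas of shape (regressors, channels, time).  ``standardize``:
    'se' divides each beta by its pointwise OLS standard error (the
    default; equalizes scales across participants and penalizes
    multicollinearity), 'residual_sd' divides by the residual SD, 'none'
    returns raw betas.
    """
    X = design.to_numpy(dtype=float)
    n_ev, k = X.shape
    if n_ev != epochs.n_events:
        raise ValueError("design rows must match epochs events")
    if n_ev <= k:
        raise ValueError("need more events than regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, R = np.linalg.qr(X)
        bad = [design.columns[i] for i in range(k)
               if abs(R[i, i]) < 1e-8 * abs(R).max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    n_ch, n_t = epochs.data.shape[1:]
    Y = epochs.data.reshape(n_ev, n_ch * n_t)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)                      # (k, points)
    resid = Y - X @ B
    dof = n_ev - k
    sigma2 = (resid ** 2).sum(axis=0) / dof      # (points,)
    if standardize == "se":
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        B = B / np.maximum(se, 1e-300)
    elif standardize == "residual_sd":
        B = B / np.maximum(np.sqrt(sigma2)[None, :], 1e-300)
    elif standardize != "none":
        raise ValueError("standardize must be 'se', 'residual_sd' or 'none'")
    return B.reshape(k, n_ch, n_t)


# ---------------------------------------------------------------------------
# cluster-based permutation test

@dataclass
class ClusterResult:
    """Signed channel x time clusters with sign-flip permutation p-values."""

    clusters: list          # dicts: indices (array of (ch, t)), mass, sign, p
    t_obs: np.ndarray       # observed one-sample t map (channels x time)
    threshold: float
    n_permutations: int
    exact: bool
    channels: list[str] = field(default_factory=list)
    times: np.ndarray | None = None

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c["p"] <= alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            ch_idx = sorted({int(p[0]) for p in c["indices"]})
            t_idx = [int(p[1]) for p in c["indices"]]
            row = {"cluster": i, "sign": c["sign"],
                   "n_points": len(c["indices"]),
                   "mass": c["mass"], "p": c["p"],
                   "channels": ",".join(self.channels[j] for j in ch_idx)
                   if self.channels else str(ch_idx)}
            if self.times is not None:
                row["t_min_ms"] = 1000.0 * self.times[min(t_idx)]
                row["t_max_ms"] = 1000.0 * self.times[max(t_idx)]
            rows.append(row)
        return pd.DataFrame(rows)


def _point_adjacency(channel_adj: sparse.spmatrix, n_t: int
                     ) -> sparse.csr_matrix:
    """Adjacency over flattened (channel, time) points: neighbouring
    channels at the same sample plus consecutive samples within a
    channel."""
    n_ch = channel_adj.shape[0]
    time_adj = sparse.diags([np.ones(n_t - 1)], [1], shape=(n_t, n_t))
    time_adj = time_adj + time_adj.T
    A = sparse.kron(channel_adj.astype(float), sparse.eye(n_t)) \
        + sparse.kron(sparse.eye(n_ch), time_adj)
    return A.tocsr()


def _cluster_masses(tmap_flat: np.ndarray, thresh: float,
                    A: sparse.csr_matrix):
    """Signed suprathreshold clusters of a flattened t-map.

    Returns a list of (member_indices, mass, sign)."""
    out = []
    for sign in (1, -1):
        mask = (sign * tmap_flat) > thresh
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = A[idx][:, idx]
        n_comp, labels = csgraph.connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            out.append((members, float(tmap_flat[members].sum()), sign))
    return out


def _t_maps(data2d: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t maps for many sign-flip assignments at once.

    ``data2d`` is (subjects, points); ``flips`` is (n_perm, subjects) of
    +/-1.  Sign flips leave each subject's squared values unchanged, so
    only the mean changes.
    """
    n = data2d.shape[0]
    sum_sq = (data2d ** 2).sum(axis=0)           # (points,)
    means = (flips @ data2d) / n                 # (n_perm, points)
    var = (sum_sq[None, :] - n * means ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def cluster_permutation(betas: np.ndarray, adjacency: sparse.spmatrix,
                        rng: np.random.Generator,
                        alpha: float = 0.05,
                        n_permutations: int = 10_000,
                        cluster_alpha: float = 0.05,
                        channels: list[str] | None = None,
                        times: np.ndarray | None = None) -> ClusterResult:
    """Two-tailed cluster-based sign-flip permutation test.

    ``betas`` is participants x channels x time (standardized betas of one
    regressor).  Points whose uncorrected two-tailed one-sample p is below
    ``cluster_alpha`` are grouped into signed clusters by channel/time
    adjacency; the cluster statistic is the mass (sum of t).  The null
    distribution of the maximal absolute mass is built from random sign
    flips of participants (exact enumeration when all flips fit in
    ``n_permutations``); cluster p-values use the add-one convention and
    family-wise significance is assessed at ``alpha``.
    """
    betas = np.asarray(betas, dtype=float)
    n_sub, n_ch, n_t = betas.shape
    if n_sub < 6:
        raise ValueError("need at least 6 participants")
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must cover all channels")
    thresh = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n_sub - 1))
    A = _point_adjacency(adjacency, n_t)
    data2d = betas.reshape(n_sub, n_ch * n_t)

    t_obs = _t_maps(data2d, np.ones((1, n_sub)))[0]
    observed = _cluster_masses(t_obs, thresh, A)

    exact = 2 ** n_sub <= n_permutations
    if exact:
        n_used = 2 ** n_sub
        flips = np.array([[1 if (i >> s) & 1 else -1 for s in range(n_sub)]
                          for i in range(n_used)], dtype=float)
    else:
        n_used = n_permutations
        flips = rng.choice([-1.0, 1.0], size=(n_used, n_sub))
    null_max = np.zeros(n_used)
    chunk = max(1, int(2e6 / (n_ch * n_t)))
    for start in range(0, n_used, chunk):
        tm = _t_maps(data2d, flips[start:start + chunk])
        for i in range(tm.shape[0]):
            masses = _cluster_masses(tm[i], thresh, A)
            if masses:
                null_max[start + i] = max(abs(m) for _, m, _ in masses)

    clusters = []
    for members, mass, sign in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_used)
        indices = np.stack([members // n_t, members % n_t], axis=1)
        clusters.append({"indices": indices, "mass": mass, "sign": sign,
                         "p": float(p)})
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return ClusterResult(clusters=clusters,
                         t_obs=t_obs.reshape(n_ch, n_t),
                         threshold=thresh, n_permutations=n_used,
                         exact=exact, channels=list(channels or []),
                         times=times)


# ---------------------------------------------------------------------------
# downsampling

def downsample(epochs: Epochs, target_rate: float) -> Epochs:
    """Decimate to ``target_rate`` (integer factor) with anti-alias
    filtering; metadata and event count preserved."""
    factor = epochs.sfreq / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"target rate {target_rate} is not an integer "
                         f"divisor of {epochs.sfreq}")
    q = int(round(factor))
    if q == 1:
        return epochs
    data = signal.decimate(epochs.data, q, axis=2, ftype="fir",
                           zero_phase=True)
    times = epochs.times[::q]
    return Epochs(data=data, channels=list(epochs.channels), times=times,
                  sfreq=epochs.sfreq / q, metadata=epochs.metadata.copy())
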