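"""Behavioral statistics for the multiple-bandits task.

Win-stay/lose-shift behavior is the behavioral readout of credit
assignment: each decision's stay/switch is predicted from the previous
trial's *relevant* outcome (the one its decision actually caused) and
*irrelevant* outcome (the one the wrong mapping would attribute to it).
Successful credit assignment shows up as a stronger relevant-outcome
effect, and in particular as higher stay rates after relevant-win /
irrelevant-loss trials than after relevant-loss / irrelevant-win trials.

The module also regresses choices on model latents (policy value
differences, evidence, arbitration weight) and fitted parameters on
behavioral measures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "build_stay_table",
    "stay_regression",
    "mixed_outcome_contrast",
    "behavioral_measures",
    "chance_tests",
    "signed_rank_z",
    "measure_correlations",
    "choice_prediction_regression",
    "parameter_behavior_regression",
]


def signed_rank_z(differences, tie_correction: bool = True):
    """Wilcoxon signed-rank test, normal approximation.

    Returns ``(w_plus, z, p)`` where ``w_plus`` is the sum of ranks of
    positive differences.  Zero differences are discarded; an all-zero
    input is degenerate and returns ``(0, nan, nan)``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, np.nan, np.nan
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction:
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return w_plus, np.nan, np.nan
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(z), float(p)


def build_stay_table(trials: pd.DataFrame, win_threshold: int = 50
                     ) -> pd.DataFrame:
    """Stay/switch observations with relevant/irrelevant outcome coding.

    One row per decision per trial with a predecessor in the same block
    (2*(T-1) rows per T-trial block).  ``stay`` is 1 when the same action
    was repeated; ``relevant``/``irrelevant`` are the +1/-1 win/loss codes
    of the previous trial's outcomes under the correct and incorrect
    attribution.  A ``subject`` column is carried through when present.
    """
    required = {"block", "trial", "action_d1", "action_d2",
                "outcome_d1", "outcome_d2"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    group_cols = [c for c in ("subject", "run", "block") if c in trials.columns]
    rows = []
    n_dropped = 0
    for _, blk in trials.groupby(group_cols, sort=True):
        blk = blk.sort_values("trial")
        tr = blk["trial"].to_numpy()
        a = blk[["action_d1", "action_d2"]].to_numpy()
        o = blk[["outcome_d1", "outcome_d2"]].to_numpy()
        for i in range(1, len(blk)):
            if tr[i] != tr[i - 1] + 1:
                n_dropped += 1
                continue
            win = np.where(o[i - 1] > win_threshold, 1, -1)
            for d in range(2):
                row = {c: blk.iloc[i][c] for c in group_cols}
                row.update({
                    "trial": tr[i], "decision": d + 1,
                    "stay": int(a[i, d] == a[i - 1, d]),
                    "relevant": int(win[d]),
                    "irrelevant": int(win[1 - d]),
                })
                rows.append(row)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} decisions without a directly "
                      "preceding trial", RuntimeWarning)
    return pd.DataFrame(rows)


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 0.1) -> np.ndarray:
    """Weakly L2-penalized logistic fit; fallback under separation."""

    def negloglik(b):
        eta = X @ b
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        return -ll + 0.5 * lam * (b[1:] @ b[1:])

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        g = -(X.T @ (y - p))
        g[1:] += lam * b[1:]
        return g

    res = optimize.minimize(negloglik, np.zeros(X.shape[1]), jac=grad,
                            method="L-BFGS-B")
    return res.x


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Per-participant logistic regression with a penalized fallback.

    Returns (coefficients, method) where method is 'ml' or 'penalized'.
    High-temperature (near-deterministic) agents separate routinely; the
    penalized fit keeps their coefficient signs usable.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.all(np.abs(res.params) < 30):
                return np.asarray(res.params), "ml"
        except Exception:
            pass
    return _ridge_logit(X, y), "penalized"


_STAY_COEFS = ("intercept", "relevant", "irrelevant", "interaction")


def stay_regression(stay_table: pd.DataFrame, mode: str = "two_stage"):
    """Logistic regression stay ~ 1 + relevant + irrelevant +
    relevant:irrelevant.

    ``mode='two_stage'`` (primary): one regression per participant, then
    group-level one-sample t-tests of each coefficient against zero;
    returns ``(per_subject, group)`` DataFrames.  Participants whose data
    lack one of the outcome conditions are dropped with a warning.

    ``mode='pooled'`` (optional variant): a single population-averaged
    logistic regression over all participants with cluster-robust
    (exchangeable GEE) inference by participant; returns one DataFrame of
    coefficients with z statistics.  This is an approximation to a mixed
    model, not a per-participant analysis.
    """
    if "subject" not in stay_table.columns:
        stay_table = stay_table.assign(subject=0)
    if mode == "pooled":
        X = np.column_stack([
            np.ones(len(stay_table)),
            stay_table["relevant"].to_numpy(float),
            stay_table["irrelevant"].to_numpy(float),
            (stay_table["relevant"] * stay_table["irrelevant"]).to_numpy(float),
        ])
        model = sm.GEE(stay_table["stay"].to_numpy(float), X,
                       groups=stay_table["subject"].to_numpy(),
                       family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit()
        return pd.DataFrame({"coef": _STAY_COEFS,
                             "estimate": np.asarray(res.params),
                             "z": np.asarray(res.tvalues),
                             "p": np.asarray(res.pvalues)})
    if mode != "two_stage":
        raise ValueError("mode must be 'two_stage' or 'pooled'")
    per_rows = []
    for subject, tab in stay_table.groupby("subject"):
        if tab["relevant"].nunique() < 2 or tab["irrelevant"].nunique() < 2:
            warnings.warn(f"subject {subject}: missing outcome conditions, "
                          "dropped from stay regression", RuntimeWarning)
            continue
        X = np.column_stack([
            np.ones(len(tab)),
            tab["relevant"].to_numpy(float),
            tab["irrelevant"].to_numpy(float),
            (tab["relevant"] * tab["irrelevant"]).to_numpy(float),
        ])
        coefs, method = _logit_fit(X, tab["stay"].to_numpy(float))
        per_rows.append({"subject": subject, "method": method,
                         **dict(zip(_STAY_COEFS, coefs))})
    per_subject = pd.DataFrame(per_rows)
    group_rows = []
    for name in _STAY_COEFS:
        values = per_subject[name].to_numpy()
        t, p = stats.ttest_1samp(values, 0.0)
        group_rows.append({"coef": name, "mean": values.mean(),
                           "t": float(t), "p": float(p),
                           "n": len(values)})
    return per_subject, pd.DataFrame(group_rows)


def mixed_outcome_contrast(stay_table: pd.DataFrame):
    """Planned contrast on mixed-outcome trials.

    Per participant, the stay probability after relevant-win/irrelevant-
    loss minus after relevant-loss/irrelevant-win (= implicit credit
    assignment); across participants a Wilcoxon signed-rank test.

    Returns ``(per_subject, group)`` where group holds the signed-rank
    statistic, z and p.
    """
    if "subject" not in stay_table.columns:
        stay_table = stay_table.assign(subject=0)
    rows = []
    for subject, tab in stay_table.groupby("subject"):
        win_loss = tab[(tab.relevant == 1) & (tab.irrelevant == -1)]
        loss_win = tab[(tab.relevant == -1) & (tab.irrelevant == 1)]
        if win_loss.empty or loss_win.empty:
            warnings.warn(f"subject {subject}: empty mixed-outcome cell, "
                          "dropped from contrast", RuntimeWarning)
            continue
        p_wl = win_loss["stay"].mean()
        p_lw = loss_win["stay"].mean()
        rows.append({"subject": subject, "p_stay_relwin_irrloss": p_wl,
                     "p_stay_relloss_irrwin": p_lw,
                     "implicit_ca": p_wl - p_lw})
    per_subject = pd.DataFrame(rows)
    w_plus, z, p = signed_rank_z(per_subject["implicit_ca"].to_numpy())
    group = {"w_plus": w_plus, "z": z, "p": p, "n": len(per_subject)}
    return per_subject, group


def behavioral_measures(trials: pd.DataFrame,
                        transfer_accuracy: dict | pd.Series | None = None,
                        win_threshold: int = 50) -> pd.DataFrame:
    """Per-participant summary measures.

    ``p_win``: proportion of chosen outcomes above the threshold;
    ``implicit_ca``: the mixed-outcome stay-probability difference;
    ``transfer_acc``: externally supplied transfer-task accuracy (the
    transfer task is consumed as data only).
    """
    if "subject" not in trials.columns:
        trials = trials.assign(subject=0)
    stay = build_stay_table(trials, win_threshold=win_threshold)
    per_subject, _ = mixed_outcome_contrast(stay)
    wins = trials.assign(
        win1=(trials["outcome_d1"] > win_threshold),
        win2=(trials["outcome_d2"] > win_threshold),
    ).groupby("subject")[["win1", "win2"]].mean()
    measures = pd.DataFrame({
        "subject": wins.index,
        "p_win": (wins["win1"] + wins["win2"]).to_numpy() / 2.0,
    }).merge(per_subject[["subject", "implicit_ca"]], on="subject",
             how="left")
    if transfer_accuracy is not None:
        transfer = pd.Series(transfer_accuracy, name="transfer_acc")
        measures = measures.merge(transfer.rename_axis("subject").reset_index(),
                                  on="subject", how="left")
    return measures


def chance_tests(measures: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of p_win (and transfer accuracy when
    present) against the 0.5 chance level."""
    rows = []
    for col in ("p_win", "transfer_acc"):
        if col not in measures.columns:
            continue
        values = measures[col].dropna().to_numpy()
        w_plus, z, p = signed_rank_z(values - 0.5)
        rows.append({"measure": col, "mean": values.mean(),
                     "w_plus": w_plus, "z": z, "p": p, "n": len(values),
                     "degenerate": not np.isfinite(z) if len(values) else True})
    return pd.DataFrame(rows)


def measure_correlations(measures: pd.DataFrame,
                         columns=("p_win", "implicit_ca", "transfer_acc")
                         ) -> pd.DataFrame:
    """Pairwise Pearson correlations among the behavioral measures.

    Zero-variance inputs yield an explicit NaN row rather than an error.
    """
    columns = [c for c in columns if c in measures.columns]
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            sub = measures[[a, b]].dropna()
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append({"x": a, "y": b, "r": np.nan, "p": np.nan,
                             "n": len(x), "degenerate": True})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"x": a, "y": b, "r": float(r), "p": float(p),
                         "n": len(x), "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-latent regressions

def _choice_design(trace) -> pd.DataFrame:
    """Per-decision predictors for the choice regression.

    ``choice`` is 1 when action 1 was taken.  ``D_*`` are the value
    differences V(a1) - V(a2) at choice time; ``evidence`` is the most
    recent evidence signal (previous trial's, 0 at a block start);
    ``weight`` the arbitration weight at choice time.
    """
    T = trace.n_trials
    rows = []
    prev_ev = 0.0
    prev_block = None
    for t in range(T):
        if trace.block[t] != prev_block:
            prev_ev = 0.0
            prev_block = trace.block[t]
        for d in range(2):
            rows.append({
                "block": trace.block[t], "trial": trace.trial[t],
                "decision": d + 1,
                "choice": int(trace.actions[t, d] == 0),
                "D_correct": trace.V_correct[t, d, 0] - trace.V_correct[t, d, 1],
                "D_incorrect": trace.V_incorrect[t, d, 0] - trace.V_incorrect[t, d, 1],
                "evidence": prev_ev,
                "weight": trace.weight[t],
            })
        prev_ev = float(trace.evidence[t].sum())
    return pd.DataFrame(rows)


def _tertile(values: np.ndarray) -> np.ndarray:
    """Tertile labels 0/1/2 with ties assigned to the lower tertile."""
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return np.where(values <= q1, 0, np.where(values <= q2, 1, 2))


def choice_prediction_regression(traces_by_subject: dict):
    """Choice ~ policy value differences, evidence, and arbitration weight.

    Per participant, a logistic regression of each decision's choice on
    D_correct, D_incorrect, evidence, weight, and the four interactions of
    the value differences with evidence and weight; coefficients are then
    tested against zero across participants.  A follow-up splits each
    participant's observations into weight tertiles and re-estimates the
    D_correct / D_incorrect effects per tertile.

    Returns ``(per_subject, group, tertile_group)``.
    """
    main_cols = ["D_correct", "D_incorrect", "evidence", "weight",
                 "D_correct:evidence", "D_incorrect:evidence",
                 "D_correct:weight", "D_incorrect:weight"]
    per_rows, tert_rows = [], []
    for subject, trace in traces_by_subject.items():
        design = _choice_design(trace)
        X = np.column_stack([
            np.ones(len(design)),
            design["D_correct"], design["D_incorrect"],
            design["evidence"], design["weight"],
            design["D_correct"] * design["evidence"],
            design["D_incorrect"] * design["evidence"],
            design["D_correct"] * design["weight"],
            design["D_incorrect"] * design["weight"],
        ])
        y = design["choice"].to_numpy(float)
        # drop constant non-intercept columns (e.g. fixed-weight agents)
        keep = [0] + [i for i in range(1, X.shape[1])
                      if np.std(X[:, i]) > 1e-12]
        dropped = [main_cols[i - 1] for i in range(1, X.shape[1])
                   if i not in keep]
        coefs, method = _logit_fit(X[:, keep], y)
        row = {"subject": subject, "method": method,
               "dropped": ",".join(dropped)}
        full = dict.fromkeys(["intercept"] + main_cols, np.nan)
        for idx, c in zip(keep, coefs):
            full[(["intercept"] + main_cols)[idx]] = c
        row.update(full)
        per_rows.append(row)

        tert = _tertile(design["weight"].to_numpy())
        for level in (0, 1, 2):
            sub = design[tert == level]
            if len(sub) < 8:
                continue
            Xt = np.column_stack([np.ones(len(sub)), sub["D_correct"],
                                  sub["D_incorrect"]])
            keep_t = [0] + [i for i in (1, 2) if np.std(Xt[:, i]) > 1e-12]
            ct, _ = _logit_fit(Xt[:, keep_t], sub["choice"].to_numpy(float))
            names_t = np.array(["intercept", "D_correct", "D_incorrect"])
            vals = dict.fromkeys(names_t[1:], np.nan)
            for idx, c in zip(keep_t, ct):
                if idx:
                    vals[names_t[idx]] = c
            tert_rows.append({"subject": subject, "tertile": level, **vals})

    per_subject = pd.DataFrame(per_rows)
    group_rows = []
    for name in ["intercept"] + main_cols:
        values = per_subject[name].dropna().to_numpy()
        if len(values) < 2:
            group_rows.append({"coef": name, "mean": np.nan, "t": np.nan,
                               "p": np.nan, "n": len(values)})
            continue
        t, p = stats.ttest_1samp(values, 0.0)
        group_rows.append({"coef": name, "mean": values.mean(),
                           "t": float(t), "p": float(p), "n": len(values)})
    tertile = pd.DataFrame(tert_rows)
    tert_group = (tertile.groupby("tertile")[["D_correct", "D_incorrect"]]
                  .mean().reset_index()) if not tertile.empty else tertile
    return per_subject, pd.DataFrame(group_rows), tert_group


def parameter_behavior_regression(params: pd.DataFrame,
                                  measures: pd.DataFrame,
                                  measure_cols=("p_win", "implicit_ca",
                                                "transfer_acc"),
                                  param_cols=("alpha", "beta", "rho",
                                              "epsilon")) -> pd.DataFrame:
    """OLS of each behavioral measure on the fitted model parameters.

    measure ~ b0 + b1*alpha + b2*beta + b3*rho + b4*epsilon.  Returns one
    row per (measure, parameter) with estimate, t and p.  A high design
    condition number triggers a collinearity warning.
    """
    data = params.merge(measures, on="subject")
    param_cols = [c for c in param_cols if c in data.columns]
    if len(data) < len(param_cols) + 2:
        raise ValueError("need more participants than coefficients")
    X = sm.add_constant(data[param_cols].to_numpy(float))
    if np.linalg.cond(X) > 1e6:
        warnings.warn("parameter design matrix is ill-conditioned",
                      RuntimeWarning)
    rows = []
    for measure in measure_cols:
        if measure not in data.columns:
            continue
        sub = data.dropna(subset=[measure])
        Xm = sm.add_constant(sub[param_cols].to_numpy(float))
        res = sm.OLS(sub[measure].to_numpy(float), Xm).fit()
        for name, est, t, p in zip(["intercept"] + list(param_cols),
                                   res.params, res.tvalues, res.pvalues):
            rows.append({"measure": measure, "param": name,
                         "estimate": float(est), "t": float(t),
                         "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
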