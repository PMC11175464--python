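"""Design matrices, mass-univariate GLM, and cluster permutation tests."""

import numpy as np
import pandas as pd
import pytest

from creditassign import eeg
from creditassign.cohort import simulate_cohort
from creditassign.task import TaskConfig


@pytest.fixture(scope="module")
def agent():
    cohort = simulate_cohort(1, config=TaskConfig(n_blocks=2,
                                                  n_trials_per_block=50),
                             rng=np.random.default_rng(5))
    return cohort.traces[0], cohort.trials[0]


@pytest.fixture(scope="module")
def montage():
    return eeg.grid_montage(4, 4)


def _epochs(rng, n_ev=40, n_ch=4, n_t=20, sfreq=100.0):
    times = np.arange(n_t) / sfreq
    meta = pd.DataFrame({"event_id": np.arange(n_ev)})
    data = rng.normal(size=(n_ev, n_ch, n_t))
    return eeg.Epochs(data=data, channels=[f"c{i}" for i in range(n_ch)],
                      times=times, sfreq=sfreq, metadata=meta)


# ---------------------------------------------------------------------------
# containers

def test_epochs_validation(rng):
    with pytest.raises(ValueError):
        eeg.Epochs(data=rng.normal(size=(5, 3, 10)), channels=["a", "b"],
                   times=np.arange(10) / 100, sfreq=100,
                   metadata=pd.DataFrame(index=range(5)))
    with pytest.raises(ValueError):
        eeg.Epochs(data=rng.normal(size=(5, 2, 10)), channels=["a", "b"],
                   times=np.arange(10) / 50, sfreq=100,
                   metadata=pd.DataFrame(index=range(5)))


def test_epochs_h5_roundtrip(tmp_path, rng):
    ep = _epochs(rng)
    ep.metadata["kind"] = ["outcome", "response"] * 20
    path = tmp_path / "epochs.h5"
    ep.save(path)
    back = eeg.Epochs.load(path)
    np.testing.assert_array_equal(back.data, ep.data)
    np.testing.assert_array_equal(back.times, ep.times)
    assert back.channels == ep.channels
    assert back.sfreq == ep.sfreq
    pd.testing.assert_frame_equal(
        back.metadata, ep.metadata.astype({"event_id": back.metadata["event_id"].dtype}))


def test_from_arrays_adapter(rng):
    times = np.arange(12) / 250
    ep = eeg.Epochs.from_arrays(rng.normal(size=(6, 3, 12)),
                                ["x", "y", "z"], times,
                                {"trial": range(6)})
    assert ep.sfreq == pytest.approx(250.0)


def test_grid_montage_adjacency(montage):
    names, A = montage
    assert len(names) == 16 and A.shape == (16, 16)
    assert (A != A.T).nnz == 0
    degrees = np.asarray(A.sum(axis=1)).ravel()
    assert degrees.min() == 2 and degrees.max() == 4   # corners vs interior


# ---------------------------------------------------------------------------
# design matrices

def test_design_event_counts_and_scaling(agent):
    trace, trials = agent
    for lock in ("feedback", "response"):
        design, events, dropped = eeg.build_design(trace, trials, lock=lock)
        assert len(design) == 2 * trace.n_trials
        assert len(events) == len(design)
        for col in design.columns:
            if col == "intercept":
                continue
            assert design[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert design[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def test_feedback_design_respects_hidden_mapping(agent):
    """Each outcome event carries the prediction error of the decision that
    caused it (correct policy) and of the decision the wrong mapping blames
    (incorrect policy)."""
    trace, trials = agent
    design, events, _ = eeg.build_design(trace, trials, lock="feedback")
    raw = []
    mapping_d1 = trials["mapping_d1"].to_numpy()
    for _, ev in events.iterrows():
        t = int(ev["trial_index"])
        d_cause = 0 if mapping_d1[t] == ev["color"] else 1
        raw.append((trace.delta_correct[t, d_cause],
                    trace.delta_incorrect[t, 1 - d_cause],
                    trace.evidence[t, d_cause]))
    raw = np.array(raw)
    for i, col in enumerate(("pe_correct", "pe_incorrect", "evidence")):
        z = (raw[:, i] - raw[:, i].mean()) / raw[:, i].std()
        np.testing.assert_allclose(design[col], z, atol=1e-10)


def test_constant_design_column_dropped():
    cohort = simulate_cohort(1, model_id="random_policy",
                             config=TaskConfig(n_blocks=1,
                                               n_trials_per_block=30),
                             rng=np.random.default_rng(9))
    with pytest.warns(RuntimeWarning):
        design, _, dropped = eeg.build_design(cohort.traces[0],
                                              cohort.trials[0],
                                              lock="feedback")
    assert "weight" in dropped and "weight" not in design.columns


def test_design_misalignment_raises(agent):
    trace, trials = agent
    with pytest.raises(ValueError):
        eeg.build_design(trace, trials.iloc[:-1], lock="feedback")


def test_valence_surprise_split(agent):
    trace, trials = agent
    design, _, _ = eeg.build_design(trace, trials, lock="feedback",
                                    split_valence_surprise=True)
    assert {"pe_correct_valence", "pe_correct_surprise",
            "pe_incorrect_valence", "pe_incorrect_surprise"} <= set(design.columns)
    assert "pe_correct" not in design.columns


# ---------------------------------------------------------------------------
# mass GLM

def test_mass_glm_exact_signal(rng):
    """Noise-free data equal to one regressor: unit raw beta everywhere for
    that regressor, zero for the others."""
    n_ev = 30
    x = rng.normal(size=n_ev)
    z = (x - x.mean()) / x.std(ddof=0)
    design = pd.DataFrame({"intercept": 1.0, "x": z,
                           "y": rng.normal(size=n_ev)})
    design["y"] = (design["y"] - design["y"].mean()) / design["y"].std(ddof=0)
    data = np.tile(z[:, None, None], (1, 3, 5))
    ep = eeg.Epochs(data=data, channels=list("abc"),
                    times=np.arange(5) / 100.0, sfreq=100,
                    metadata=pd.DataFrame(index=range(n_ev)))
    betas = eeg.mass_glm(ep, design, standardize="none")
    np.testing.assert_allclose(betas[1], 1.0, atol=1e-10)
    np.testing.assert_allclose(betas[2], 0.0, atol=1e-8)


def test_mass_glm_matches_pointwise_reference(rng):
    ep = _epochs(rng, n_ev=50, n_ch=4, n_t=6)
    design = pd.DataFrame({"intercept": np.ones(50),
                           "a": rng.normal(size=50),
                           "b": rng.normal(size=50)})
    betas = eeg.mass_glm(ep, design, standardize="none")
    X = design.to_numpy()
    for c in range(4):
        for t in range(6):
            ref, *_ = np.linalg.lstsq(X, ep.data[:, c, t], rcond=None)
            np.testing.assert_allclose(betas[:, c, t], ref, atol=1e-8)


def test_mass_glm_standardization_is_t_statistic(rng):
    ep = _epochs(rng, n_ev=60, n_ch=2, n_t=4)
    design = pd.DataFrame({"intercept": np.ones(60),
                           "a": rng.normal(size=60)})
    t_betas = eeg.mass_glm(ep, design, standardize="se")
    raw = eeg.mass_glm(ep, design, standardize="none")
    # standardized magnitudes are plausible t values, raw betas are not
    assert np.all(np.isfinite(t_betas))
    assert not np.allclose(t_betas, raw)


def test_mass_glm_rank_deficiency_names_columns(rng):
    ep = _epochs(rng, n_ev=30)
    design = pd.DataFrame({"intercept": np.ones(30),
                           "a": np.arange(30.0)})
    design["dup"] = design["a"] * 2.0
    with pytest.raises(ValueError, match="dup|a"):
        eeg.mass_glm(ep, design)


def test_planted_effect_linearity(agent, montage, rng):
    trace, trials = agent
    names, A = montage
    times = np.arange(0.0, 0.4, 1.0 / 125.0)
    design, events, _ = eeg.build_design(trace, trials, lock="feedback")
    profile = np.zeros(16)
    profile[:4] = 1.0
    betas = {}
    for amp in (0.5, 1.0):
        ep, truth = eeg.simulate_epochs(
            design, events, {"pe_correct": (amp, profile, (0.1, 0.3))},
            names, times, np.random.default_rng(0), noise_sd=0.0,
            adjacency=A)
        betas[amp] = eeg.mass_glm(ep, design, standardize="none")
    np.testing.assert_allclose(2.0 * betas[0.5][1], betas[1.0][1], atol=1e-8)
    k = list(design.columns).index("pe_correct")
    np.testing.assert_allclose(betas[1.0][k], truth["pe_correct"], atol=1e-8)


def test_planted_beta_maps_recovered_at_moderate_noise(agent, montage):
    trace, trials = agent
    names, A = montage
    rng = np.random.default_rng(21)
    times = np.arange(0.0, 0.8, 1.0 / 125.0)
    design, events, _ = eeg.build_design(trace, trials, lock="feedback")
    profile = np.zeros(16)
    profile[[5, 6, 9, 10]] = 1.0
    effects = {"pe_correct": (1.0, profile, (0.25, 0.55))}
    ep, truth = eeg.simulate_epochs(design, events, effects, names, times,
                                    rng, noise_sd=1.0, adjacency=A)
    betas = eeg.mass_glm(ep, design, standardize="none")
    k = list(design.columns).index("pe_correct")
    r = np.corrcoef(betas[k].ravel(), truth["pe_correct"].ravel())[0, 1]
    assert r > 0.9


# ---------------------------------------------------------------------------
# cluster permutation test

def _null_betas(rng, n_sub=12, n_ch=16, n_t=32):
    return rng.normal(size=(n_sub, n_ch, n_t))


def test_cluster_pvalues_in_unit_interval(montage, rng):
    names, A = montage
    res = eeg.cluster_permutation(_null_betas(rng), A, rng,
                                  n_permutations=256, channels=names)
    for c in res.clusters:
        assert 0 < c["p"] <= 1
    frame = res.to_frame()
    if not frame.empty:
        assert {"cluster", "sign", "mass", "p"} <= set(frame.columns)


def test_cluster_exact_enumeration_fallback(montage):
    names, A = montage
    rng = np.random.default_rng(2)
    betas = rng.normal(size=(8, 16, 8))
    res = eeg.cluster_permutation(betas, A, rng, n_permutations=1000,
                                  channels=names)
    assert res.exact and res.n_permutations == 256


def test_cluster_sign_symmetry(montage):
    names, A = montage
    rng_data = np.random.default_rng(3)
    betas = rng_data.normal(size=(10, 16, 16)) + 0.8
    res_pos = eeg.cluster_permutation(betas, A, np.random.default_rng(7),
                                      n_permutations=300)
    res_neg = eeg.cluster_permutation(-betas, A, np.random.default_rng(7),
                                      n_permutations=300)
    masses_pos = sorted(c["mass"] for c in res_pos.clusters)
    masses_neg = sorted(-c["mass"] for c in res_neg.clusters)
    np.testing.assert_allclose(masses_pos, masses_neg, atol=1e-9)
    p_pos = sorted(c["p"] for c in res_pos.clusters)
    p_neg = sorted(c["p"] for c in res_neg.clusters)
    np.testing.assert_allclose(p_pos, p_neg, atol=1e-12)


def test_cluster_recovers_planted_effect(montage):
    names, A = montage
    rng = np.random.default_rng(4)
    betas = rng.normal(size=(12, 16, 32))
    betas[:, 4:8, 10:20] += 1.2         # coherent effect across subjects
    res = eeg.cluster_permutation(betas, A, rng, n_permutations=500,
                                  channels=names,
                                  times=np.arange(32) / 125.0)
    sig = res.significant(0.05)
    assert sig
    top = max(sig, key=lambda c: abs(c["mass"]))
    assert top["sign"] == 1
    chans = {p[0] for p in top["indices"]}
    assert chans & {4, 5, 6, 7}


def test_cluster_masses_match_mne(montage):
    """Independent cross-check: observed cluster masses agree with the
    reference implementation in mne (same threshold and adjacency)."""
    mne_stats = pytest.importorskip("mne.stats")
    names, A = montage
    rng = np.random.default_rng(6)
    betas = rng.normal(size=(10, 16, 24))
    betas[:, :4, 5:15] += 0.9
    res = eeg.cluster_permutation(betas, A, rng, n_permutations=128)
    X = np.transpose(betas, (0, 2, 1))          # subjects x time x channels
    t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
        X, threshold=res.threshold, tail=0, adjacency=A.astype(int),
        n_permutations=64, t_power=1, out_type="mask", seed=1, verbose=False)
    mne_masses = sorted(float(t_obs[m].sum()) for m in clusters)
    ours = sorted(c["mass"] for c in res.clusters)
    np.testing.assert_allclose(ours, mne_masses, atol=1e-8)


def test_cluster_requires_enough_subjects(montage, rng):
    names, A = montage
    with pytest.raises(ValueError):
        eeg.cluster_permutation(rng.normal(size=(4, 16, 8)), A, rng)


# ---------------------------------------------------------------------------
# downsampling

def test_downsample_500_to_125(rng):
    ep = _epochs(rng, n_ev=10, n_ch=3, n_t=256, sfreq=500.0)
    down = eeg.downsample(ep, 125.0)
    assert down.data.shape[2] == 64
    assert down.sfreq == pytest.approx(125.0)
    assert len(down.metadata) == ep.n_events
    with pytest.raises(ValueError):
        eeg.downsample(ep, 300.0)


def test_downsample_constant_preserved():
    data = np.full((4, 2, 200), 3.7)
    ep = eeg.Epochs(data=data, channels=["a", "b"],
                    times=np.arange(200) / 500.0, sfreq=500.0,
                    metadata=pd.DataFrame(index=range(4)))
    down = eeg.downsample(ep, 125.0)
    # away from the filter's edge transients the value is untouched
    np.testing.assert_allclose(down.data[..., 10:-10], 3.7, atol=1e-6)


def test_downsample_two_stage_equals_one_stage(rng):
    ep = _epochs(rng, n_ev=6, n_ch=2, n_t=400, sfreq=500.0)
    once = eeg.downsample(ep, 125.0)
    twice = eeg.downsample(eeg.downsample(ep, 250.0), 125.0)
    # interior samples agree within the anti-alias filter tolerance
    core = slice(10, -10)
    err = np.abs(once.data[..., core] - twice.data[..., core])
    scale = np.abs(once.data[..., core]).mean()
    assert err.mean() < 0.15 * scale
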