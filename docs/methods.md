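# Methods

This note records the model, the statistical procedures, the synthetic
data generators, and the numerical and design choices made where the
problem left latitude. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task environment (`creditassign.task`)

Each block holds two independent two-armed decisions. Decision 1's
outcome value follows a bounded Gaussian random walk `P` (decision 2: `Q`)
with step SD 15 points; the chosen action pays `P`, the other `100 − P`
(exact anti-correlation). Defaults are the study conditions: 3 blocks ×
100 trials, values in [1, 99], win/loss threshold 50. The first walk value
is uniform over the integers 1–99; each step adds N(0, 15), is bounded,
and is rounded to the nearest integer.

**Boundary handling.** The task description does not say how the walk is
kept inside [1, 99]. Three schemes are implemented: `reflect` (default;
overshoots are mirrored off the bounds, keeping the stationary
distribution spread across the range), `clip` (saturate at the bounds),
and `resample` (redraw the step until it lands inside; a
truncated-Gaussian step). The only external constraint is the reported
mean same-side run length of ≈5.7 trials. Measured over 10,000 blocks the
schemes give ≈7.6 (reflect), ≈8.8 (clip) and ≈6.8 (resample); the
statistic scales roughly like 1/SD, so none of the SD-15-faithful schemes
reproduces 5.7 (which would require SD ≈ 20). `reflect` is kept as the
default on stationarity grounds; the comparison is recomputed by the test
suite rather than asserted away. A plausible reading is that the 5.7
figure describes the specific task instantiation used in the original
experiments rather than the walk's population behavior.

**Tie rule.** A value of exactly 50 counts as a loss (a win is strictly
above threshold); with integer walks exact ties occur on roughly 1% of
trials and the rule is deterministic.

**Exact-zero step SD** is legal and yields a constant walk (useful for
degenerate-input tests); negative SD is a configuration error.

## Model family (`creditassign.models`)

Parameters and bounds: learning rate α ∈ [0, 1], inverse temperature
β ∈ [0, 20], perseveration ρ ∈ [−5, 5], assignment rate ε ∈ [0, 1]
(surprise-minimization models only), decay ∈ [0, 1] (free-decay variant
only). Rewards are centered, `r = points/50 − 1 ∈ [−0.98, 0.98]`.

Within-trial order is fixed: choice probabilities from the current values
and weight → both actions realized → both outcomes → prediction errors
against pre-update values → value update (chosen `+αδ`; unchosen `−αδ`
counterfactually, or multiplicative decay in the two Supplementary-style
variants) → surprise `|δ|` → evidence per outcome (cross-decision surprise
comparison) → arbitration update `ω ← ω + ε·ΣΔ`. All state (values, ω,
perseveration memory) resets to 0 at every block start, so the weight
re-starts at 0.5 each block.

Fixed-weight variants pin w at 0.9 / 0.1 / 0.5 for fitting; the weight-1 /
weight-0 validation simulations use the same code path with w pinned at
exactly 1 / 0 (then the model is likelihood-identical to a single-policy
TD learner, which the tests verify to 1e-12). The joint-action model
softmaxes over the four action combinations with a scalar prediction error
against the summed centered outcomes and no counterfactual updating.

**Numerics.** Softmax with max-subtraction; inverse logit clamped at
|ω| = 700; likelihood contributions floored at 1e-300. The trial recursion
is sequential, so the likelihood inner loops are numba-compiled; the test
suite checks them against an independently written slow trial loop to
1e-10 and checks the generative and likelihood paths against each other
latent-by-latent.

## Fitting and model selection (`creditassign.fitting`)

Per participant, MAP estimation under the empirical priors
α ~ Beta(1.2, 1.2), β ~ Gamma(2, 1) truncated to [0, 20], ρ ~ N(0, 1)
truncated to [−5, 5], ε ~ Beta(1.2, 1.2) (truncated densities are
renormalized over their bounds). Optimization is L-BFGS-B from
prior-drawn starts (default 10 restarts), constrained 1e-6 inside the
parameter box because several priors vanish on the boundary itself.

Information criteria use n = number of modeled choices = 2 × trials (two
decisions per trial), for all models including the joint-action model
(whose single 4-way choice per trial covers both key presses; the common n
keeps BIC comparable across models). Group-level Bayesian model selection
follows the random-effects Dirichlet scheme: per-participant log evidence
(−BIC/2 by default; −AIC/2 as a switch) enters a variational update of the
Dirichlet concentrations (uniform prior concentration 1, tolerance 1e-6),
and the exceedance probability is the Monte-Carlo frequency with which
each model's sampled population frequency is the largest (10^5 draws).

**Known identifiability limit** (measured by the model-recovery harness,
`fitting.model_recovery`): under prior-drawn generating parameters at
3 × 100 trials, surprise-minimization agents with high ε converge to
w ≈ 1 within tens of trials and low-β draws carry little likelihood
signal, so per-subject BIC often prefers the nested correct-policy model —
its 3-parameter parsimony beats the ≈1–3 NLL units the ε parameter buys.
The four competitor models recover cleanly (0.85–1.0 diagonal selection
frequency); with the −AIC/2 evidence switch the full five-model diagonal
dominates. Users comparing these nested models on short sessions should
treat the evidence approximation as a reportable analysis choice.

Parameter recovery on 100 prior-drawn subjects (recomputed by the test
suite) gives generating-vs-recovered correlations well above 0.5 for α, β
and ε; ρ is weakly identified at these sample sizes and is reported
without a hard threshold.

## Behavioral statistics (`creditassign.behavior`)

The stay table codes each decision's stay/switch (1/0) against the same
decision's previous action, with the previous trial's two outcomes
dichotomized (+1 win / −1 loss) and attributed as *relevant* (the outcome
the decision actually caused) and *irrelevant* (the outcome the wrong
mapping would attribute to it); each outcome therefore appears once as
relevant and once as irrelevant per trial. First trials of a block have no
predecessor and are excluded.

The primary analysis is two-stage: a per-participant logistic regression
`stay ~ relevant + irrelevant + relevant:irrelevant` followed by
group-level one-sample t-tests. Near-deterministic agents separate the
per-participant fits; a weakly L2-penalized fallback (penalty 0.1 on the
non-intercept coefficients) is used and flagged in that case. A pooled
population-averaged variant (GEE with exchangeable correlation by
participant) is available as a clearly labeled option. The planned
mixed-outcome contrast compares stay probabilities after relevant-win/
irrelevant-loss vs relevant-loss/irrelevant-win per participant (their
difference is the implicit credit-assignment measure) with a Wilcoxon
signed-rank test across participants; chance tests use the same
signed-rank statistic against 0.5. The signed-rank z uses the normal
approximation with tie correction and no continuity correction, and is
cross-checked against scipy in the tests.

The choice regression uses, per decision at choice time t, the policy
value differences `D = V(a1) − V(a2)`, the previous trial's total evidence
signal (0 at block starts), and the arbitration weight, plus the four
D × evidence and D × weight interactions; per-participant logistic fits
are summarized by group t-tests. Weight tertiles are computed per
participant with ties assigned to the lower tertile. With uncentered
predictors the weight dependence appears in the interaction terms (the
main D effects are evaluated at weight 0), so the tertile split is the
interpretable readout.

**A closed-loop caveat found during validation:** agents driven purely by
the *incorrect* policy show a small positive relevant-outcome stay
coefficient (≈0.25, vs ≈1.2 for the irrelevant outcome) even though their
learning never touches the relevant outcome. The correlation is present
at lag 0 (the trial's own future outcome), identifying it as a feedback
artifact: under the crossed mapping, each decision's policy is reinforced
by outcomes generated by the *other* decision's actions, closing a loop
that couples staying to both outcome streams. Weight-1 agents, whose
policies listen only to their own outcomes, show a cleanly null
irrelevant effect, and zero-temperature agents show exact nulls for both
— the pattern is a property of the crossed dynamics, not of the coding.

## Synthetic cohorts (`creditassign.cohort`)

A cohort simulates n agents with prior-drawn (or supplied) parameters on
freshly generated sessions. Transfer-task accuracy — an explicit report
of the learned mapping in the real experiment — is emulated as a binomial
readout: 20 pseudo-trials per block with success probability equal to the
block's final arbitration weight. This captures the intended coupling
(agents that arbitrated to the correct mapping report it accurately;
uncommitted agents are at chance) but none of the real task's stimulus
recombination, response deadlines or memory demands, so correlations
involving transfer accuracy test the pipeline's plumbing and the
qualitative coupling, not the empirical effect sizes.

## EEG analysis (`creditassign.eeg`)

Epochs are events × channels × time arrays with uniform times and
per-event metadata; they round-trip through an HDF5 layout and import
from plain arrays plus an event table. Feedback-locked designs carry, per
outcome event, the correct-policy prediction error of the decision that
caused the outcome, the incorrect-policy prediction error of the decision
the wrong mapping blames, that outcome's evidence signal, and the
arbitration weight. Response-locked designs use within-decision latents;
because the evidence signal has no outcome anchor at response time, its
response-locked recombination is `surprise_incorrect(d) −
surprise_correct(d)` within the decision (configurable; the feedback
pairing is available as an option). All non-intercept columns are
z-scored per participant; constant columns (e.g. the weight of a
fixed-weight agent) are dropped and flagged. An optional design variant
splits each signed prediction error into valence (sign) and surprise
(magnitude) columns.

The mass-univariate GLM is OLS per channel × time point; betas are
standardized by their pointwise OLS standard error by default (penalizing
multicollinear, high-variance estimates; residual-SD scaling and raw
betas are switches). Group inference is a two-tailed one-sample cluster
test: points with uncorrected p < 0.05 are grouped into signed clusters
by channel adjacency (explicit neighbor matrix; a 4 × 4 grid montage with
rook adjacency ships for synthetic work) plus consecutive-sample time
adjacency; the cluster statistic is the mass (sum of t); the null is the
maximal absolute mass over random participant sign-flips (default 10^4,
exact enumeration when all 2^n flips fit the budget); cluster p-values
use the add-one convention so p ∈ (0, 1]. The implementation is
cross-checked against the reference cluster test in `mne` in the test
suite, and its family-wise error rate is measured on null data (200
replicate datasets at 12 participants × 16 channels × 64 samples — sizes
chosen to keep the calibration a routine desk-scale run).

The synthetic-epochs generator plants boxcar channel × time effects of
chosen z-scored regressors into first-order autoregressive, spatially
smoothed Gaussian noise (white noise would overstate the permutation
test's power). Planted beta maps are returned as ground truth for
recovery tests. Downsampling decimates by an integer factor after FIR
anti-alias filtering (e.g. 500 → 125 Hz).

## Monte-Carlo validation (`creditassign.validate`)

`run_convergence_sims` simulates prior-drawn surprise-minimization agents
(default 1000 runs of the 3 × 100-trial task) and records the final
arbitration weight and each run's mean surprise per policy. Summary
statistics: the count of runs with final weight > 0.5 (with a
Clopper-Pearson interval); the paired signed-rank Z for the surprise
separation, whose complete-separation ceiling at n = 1000 is
250250/√83458375 ≈ 27.39; and the walk stability statistic described
above. `scripts/acceptance.py` recomputes all three from a single seed,
and the CLI's `validate` subcommand prints them with their reference
values.

## Problem sizes

Defaults follow the study conditions (1000 validation runs, 3 × 100
trials, 10^4 permutations, 10^5 Dirichlet samples). The test suite runs
reduced-but-honest sizes chosen as routine desk-scale analyses: recovery
harnesses at 20–100 subjects with 3–5 optimizer restarts, permutation
calibration at 200 replicates × 200 permutations. None of the reductions
changes a default that defines the study conditions.

## Limitations

- No EEG preprocessing (filtering, re-referencing, artifact handling):
  inputs are clean epochs by contract.
- The transfer task is consumed as accuracy data only; there is no
  trial-level generative model of transfer choices.
- Per-participant fitting only (no hierarchical shrinkage across
  participants), matching the two-stage analysis strategy.
- The walk stability statistic and the surprise-minimization row of the
  BIC model-recovery matrix are the two places where the implementation's
  measured behavior departs from the reference values it was built
  against; both are documented above and recomputed, not asserted, by the
  code.
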