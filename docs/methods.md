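# Methods

## Task model

Trials are organized in blocks of five identical trials; a tone marks block
start and a single odor precedes every reward, so block identity is never
cued directly. Training proceeds in three phases: a deterministic phase
with strictly alternating 1 µL (s₁) and 10 µL (s₂) blocks, a probabilistic
phase in which the block type switches with probability 0.5 at each block
start, and a probe phase in which, every other day, 3 of the 30 daily
blocks (10%) are replaced by intermediate-reward blocks (2, 4, 6 or 8 µL),
each volume at most once per day and never in a day's first block;
replacement positions are uniform-random (their placement is not otherwise
constrained by the task description). Rewards are normalized affinely,
r = (volume − 1)/9, so the training anchors map to exactly 0 and 1.

Default day counts are 13 deterministic + 19 probabilistic + 22 probe-phase
days at 30 blocks/day. These were solved from the target per-animal
exposure — ≈3,980 trials of each training block and ≈42 trials of each
intermediate volume — given the 30-block day and the every-other-day probe
cadence; the phases' documented ranges ("10–15 days" deterministic,
intermediates after >20 days) admit this split.

All schedule randomness flows from a single seed per schedule; trial tables
carry `prev_block_type`, the type of the immediately preceding block in the
full history (`none` only for the very first block). Because probe-phase
blocks can follow an intermediate block, `prev_block_type` takes four
values (s1, s2, intermediate, none); models map the latter two to a neutral
context (the average of the two context-conditioned initial values or
priors).

## Models

Six variants, all predicting the dopamine reward response as
predicted_da = β·δ (an optional additive offset exists but is off by
default; β is described as a linear map from theoretical prediction errors
to the measured signal, and a pure gain is the minimal such map).

**Standard RL** — single observable state per block: δₜ = rₜ − V,
V ← V + αδₜ within a block. At block start V resets to an initial value:
one shared value (`std_single`, 3 parameters: α, V₀, β) or one per
previous-block context (`std_dual`, 4 parameters).

**Belief-state RL** — hidden states with Gaussian reward likelihoods
N(r; r̄ₛ, σ²), r̄ = (0, 1) for two states. At block start the belief resets
to the variant's prior (beliefs do not carry across blocks: the tone marks
a fresh draw of the latent state). The value uses the *pre-outcome* belief
(the prior on trial 1, thereafter the posterior given rewards 1..t−1 of the
current block): δₜ = rₜ − w·bₜ. This timing is the only one under which
trial-1 RPEs are reward-independent-value (hence linear in r) while trial-2
RPEs are belief-modulated, matching the qualitative pattern the model
family exists to test. After the outcome the belief is updated by Bayes'
rule (computed in log space; zero-prior states stay absorbing, extreme
rewards never underflow) and weights by Δw = αδₜb. The update's belief is
the post-outcome one by default — the reward has just disambiguated the
state, so credit flows to the inferred state — with a switch
(`use_post_outcome_belief=False`) for the pre-outcome convention; the
defining equation does not disambiguate, and the package's qualitative
results hold under either choice.

Prior variants: `bs_fixed` pins P(s) = 0.5 (3 parameters: α, σ², β);
`bs_one_prior` frees a single context-independent prior (p₁, 1−p₁) (the
"prior following s₁ is p₁, prior of s₂ is 1−p₁" parameterization is
algebraically context-independent); `bs_two_prior` frees both contexts —
after s₁ the prior is (p₁, 1−p₁), after s₂ it is (1−p₂, p₂) (5
parameters); `bs_three_state` adds an intermediate hidden state with
reward mean 0.5 (the center of the normalized scale), prior mass p₃ shared
across contexts with the remaining 1−p₃ split by the p₁/p₂ rule, and
initial weight 0.5 (6 parameters). The three-state construction details
(mean, mass-splitting, initial weight) are package choices; nothing in the
task pins them down.

Weights initialize at the naive (0.5, 0.5) when simulating or fitting a
full history, or can be set to the training asymptote (0, 1) when starting
at the probe phase.

A note on asymptotics: with Δw = αδb and post-outcome credit, repeated
training blocks equilibrate the weights not exactly at (0, 1) but at
(−c, 1+c) with c = α(1−α)⁴ / [2(1 − (1−α)⁴)] — each block's first trial is
predicted under the mixed prior but credited to the identified state, and
the within-block decay balances that kick. The offset is O(α) (≈0.11 at
α = 0.05) and is verified against this closed form in the test suite.

The sequential trial loops are JIT-compiled (numba); a pure-Python
composition of the documented scalar update rules serves as the reference
implementation the kernels are tested against.

## Synthetic data

`synth.generate_mouse` runs a ground-truth model over a generated full
history and emits two observables per trial: the dopamine response
(predicted_da plus homoscedastic Gaussian noise, sd 0.5 dF/F-scale units
against true gains β ∈ [1, 3] — single-trial SNR of order 1–4, typical of
fiber photometry) and the anticipatory lick rate, an affine floor-clipped
function of the pre-outcome value, max(0, 6·V + 1 + N(0, 0.8)) licks/s.
The lick scale is arbitrary (no quantitative lick model accompanies the
study); only its positive monotone coupling to value matters for the
correlation analyses. DA and lick noise are independent across trials.

Cohort ground-truth parameters are drawn uniformly inside the fitting
bounds: α ∈ [0.05, 0.25], σ² ∈ [0.03, 0.15], β ∈ [1, 3], context priors
p₁, p₂ ∈ [0.55, 0.85] (stay-biased, so every simulated animal carries the
previous-block effect on trial-1 expectation that the context-conditioned
model variants exist to capture; the standard-model draws encode the same
effect via initial values [0.1, 0.4] after s₁ and [0.6, 0.9] after s₂).

`synth.generate_raw_trace` renders trials as a 1 kHz fluorescence trace for
exercising the photometry pipeline: a difference-of-exponentials indicator
kernel (rise 30 ms, decay 400 ms, unit peak) is injected at odor onset
(amplitude ∝ value) and reward onset (amplitude = β·δ), on a baseline with
optional single-exponential bleaching and white noise. Trial timing follows
the task: 1 s odor, 1 s delay, reward; inter-trial interval 4 s fixed plus
an Exponential(4.7 s) tail (mean ≈ 8.7 s, flat hazard); a 2 s tone precedes
each block's first odor by 3 s (tone end to trial start). The kernel and
bleaching model are invented conveniences — they emulate no measured
indicator dynamics — so passing photometry tests demonstrates correctness
of the extraction arithmetic, not fidelity to real GCaMP kinetics. What the
synthetic data do not emulate: motion artifacts, hemodynamic or
pH-dependent signal components, sub-trial RPE temporal structure, lick-rate
dynamics within the delay period, and session-level nonstationarities other
than bleaching.

## Photometry

dF/F = (F − F₀)/F₀ with three baseline definitions: per-trial (mean F over
the 1 s before odor onset), per-block (1 s before tone onset), and a 60 s
centered running median (truncated at trace edges; implemented with a
rolling median). Windows are half-open [onset, onset + 1 s); the boundary
convention is fixed by the package and tested. CS and US responses are window means; the US response additionally
subtracts the mean dF/F over the 100 ms centered on reward onset
(±50 ms), because the CS transient need not have decayed. The US peak is
the single-sample maximum (no smoothing). Min–max normalization by each
animal's trial-1 range is provided for display only; fitting always uses
baseline-corrected responses.

## Fitting

Per mouse, responses are averaged per (reward volume, trial-in-block,
previous-block type) cell — cells observed zero times are simply absent —
and the model is fit to those averages: a forward pass over the mouse's
full trial history from naive weights, predictions averaged over the same
cells, and a Gaussian likelihood of the observed cell means with the
residual variance profiled out analytically,
NLL = n/2·[ln(2π·RSS/n) + 1] (equivalent to least squares; no explicit
noise parameter is fitted, and RSS is floored at 1e−30 so the zero-residual
limit stays finite). Bounds: α ∈ [0, 0.3], σ² ∈ [0.01, 0.5], initial
values ∈ [0, 1], priors ∈ [0.001, 0.999], β ∈ [0, 100] (the gain bound is a
package choice). Optimization runs L-BFGS-B from 5 random starting points
(uniform in the bounds shrunk 1% to the interior; β starts log-uniform over
[0.1, ~30]), then polishes the best solution with bounded Powell search,
which is gradient-free and robust on the flat ridges induced by small
learning rates. Deterministic given the seed.

Identifiability at study-condition noise: the context priors and gain
recover with median relative errors of a few percent; α and σ² are weaker
(medians ≈ 15–20%) because their signal is concentrated in the low-n
intermediate-volume cells, which the unweighted condition-average
likelihood does not privilege. Zero-noise fits recover all parameters to
optimizer precision.

## Model selection

Per-model evidence is approximated as −BIC/2, BIC = k·ln(n) + 2·NLL with
n the number of condition cells. Cohort comparison uses variational
random-effects Bayesian model selection with a flat Dirichlet prior
(α₀ = 1): iterate uₙₖ ∝ exp(log-evidenceₙₖ + ψ(αₖ) − ψ(Σα)),
αₖ = α₀ + Σₙuₙₖ to convergence (1e−8). Exceedance probabilities are
Monte-Carlo estimates over Dirichlet(α) draws (default 10⁶; standard error
< 1e−3); the Bayes omnibus risk compares the random-effects free energy to
the equal-frequency null, BOR = 1/(1 + exp(F_rfx − F₀)), and
pxp = (1 − BOR)·xp + BOR/K. Exact frequency ties in the Monte-Carlo argmax
are a probability-zero event; the first-index rule makes the estimate
deterministic given the seed.

## Statistics

The exact Wilcoxon signed-rank test builds the null distribution of the
rank sum by dynamic programming over subset sums of {1..n} in integer
arithmetic (the 2ⁿ sign assignments are enumerated implicitly and the
distribution sums to 2ⁿ exactly); the reported statistic is min(W⁺, W⁻)
and the two-sided p is 2·P(W ≤ w) capped at 1 — the convention under which
the n = 11 paired comparisons print p = 0.032 at w = 9 and p = 0.32 at
w = 21. Zeros or tied magnitudes raise an error (the exact null requires
distinct ranks) with a pointer to mid-rank approximations. Correlations are
Pearson r with t = r·√((n−2)/(1−r²)), one- or two-tailed. Polynomial fits
report adjusted r² = 1 − (1−r²)(n−1)/(n−d−1). Anticipatory-lick deltas are
differences of consecutive-trial lick rates within a day (within-block by
default).

## Problem sizes and numerical choices

Test-suite and pipeline simulations use the full study-scale histories
(~8,100 trials/mouse, 11-mouse cohorts) for generation and fitting;
Monte-Carlo sample counts in tests are 2×10⁵–10⁶ depending on the
tolerance being checked. Optimizer tolerances: ftol 1e−12 (L-BFGS-B),
Powell xtol 1e−10. Non-finite model predictions during fitting return a
large finite penalty (1e10) rather than raising inside the optimizer.
Degenerate inputs raise explicit errors: empty schedules, out-of-range
volumes, degenerate min–max ranges, missing (mouse, model) cells in cohort
selection, non-finite evidences (naming the offending cell).

## Known limitations

- Trial-level modeling only: no intra-trial temporal-difference structure,
  no cue-onset response fitting (cue values are reported but not fitted).
- The belief-state weight update's belief (pre vs post outcome) is a
  convention, not a fitted distinction; both are implemented.
- β as pure gain cannot capture an additive shift of measured responses;
  the optional offset parameter exists but is not part of the six standard
  variants.
- The synthetic lick model is minimal (affine in value); real anticipatory
  licking saturates and has temporal dynamics the delta analyses here do
  not probe.
- Model selection treats −BIC/2 as log evidence; with few observations per
  mouse this is a coarse Laplace-style approximation.
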