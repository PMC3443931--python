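# Methods

This note documents the models, conventions, and numerical choices behind
`avbisect`: what the synthetic observers and sessions emulate, how the
psychometric quantities are estimated, how the cue-integration model is
evaluated, and where the honest limits of 30-trial psychophysics lie.

## Task and session designs

Both tasks present three successive stimuli over 1000 ms and ask whether
the second was closer to the first or the third; response 1 codes "closer
to the third", and positive probe offsets point toward the third stimulus
(later in time; toward the far end of the speaker array in space).

* **Temporal bisection** (`TaskDesign.time()`, units ms): 5 interleaved
  conditions × 30 trials — vision only, audition only, and three
  audio-visual conflicts.  The stored conflict Δ ∈ {−50, 0, +50} ms is the
  *half*-conflict of the second stimulus: its auditory component occurs
  Δ ms after its visual component while the first and third stimuli carry
  −Δ, so the effective audio-visual separation of the probe is 2Δ.
* **Spatial bisection** (`TaskDesign.space()`, units deg): 7 conditions ×
  30 trials, conflicts Δ ∈ {0, ±4.5, ±9}°; the second stimulus's visual
  component sits at +Δ and its auditory component at −Δ, the outer stimuli
  are audio-visually aligned, and the second stimulus always occurs 500 ms
  after the first.

`cue_offsets` is the single place where this geometry lives: relative to
its own first/third midpoint, the visual cue of a probe at offset x sits at
x in time and x + Δ in space, the auditory cue at x + 2Δ in time and x − Δ
in space.

## Observer models

An observer is a pair of unimodal noise levels (σ_V, σ_A) plus a
combination rule.  On every trial the decision variable is
e = w_V·offset_V + w_A·offset_A with rule-dependent weights, corrupted by
Gaussian noise of width σ_eff, and

    P(response = 1) = λ/2 + (1 − λ) Φ(e / σ_eff).

Rules: `optimal` uses the inverse-variance weights and the fused
σ_VA = σ_Vσ_A/√(σ_V²+σ_A²); `visual_capture` and `auditory_capture` put
all weight on one cue with that cue's σ; `fixed_weights` uses a supplied
w_A with σ_eff = √(w_V²σ_V² + w_A²σ_A²).  The lapse rate λ defaults to 0
(the fitted model carries no lapse term either) and is capped at 0.1 for
robustness experiments.  A training screen of 10 maximal-offset trials
(default offset 5·max(σ_V, σ_A), which makes an attentive observer's
accuracy ≈ 1) gates each simulated session at 7-of-10 correct.

## Adaptive placement

Each condition runs its own QUEST-style track: a 201-point grid posterior
over candidate bisection points, Gaussian prior (SD 200 ms / 20°), and a
cumulative-Gaussian response likelihood with an assumed slope of the order
of child thresholds (120 ms / 15°).  The recommendation is the posterior
*mean* (smoother than the mode on coarse grids; the mode is available),
and every placement adds zero-mean Gaussian jitter (SD 100 ms / 10°) so
that the flanks of the psychometric function are sampled and "closer to
first" and "closer to third" responses stay balanced.  Likelihoods are
floored at 1e−10 before the log, and the grid always spans at least ±3
assumed slopes.  The posterior is exactly order-invariant in the updates
(log-additivity), which the tests exercise.

## Psychometric estimation

`P(1|x) = Φ((x − μ)/σ)` is fitted by maximizing the Bernoulli likelihood
of the raw trials — adaptive placement leaves offsets unbinned, so binned
least squares would discard information.  Internally this is probit
regression Φ(a + bx), μ = −a/b, σ = 1/b, solved by IRLS from the canonical
deterministic start (null-model intercept, zero slope), with probabilities
clipped to [1e−12, 1−1e−12] and the linear predictor to ±7.5.  The solver
is vectorized over a leading batch axis, which is what makes 100-replicate
bootstraps of whole cohorts cheap.  Fits are deterministic given the data.

Three failure modes are *flagged*, never silently repaired:

* **Single-class responses** raise an error naming the condition.
* **Perfect separation** (all 0-responses below all 1-responses) means the
  likelihood increases without bound as σ → 0: no finite threshold MLE
  exists.  The threshold is reported as NaN and the fit non-converged.
  The PSE, however, remains identifiable — any point inside the separation
  gap maximizes the limiting likelihood — so the gap midpoint is reported
  and downstream PSE analyses (bias correction, conflict slopes) keep the
  condition, while threshold analyses drop it.
* **Thresholds below the placement resolution** (fewer than 3 trials
  within ±2σ̂ of μ̂): the whole rise of the fitted function falls between
  adjacent placements, so the sample carries no information about a slope
  that steep; flagged non-converged.

These pathologies are not edge-case paranoia: with 30 trials and a fixed
placement jitter, observers whose true σ is much smaller than the jitter
are separation-prone (a property of the design, visible in the tests), and
reporting their σ̂ ≈ 0 as converged estimates would poison every downstream
group statistic.

**Standard errors** are nonparametric case-resampling bootstrap SDs
(default 100 replicates, seeded; replicates refitted in one batched
solve).  Failed replicates are dropped and counted; more than 20% failures
attaches a warning; a single replicate is degenerate (SE 0, flagged).

**Bias correction.**  Bisection tasks carry constant response biases (the
first interval tends to appear longer), so each conflict condition's PSE
is referenced to the zero-conflict PSE of the same session; the Δ = 0
entry is exactly 0 by construction and the correction is
translation-invariant.

**Pooled bimodal threshold.**  All conflict conditions contribute to one
two-cue threshold: each condition's trials are recentered on that
condition's fitted PSE, pooled, and fitted with μ constrained to 0 (a
one-parameter batched IRLS).  Without recentering, conflict-dependent PSE
shifts inflate the pooled σ — both modes are implemented and compared in
the tests; recentering is the default.  Bootstrap resampling for the
pooled SE stays within condition and refits the recentering PSEs per
replicate.

## Sign conventions (one paragraph, used everywhere)

Fitted PSEs are always the μ of Φ((x − μ)/σ) against the *physical* probe
offset.  The symmetric ±Δ frame in which Ŝ(Δ) = (1 − 2w_A)Δ holds is
reached by `symmetrize_conflict_pses`: in time, add +Δ (the asymmetric
temporal geometry puts the whole conflict on the auditory side, so the
fitted PSE runs from 0 under visual dominance to −2Δ under auditory
dominance; recentering on the inter-cue midpoint maps these to ±Δ); in
space, negate (both cues move with the probe, so the fitted 50% point is
the negative of the perceived shift of the standard — the classic
ventriloquist measure, +Δ under visual capture).  After this mapping the
conflict-slope regression yields +1 for pure visual dominance and −1 for
pure auditory dominance in both domains, and the slope-derived weight is
w_A = (1 − slope)/2, reported unclamped with an `in_range` flag (clamping
would bias weight-vs-weight comparisons).

## Model evaluation

Per observer: the forced-fusion prediction σ_VA and weights from the two
fitted unimodal thresholds, predicted PSEs per conflict, and the
OLS conflict slope of the bias-corrected symmetric PSEs (plain OLS by
default, matching the descriptive convention; inverse-variance weighting
available).  Because σ_VA(σ̂_V, σ̂_A) is concave in each argument, plugging
in noisy 30-trial estimates biases the prediction low — enough to generate
spurious "measured > predicted" outcomes for genuinely optimal observers.
The pipeline therefore applies the standard bootstrap bias correction
(2·plug-in − mean over paired unimodal bootstrap replicates, requiring at
least 20 converged replicate pairs) and reports the replicate SD as the
prediction's SE; the uncorrected value is kept alongside.

Per age group: means ± SEM of thresholds and both weight routes (SEM is
NaN for single-observer groups); the explained-variance statistic over all
children and all conflict levels, with σ² and σ̂² as population variances
(denominator N, so a constant prediction at the data mean gives exactly
0); and a one-tailed one-sample t-test of measured − predicted bimodal
thresholds with alternative "measured > predicted" (the direction of
non-optimality), starred at 0.05 and 0.01, degenerate zero-variance cases
flagged (t = 0, p = 0.5 for identical values).  No multiple-testing
correction by default (stars are reported per group); a Bonferroni option
exists.  The R² statistic is invariant under joint affine rescaling of
measured and predicted values (unit changes), never exceeds 1, and is
negative when the model does worse than the mean.

## Synthetic cohorts

`realistic_cohort()` uses realistic, unequal thresholds by age (audition
more precise for time, vision for space, children's thresholds larger)
with capture children and optimal spatial adults — useful as a plausible
end-to-end default.

`signature_cohort()` is built to *dissociate* capture from integration,
and its design is instructive about the method's limits:

* Capture groups use σ_V ≈ σ_A.  With strongly unequal thresholds the
  inverse-variance weights already favor the dominant cue and a capture
  observer mimics the MLE prediction — the dissociation only exists where
  the two precisions are comparable.
* Optimal groups use *unequal* thresholds.  With σ_V ≈ σ_A every
  predicted PSE is ≈ 0, the predicted-PSE variance vanishes, and the
  explained-variance statistic is ≈ 0 by construction even for a perfect
  integrator; asymmetric weights give the predictions a real range that
  the measurements then follow.
* All thresholds sit within roughly 0.6–1.3× the fixed placement jitter
  of their task.  Below that band 30-trial samples are separation-prone;
  above it the placements are too narrow to pin the slope.  This is a
  measurement-design constraint any experimenter faces, not a model
  property.

What these cohorts do **not** emulate: real children's lapse and attention
dynamics, session fatigue, inter-trial dependencies, partial (weighted
rather than all-or-none) capture, and causal-inference-style breakdown of
fusion at large conflicts.  Passing the cohort tests shows the estimators
recover what the generative model put in — it says nothing about whether
real children are capture observers.

## Problem sizes and numerical choices

The validation suite simulates sessions at the study's own scale (30
trials per condition, 100 bootstrap iterations).  Parameter-recovery runs
use 100 spatial observers for the threshold check and 500 replicates for
the slope-weight check; the signature cohort uses 16 observers per group.
A full default cohort (48 observers, both domains, bootstrapped) runs in
well under a minute on one CPU because all bootstrap refits are batched.
Explained variance for an all-optimal, strongly vision-weighted spatial
cohort tops out around 0.8–0.88 at 30 trials/condition — the PSE fit noise
is an irreducible part of the "measured" variance — so evaluations treat
R² ≈ 0.8 as the practical ceiling of a perfect integrator at this design,
and R² ≈ 0 as the capture signature when precisions are comparable.

Determinism: a config plus one root seed fixes every output byte; the root
`SeedSequence` spawns one child per observer for simulation and one for
analysis, so observers are independently reproducible.  Trial CSVs are
written with 17 significant digits and read back with round-trip float
parsing, making write∘read the identity.

## Known limitations

* Thresholds from 30-trial adaptive runs are heavy-tailed; group means of
  derived ratios (e.g. bimodal/unimodal) are noisy, and analyses here
  prefer ratios of means and bias-corrected predictions for that reason.
* The temporal task's 3-point conflict design (±50 ms) identifies the
  conflict slope much more weakly than the spatial 5-point design; weight
  recovery quoted in the tests uses the spatial task.
* The QUEST parameters (prior, assumed slope, jitter) are explicit knobs
  of the simulation, not claims about any particular hardware setup.
* No lapse term is fitted; heavy lapsing (λ > a few percent) biases σ̂
  upward.  A lapse-robust refit is deliberately out of the default path.
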