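# Methods

This note documents the models, conventions and numerical choices behind
`prorich`, in the spirit of a statistical package's model documentation.

## The D score

The IAT D score treats the latency cost of the incompatible key mapping
(poor + good) relative to the compatible one (rich + good) as a
standardized effect, analogous to Cohen's d. The implementation follows
the improved scoring algorithm step for step, and two ordering details
matter:

- the pooled SD of each block pair is computed on **all retained trials**
  (correct and incorrect, after the 10 000 ms removal) and **before**
  error replacement, because the SD step precedes the replacement step;
- a latency of exactly 10 000 ms is retained — "exceeding" is strict.

Error latencies are replaced by their block's correct-trial mean plus a
600 ms penalty, so the score is *not* invariant to rescaling latencies
whenever errors are present (the penalty is absolute); the test suite
asserts scale invariance only for error-free inputs. No fast-trial
deletion is applied at the trial level: the 300 ms rule enters only
through the participant-level exclusion criteria. Whether archival
datasets computed the pooled SD on correct-only rather than all retained
trials is not always documented; anyone comparing against archived D
values should check this convention first (ours: all retained trials).

Degenerate inputs raise typed errors rather than returning NaN: a scored
block that is empty (or has no correct trial) after exclusions raises
`UndefinedScoreError` naming the block; an all-identical latency pair
raises `DegenerateInputError`.

## Exclusion cascade

All eight careless-responding criteria are evaluated for every
participant on the trials as administered (before the 10 000 ms removal,
which belongs to scoring); only the *attribution* for the audit log uses
the fixed order (duplicates, criteria 1–8, then income → education →
gender, so a participant missing both income and education counts under
income). Thresholds are inclusive (≥) and proportions are compared as
exact rationals (`fractions.Fraction`), so a block with exactly 35% fast
responses is excluded with no floating-point ambiguity.

The task never documents whether the single-categorization blocks
(1, 2, 5) count as "practice" for the exclusion rules. We use the
dual-categorization practice blocks {3, 6} and critical blocks {4, 7} —
the same four blocks the D score uses — and both sets are arguments of
`apply_iat_criteria` for anyone preferring a different mapping.

## Explicit measures

Measures are scored from item-level ratings; multi-item components are
averaged within target (rich/poor) before differencing, with equal item
weights — item subsets are randomized per participant in the source
design and no weighting scheme is documented, so `n_items_used` is
recorded per score. Others' evaluations (2) and relative preference (9)
are reverse-coded; polarity (12) is the mean of its two items and is
tested against its scale midpoint (3.5) instead of 0. The monopolar
ambivalence measure applies

    ambivalence = min(pos, neg) / (6 + max(pos, neg) − min(pos, neg))

per target (range [1/11, 1]; symmetric; strictly increasing in the
minimum intensity) and differences rich − poor. Certainty, importance,
forecasting and mindfulness items (codes 15–18) are accepted in input
files but never scored. Correlations with D use pairwise-complete cases,
so each measure reports its own n.

## Moderated regression

Gender is contrast-coded women = −0.5, men = +0.5. This coding is what
makes the printed pilot estimates mutually consistent: the interaction
coefficient equals the men-minus-women slope difference, the gender term
equals the gender difference at mean income/education, and the education
main effect equals the average of the four education simple slopes.
Income, education and the outcome are z-scored on the final analysis
sample (sample SD, ddof = 1). Simple effects are linear combinations of
the omnibus coefficients with se = √(c′Σc) and unchanged residual df;
the suite verifies they agree to 1e−10 with the re-center-and-refit
implementation. Two-sided p-values throughout.

Multicollinearity: if any VIF exceeds 10, income is replaced by its
residual from a regression on education and the model refit. The source
description of this contingency is self-contradictory about direction
("residuals for income in a model predicting education as a function of
income"); we residualize income on education, which preserves education's
interpretation and orthogonalizes the pair, and flag the fit with
`orthogonalized=True`.

## Synthetic cohort generator

The generator's defaults are the pilot-sample study conditions: n = 175
with 115 women; 5-point income and education drawn from the pilot
marginal frequencies ([35, 42, 39, 42, 17] and [2, 11, 54, 71, 37] of
175) via a latent bivariate normal cut at the marginal quantiles; and the
omnibus coefficient vector reconstructed from the pilot simple effects
(b0 = 0, bG = 0.084, bI = 0.040, bE = 0.111, bGI = 0.132, bGE = 0.0455,
bIE = −0.036, bGIE = −0.089). The latent correlation is solved by Brent's
method on the *exact* Pearson correlation of the discretized pair
(bivariate-normal rectangle probabilities), undoing discretization
attenuation so the observed correlation equals the configured 0.22.

A participant's true D is the omnibus linear predictor plus normal
residual noise, encoded into trial latencies as a log-space slowdown on
poor+good blocks. Latencies are lognormal (median ≈ 800 ms, log-SD 0.35,
floored at 150 ms) — a convention, not an estimate, since the source
data's latency distribution is not published. The slowdown is solved from
lognormal moments so the expected scored D matches the target; because
the pooled-SD denominator saturates the attainable D near ±2, extreme
targets are clamped to the attainable range. Careless responding is
generated by three named archetypes (fast responder, high error, ultra
slow), each engineered to trip a specific exclusion criterion.

Explicit items are integer ratings from clipped rounded normals whose
default measure-level means equal the pilot descriptive means.

What the generator does **not** emulate: sequential effects (practice,
fatigue), stimulus-word effects, non-lognormal latency tails, and any
dependence of explicit responses on the participant's demographics or D.
Passing tests therefore demonstrate correctness of the *analysis
machinery* under the stated statistical structure, not fidelity to every
property of web-collected reaction-time data.

## Power simulation

Each replicate draws gender, correlated ordinal income/education
(z-scored within sample), computes outcome = Xβ + N(0, σ), fits the
full-interaction OLS, and evaluates each registered contrast two-sided at
α = 0.05; power is the proportion of significant replicates, with
binomial Monte-Carlo standard errors. Per-replicate generators are
spawned from the master seed (`numpy` SeedSequence), so runs are
bit-reproducible and parallelizable. Batteries use 1000 replicates with
n = 1000 per dataset (projected, stage 1) and n = 767 (observed final
sample, stage 2).

The one free noise parameter σ is calibrated so the design-expected
standard error of the Gender × Income coefficient at the pilot design
(n = 175) equals the printed 0.055; the source standardizes D but never
reports σ itself, and t-based decisions are invariant to outcome
rescaling, so this pins σ (≈ 0.326) without further assumptions.
Whether the outcome is re-standardized per replicate is configurable
(default: yes); it does not affect power, again by t invariance. The
calibration matches one printed standard error exactly and the others
approximately (the realized pilot design's cell counts differ slightly
from random draws), which leaves the mid-range power estimates within
about three percentage points of the published values; the saturated
(≈100%) and α-adjacent (≈5%) tests reproduce exactly.

Sensitivity analysis multiplies one generating coefficient by (1 − s)
over a grid of shrink factors s and reports the power curve and the
largest s keeping power ≥ 0.80 — the "smallest detectable effect"
convention.

## Problem sizes in the test suite

The suite favours exact small-input oracles (hand-computed D scores,
normal-equation fits, closed-form t-tests) plus moderate simulation sizes
chosen for stable assertions: 500 simulated participants per point on the
D-monotonicity curve, 1000 replicates for power reproduction and test
size, n = 10 000 for parameter recovery. The full suite runs in about a
minute on one CPU.
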