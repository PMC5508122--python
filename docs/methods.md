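# Methods

## Estimands and estimators

For each belief item the package reports three families of interval
estimates, all descriptive (no multiplicity adjustment — the intervals
support selection judgments, they are not hypothesis tests):

**Item means.** Arithmetic mean of the non-missing scores with a Student-t
interval, `m̄ ± t₍₁₋α/₂, n−1₎ · s/√n`. The default confidence level is
0.9999. The deliberately extreme level reflects the display's purpose: a
99.99% diamond that still sits clearly at one end of the scale is strong
evidence that the population really is there, so mean diamonds stay
decision-relevant even when very many are inspected at once. A zero-variance
item yields a zero-width interval flagged `degenerate` rather than an error,
since constant columns occur in real exports.

**Item–target correlations.** Pearson r over pairwise-complete cases with a
Fisher-z interval, `tanh(atanh(r) ± z₍₁₋α/₂₎/√(n−3))`, clamped to [−1, 1];
default level 0.95; at least 4 complete pairs required (the z standard error
needs n − 3 > 0). Exactly collinear inputs (|r| = 1, e.g. an accidentally
duplicated column) return a degenerate zero-width interval at ±1 instead of
failing. The Fisher-z construction was chosen for being analytic, fast, and
standard; the test suite cross-checks its bounds against a 10,000-replicate
case-resampling bootstrap (agreement within 0.02 at n = 200) so the choice
is load-bearing only at small n, where the z interval is the better-behaved
of the two anyway.

**Explained variance.** OLS R² (via statsmodels) of each target on all
usable items jointly, complete cases only. Interval bounds invert the
noncentral-F distribution of the observed
`F = (R²/k) / ((1−R²)/(n−k−1))` over its noncentrality parameter λ
(Brent bisection, tolerance 1e−8 on λ), using the fixed-score convention
λ = n·f² with f² = R²/(1−R²), so bounds map back through R² = λ/(λ+n).
The lower bound is floored at 0 (the search returns λ = 0 whenever even a
central F leaves insufficient mass below the observed statistic). Because
R̂² is upward-biased by roughly k/n, the resulting interval is asymmetric
around — and can sit almost entirely below — the point estimate; this is
correct behavior, verified against a case-resampling bootstrap (within 0.03
at n = 500, k = 3).

Missing data: pairwise-complete for means and correlations (each panel uses
the most information available to it), complete-case for R² (a joint model
needs joint observations). These can legitimately disagree in n; the tidy
estimates table reports n per estimate.

## Numerical conventions

Degeneracy and tie comparisons use an absolute tolerance of 1e−12. Interval
invariants (lower ≤ point ≤ upper, correlation bounds in [−1, 1], R² bounds
in [0, 1]) are enforced at construction. Sorting for display order is stable,
so tied point estimates keep the input order. All stochastic components
(jitter, the generator) run on `numpy.random.default_rng` with explicit
seeds; the default jitter seed is 42 so figures are reproducible by default.

## The figure

Diamonds span the interval horizontally with the widest point at the point
estimate (half-height 0.25 row units; 0.20 in the right panel where two
targets share a row at vertical offsets ±0.18). Fill colors come from
three-anchor piecewise-linear RGB gradients: red (1,0,0) → blue (0,0,1) →
green (0,1,0) over the response scale for means, red → gray (0.5,0.5,0.5) →
green over [−1, 1] for correlations. Interpolating linearly in RGB (rather
than a perceptually uniform space) was a deliberate trade: it guarantees the
properties the display semantics rely on — the anchor hues are attained
exactly at the scale ends and midpoint, the red channel never increases and
the green channel never decreases across the domain — whereas paths through
Lab-like spaces are not channel-monotone after conversion back to RGB.
Target stroke colors cycle through a fixed palette beginning red, blue.
Raw scores are jittered uniformly within ±0.45 scale units horizontally and
±0.2 row units vertically (legible at a few hundred respondents per item).
Items whose estimation failed are rendered as labeled empty rows, never
silently dropped, because silent omission would bias selection. SVG output
is byte-stable for identical specs (fixed hash salt, no embedded timestamp);
PNG and PDF are offered for convenience without the byte-stability promise.

Scale bounds, needed for the fill-color midpoint, come from item metadata
when declared and otherwise fall back to the observed data range with a
logged warning.

## The relevance classifier

The classifier condenses each item's pattern into one of four actions,
driven by the association with the largest |r| across targets. Defaults:
|r| < 0.1 counts as no association, |r| ≥ 0.3 as strong, means within the
outer 15% of the scale range as "near an extreme"; associations in
[0.1, 0.3) yield the same labels flagged low-confidence. The field
literature describes these patterns qualitatively, so the cut-offs are
package conventions, all configurable via `RelevanceThresholds`. The rules
assume targets are coded so that higher scores mean more inclination toward
the discouraged behavior (set `target_high_undesirable=False` to flip);
under that coding, a positive association marks the item's high end as the
risk-promoting end, so: strong association + mean already at the safe end →
*confirm*; positive association + non-extreme mean → *negate*; negative
association + non-extreme mean → *reinforce*; negligible association →
*deprioritize*.

## The synthetic generator

The generator emulates a belief-elicitation survey: k belief items and m
targets drawn jointly from one latent correlation matrix, so every
item–target correlation is controlled exactly. Items load on the targets
(loadings `L = R_tt⁻¹ ρ` per item) and are conditionally independent given
them; the assembled matrix is eigenvalue-checked before Cholesky sampling.
Latent scores map onto the response continuum at one latent SD per sixth of
the scale range (≈99.7% of mass inside the scale before clipping), then
round to the nearest integer and clip to the bounds — equal-width latent
thresholds. Latent mean shifts (in SD units ≈ scale points) create floor- or
ceiling-shifted items. Missingness is completely at random at a configurable
rate.

Discretization attenuates correlations and shifts clipped means, so the
truth record carries, besides the configured latent correlations, the
*exact* expected means and post-discretization correlations, computed from
normal bin probabilities (1-D) and bivariate-normal rectangle probabilities
(2-D) rather than simulation. `recovery_report` checks interval coverage
against both truths.

The bundled study-like configuration has 227 respondents, 21 items on 1–7
scales, attitude and intention targets (inter-target latent r = 0.55,
target latent means −0.4/−0.6 as typical for a risk behavior a sample is
ambivalent about), 2% missingness, latent item–target correlations between
0.03 and 0.45 in magnitude, and four pattern-exemplar items: mid-scale
strongly positive (negate), floor-shifted strongly positive (confirm),
ceiling-shifted unassociated (deprioritize), mid-scale strongly negative
(reinforce).

What the generator does *not* emulate: respondent heterogeneity (no random
response styles or subgroups, hence no bimodal distributions), informative
missingness, item wording effects, and ordinal measurement error beyond
discretization. Tests passing on this generator therefore demonstrate the
estimators' and display's correctness under a well-specified latent-normal
world, not robustness to real survey pathologies.

## Verification sizes and expected behavior

The coverage checks use 10,000 replicates (n = 50, ρ = 0.3) for the
correlation interval — Monte-Carlo three-sigma band ±0.6 percentage points
around 95% — and 1,000,000 vectorized replicates (n = 50) for the mean
interval — band ±0.003 points around 99.99%. Parameter recovery pools
200 seeded replicates of the bundled configuration (200 × 42 correlation
intervals) and requires ≥90% of the 95% intervals to contain the latent
truth; pooled coverage lands near 93% rather than 95% because discretization
attenuates the observed correlations relative to the latent values (coverage
of the exact attenuated truth is ≈94%). Oracle-equivalence tests compare
bounds against an independently coded Fisher-z formula (1e−10), and against
percentile bootstraps as noted above.

## Known limitations

Dichotomous determinants or targets are out of scope (the method is built on
Pearson correlations of graded scores). No partial correlations or
regression-coefficient displays are offered, by design. The R² interval
assumes fixed predictors and normal errors; with many predictors and few
complete cases it is exact only asymptotically. Reverse-coded items are not
detected automatically; recode before analysis.
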