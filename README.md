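# ciber

**Confidence Interval-Based Estimation of Relevance (CIBER)** — a tool for
selecting which social-cognitive (sub-)determinants of a behavior an
intervention should target.

## The problem

Before building a behavior-change intervention, developers run a determinant
study: respondents rate a battery of belief items (e.g., 21 expectancies about
a risk behavior, each on a 7-point scale) plus one or more proximal targets
such as attitude and intention. Selecting which beliefs to target requires
judging, for every item simultaneously, (a) its univariate distribution — is
there room to move people? — and (b) its association with the targets — does
moving it matter? With 10 items and one target that is already
10 × 3 × (1 + 1) = 60 point-and-bound estimates to weigh at once; regression
coefficients don't help because they are conditional on the other predictors,
and *p*-values answer the wrong question.

CIBER resolves this by estimating and *visualizing* everything jointly in one
two-panel diamond plot:

* **Left panel** — per item: the jittered raw scores and a diamond spanning the
  99.99% confidence interval of the mean,
  `m̄ ± t₍₁₋α/₂, n−1₎ · s/√n`, filled on a red → blue → green gradient (low →
  mid-scale → high mean).
* **Right panel** — per item × target: a diamond spanning the 95% Fisher-z
  confidence interval of the Pearson correlation,
  `tanh(atanh(r) ± z₍₁₋α/₂₎/√(n−3))`, filled red → gray → green (strong
  negative → null → strong positive), stroked in a fixed per-target color.
* **Banner** — per target: the OLS R² of the target on all items jointly, with
  a confidence interval from inverting the noncentral-F distribution of the
  observed F statistic (λ = n·R²/(1−R²)).

A rule-based classifier then maps each item's (mean, associations) pattern to
an intervention action: **negate** (strong positive association, mean not yet
at the safe end), **reinforce** (strong negative association, likewise),
**confirm** (strong association but the population already sits at the safe
extreme), or **deprioritize** (no meaningful association).

Because real determinant-study data are rarely shareable, the package includes
a synthetic generator: latent multivariate-normal scores with an exactly
specified item–target correlation structure, discretized to bounded integer
scales, with the exact post-discretization ("attenuated") truth returned for
recovery testing.

## Worked example

Generate the bundled synthetic study (227 respondents, 21 belief items on
1–7 scales, attitude and intention targets) and run the whole pipeline:

```bash
ciber demo --out-dir demo_out --seed 0
```

This writes `synthetic_study.csv`, the figure `ciber_demo.svg` (21 rows ranked
by association with attitude, 42 correlation diamonds, 2 R² banner entries),
an estimates table, and a relevance report. From
`demo_out/ciber_demo_estimates.csv`:

```
kind         item       target    point     lower     upper     level   n
mean         belief_01            4.0226    3.7495    4.2957    0.9999  221
association  belief_01  attitude  0.4137    0.2965    0.5185    0.95    216
rsq                     attitude  0.6644    0.5089    0.6862    0.95    153
```

Read: belief 1 sits mid-scale (mean 4.02 on 1–7, even the 99.99% interval is
far from either end) *and* correlates 0.41 [0.30; 0.52] with attitude — a
highly relevant belief with room to move, which the relevance report
(`ciber_demo_relevance.csv`) accordingly labels `relevant-negate`. All 21
beliefs jointly explain R² = 0.66 [0.51; 0.69] of attitude (the interval is
shifted below the point estimate because OLS R² with 21 predictors and 153
complete cases is upward-biased, which the noncentral-F inversion accounts
for). The same pipeline runs on your own survey export:

```bash
ciber plot --data survey.csv --determinants 'belief_*' \
  --targets attitude,intention --order-by attitude --output fig.svg
```

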