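# Methods

This note documents the statistical model behind `dogchange`, the choices
made where the procedure admits more than one reasonable reading, and what
the synthetic cohorts do and do not emulate.

## Study design the package targets

A cohort of old family dogs is tested on a behavioural battery twice, four
months apart. Four arms: physical therapy, cognitive therapy, combined
(alternating weekly), and a waiting-list control. A subsample of controls
re-enrols into a therapy arm afterwards and receives a third test
occasion; such a dog contributes *two* baseline→second pairs to the change
analysis — occasions 1→2 as a control and 2→3 as a treated dog, with the
occasion-2 measurement acting as the new (pre-therapy) baseline. With the
default arm sizes (20/19/24/21, twelve re-enrolled controls split 4/2/6
into physical/cognitive/combined), 72 dogs yield 84 change records. Arm
sizes are therefore *exposure* counts and sum to
`n_dogs + n_reenrolled_controls`.

## Measurement model

Per task, items are correlated (polychoric for all-ordinal tasks, Pearson
otherwise; tasks mixing ordinal and metric items use Pearson) on the
baseline occasion, and the matrix is eigendecomposed.

- **Polychoric estimator.** Two-step maximum likelihood: thresholds fixed
  at normal quantiles of each margin, then the latent correlation
  maximised over (−0.999, 0.999) by bounded scalar search (tolerance
  1e-6) on the bivariate-normal cell likelihood. Estimates at the
  boundary (e.g. empty discordant cells) are clipped to ±0.999 and
  flagged. Polychoric matrices can be indefinite; they are repaired by
  clipping negative eigenvalues at zero and re-standardising, with a
  flag.
- **Retention.** Horn's parallel analysis: 1000 random standard-normal
  data sets of the same shape; a component is retained while its
  eigenvalue exceeds the 95th percentile of the corresponding random
  eigenvalue rank. The draw stream is seedable and is driven by the
  pipeline seed.
- **Rotation.** Direct quartimin (Oblimin with γ = 0) by oblique
  gradient projection (convergence 1e-6, ≤ 1000 iterations), applied only
  when ≥ 2 components are retained. Component order (explained SS) and
  sign (dominant loading positive) are normalised for determinism.
- **Adequacy.** Overall KMO from anti-image partial correlations;
  Bartlett's sphericity χ² = −(n−1−(2p+5)/6)·ln det R; per-component
  standardized Cronbach's α from the correlation submatrix of included
  items.

Items with |loading| ≤ 0.5 are excluded from a component. The inclusion
rule reads the loading in absolute value: an item loading −0.6 is
included and sign-flipped before averaging, so that every included item
points in the component's direction. (The alternative — including only
positive loadings — would silently discard validly loading reversed
items.)

## Component scores

Item values from both occasions are pooled and z-standardised *jointly*;
per-occasion standardisation would absorb exactly the occasion shift the
change analysis is about. A component score is the mean of its included
z-items. At most one item may be missing, and only for components of ≥ 3
items; otherwise the score is missing. Pooling is over the analysed
cohort's rows; when scores are instead computed from an externally
derived loading table, that table is consumed as-is.

Two questionnaire composites are means of integer-coded items, codes
ascending in the order the response levels are listed: health status
(medication no/yes → 0/1; vitamins 0–3; number of health problems 0–3;
higher = more health problems) and training level (six items; higher =
more trained).

## Reliability gate

Test–retest reliability of each component score is ICC(3,1): two-way
mixed model, single rater, consistency form
(MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error) on the
occasion-1/occasion-2 matrix. The absolute-agreement form is available
behind a parameter (`agreement=True`); consistency is the default because
a systematic occasion shift (experience) should not by itself count
against a task's repeatability here — the experience effect is handled
explicitly downstream. Components with ICC < 0.5 are excluded and logged.

## Change classification

For each retained component, over all analysed pairs:

    range              = max(baseline) − min(baseline)
    percentage         = range / 100
    experience effect  = median(second) − median(baseline)
    decrease threshold = −pct·percentage + experience effect
    improve  threshold = +pct·percentage + experience effect

and per dog `change = second − baseline`, classified *declining* if
change ≤ decrease threshold, *stable* if it lies in (decrease, improve],
*improving* if strictly above. The boundary conventions follow the
inequalities exactly. `pct` defaults to 10; `threshold_balance_search`
scans a candidate grid and returns the width minimising the summed
chi-square distance of the category counts from even thirds (ties to the
earlier candidate).

Thresholds pool **all analysed pairs** (84 by default), not only first
pairs; the range uses baseline values only. Useful identities, verified
as property tests: the classification is invariant to affine rescaling of
the component score; subtracting the experience effect from all changes
and re-centring the band at zero reproduces the categories; widening the
band never shrinks the stable set.

## Modelling

The three-category outcome is fitted by maximum-likelihood softmax
regression (statsmodels MNLogit, Newton optimiser, tolerance 1e-8,
≤ 500 iterations), reference category *stable*. AIC = −2·logLik + 2k with
k the full coefficient count. Forward selection starts from the
intercept-only model; at each step the candidate with the largest AIC
drop among those with LRT p < 0.05 **and** ΔAIC ≥ 2 enters (ties by
candidate order; both tie-break rules are deterministic). The four
intervention codings — four-group factor, any-physical, any-cognitive,
any-intervention — are mutually exclusive: once one enters, the others
leave the candidate list. Rows missing any candidate are dropped once up
front so every compared model is fitted on identical records.

Odds ratios are exp(β) with Wald 95% CIs exp(β ± 1.96·SE). The
improving-vs-declining contrast (neither category is the reference) uses
the coefficient difference with a delta-method SE from the coefficient
covariance; a refit with the reference switched reproduces it, which is
tested. VIF is undefined for multinomial models, so collinearity is
diagnosed on category-vs-rest binomial GLMs: the generalized VIF of each
predictor is the determinant ratio on the coefficient correlation matrix,
which reduces to 1/(1−R²) for single-column predictors.

Non-convergent or quasi-separated fits are flagged, not raised; the
forward search skips candidates whose trial fit fails. Mixed effects are
deliberately out of scope: with at most two records per dog and near-zero
dog-level variance in this design, a dog random effect is not estimable
in any useful way.

## Synthetic cohorts

The generator draws, per dog and component, a latent ability
T ~ N(0, σ²_T); the occasion score is T plus an occasion shift plus fresh
N(0, 1−σ²_T) noise. The occasion shift is the component's experience
effect (applied from occasion 2 onward — familiarity is assumed to
saturate after the first retest) plus the intervention effect of every
therapy modality completed before that occasion (combined therapy
receives both the physical and the cognitive effect). Independent
per-occasion noise produces regression to the mean automatically: dogs
observed low at baseline tend to score higher at retest.

Raw items are noisy linear images of the occasion score with loading 0.8;
ordinal items threshold a latent Gaussian at fixed cuts (four levels),
durations/frequencies/latencies are affine maps onto plausible scales
(latency negatively, to exercise the negative-loading path). σ²_T is set
from the configured `latent_icc` by inverting the analytic attenuation of
the mean-of-items score (item noise plus ordinal discretisation, the
latter via the exact digitised-normal correlation), so the *observed*
component scores' retest correlation approximates the configured value.

Defaults (chosen once as a realistic instance of the design; cohorts of
this kind come with no published latent-scale variances or effect sizes,
so these are stated choices, not inferences):

| parameter | default | rationale |
|---|---|---|
| components (tasks) | greeting, persistency, problem_solving, exploration | one all-ordinal task (polychoric path), one designed to fail the gate |
| latent_icc | 0.75 / 0.65 / 0.55 / 0.35 | spans the 0.5 reliability gate |
| experience_effect | +0.10 / −0.50 / +0.15 / +0.20 SD | small positive shifts plus one large negative (fatigue-like) case |
| intervention_effects | physical → +0.6 SD on greeting; cognitive → +0.6 SD on problem_solving | one moderate far-transfer effect per modality |
| items per component | 4, loading 0.8 | all items clear the 0.5 loading cutoff |
| age range | 7.7–14.5 y | senior family-dog window |

Questionnaire moderators are drawn independently of the latent abilities,
so under the default configuration only the intervention codings and the
baseline score carry real signal; any other selected moderator is a
false positive at the selection procedure's operating rate.

**What the generator does not emulate:** the actual twelve video-coded
tasks and their item semantics, breed/weight structure, correlated
moderators (e.g. training level ↔ performance), informative missingness,
dropout between occasions, and inter-observer coding variation (the ICC
machinery covers that use case, but the generator produces a single
observer). Passing tests on synthetic cohorts therefore demonstrate the
*procedure* — calibration of the reliability gate, correctness of the
classifier, operating characteristics of the selection — not substantive
conclusions about real dogs.

## Numerical and degenerate-input conventions

- Polychoric: degenerate margins (a single observed level) raise;
  boundary estimates clip to ±0.999 with a warning.
- Zero-variance items raise, naming the variable; a zero baseline range
  raises (the percentage band is undefined).
- Missing change values propagate to a missing category and are excluded
  from counts; listwise deletion per model.
- Identity-like correlation matrices retain zero components (flagged
  empty loading table) and KMO is NaN when all off-diagonals are zero.
- All randomness flows from explicit seeds (cohort seed; parallel-analysis
  stream derived from the pipeline seed); equal seeds give byte-identical
  reports.

## Problem sizes

Default test-suite and acceptance runs use the study's own design size
(72 dogs, 84 change records); Monte-Carlo checks use 100–500 replicates
at that size, which puts the standard error of estimated rates around
0.01–0.02 — small relative to the asserted tolerances.
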