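# Methods

## The scoring model

SLIEX summarises the effect of an intervention on the fasting lipid
profile as one integer out of 18. It deliberately treats the four markers
(TG, TC, LDL-C, HDL-C) symmetrically in structure but not in weight: each
marker contributes a −1/0/+1 *change* component for the raw direction of
movement and a *weightage* component for its NCEP ATP III category
transition, and the weightage range grows with the number of categories a
marker has (LDL-C, with five categories, can earn up to +5; HDL-C, with
two, at most +2). The implicit assumptions are:

* category transitions carry the clinically meaningful signal — moving
  from High to Normal LDL-C is worth more than an equally large shift
  within one category;
* staying in category is a "minimal benefit" worth +1 everywhere except
  HDL-C remaining Abnormal, which earns 0 — not worsening is rewarded
  only when the standing state is acceptable or the marker had room to
  improve categorically;
* the four markers' contributions are additive and independent.

The total over the markers present at both timepoints is expressed
against the attainable maximum (Σ per-marker (1 + max weightage): TG 5,
LDL-C 6, HDL-C 3, TC 4, hence 18 complete) as a percentage, classified
Fair (< 25), Good (25–50), Very good (> 50–75), Excellent (> 75).

### Numerical and boundary choices

* **Category intervals** are half-open and closed at the lower bound of
  each non-Normal category. The published per-unit ranges leave small
  printed gaps (TG "1.69–2.24" then "2.25–5.63" mmol/L); closing each
  interval below preserves every printed endpoint while covering all
  positive reals with no overlap. TC "High", printed without a relation
  symbol in mmol/L, is read as ≥ 6.20 to match its mg/dL row (≥ 240).
* **No silent unit conversion**: classification uses the supplied unit's
  own cut points. The two unit systems' printed cuts are not exact
  conversions of each other (HDL-C 1.05 mmol/L ↔ 40.6 mg/dL vs the
  printed 41), so converting first could flip a boundary case. The
  property test for cross-unit agreement therefore excludes values within
  0.5% of either unit's boundaries.
* **Conversion factors** are the standard clinical ones: 1 mmol/L =
  88.57 mg/dL for TG, 38.67 mg/dL for the cholesterol markers.
* **"No change"** defaults to exact equality (tolerance 0), matching how
  the tool's worked example scores 3.00 → 3.00 as 0. A configurable
  absolute tolerance is provided for assay noise; it widens the zero band
  symmetrically.
* **Percent** is kept unrounded internally; classification uses the
  unrounded value, and reports round half-up to one decimal (38.888… →
  38.9). Negative totals yield negative percentages, classified Fair; a
  `worsened` flag (total < 0) is exposed separately rather than flooring
  the percentage at zero.
* One published summary table describes the HDL-C change rule with the
  sign inverted relative to the methods text and the worked example
  (which scores an HDL-C *increase* as +1). This implementation follows
  the methods text and worked example.

## Agreement statistics

The reliability module mirrors a three-observer validation design:
observers independently score the same items, and agreement is reported
pairwise.

* **Cohen's kappa** (unweighted) with the large-sample standard error,
  computed from the raters' square contingency table
  (statsmodels backend). When both raters assign one identical score
  throughout, chance agreement equals observed agreement and kappa is
  undefined; such cells are reported as a *constant* flag with 100%
  observed agreement, never silently as NaN. Interpretation bands:
  ≤ 0 none; ≤ 0.20 none-to-slight; ≤ 0.40 fair; ≤ 0.60 moderate;
  ≤ 0.80 substantial; else almost perfect.
* **ICC**: the model is configurable; the default is ICC(2,1) — two-way
  random effects, absolute agreement, single measurement — because
  observers are treated as a sample from a pool of potential raters and
  each rates every item (pingouin backend, F-distribution 95% CI).
  A matrix with zero between-item variance raises a degenerate-variance
  error: there is no reliability to apportion. When the residual mean
  square is exactly zero (raters numerically identical, or differing by
  an exact constant) the F-method CI degenerates; identical raters report
  ICC 1 with a point CI, constant-offset raters report the point estimate
  with an undefined (NaN) CI. Bands: < 0.5 poor, < 0.75 moderate,
  < 0.9 good, ≥ 0.9 excellent.
* **Systematic differences**: one-way ANOVA across raters (scipy
  backend), reported with its F, p and degrees of freedom.

Pairwise kappas and ICCs published for the original three-observer study
are *not* reproduced here: the underlying observer-by-item ratings were
never published, so the agreement module is validated against
hand-computed oracles (explicit p_o/p_e kappa, explicit sums-of-squares
ICC and ANOVA decompositions) and invariance properties instead.

## Synthetic data

The generator states a small world mirroring the original validation
design and is used for all fixtures:

* **Panels** (default n = 24 pairs, the 12-study × 2-arm design): per
  marker, an NCEP category is drawn from a prior (uniform over the
  ladder by default, so fixtures span every category), the pre value is
  uniform within that category's mmol/L interval — the unbounded top
  interval is truncated at twice its lower bound for sampling only — and
  the post value is `pre × effect × exp(N(0, noise_sd))`. Defaults:
  effect 1.0 (null intervention) and noise_sd 0.05, a mild
  within-subject biological/assay variation on the log scale.
* **Ratings** (default 3 raters): each rater reproduces the item's true
  score but mis-scores by ±1 with probability `rater_error_rate`
  (default 0.05, consistent with reported typical observer differences of
  1–3 points on summated scores), clipped to the legal score range.

What the generator does **not** emulate: correlation between markers (in
reality TC is approximately LDL-C + HDL-C + TG/2.2), lognormal population
value distributions, regression to the mean, or rater errors larger than
one point. A green simulation test therefore establishes that the
pipeline recovers the parameters of this transparent world — not that it
would behave identically on physiological cohorts.

Determinism: every stochastic routine takes an explicit integer seed and
uses an isolated `numpy.random.Generator`; identical seeds give
bit-identical output.

## Known limitations

* Only one pre and one post timepoint; no trajectories.
* No alternative guideline ladders (ESC/AHA 2018, non-HDL-C, ApoB) and
  no clinical-risk weighting of the markers.
* How an exact-boundary value inside a printed inter-category gap should
  classify is this package's half-open convention, not a published rule.
* The attainable-maximum rescaling treats missing markers as ignorable;
  if missingness correlates with severity the percentage is biased.
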