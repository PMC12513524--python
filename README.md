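# sliex

An 18-point scoring tool that quantifies the overall benefit of an
intervention (exercise, statin therapy, ...) on the four-marker fasting
lipid profile — triglycerides (TG), total cholesterol (TC), LDL-C and
HDL-C — from a pre/post pair of panels. It is aimed at health
professionals who need a single interpretable number when some markers
improve and others worsen, plus the inter-rater reliability statistics
(Cohen's kappa, intraclass correlation, one-way ANOVA) used to validate
such scores across observers.

## The score

Each marker contributes two components:

* **Change score** ∈ {−1, 0, +1}: +1 if the raw value moved in the
  beneficial direction (down for TG, TC, LDL-C; up for HDL-C), 0 for no
  change, −1 for worsening. Panel range −4 … +4.
* **Weightage score**: points for the NCEP ATP III category transition
  from pre to post. For TG, LDL-C and TC, with rank difference
  *d* = rank(pre) − rank(post) on the marker's category ladder
  (rank 0 = best), the score is *d* + 1 when *d* ≥ 0 (staying in category
  earns the minimal-benefit +1) and *d* when the category worsens.
  HDL-C has a two-level ladder with one special cell: staying Abnormal
  earns 0. Per-marker ranges: TG −3…+4, LDL-C −4…+5, HDL-C −1…+2,
  TC −2…+3; panel range −10 … +14.

The total (change + weightage, at most 4 + 14 = 18 for a complete panel)
is divided by the attainable maximum and multiplied by 100 to give the
**percentage of improvement**, classified

| % improvement | classification |
|---|---|
| < 25 | Fair |
| 25–50 | Good |
| > 50–75 | Very good |
| > 75 | Excellent |

Markers missing from either timepoint are excluded and the denominator is
rescaled (e.g. a panel without TC is scored out of 14).

## Worked example

```python
from sliex import LipidPanel, score_panel

pre  = LipidPanel({"TG": 0.86, "LDL_C": 1.40, "HDL_C": 1.20, "TC": 3.00})
post = LipidPanel({"TG": 0.80, "LDL_C": 1.30, "HDL_C": 1.30, "TC": 3.00})
print(score_panel(pre, post).summary())
```

prints

```
  TG     change +1  weightage +1  (Normal -> Normal)
  LDL_C  change +1  weightage +1  (Normal -> Normal)
  HDL_C  change +1  weightage +1  (Normal -> Normal)
  TC     change +0  weightage +1  (Normal -> Normal)
  total 7/18  (38.9%)  Good
```

TG, LDL-C and HDL-C each moved in the beneficial direction (+1 change);
TC was unchanged (0). All four markers stayed in their Normal NCEP
category, each earning the minimal-benefit +1 weightage. The total of
7/18 is a 38.9% improvement, classified Good.

The same panels via the CLI:

```bash
sliex score --input panels.csv --unit mmol/L           # wide CSV/TSV in, results out
sliex agree --input ratings.csv --icc-model ICC2       # kappa / ICC / ANOVA table
sliex simulate --n 24 --seed 1 --output sim.csv        # synthetic fixtures
```

## Reliability statistics

`sliex.agreement` computes, for a raters × items score matrix: unweighted
Cohen's kappa with its large-sample standard error per rater pair (pairs
of raters who assign one identical score throughout are flagged
*constant* rather than given a number), pairwise and pooled ICC — default
ICC(2,1), two-way random effects, absolute agreement, single measurement,
with the F-distribution 95% CI — and a one-way ANOVA F test for
systematic level differences between raters.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-scores the two published worked-example panels from their printed
pre/post values and brute-forces the structural constants of the scoring
rules (complete-panel maximum, TC-missing maximum, per-marker weightage
maxima) by enumerating every category transition, writing one JSON object
per target.
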