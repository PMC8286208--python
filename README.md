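# swlslink

Link scores between the 4-item and 5-item versions of the Satisfaction
With Life Scale (SWLS).

The SWLS is a five-item measure of global life satisfaction; each item is
rated 1–7 and the total is the plain sum x₁+…+x₅ ∈ [5, 35]. In
traumatic-injury populations the fifth item ("If I could live my life
over, I would change almost nothing") performs poorly and is often
dropped, but a 4-item total (4–28) is no longer comparable with the
decades of published 5-item scores. **Proration** restores comparability:
add the mean of the four retained items to their sum,

```
prorated = Σ₄ + Σ₄/4 = 1.25 × Σ₄ ,   Σ₄ = x₁ + x₂ + x₃ + x₄ ,
```

which imputes the missing item with the observed item mean and always
lands inside the real 5–35 range. The same rule applies to a group mean of
Σ₄. This package is for rehabilitation-outcomes researchers and clinicians
who administer the 4-item form but need scores on the familiar 5-item
metric, and for methodologists who want the validation battery behind such
a link:

- **scoring** — response validation, direct and prorated totals,
  interpretive category cutoffs (31–35 extremely satisfied … 5–9 extremely
  dissatisfied), and the static 25-row 4→5-item crosswalk;
- **agreement** — paired difference statistics, Bland–Altman 95% limits of
  agreement (mean difference ± 1.96 × SD of differences), Pearson r,
  single-measure intraclass correlations ICC(C,1) and ICC(A,1) from the
  two-way ANOVA with F-based 95% CIs, |difference| threshold proportions,
  and 6×6 category concordance;
- **simulate** — seedable correlated 7-point Likert matrices calibrated so
  the discretized item means hit chosen targets (default: the published
  overall injury-sample profile, means 3.76/3.80/4.32/4.53/3.72);
- **pipeline / `swls` CLI** — wide CSV in → per-group Table-style report
  (JSON + CSV) and Bland–Altman plots out.

## Worked example

```bash
python examples/02_agreement_battery.py
```

generates 20,000 synthetic respondents from the default profile, scores
them both ways and prints:

```
n = 20000
direct mean (SD)    = 20.1 (7.6)
prorated mean (SD)  = 20.5 (7.6)
difference mean (SD) = -0.40 (1.28)
95% limits of agreement: -2.91 to 2.11
Pearson r = 0.99 (very high: True)
ICC(C,1) = 0.99 [excellent]
ICC(A,1) = 0.98 [excellent]
|difference| < 2 points: 84%
|difference| < 3 points: 97%
|difference| < 4 points: 100%
same category: 81%, lower: 6%, higher: 13%, max shift 1
```

The mean difference is negative because the dropped fifth item has the
lowest item mean, so the prorated score runs ~0.4 points above the direct
score — exactly mean(x₅) − mean(Σ₄)/4, an algebraic identity. The limits
of agreement bracket ~95% of individual differences; the very high r and
excellent ICC say individuals are ranked almost identically by the two
scores, and ICC(A,1) < ICC(C,1) reflects the small systematic offset.

Other examples: `01_proration_and_crosswalk.py` (individual/group
proration, crosswalk table), `03_simulation_calibration.py` (latent-mean
calibration), `04_end_to_end_report.py` (grouped pipeline run). The same
capabilities are available from the shell:

```bash
swls simulate --n 600 --seed 7 --out responses.csv
swls report --in responses.csv --out-json report.json --plot ba.png
swls crosswalk --out crosswalk.csv
```

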