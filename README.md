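# weightask

Tools for studying how people talk about their own body weight on Q&A-style
social media, built for researchers in infodemiology and weight-stigma
epidemiology. The package centers on posts of the form *"Am I
\<skinny|thin|fat|obese\>?"* in which the asker also states their age,
gender, height and weight, and on what those askers post later — questions
about health topics, and questions about being bullied — analyzed against
the obesity prevalence and median income of the asker's county.

Because real Q&A archives of this kind are proprietary, the package ships a
fully ground-truthed **synthetic corpus generator**: every asker's true
anthropometrics, inquiry term, county, future postings and bullying posts
are drawn from configurable models, so every stage of the pipeline —
extraction, classification, and all estimators — can be validated against
known truth.

## What it computes

- **Precision-first extraction.** Inquiry terms are matched literally
  (`am I <term>?`, case-insensitive); age, gender, weight and height are
  parsed only from unambiguous unit/keyword contexts (`180 pounds`,
  `5 foot 9`, `15 years old`). A bare `"I weigh 128"` is deliberately not
  parsed: the extractor prefers omission to error. Bullying posts are term
  matched on word boundaries (`bully/bullied/bullying`).
- **Weight classification.** BMI = 703·lb/in². Adults (20+) use the
  standard bands — underweight < 18.5 ≤ normal < 25 ≤ overweight < 30 ≤
  obese (half-open intervals). Teens (13–19) use BMI-for-age percentiles by
  the LMS method, z = ((BMI/M)^L − 1)/(L·S), against a bundled reference
  grid, with bands <5 / 5–85 / 85–95 / 95+.
- **Posting ratios.** For a stratum s (gender × actual weight class ×
  inquired-term class) and category c,
  ratio = P(user in s posts to c) / P(any asker posts to c),
  with a two-sided exact binomial p-value and Benjamini–Hochberg FDR
  control (5%, per-gender families). Ratio > 1 and q ≤ 0.05 marks an
  over-expressed category.
- **Bullying and county analyses.** Per (gender × term) bullying
  fractions with a gender × term interaction test (likelihood-ratio G²);
  the bullying fraction as a curve over county obesity prevalence with a
  quadratic U-shape criterion; the |obesity − mean| exposure transform;
  self-classification accuracy in high- vs low-obesity counties; and the
  direction of the income–bullying gradient (logistic slope plus a
  Cochran–Armitage trend test).

## Worked example

Run the whole pipeline on a synthetic corpus from the shell:

```bash
weightask report --seed 12 --out demo
```

which prints (abridged):

```
retained askers: 658
exclusion accounting:
  term  extracted  excluded  retained
skinny        156       110        46
  thin        404       271       133
   fat       1295       862       433
 obese        145        99        46
 total       2000      1342       658
...
bullying gender x term interaction: G2=1.74 df=3 p=0.628
```

Of 2,000 simulated askers, 658 survive the exclusions (incomplete profile
or multiple inquiry terms) — the same accounting the analytic-sample
builder applies; with no planted effects, no category is over-expressed
and the interaction test is null, as it should be.

With planted effects, the estimators recover them. The preset recovery
study generates 20,000 askers in which overweight/obese men post about
diabetes 4.6× more than baseline, overweight/obese women post about
trying to conceive 3.1× more, and men asking "am I obese?" have a 1.8%
bullying-post probability:

```python
>>> from weightask.studies import run_recovery_study
>>> r = run_recovery_study(seed=1)
>>> round(r["diabetes_ratio"], 2), round(r["diabetes_se"], 2)
(3.58, 0.79)
>>> round(r["conceive_ratio"], 2)
2.97
>>> round(r["male_obese_bullying_pct"], 2)
1.86
```

Each estimate sits within sampling error of its planted value (the ratio
estimator carries an O(f) attenuation from including the stratum in the
pooled denominator; see `docs/methods.md`).

## Layout

| module | contents |
| --- | --- |
| `weightask.synthetic` | corpus generator, dialect rendering, ground truth |
| `weightask.extraction` | inquiry/bullying matchers, profile parser, validation report |
| `weightask.classification` | BMI, adult/teen categories, congruence, sample tables |
| `weightask.posting` | posting ratios, BH-FDR, over-expression screen, bullying tests |
| `weightask.county` | county linkage, bullying curve, accuracy split, income gradient |
| `weightask.pipeline` / `weightask.cli` | stage orchestration and the `weightask` command |
| `weightask.studies` | preset recovery and reference-correlation experiments |
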