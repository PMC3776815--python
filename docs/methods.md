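# Methods

This note documents the models behind `weightask`: what the synthetic
corpus generator emulates, how the estimators are defined, the numerical
conventions, and the design choices made where more than one reasonable
option existed.

## The synthetic asker population

The generator produces, per asker: demographics, anthropometrics, one
weight-inquiry post, optional future posts to topical categories, and an
optional bullying post. It exists because real Q&A archives with
registration zip codes are proprietary; it reproduces the *statistical
structure* the analyses assume, with every quantity knowable, so planted
effects can be recovered and extraction validated exactly.

**Ages** are drawn from a truncated geometric distribution over the
configured range (default 13–59): offset ~ Geometric with mean 4.1 years
above the minimum, giving a teen-heavy population with mean age ≈ 17 —
the age profile typical of askers of these questions. **Gender** is female
with probability 0.65 by default, matching the roughly two-thirds-female
composition of such asker samples.

**Anthropometrics** are lognormal around piecewise-linear median-by-age
curves, separate by gender: height and weight medians at age knots
(13, 14, …, 20, 25, 35, 50, 60), linearly interpolated, with lognormal
standard deviations 0.15 (weight) and 0.035 (height). The default curves
are shaped like US medians (e.g. 16-year-old males ≈ 68 in / 134 lb,
females ≈ 64 in / 118 lb). Because the sample median of a lognormal is the
configured median, median reported weight per age tracks the reference
curve by construction — the property the reference-correlation study
measures. Zero dispersion returns the medians exactly.

**Inquiry terms** (skinny / thin / fat / obese) are drawn from per-(gender,
actual-weight-class) distributions whose defaults mirror a real asker
population: "fat" dominates everywhere, and normal-weight women ask "fat"
far more often than their BMI warrants. An optional *congruence shift*
multiplies the odds of the congruent term in counties above the median
obesity prevalence, which lets county-accuracy effects be planted.

**Rendering.** Each of the four fields is independently omitted with a
per-field probability; a rendered field uses an ambiguous dialect with
probability `ambiguity_rate`, otherwise a random unambiguous dialect from
the inventory in `data/dialects.yaml` (e.g. weight: `"I weigh 180 pounds"`
vs the ambiguous `"I weigh 180"`). Default omission rates (age 0.23,
weight 0.295, height 0.135, gender 0.11) reproduce the omission profile of
a 200-question manual validation of a precision-first extractor; the
default ambiguity rate is 0.05. Rendered values are integers (people post
"180 pounds", not "180.4"), and ground truth stores the rendered values so
round-trips are exact.

**Future posts.** For category c with baseline rate b_c (defaults: 14
topical categories at 0.01 each), an asker in stratum s posts with
probability clamp(b_c · m(s,c), 0, 1), where the multiplier m comes from
the planted effect table (default 1; entries may match on any subset of
gender / actual class / term class; multiple matches multiply; a
probability pushed above 1 is clamped with a warning). Timestamps are
uniform in (t0, t0 + 365 d). The one-year horizon is a modeling choice —
"later" is all the analyses require.

**Bullying posts** occur with a per-(gender × term) base probability
(defaults: male-obese 1.8%, male-fat 0.6%, other males 1.2%, females
2.4%), optionally modulated by county: a U-shape factor
1 + strength·z², z the county's standardized obesity prevalence, and/or an
income factor exp(coef · income/$10k centered). Each bullying post carries
a latent "genuinely bullied" flag drawn at 0.68, emulating the yield of
manual annotation of term-matched bullying posts; the term matcher alone
intentionally admits such false positives.

**Counties** are synthetic: 40 counties spanning 15–45% obesity prevalence
with median income declining from ≈ $65k to ≈ $35k (plus a deterministic
ripple so income is not a function of obesity alone), one zip code each,
uniform assignment. No real geography is implied.

What the generator does *not* emulate: answer posts and voting, multiple
weight questions per user, free-text beyond the dialect inventory
(misspellings, slang, non-English), correlation between omission and asker
characteristics, and within-county heterogeneity. Passing tests therefore
show that the *estimators* behave correctly under the assumed structure,
not that the extractor would reach the same precision on arbitrary wild
text.

## Extraction

All rules are explicit regular expressions; nothing is learned. A field
is populated only when a number appears with an explicit unit or keyword:
weights need `lb(s)/pound(s)` or `kg` (converted at 1 kg = 2.20462 lb),
heights need feet-and-inches forms or explicit `cm` (1 in = 2.54 cm) —
bare numbers are never heights — and ages need `years old` (or a guarded
`I am N` with no measurement context following). Gender uses explicit
tokens only (male/man/boy/guy, female/woman/girl); conflicting tokens
yield omission. Values outside plausibility bounds (age 13–99, weight
50–700 lb, height 36–90 in) are discarded. Terms like "normal weight" or
"overweight" are not in the inquiry vocabulary. The dialect fixture is a
reconstruction of how such statements are actually written, and is
versioned so the inventory can grow without touching code.

## Classification conventions

- Half-open bands everywhere: BMI 25.0 is overweight, 30.0 obese, 18.5
  normal; percentile 85 falls in 85–95. Verbal band descriptions overlap
  at the edges ("18.5 to 25", "25 to 30"), so a convention had to be
  fixed; half-open intervals are the partition-preserving choice.
- Teen/adult boundary at 19/20: ages 13–19 are classified by BMI-for-age
  percentile, 20+ by adult thresholds. Sources differ on whether the
  percentile rule should apply under 18 or under 20; the 13–19 convention
  matches the reference sample table this package reproduces and is the
  default.
- Integer ages are converted to months as 12·y + 6 (mid-year), since
  posts state whole years.
- The LMS grid (`lms_reference_synthetic.csv`) is a synthetic smooth
  CDC-style reference: both sexes, 156–240 months at 6-month knots, M
  rising from ≈ 18.5 to ≈ 22.7 (boys) and ≈ 18.9 to ≈ 21.7 (girls), L ≈ −2,
  S ≈ 0.13. L, M, S are linearly interpolated in age. The percentile is
  Φ(z)·100 with z = ((BMI/M)^L − 1)/(L·S) (log form at L = 0); tests
  verify agreement with numerical inversion of the quantile function to
  0.1 percentile points.
- Congruence: by default {fat, obese} agree with overweight-or-obese
  (adult BMI ≥ 25, teen percentile ≥ 85) and {skinny, thin} with the
  complement. Any such mapping is a convention, so it is a parameter; no
  published accuracy figure is asserted for it.

## Posting-ratio estimator

The unit of analysis is the user: k counts users with ≥ 1 post to the
category, not posts, which removes heavy-poster bias. The pooled
denominator is *all* retained askers, including the stratum itself —
the literal reading of "the entire population of askers". Consequence: a
planted multiplier m on a stratum holding fraction f of askers is
estimated consistently as m/(1 + f(m − 1)), not m; the bias is O(f) and
vanishes for small strata. The preset recovery study keeps planted strata
near 3% of the population, making the attenuation (≈ 0.3 on a ratio of
4.6) small against the sampling error of the estimate at n = 20,000
(standard error ≈ 0.8).

Significance per (stratum, category) is a two-sided exact binomial test
of k_s given n_s against the pooled rate — chosen for validity at small
counts; since the pooled rate is itself estimated, p-values are mildly
conservative for large strata. q-values are Benjamini–Hochberg, adjusted
within each gender's family of tests by default (matching how such
results are reported per gender); a pooled family is a config option.
Over-expression = significant at q ≤ 0.05 and ratio > 1.

The gender × term bullying interaction is tested as heterogeneity of term
effects across genders: the residual deviance (G²) of the additive
logit(bullying) ~ gender + term model against the saturated model,
df = (terms − 1); with expected cell counts below 1 a warning is issued.

## County analyses

Counties carry a single exposure, percent obese, plus median income.
The bullying curve uses 10 equal-width bins over the observed prevalence
range (configurable, ≥ 3); empty bins yield an absent fraction; the curve
is also partitioned by inquired-term class (low = skinny/thin,
high = fat/obese), and the partition sums to the overall curve exactly.
U-shape detection is a weighted quadratic fit on bin midpoints with
positive curvature as the criterion — "bimodal" is a verbal description,
and curvature is the simplest falsifiable version of it. The
absolute-deviation transform is |x − mean(x)| with the *sample* mean over
counties (a national reference mean would be equally defensible; the
sample mean keeps the package self-contained). High/low county splits use
the median prevalence by default (mean available). The income association
is summarized as the sign of a logistic slope (per $10k) plus a
Cochran–Armitage trend test over income quartiles; a single-valued income
is reported as not evaluable. Duplicate zips in the linkage map keep the
first entry, deterministically, with a warning.

## Reproducibility and problem sizes

All randomness in a run flows from one integer seed through a single
`numpy` Generator; identical seed and config give byte-identical JSONL
output (fixed sort orders, fixed float formatting). The preset studies use
20,000 askers (effect recovery, the size at which ±3 SE brackets the
planted values comfortably) and 5,000 askers over ages 13–20 (reference
correlation, R² ≈ 0.95–0.99 against a floor of 0.88). Simulation-based
tests of error control use records-level replicates (100 null replicates
of a 2,000-user screen for FDR control; 10 replicates each for power,
U-shape and income-direction recovery) — sizes chosen to make the checks
sharp while keeping the suite quick to run.

## Known limitations

- The extractor is English-only, rule-based, and will omit any dialect
  outside its inventory; its measured error rate (~0) on synthetic text is
  a property of the shared inventory, a lower bound on real-text error.
- The posting-ratio attenuation above means very large strata (f ≳ 10%)
  are materially biased toward 1; use small strata or interpret
  accordingly.
- Ecological associations (county obesity, income) are descriptive;
  nothing here supports causal claims, and the generator's counties are
  synthetic ids, not real places.
- The bullying "annotation" is a Bernoulli stand-in for human labeling;
  it models the yield, not the content, of manual review.
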