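# prorich

A reusable, tested pipeline for studying **implicit pro-rich bias**: how
quickly people associate *rich* vs *poor* with *good* vs *bad* on the
Implicit Association Test (IAT), and how that bias varies with the
perceiver's gender, income and education.

The package is aimed at researchers working with trial-level IAT data of
the Project Implicit style (seven blocks: category introductions, 20-trial
dual-categorization practice blocks, 40-trial critical blocks,
counterbalanced key mappings). It implements the full analysis chain:

1. **D scoring** (`prorich.scoring`) — the improved scoring algorithm:
   drop trials over 10 000 ms, pool latency SDs over the practice pair
   (blocks 3/6) and critical pair (4/7) *before* error replacement,
   replace each error latency with its block's correct-trial mean + 600 ms,
   and average the two (incompatible − compatible)/SD quotients:

   D = ½ · [ (M₆ − M₃)/S₃₆ + (M₇ − M₄)/S₄₇ ]

   Positive D = faster when *rich* shares a key with *good* (pro-rich bias).
   Signs follow pairing roles, so block-order counterbalancing cancels.
2. **Exclusion cascade** (`prorich.exclusions`) — duplicate-ID removal
   (earliest record kept), eight inclusive careless-responding criteria
   (fast-response, error-rate and over-10 s thresholds on practice and
   critical blocks, evaluated as exact rationals), then ordered
   demographic-completeness exclusions (income → education → gender),
   with a full audit log.
3. **Explicit measures** (`prorich.measures`) — fourteen self-report
   measures as rich-minus-poor difference scores (reverse-coding where
   required), including the ambivalence index
   `min(pos, neg) / (6 + max(pos, neg) − min(pos, neg))`, plus one-sample
   t-tests and Pearson correlations with D.
4. **Moderated regression** (`prorich.regression`) — OLS of standardized D
   on gender (women = −0.5, men = +0.5), z-scored income and education and
   all interactions; VIF diagnostics with an orthogonalization
   contingency; simple slopes at ±1.5 SD as linear combinations of the
   coefficients, c′b with se = √(c′Σc).
5. **Power engine** (`prorich.power`) — Monte-Carlo power for every
   coefficient and simple-effect contrast, plus shrink-factor sensitivity
   curves (smallest effect detectable with ≥80% power).
6. **Synthetic cohort generator** (`prorich.cohort`) — trial-level data
   with the study's structure: lognormal latencies encoding a target D,
   a 115:60 women:men ratio, 5-point income/education with observed
   correlation 0.22 (latent bivariate normal, attenuation-corrected),
   item-level explicit ratings, and named careless archetypes so every
   exclusion criterion has a fixture. No downloads required.

## Worked example

Run the whole chain on a synthetic cohort of 274 participants with
realistic carelessness and missingness:

```python
from prorich import config as cfg
from prorich.pipeline import run_pipeline

c = dict(cfg.DEFAULT_CONFIG, seed=42, n_participants=274, residual_sd=0.35,
         careless_rate=0.17, missing_income_rate=0.18,
         missing_education_rate=0.015, n_reps=1000, power_n=1000)
run_pipeline(c, "out")
```

`out/exclusion_summary.csv` mirrors the study-style accounting — of 274
entering, 41 trip a careless-responding criterion, 41 are missing income
and 2 education, leaving 190 for analysis:

```
            stage   n
            input 274
     duplicate_id   0
     iat_criteria  41
   missing_income  41
missing_education   2
   missing_gender   0
         retained 190
```

`out/model.csv` holds the omnibus fit on standardized D (b, se, t, p, VIF
per term). At n = 190 the generator's Gender × Income effect is recovered
as significant (b = 0.298, t = 2.06, p = 0.041; all VIF < 1.3), and
`out/power_report.json` gives the Monte-Carlo power of each test under
the generating model, e.g.:

```
gender_x_income           power=1.000  mc_se=0.000
income_slope_men          power=1.000  mc_se=0.000
income_slope_women        power=0.449  mc_se=0.016
```

i.e. at n = 1000 per simulated dataset the Gender × Income interaction and
the men's income slope are detected essentially always, while the small
negative income slope among women is detected in ~45% of replicates.

The same stages are available from the shell:

```bash
prorich simulate --seed 42 --outdir out
prorich score    --trials out/trials.csv --outdir out
prorich exclude  --trials out/trials.csv --demographics out/demographics.csv --outdir out
prorich regress  --demographics out/demographics.csv --scores out/scores.csv --outdir out
prorich power    --seed 42 --reps 1000 --n 1000 --outdir out
prorich all      --seed 42 --outdir out
```

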