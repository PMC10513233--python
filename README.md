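# sedbouts

Analysis of sedentary behaviour from daytime wrist actigraphy, built for
case-control comparisons such as adults with acute insomnia (AI) versus
healthy controls (HC).

Wrist-worn actigraphs integrate movement into *activity counts* per
one-minute epoch. Following the standard Freedson cut-point, an epoch
with fewer than 100 counts per minute (cpm) is *sedentary*; a *sedentary
bout* is a maximal run of consecutive sedentary epochs. The package
turns per-subject epoch recordings into interpretable bout features and
group statistics:

- **Preprocessing** — moving-median imputation of missing epochs
  (centered 30-minute window) and carving of each recording into
  complete daytime days of exactly 840 one-minute epochs
  (08:00–22:00 wall clock).
- **Bout features** — per-day time and bout counts in five duration
  bins (1–3, 4–5, 6–30, 31–60, >60 minutes), total sedentary time
  `sed_total`, total active time `wake_total` (`sed_total + wake_total
  = 840` on complete days), and 2-hour aggregates; per-subject averages
  over all seven days, weekdays, or the weekend.
- **Exponential bout-time model** — bout-time samples are modelled as
  exponential, `f(x|λ) = λ e^{-λx}` (mean = sd = 1/λ); the mean is
  estimated by the sample mean with an exact chi-square pivot 95% CI,
  `[2n m̂ / χ²_{0.975, 2n}, 2n m̂ / χ²_{0.025, 2n}]`.
- **Two-sample Kolmogorov–Smirnov test** — `D = sup_x |F_X(x) −
  F_Y(x)|` on the empirical CDFs, with the exact permutation p-value
  (lattice-path counting) for small tie-free samples and the
  asymptotic Kolmogorov distribution at `λ = D√(n₁n₂/(n₁+n₂))`
  otherwise.
- **Logistic regression** — `ln(p/(1−p)) = β₀ + Σ βⱼ xⱼ` of the group
  label (1 = healthy) on the five bout-bin features, fitted by IRLS
  with Wald standard errors and p-values; negative slopes mean longer
  sedentary bouts lower the odds of the healthy label.
- **Synthetic cohorts** — an alternating sedentary/active renewal
  process with exponential dwell times and state-conditional count
  distributions generates realistic cohorts (default 15 AI + 22 HC
  subjects, 7 days each, ~1% missing epochs) with known ground-truth
  segmentation, so the full pipeline is testable without any recording.

## Worked example

Generate a synthetic cohort and run the full pipeline:

```sh
sedbouts synth --out demo/data --seed 1
sedbouts run --manifest demo/data/manifest.csv --out demo/out
```

`demo/out/report.txt` then contains (excerpt):

```
Group comparison [all7] (minutes/day, 95% bounds)
  sed_bouts_1_3    AI 31.21 [19.93, 55.76]   HC 37.59 [25.76, 59.98]   D 0.39  p 0.1255
  ...
  sed_total        AI 528.05 [337.20, 943.46]   HC 473.06 [324.21, 754.86]   D 0.59  p 0.0020

Logistic regression (label 1 = healthy control)
  Intercept        beta 9.851  SE 7.168  p 0.1694
  sed_bouts_1_3    beta -0.073  SE 0.098  p 0.4566
  sed_bouts_4_5    beta 0.002  SE 0.084  p 0.9813
  sed_bouts_6_30   beta -0.012  SE 0.013  p 0.3832
  sed_bouts_31_60  beta -0.053  SE 0.025  p 0.0375
  sed_bouts_gt60   beta 0.053  SE 0.070  p 0.4449
```

Reading this: the simulated AI group averages 528 sedentary minutes per
daytime day against 473 for HC, with the bracketed exponential-model 95%
bounds on each mean; the K-S test on the per-subject `sed_total` values
gives D = 0.59, p = 0.002, so the two groups' distributions differ. In
the logistic table a negative `beta` means more minutes in that bout bin
lower the probability of being labelled healthy.

Machine-readable CSVs (`features.csv`, `comparison_*.csv`,
`logistic.csv`, `two_hour.csv`, `daily.csv`) are written alongside at
full precision, and `sedbouts report --features demo/out/features.csv
--out demo/report2` recomputes every report from the feature table
alone.

The same analysis is available as a library:

```python
from sedbouts import simulate_cohort
from sedbouts.pipeline import analyze_cohort

bundle = analyze_cohort(simulate_cohort(rng_seed=1))
print(bundle.comparisons["all7"])
```

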