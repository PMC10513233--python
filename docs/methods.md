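# Methods

## Data model

A recording is a per-minute series of non-negative activity counts
(cpm) with wall-clock timestamps at strict 60-second spacing; missing
epochs are explicit. The canonical interchange format is a two-column
CSV (`timestamp`, `count`; empty count = missing) plus a manifest CSV
(`subject_id,group,age,sex,file`). Cohort inclusion filters on age with
inclusive bounds (default 20–40 years); the bounds are parameters so
other windows are reproducible.

## Preprocessing

**Imputation.** Missing epochs (typically ~1% of a series) are filled
with the median of the observed values in a centered window of
`window_minutes` epochs (default 30), truncated at the series edges.
Only missing epochs are altered — the filter never smooths observed
data — and medians are taken over original observed values, never over
earlier fills. If a window contains no observed value, the nearest
observed value is used (earlier one on ties), which keeps the operation
total at realistic missingness. Centering was chosen over a trailing
window to avoid phase lag; both the window length and the daytime
window are configurable. Imputation runs on the full recording before
daytime carving so epochs near 08:00 can borrow pre-08:00 neighbours.

**Daytime carving.** Each calendar date whose half-open window
[08:00, 22:00) is fully covered yields one `DaytimeDay` of exactly
840 epochs; partial days are dropped and logged. The half-open
convention gives an unambiguous 840-minute day (14 h x 60). Weekend =
Saturday or Sunday by ISO weekday.

## Bout features

An epoch is sedentary iff `count < threshold` (default 100 cpm,
strict); `wake_total` counts epochs with `count >= threshold`. Bouts
are maximal same-state runs; day-boundary bouts keep their observed
(truncated) duration rather than being discarded, so the five-bin
decomposition sums exactly to `sed_total` and
`sed_total + wake_total = 840` on every complete day. Bins are
inclusive integer ranges 1–3, 4–5, 6–30, 31–60 and 61+; with 1-minute
epochs every duration falls in exactly one bin. No minimum bout length
or interruption allowance is applied: a bout is an uninterrupted run.

The day is tiled by seven 2-hour slots ([08–10), ..., [20–22)), each
epoch assigned by its start time. Per slot we report sedentary/active
minutes and the mean cpm of the epochs in that state; a slot with no
epochs of a state has an undefined mean, which is excluded from
cross-day averages.

Per-subject features are per-day arithmetic means over a day subset
(all seven days, the five weekdays, or the two weekend days).
Descriptive count statistics (mean/sd overall and conditional on the
100-cpm split) pool all epochs of the subset's days; sds use ddof=1.

## Exponential bout-time model

Bout-time samples are modelled as exponential, `f(x|lam) = lam *
exp(-lam x)` for x > 0, with mean = sd = 1/lam. The mean is estimated
by the sample mean (the MLE) and its two-sided 95% interval uses the
exact pivot `2 n m / mean ~ chi2(2n)`, giving
`[2 n m / chi2_{0.975,2n}, 2 n m / chi2_{0.025,2n}]`. The pivot is
exact for exponential data at any n, unlike a normal approximation.
The default statistical unit is the per-subject average (n = subjects
per group); `ks_granularity: subject-day` switches every comparison to
per-subject-day values. (The asymmetric bounds in published
cohort tables of this kind are numerically consistent with the pivot
applied at person-day counts, so both granularities are first-class.)
A feature sample containing zeros (a subject with no bouts in a bin)
is outside the exponential support; the report then shows the
arithmetic mean with undefined bounds and logs a note rather than
silently dropping zeros.

## Two-sample Kolmogorov-Smirnov test

`D` is the supremum distance between the two right-continuous ECDFs,
evaluated on the pooled sample and computed on the integer lattice
`|i*n2 - j*n1|/(n1*n2)` so that exact-null comparisons are free of
floating-point rounding. For tie-free samples with `n1*n2 <= 10^4` the
p-value is exact: the permutation null of D is obtained by counting
monotone lattice paths that stay inside the band `|i*n2 - j*n1| < g`,
each path being one equally likely interleaving of the pooled order
statistics. Larger or tied samples use the asymptotic Kolmogorov
distribution at `lam = D * sqrt(n1 n2/(n1+n2))`, evaluated with the
alternating series for large lam and the Jacobi-theta dual series for
small lam. The exact branch reproduces an independent implementation
to machine precision, and the measured type-I error at the study
sample sizes (15 vs 22) over 2,000 null replicates is 0.049. The
widely used Stephens small-sample adjustment of lam was evaluated and
rejected: at n1=n2=10, D=0.5 it gives p=0.111 against an exact
permutation value of 0.168, while the exact branch is, by
construction, error-free there.

## Logistic regression

Group label (0 = AI, 1 = HC) is regressed on the five bout-bin
features in raw minutes/day, no interactions, no regularization, no
standardization. Fitting is maximum likelihood by iteratively
reweighted least squares with step-halving onto a likelihood-increasing
path; convergence when the largest absolute coefficient change falls
below 1e-8 (cap 100 iterations). Standard errors come from the inverse
observed information at the optimum and p-values are two-sided Wald
tests. Perfect separation is detected (diverging coefficient norm or
all labels perfectly predicted) and reported as a non-converged fit
with the last iterate, never silently clipped.

## Synthetic cohort generator

Each subject alternates between sedentary and active states with
independent exponential dwell times, rounded up to whole minutes
(minimum one epoch, matching the device's 1-minute integration). The
long-run sedentary occupancy is `E[ceil(S)]/(E[ceil(S)] + E[ceil(A)])`
with `E[ceil(Exp(m))] = 1/(1 - exp(-1/m))`. Counts are drawn per state
from discretized gamma distributions clipped to the state's support —
sedentary on [0, 100), active on [100, 1500] — so threshold
classification recovers the simulated segmentation exactly; active
intensity is modulated by a cosine diurnal profile (amplitude 0.3)
peaking at a group-specific hour (19:00 AI, 15:00 HC, reflecting the
observation that insomnia cohorts peak in the evening and controls in
mid-afternoon). Missing epochs are injected uniformly at 1%.

Default presets (dwell means in minutes): AI sedentary 10.0 / active
5.272; HC sedentary 7.5 / active 6.074. The active means were solved
from the occupancy identity so that expected `sed_total` lands near
540 (AI) and 460 (HC) minutes/day, and the sedentary means were chosen
so the cohort-level outputs reproduce the qualitative case-control
ordering (AI above HC on the 6–30, 31–60 and >60 bins and `sed_total`;
HC above AI on the 1–3 bin and `wake_total`). This is a calibration of
the generator's contrast structure, not a claim of numeric reproduction
of any real cohort. State-conditional count levels (AI 19.3/333 cpm,
HC 23.5/355 cpm) give overall mean counts near the levels typical of
such cohorts. Subjects perturb their group's dwell means by independent
log-normal multipliers (sd 0.2, a repository choice — real
between-subject variability figures are not available); subject streams
are spawned from a single seed, so cohorts are bit-reproducible and
subjects independent. Recording weeks start on a Monday (5 weekdays +
2 weekend days); ages are uniform on [20, 40].

**What the generator does not emulate.** Real bout-duration
distributions are overdispersed relative to a single exponential: an
actual cohort accumulates substantial time in *both* the 1–3 and >60
bins, whereas a single-exponential dwell law concentrates bout time
around one scale. Consequently the synthetic bin *profile* is narrower
than real data even though the group *orderings* are right. A second
consequence is that a subject's five bin features are a smooth function
of essentially two latent quantities (dwell scale and occupancy), so
across subjects the features are near-collinear; at the default cohort
size (15 + 22) a logistic regression on them has sign-unstable
coefficients even though the population-level coefficient signs (fitted
on very large synthetic cohorts) are negative on the three long bins
and near zero on the short bins. Passing pipeline tests on this
generator therefore demonstrate correctness of the bout accounting and
the statistical machinery, not that a 37-subject logistic fit on real
data would be stable. Nighttime behaviour, non-wear, device noise and
physiological waveforms are out of scope.

## Numerical and reporting choices

- Machine CSVs are written with `%.17g` (bit round-trippable floats);
  display rendering rounds to 2 decimals and prints p-values below
  1e-4 in scientific notation.
- Reports are fully recomputable from the per-subject feature CSV;
  identical config + inputs give byte-identical machine outputs.
- Degenerate inputs: all-missing series, empty day subsets,
  single-class labels and non-positive exponential samples raise
  explicit errors; malformed subject files are skipped with a logged
  warning and the run continues.
- Problem sizes used in the test suite (e.g. 500 simulated days for
  the generator round-trip, 1,000 random masks for the extraction
  oracle, 2,000 null replicates for K-S calibration, 100 seeded
  cohorts for sign-structure checks) were chosen to make the Monte
  Carlo error small relative to the asserted bands.
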