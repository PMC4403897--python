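# Methods

## Signal model and feature extraction

A trial is a gauge-pressure waveform P(t) in mmHg, sampled nominally at
100 Hz (10 ms period; traces whose median inter-sample gap deviates more than
20% from the nominal period are rejected). The analysis threshold is
100 mmHg: pressures below it are treated as probing artifacts or rest and are
excluded from analysis.

**Segmentation.** Supra-threshold segments are maximal runs of samples with
P > 100 strictly; a sample exactly at 100 mmHg is a crossing point, not a
member ("rises above" is read strictly). Crossing times t_rise and t_fall are
linearly interpolated between the bracketing samples, which removes the
±10 ms quantisation a sample-index rule would impose; when a trace starts or
ends above threshold the trace endpoint is used. Single-sample runs are
retained.

**Parameters.** pmax is the maximum sample over the whole trial. t100 is
t_fall − t_rise of the *analysis segment* — the segment with the largest
pressure–time product, ties broken by earliest t_rise (a recording is one
cued effort; brief noise dips below threshold split it, and the dominant
segment is the effort). Pt100 is the trapezoidal integral of the *absolute*
pressure (area down to zero, not the excess over threshold) from t_rise to
t_fall, with the interpolated crossing points (pressure = threshold)
contributing the boundary slivers. Under this reading
`100·t100 ≤ Pt100 ≤ pmax·t100` holds on every extracted segment, and the
trapezoid rule is exact on the piecewise-linear interpolant, hence invariant
under sample refinement (checked to 1e-9) and within 0.5% of a 1000 Hz
Riemann oracle on smooth plateaus.

Pt100 is reported in mmHg·s (a pressure–time product; the per-second unit
sometimes seen in print is dimensionally inconsistent with an area under a
pressure–time curve).

**Aggregation.** Per participant and task, trial features are combined by
element-wise maximum (strength-testing convention: the personal best) by
default; arithmetic mean is available, and the rule used is recorded in the
output. A participant is retained while at least one valid trial per task
remains; if all trials are excluded the participant is missing for that task.

## Synthetic cohorts

The generator emulates the two tasks at the population parameters of a
published normative pilot cohort; its defaults are the study conditions, not
tuning knobs.

- **Latent peaks** (personal bests) are bivariate normal across the two
  tasks with correlation 0.7 (the same tongue produces both; no joint
  information is published, so the correlation is a configurable design
  choice): strength 573.74 ± 143.11 mmHg (males) and 488.24 ± 108.96
  (females); endurance peaks 556.20 ± 138.33 and 539.80 ± 149.83. Peaks
  below a 150 mmHg physiological floor are redrawn (probability ~1e-3 at
  these parameters).
- **Endurance durations** are lognormal, `μ = log(median)` and
  `σ = log(Q3/Q1)/(2·z₀.₇₅)` solved from the published median and IQR
  (males 10.25 s, IQR 7.96–16.80; females 13.15 s, IQR 9.89–20.50). The
  two-parameter family matches the median exactly and the quartile ratio;
  it cannot match both quartiles individually.
- **ITS shape**: half-cosine rise (0.5 s), hold near the peak for
  3.0 ± 0.3 s (the cued three-second push), Gaussian plateau noise
  (SD 5 mmHg), half-cosine release; 0.5 s lead-in baseline.
- **ITE shape**: linear rise, then a linearly fatiguing plateau whose decay
  rate is solved so the pressure first drops below 100 mmHg exactly
  `endurance` seconds after it first rose above it (so extracted t100 equals
  the configured endurance to within two sample periods at zero noise, and a
  noiseless trace has exactly one supra-threshold segment), then a rapid
  release. Linear decay is the simplest shape consistent with a single-dip
  endurance morphology. A zero-fatigue constant plateau with a forced cut is
  available for rectangle-limit checks.
- **Trials**: two per task; one realises the latent personal best, the
  others fall short by a uniform fraction up to 10%. Each generated trace is
  rescaled so its sample maximum equals the drawn peak — the configured
  distributions therefore describe *achieved maxima*, which is what summary
  tables of strength studies report, and max-aggregation recovers the latent
  exactly. Samples are clipped to [0, 1500] mmHg; the upper clamp is a
  generous device span, deliberately above the 0–300 mmHg calibration-check
  range since observed pressures reach ~650 mmHg.
- **Artifacts**: with probability 0.1 a trial receives a sub-threshold
  probing blip (< 0.3 s, peak < 100 mmHg) on the lead-in baseline; features
  are unchanged by construction, which the suite verifies pairwise.
- **Ages** are uniform on 18–40 years and have no effect on generated
  pressures by default (no age coefficient is published); the age-adjusted
  ANOVA therefore estimates a null covariate on synthetic data.

What the generator does *not* emulate: baseline drift, sensor saturation,
swallowing events mid-trial, learning/fatigue across trials, or any real
age–pressure relationship. Passing tests show the pipeline's arithmetic and
statistics are correct under the stated waveform model, not that the model
captures every feature of clinical recordings.

## Calibration

Readback vs reference pairs (≥ 3 points, reference within 0–300 mmHg) are
fitted by ordinary least squares, `readback = slope·reference + intercept`.
The pass gate compares the maximum absolute residual over the sensor's
specified accuracy range (0–225 mmHg) to a tolerance defaulting to the
stated ~1 mmHg accuracy; no published pass rule exists, so a residual-based
gate was chosen because fitting both slope and intercept separates gain from
offset drift, either of which a between-session comparison (max predicted
disagreement over a 1 mmHg grid, default) will flag.

## Cohort statistics

- **Screening**: skewness, excess kurtosis (both bias-corrected) and
  Shapiro–Wilk at α = 0.05. The routing is advisory — parametric and
  rank-based descriptive blocks are always both computed, the screen decides
  which is headlined.
- **Descriptives**: mean, SD (n−1), t-based 95% CI; median and quartiles by
  linear interpolation between order statistics (no quantile rule is
  published; this is the common default).
- **Gender comparisons**: pooled-variance independent-samples t-test by
  default (this is the variant consistent with the published p-values;
  Welch by flag), two-sided; from raw data or from summary statistics. Zero
  variance with equal means returns p = 1 by convention. The age-adjusted
  model is OLS `value ~ gender + age` with a type-II partial F for gender,
  plus the observed power of that term at the estimated noncentrality
  (λ = F·df₁), the convention of classical ANOVA software. A Mann–Whitney U
  accompanies every comparison as the nonparametric route. No
  multiple-testing correction is applied across the four outcomes (matching
  the workflow being reproduced); reports carry the number of tests run.
- **Reliability**: ICC(A,1) — two-way random effects, absolute agreement,
  single measure — from the mean-squares decomposition
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`, the standard reading of
  "ICC agreement"; ≥ 0.75 is reported as good. Cross-checked against an
  independent implementation in the test suite.
- **Power**: exact noncentral-t. Sample size is the smallest integer n (from
  2 upwards) whose power reaches the target — the increment search, rather
  than a normal approximation, is what reproduces 51/group (90%) and
  39/group (80%) at Δ = 85.5, σ = 131.54, α = 0.05.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` seeded from the
  cohort/run config; identical config + seed reproduces cohorts, feature
  tables and statistics byte-for-byte.
- Problem sizes in the test suite (e.g. 2,000 per gender for parameter
  recovery, 500 subjects for ICC recovery, 100,000 Monte-Carlo power
  replicates) are chosen so Monte-Carlo error is small against the asserted
  tolerances while the full suite stays fast on a laptop.
- Degenerate inputs: constant descriptive vectors collapse the CI to the
  point (skewness/kurtosis reported as 0); zero-width segments integrate to
  0; an endurance so short the threshold would be re-crossed during the rise
  is rejected as infeasible.

## Known limitations

- The trial-aggregation rule (max) and the strength–endurance correlation
  (0.7) are conventions, not published facts; both are configurable.
- The ITE stop rule treats *any* drop below 100 mmHg as segment-ending; no
  quantitative definition of a "significant dip" is published.
- The published reliability coefficients (ICC 0.861 strength / 0.687
  endurance) and the age-adjusted ANOVA's p = 0.09 / 39.7% observed power
  derive from unpublished raw recordings and cannot be recomputed here; the
  suite instead verifies the estimators on simulated data with known ground
  truth.
- ITS traces are analysed as recorded; the three-second instruction is not
  enforced by truncation.
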