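# Methods

This note documents the models implemented in `titrate`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that affect results.

## Data model and binning

A session is a long-format event log (one CSV row per event) keyed by
subject, session and trial. All times are seconds relative to the cue
(tone) onset of their trial; inter-trial events (foot-shocks) are logged
with negative times on the following trial. This cue-relative origin is
used because every analysis here is cue-relative.

Time bins are half-open, 0-based: bin k covers [k·w, (k+1)·w). A press at
exactly t = k·w falls in bin k. The convention is arbitrary but fixed;
edge presses are rare in continuous data but the choice matters for
constructed fixtures. Presses before cue onset or at/after the analysis
window are excluded from binning. Only probe trials enter timing analyses;
FI trials are retained in logs but skipped.

Bisection lever identity is stored semantically ("short"/"long" lever),
not physically (left/right); counterbalanced physical assignment is
irrelevant to analysis. Bisection response latency is stored as measured
from cue offset (lever presentation); for FI/probe trials latency is from
cue onset. The package stores latency as given and never recomputes it
from assumptions about lever-insertion hardware timing.

## Pseudologistic psychometric model

p(long | t) = 1 / (1 + exp(−π (t − T50) / (√3 · σ(t)))), with
σ(t) = γ·t by default. Evaluating the timing noise at the probe duration
makes γ proportional to the Weber fraction (scalar variability); a config
switch (`sigma_at="t50"`) instead uses σ = γ·T50, reducing the model to an
ordinary logistic — both variants exist in the source literature and the
choice only matters away from T50. Constant and Poisson variance
components are fixed at zero (negligible in well-trained adult subjects);
no lapse-rate or bias terms are modelled.

Fitting: default objective is unweighted least squares on the per-duration
p(long) proportions (the semantics of common curve-fitting software, and
what the reported R² refers to); binomial maximum likelihood on the
per-duration counts is available (`objective="ml"`), as is weighting by
responded-trial count (`weighted=True`) since anchors carry ~5-10× the
trials of intermediates. R² = 1 − SSE/SST over the per-duration
proportions in every case. Initialization: T50 at the geometric mean of
the duration range, γ = 0.3; bounds T50 ∈ (min, max duration),
γ ∈ (10⁻³, 2) — a bounded start prevents degenerate optima on adversarial
inputs (e.g. reversed-lever data). Durations with zero responded trials
are excluded from the fit, not imputed. Fits are flagged unusable when
R² ≤ 0.5 (inclusive at the bound) or when the optimizer fails; unusable
fits still report their parameters, never silently.

A known property of the default estimator: with ~12-24 trials per
intermediate duration, least squares on proportions carries a modest
downward small-sample bias in γ (of order 5-10 % at the default design).
The ML objective reduces it; the default is kept for comparability with
standard practice.

## Gaussian + ramp (molar peak fit)

R(t) = a·exp(−½((t − t0)/b)²) + c·(t − t0) + d, fit by bounded
least squares to the 2-s-binned block-average curve in presses/s. Reported
peak time is the Gaussian center t0, not the argmax of the composite
function (width = 2b is read from the Gaussian component, so peak
parameters are too; the argmax readout is exposed as
`PeakFitResult.argmax_time_s`). Peak rate is R(t0) = a + d.
Initialization: t0 at the curve argmax, b = 10 s, d at the minimum rate,
c = 0, a = max − min; bounds keep t0 within the probe window and
b ∈ (0.5, 90) s. A perfectly flat curve is degenerate and is returned with
`converged=False`. Rates are fit in presses/s (this scales a, c, d but not
t0 or b).

## Three-state single-trial model

Each 1-s-binned probe trial is segmented into three piecewise-constant
states (low-high-low) by exhaustive search over all change-point pairs
(s, e) — the high state spanning bins s..e inclusive — subject to minimum
durations: high ≥ 4 s, each low ≥ 1 s. Each state's rate is its segment
mean. The default objective minimizes the residual sum of squares of the
piecewise-constant rate model; the classic duration-weighted
rate-difference index t1(r−r1) + t2(r2−r) + t3(r−r3) is available
(`objective="index"`) for sensitivity analysis, since the historical
custom programs differ and the choice cannot be settled from published
descriptions.

Start and stop are reported as the left edges (seconds, 0-based) of the
first and last high-state bins, so spread = stop − start equals
(number of high bins − 1) seconds; this follows the literal reading of
"first and last bins of the high-rate state". Ties in the objective are
broken toward the earliest start, then earliest stop. Numerically, scores
within 10⁻⁹ of the optimum are treated as tied: with integer counts,
mathematically identical segmentations can differ in floating-point score
depending on summation order, while genuinely different segmentations
differ by far more than 10⁻⁹; the tolerance makes the reported optimum
independent of how the search is implemented.

Trials qualify for summary statistics only when r2 > r1 and r2 > r3
(strict). Block summaries report medians and IQRs of start/stop/spread
over qualifying trials; quartiles use linear interpolation (the
median-unbiased default of common statistical environments — IQR values
depend on this and it is fixed here). The initiation (r1/r2) and
suppression (r3/r2) ratios are computed per trial and then averaged
(robust to rate heterogeneity across trials); the block-level alternative
(ratio of mean rates) is available. Start-stop and start-spread Pearson
correlations are computed over qualifying trials whose high state strictly
brackets the FI criterion (start < 30 < stop); strict bracketing is the
package's reading of "bracketed", and correlations require ≥ 3 bracketed
trials and nonzero variance, otherwise they are reported absent with the
subset size.

## Synthetic generators

**Bisection.** Per-duration trial counts follow the task design exactly;
the default design is a pooled test condition — two test sessions of two
90-trial blocks each — giving 120 trials per anchor and 24 per
intermediate duration, the counts an individual bisection curve is
estimated from (`BisectionDesign.single_session()` gives one session's
60/12). Trial order is randomized. Each trial is omitted with probability
`omit_prob`; otherwise the choice is Bernoulli with p(long) from the
pseudologistic model, and a single choice press occurs at cue offset plus
a lognormal latency (mean 0.5 s, CV 0.3 — a typical well-trained choice
latency scale).

**Peak interval.** Sessions hold 37 FI and 18 probe trials in random
order (the training-phase design). Per trial, a remembered criterion
m ~ lognormal(mean = FI, CV = `memory_cv` = 0.2) is drawn; the high state
spans start = 0.7·m·j₁ to stop = 1.5·m·j₂ with independent lognormal
jitters j of CV 0.3. The thresholds (0.7, 1.5) bracket the criterion
asymmetrically as observed in trained animals (start ≈ 21 s,
stop ≈ 45 s at FI 30); memory CV 0.2 is a typical scalar-timing
coefficient; jitter CV 0.3 makes threshold variance comparable to memory
variance, which is what yields the classic negative start-spread
correlation (shared memory noise alone would correlate start and spread
positively). The rare jitter pair that would invert start ≥ stop is
redrawn, preserving the lognormal marginals. Presses are homogeneous
Poisson within each state at rates r1 = 0.1, r2 = 1.5, r3 = 0.1 presses/s
(sharp but imperfect state contrast); trials are omitted with probability
0.05. FI trials run the same response process over a 60-s tone and
terminate, reinforced, at the first press after 30 s. Because start, stop
and their dispersion are all multiplicative in the timed interval, the
start-time CV is invariant across FI values (scalar property), which is
verified by `scalar_property_check`.

**Stress** multiplies omission (×8), gamma (×1.5) and response rates
(×0.8) — calibration knobs producing the qualitative pattern of disrupted
subjects (response proportion falling toward ~0.5, flatter psychometric),
not estimates of any empirical effect size — and interleaves 10 ITI
foot-shock events, each logged at least 10 s before the next cue onset.

What the generators deliberately do not emulate: learning dynamics across
sessions (acquisition can be emulated by scheduling parameters per block),
pacemaker-accumulator or drift-diffusion process detail, post-reinforcement
pausing within FI trials, and any mechanistic fear process. Consequently,
passing recovery tests shows the estimators are correct and calibrated for
data of this structure; it does not certify behavior against motivational
drift, rate nonstationarity within sessions, or non-scalar noise, which
real data may contain.

## Reproducibility and problem sizes

All stochastic components draw from numpy Generators; cohorts derive
per-subject child seeds from a single root seed via `SeedSequence.spawn`,
so results are bit-reproducible given the seed. CLI outputs are plain CSV
with shortest-repr floats, making repeated runs byte-identical.

Validation problem sizes (chosen to give stable statistics at interactive
runtimes): psychometric recovery uses 20 simulated subjects at the pooled
condition design; change-point correctness is checked against brute-force
enumeration on 210 Poisson trials over three seeds; molar-fit recovery
uses 20 simulated 36-trial blocks; scalar-property and omission checks use
3000-5000 trials per condition.

## Known limitations

- The psychometric model has no lapse or bias parameters; data from
  subjects with asymptotic error rates will depress R² rather than be
  absorbed into the fit.
- The three-state search is exact but O(n²) in bins per trial — ample at
  90 bins, not intended for millisecond binning.
- `summarize_block` treats the qualification filter as given; blocks with
  zero qualifying trials return absent summaries rather than falling back
  to weaker two-state fits.
- Vendor-native operant logs are not parsed; sessions must be exported to
  the documented CSV schema.
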