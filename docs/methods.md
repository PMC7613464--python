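# Methods

`windupkit` quantifies wind-up — the progressive amplification of
nociceptive responses during repetitive stimulation — across four
measurement modalities, together with the statistical utilities those
analyses rely on. This note records the models, conventions and numerical
choices, and what the synthetic-data generators do and do not emulate.

## In vitro calcium traces: repeat-reliability QC

Cultured dorsal-horn (DH) or dorsal-root-ganglion (DRG) cells are imaged
ratiometrically (Fura-2 340/380, 1 Hz, 340 s) and receive three identical
30 s high-K⁺ depolarising pulses at 60, 150 and 240 s, each followed by a
60 s washout. Because such cultures mix neurons with glia and unhealthy
cells, every cell is screened before kinetic analysis by a
repeat-reliability signal-to-noise ratio over the three pulse-aligned
90 s epochs:

    SNR = explainable variance / (total variance − explainable variance)

* explainable variance — variance over time of the pointwise mean across
  the three repeats (the variance a repeat-consistent signal explains);
* total variance — variance of all samples of all repeats pooled about
  the grand mean.

Population variances (divide by N) are used throughout, which makes
`explainable ≤ total` an algebraic identity and the SNR invariant under
adding a constant to, or positively rescaling, the trace. Cells pass at
SNR strictly greater than 1 (signal power exceeding noise power). Whether
the original screening pooled variances across epochs or averaged
per-epoch estimates is not derivable from the published description; the
pooled decomposition was chosen as the standard signal-power form and is
recorded in the run manifest. Identical repeats give SNR = +∞; a fully
constant recording scores 0 by convention.

## Kinetic metrics

Per QC-passed cell and pulse:

* **Baselines** — mean over the 15 s before each pulse onset and over the
  final 15 s. The window length is a package choice (long enough to
  average 1 Hz noise, short enough to avoid decay tails) and is
  configurable.
* **Peaks** — the sample at each pulse-offset time (90, 180, 270 s by
  default); a window-maximum mode is available for robustness studies.
* **AUC** — trapezoidal integral of (trace − reference) over each 90 s
  epoch, negative contributions retained. The reference is a cohort-level
  scalar (by default the cohort mean of start baselines) so that AUC
  differences are not baseline-dependent.
* **Tau** — the decay segment from the peak sample to just before the
  next onset (recording end for pulse 3) is normalised so its final decay
  value is 0 and fitted with A·e^(−t/τ) by nonlinear least squares.
  Because the washout can end before the trace has fully settled, the
  subtracted resting level is **not** the literal last sample: it is the
  mean over the entire pre-stimulus baseline (60 samples), which both
  matches the decay's true asymptote in the noiseless limit and averages
  measurement noise hard enough that the median relative error of τ stays
  below 5% at noise up to 5% of the response amplitude across
  τ ∈ {5, 10, 20, 40} s. Initial guesses: A₀ from the first shifted
  sample, τ₀ from linear interpolation to 37% (e⁻¹) of A₀. Degenerate
  segments (non-positive amplitude, no net decay) and non-convergence
  return a flagged failure, never an exception.
* **Tau outliers** — fitted τ above 200 s (DH) or 100 s (DRG) are
  removed; ceilings configurable.

## In vivo ΔF/F and response detection

Recordings are ROI fluorescence traces (~4 Hz) with a 2 min pre-stimulus
baseline followed by a train of 16 electrical pulses (0.2/0.5/1 Hz).
Processing: pointwise background-ROI subtraction; ΔF/F =
100·(F_t − F₀)/F₀ with F₀ the mean over the full pre-stimulus baseline
(configurable); ROIs with non-positive F₀ are flagged and excluded.

A response to an event is called against the threshold
1.2·μ(B_E) + 2·σ(B_E), where B_E is the 5 s window starting 10 s before
the event and σ is the population SD — i.e. 20% above the local baseline
mean plus two standard deviations, with strict-inequality crossing. The
rule is applied to the background-corrected *fluorescence* trace: on a
ΔF/F trace the pre-stimulus mean is ≈0 and the 1.2× factor would be
vacuous, whereas on fluorescence the 20% margin keeps the false-positive
rate of stationary-noise ROIs far below 5% per event. The maximal ΔF/F is
read from the normalised trace over the same search window. The post-event
search window is not fixed by the detection rule itself; the package
defaults to the inter-stimulus interval for per-pulse calls and to the
train span plus one interval plus 5 s for whole-train calls, and records
the choice in the manifest.

Group summaries treat the animal as the experimental unit: ROI maxima are
averaged within animal, then animal means summarised per cohort as
mean ± SEM (SEM reported absent for a single animal).

## Wind-up electrophysiology

Spikes evoked by a 16-pulse train are classed by post-stimulus latency:
A-fibre [0, 50) ms, C-fibre [50, 250) ms, post-discharge [250 ms, ISI).
Bands are half-open and lower-inclusive (a spike at exactly 50 ms is C);
the post-discharge upper bound defaults to the inter-stimulus interval
and is configurable. Latencies outside the bands are reported as overflow
so spike counts are always conserved.

With 1-based per-stimulus counts c₁…c₁₆:

* Input = c₁ × 16 (the non-potentiated response);
* wind-up = Σcᵢ − Input (negative under habituation);
* the acceleration of firing is summarised by the one-phase association
  fit y(i) = y₀ + (plateau − y₀)(1 − e^(−k(i−1))), so y(1) = y₀ exactly.
  Initial values: y₀ at c₁, plateau at the mean of the last three counts,
  k at 0.3. Flat trains leave k unidentifiable and are returned as k = 0
  with a flag. Noiseless curves are recovered to 10⁻⁶; under Poisson
  count noise at plateau ≈ 60 spikes the median error of k is ~1–3%
  over 500 replicates.

Receptive-field positivity requires strictly more than 30 spikes over
5 s (the threshold scales proportionally with the window). EMG afferent
volleys are classed from conduction velocity = distance/latency into
Aβ [20, 100), Aδ [2, 20) and C [0.05, 2) m/s.

## Psychophysics

**Wind-up ratio (WUR).** Five single-stimulus ratings and five
10-stimulus-train mean ratings (0–100 scale) per participant; WUR is the
ratio of the train mean to the single mean. The alternative per-repeat
ratio average is available as an option, but the ratio of means is the
default (it is defined whenever at least one single rating is non-zero
and is less volatile at small single ratings). Records with undefined WUR
or WUR > 6 (strictly) are excluded — such values arise almost entirely
from near-zero single ratings. Summaries report medians and IQRs with
linear-interpolation (type-7) quantiles.

**Up-down 50% withdrawal threshold.** Von Frey filaments from a log-spaced
ladder are applied sequentially, stepping down after a withdrawal and up
after none. The threshold is 10^(X_f + k·δ) grams with X_f the log₁₀ of
the final force and δ the mean log₁₀ ladder spacing. The pattern constant
k is obtained by maximum likelihood under the method's normal
response-curve model — withdrawal probability Φ((x − m)/δ) on the log
scale — as k = (m̂ − X_f)/δ. This is the model from which the classical
printed constants were derived; computing k directly covers every
admissible sequence uniformly instead of a finite lookup, and simulation
shows the median estimate lands within one ladder step of a deterministic
true threshold across starting positions. Runs pinned at a ladder
boundary return the boundary force; monotone runs that end before a
boundary return the final force as the best bracket (the likelihood has
no interior maximum).

**Box-Cox tuning by Lilliefors.** WUR distributions are right-skewed; for
association analyses the trait is power-transformed with
(x^λ − 1)/λ (ln x at λ = 0), λ searched over −3…3 in steps of 0.1 and
scored by the Lilliefors statistic — the Kolmogorov–Smirnov distance
between the transformed sample's ECDF and a normal with mean and SD
(ddof = 1, the convention of the standard R/Python implementations)
estimated from the same sample. The minimiser wins; ties resolve toward
λ = 1. The unscaled transform is used (not the geometric-mean-normalised
variant); since the normal-fit KS distance is affine-invariant, the
selected λ is unchanged by positive rescaling of the data. A Monte-Carlo
p-value is available by re-running the statistic on simulated
standard-normal samples with the estimation step included. Note that λ is
only well identified when the data's relative spread is appreciable: for
a tightly concentrated positive sample every power transform is
near-affine and the criterion is flat in λ.

## GWAS power

For an additive single-SNP linear model where the SNP explains a fraction
R² of trait variance, the two-sided 1-df association test is
asymptotically noncentral χ² with ncp = n·R²/(1 − R²). Power at level α
is the upper tail of that distribution beyond the central χ² critical
value. Covariate degrees of freedom are ignored (an O(1/n)
approximation at the sample sizes of interest). At n = 1000 and
α = 5.3×10⁻⁸ this gives 54.8% power for R² = 3% and 96.5% for R² = 5%.
The simulation route draws Hardy–Weinberg genotypes at a given minor
allele frequency, scales the effect so the SNP explains exactly R²
against unit-normal residuals, and runs a per-replicate OLS t-test;
monomorphic draws are redrawn and counted.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analyses assume*,
with known ground truth, so that every stage is testable without any
external download. They are not biophysical simulations.

* **Ratio traces** — responders ramp linearly to a cell-specific peak
  over each 30 s pulse (the within-pulse rise shape is unspecified by the
  protocol; a linear ramp is the simplest monotone choice and is
  configurable) and decay exponentially with a cell-specific τ
  (default τ ~ N(20, 5²) s, amplitude ~ N(1, 0.2²) ratio units, baseline
  0.5, Gaussian noise SD 0.05). Non-responders are noise around baseline.
  "Dying" cells respond to pulse 1 and then hold their elevated level —
  a deliberately simple parameterisation of the
  response-then-sustained-calcium failure mode; the filter rejects them
  because their three epochs disagree. Defaults: 70% responders, 10%
  dying.
* **ΔF/F recordings** — 4 Hz sampling, 120 s baseline, 16
  stimulus-locked transients with instantaneous rise, exponential decay
  and linear summation, on a fluorescence scale with an additive
  background. Real indicator kinetics (finite rise time, saturation,
  bleaching, motion) are not modelled.
* **Spike tables** — per-stimulus counts follow the one-phase
  association law (defaults y₀ = 27, plateau = 60, k = 0.34, roughly the
  published scale of 0.5 Hz trains) with Poisson noise (dispersion
  parameter switches to deterministic rounding at 0 or negative binomial
  above 1); each spike's latency is drawn uniformly within a band chosen
  by fixed band fractions. Real latency distributions within bands are
  not uniform; nothing in the analysis depends on the within-band shape.
* **WUR cohorts** — true WUR is log-normal (default median 1.27,
  log-SD 0.27, matching the reported cohort median and IQR scale), with
  log-normal between-participant rating levels and repeat noise; an
  outlier class reports near-zero (0.001) single ratings, producing the
  WUR > 6 artefacts the QC rule targets.

All randomness flows from one seeded `numpy.random.Generator` per call;
identical seeds give bit-identical outputs. Passing tests on these
cohorts demonstrates that the estimators recover the parameters of data
that satisfy the model assumptions — they cannot certify behaviour under
real-data pathologies (drift, motion, non-stationary noise) that the
generators exclude.

## Problem sizes and determinism

The bundled test-suite and acceptance runs use desk-scale cohorts chosen
so every stage's behaviour is measurable with comfortable Monte-Carlo
margins: 300–400 cells for filter recovery, 500 replicate fits for
rate-constant error, 2000 participants for WUR/Box-Cox recovery, 5000
replicates for simulated power. The full pipeline (`windupkit run`) is
bit-reproducible: same config and seed give byte-identical CSV and
manifest output, and the manifest records every threshold and convention
used, so a run can be reproduced without the original command line.

## Known limitations

* The tau fit assumes a single-exponential decay to the pre-stimulus
  resting level; cells with drifting baselines violate the asymptote
  assumption and surface as large residual RMS rather than being
  auto-detected.
* The up-down pattern constants come from the method's likelihood model
  rather than the classical printed table; individual thresholds can
  differ from table-based implementations by a fraction of a ladder step.
* The power calculation ignores covariate degrees of freedom and assumes
  a perfectly typed biallelic SNP in Hardy–Weinberg equilibrium.
* Cohort-specific published values (e.g. a measured median WUR or a
  tuned λ for a particular cohort) are data-dependent and are not
  reproduced by synthetic runs; the pipelines are validated by parameter
  recovery instead.
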