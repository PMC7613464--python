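# windupkit

Quantitative analysis of **pain wind-up** — the progressive amplification
of nociceptive responses under repetitive stimulation — across the
measurement modalities used to study it: in vitro calcium imaging of
dorsal-horn cultures, in vivo ΔF/F imaging, dorsal-horn single-unit
electrophysiology, and human quantitative sensory testing, plus the
supporting statistics (Box-Cox/Lilliefors transformation tuning and GWAS
power for a quantitative trait).

It is written for neurophysiology labs that have trace- or spike-level
data and want the standard wind-up quantities computed with explicit,
reproducible conventions — and for anyone who needs a tested reference
implementation of these estimators.

## What it computes

* **`trace_qc`** — repeat-reliability screening of three-pulse
  ratiometric (Fura-2) traces. With explainable variance the variance of
  the across-repeat mean and total variance the pooled variance,
  SNR = explainable / (total − explainable); cells pass at SNR > 1
  (signal power above noise power).
* **`calcium_metrics`** — per-pulse baselines, peaks at the fixed
  pulse-offset times, baseline-referenced AUC, and the decay constant τ
  from A·e^(−t/τ) fitted to each washout (after one τ the response
  retains e⁻¹ ≈ 37% of A). Cohort-specific τ outlier ceilings
  (DH 200 s, DRG 100 s).
* **`dff_invivo`** — background subtraction, ΔF/F = 100·(F−F₀)/F₀, and
  stimulus-evoked response detection at the threshold
  1.2·μ(B_E) + 2·σ(B_E) over a 5 s baseline window starting 10 s before
  each event; animal-level aggregation of maximal ΔF/F.
* **`windup_ephys`** — spike-latency banding (A 0–50 ms, C 50–250 ms,
  post-discharge ≥ 250 ms), Input = first-pulse count × 16,
  wind-up = total − Input, and the rate constant k of the one-phase
  association y(i) = y₀ + (plateau − y₀)(1 − e^(−k(i−1))); also the
  receptive-field criterion (>30 spikes / 5 s) and EMG
  conduction-velocity fibre classes.
* **`psychophys`** — the wind-up ratio WUR = mean(train)/mean(single)
  with the WUR > 6 exclusion rule, the up-down 50% withdrawal threshold
  10^(X_f + k·δ), and Box-Cox exponent selection by the Lilliefors
  statistic.
* **`gwas_power`** — power of the 1-df additive association test via the
  noncentral χ² with ncp = n·R²/(1 − R²), plus a simulation cross-check.
* **`synthgen`** — seeded generators for all of the above with known
  ground truth.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import numpy as np
from windupkit import synthgen, trace_qc, calcium_metrics, windup_ephys, gwas_power

# ---- in vitro: simulate a cohort, QC it, fit decay constants ----------
params = synthgen.TraceSimParams(n_cells=200, responder_fraction=0.7,
                                 dying_fraction=0.1, noise_sd=0.05, seed=1)
traces, truth = synthgen.gen_ratio_traces(params)
kept, discarded, summary = trace_qc.filter_reliable(traces)
print(summary)
# {'sim': {'n_in': 200, 'n_kept': 139}}

m = calcium_metrics.compute_epoch_metrics(kept[0])
print(round(m.tau_fits[0].tau, 2), "s")
# 21.04 s

# ---- wind-up: per-stimulus counts -> Input, wind-up, rate constant ----
spikes, _ = synthgen.gen_spike_table(synthgen.WindupSimParams(seed=1))
res = windup_ephys.analyze_neuron(spikes, isi_s=2.0)
print(res.input, res.windup, round(res.rate_fit.k, 3))
# 432.0 412.0 0.288

# ---- power at genome-wide significance --------------------------------
spec = gwas_power.PowerSpec(n=1000, r2=0.03, alpha=5.3e-8)
print(round(100 * gwas_power.analytic_power(spec), 1), "%")
# 54.8 %
```

The QC summary says 139 of 200 simulated cells repeat reliably across
the three depolarisations (the cohort contains 30% non-responders and
dying cells plus a few low-amplitude responders). The fitted τ ≈ 21 s is
that cell's calcium-clearance time constant. For the simulated neuron,
432 spikes is the non-potentiated response (27 first-pulse spikes × 16),
412 excess spikes is its wind-up, and k ≈ 0.29 per stimulus describes
how fast firing accelerates toward its plateau. The last line is the
probability of detecting, at p < 5.3×10⁻⁸ in n = 1000, a variant
explaining 3% of trait variance.

## Command line

```bash
windupkit simulate --seed 1 --outdir bundle/        # synthetic inputs + truth
windupkit qc bundle/traces.csv --outdir qc/         # reliability filter
windupkit metrics qc/kept.csv --out metrics.csv     # baselines/peaks/AUC/tau
windupkit windup bundle/spikes.csv --out windup.csv # Input, wind-up, k
windupkit wur bundle/ratings.csv --out wur.csv      # wind-up ratios + QC
windupkit power --n 1000 --r2 0.03                  # power calculator
windupkit run --seed 1 --outdir out/                # everything + manifest
```

Every run writes a JSON manifest of the thresholds and conventions used;
identical config and seed give byte-identical outputs.

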