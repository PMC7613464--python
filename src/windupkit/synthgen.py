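"""Synthetic recordings with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume — not
the underlying biophysics:

* three-pulse high-K+ ratiometric traces (1 Hz, 340 s) with responder,
  non-responder and "dying-cell" classes, per-cell baseline, peak
  amplitude, exponential decay constant and additive Gaussian noise;
* in vivo dF/F recordings (~4 Hz) with a 2 min baseline and a train of 16
  stimulus-locked transients that summate when the decay outlasts the
  inter-stimulus interval;
* per-stimulus spike tables following the saturating wind-up growth law
  ``y(i) = y0 + (plateau - y0) * (1 - exp(-k * (i - 1)))`` partitioned
  into A / C / post-discharge latency bands;
* skewed (log-normal) wind-up-ratio rating cohorts with an outlier class
  of near-zero single-stimulus ratings.

Every generator draws all randomness from a single seeded
``numpy.random.Generator``; identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from windupkit.errors import ParameterError
from windupkit.psychophys import WurRecord
from windupkit.trace_qc import PulseSchedule, RatioTrace
from windupkit.dff_invivo import DffRecording

__all__ = [
    "TraceSimParams",
    "TransientParams",
    "WindupSimParams",
    "WurSimParams",
    "gen_ratio_traces",
    "gen_dff_recording",
    "gen_spike_table",
    "gen_wur_cohort",
    "windup_growth_law",
]


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# In vitro three-pulse ratio traces


@dataclass(frozen=True)
class TraceSimParams:
    """Conditions of the simulated Fura-2 three-pulse experiment.

    Responders ramp linearly to their peak over each 30 s pulse and decay
    exponentially with their cell-specific tau during the washout; dying
    cells respond to the first pulse only and then stay elevated;
    non-responders are noise around baseline.  Ratio units throughout.
    """

    n_cells: int = 200
    responder_fraction: float = 0.7
    baseline_level: float = 0.5
    baseline_drift: float = 0.0  # ratio units per second
    peak_amplitude_mean: float = 1.0
    peak_amplitude_sd: float = 0.2
    tau_mean: float = 20.0
    tau_sd: float = 5.0
    noise_sd: float = 0.05
    dying_fraction: float = 0.1
    schedule: PulseSchedule = field(default_factory=PulseSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        _check_prob("responder_fraction", self.responder_fraction)
        _check_prob("dying_fraction", self.dying_fraction)
        if self.responder_fraction + self.dying_fraction > 1.0 + 1e-12:
            raise ParameterError("responder_fraction + dying_fraction must be <= 1")
        if self.tau_mean <= 0:
            raise ParameterError("tau_mean must be positive")
        for name in ("peak_amplitude_mean", "baseline_level"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("peak_amplitude_sd", "tau_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _responder_waveform(
    t: np.ndarray,
    schedule: PulseSchedule,
    amplitude: float,
    tau: float,
    pulses: Sequence[int],
    hold_after: int | None = None,
) -> np.ndarray:
    """Pulse-locked component: linear ramp over the pulse, then exponential decay.

    ``pulses`` lists the pulse indices the cell responds to; with
    ``hold_after`` set, the trace stays at the peak from that pulse's
    offset onward (the dying-cell shape).
    """
    out = np.zeros_like(t)
    onsets = schedule.pulse_onsets
    for p in pulses:
        onset = onsets[p]
        offset = onset + schedule.pulse_duration
        end = onsets[p + 1] if p + 1 < len(onsets) else t[-1] + schedule.sample_interval
        rising = (t >= onset) & (t < offset)
        out[rising] = amplitude * (t[rising] - onset) / schedule.pulse_duration
        if hold_after is not None and p == hold_after:
            out[t >= offset] = amplitude
            break
        decaying = (t >= offset) & (t < end)
        out[decaying] = amplitude * np.exp(-(t[decaying] - offset) / tau)
    return out


def gen_ratio_traces(
    params: TraceSimParams,
) -> tuple[list[RatioTrace], pd.DataFrame]:
    """Simulate one cohort of three-pulse ratio traces.

    Returns the traces plus a ground-truth table with one row per cell:
    ``cell_id, cohort, cell_class, baseline, amplitude, tau``
    (amplitude/tau are NaN for non-responders; tau is NaN for dying
    cells, which do not decay).
    """
    rng = np.random.default_rng(params.seed)
    sched = params.schedule
    n_samples = int(round(sched.recording_length / sched.sample_interval))
    t = np.arange(n_samples) * sched.sample_interval

    classes = rng.choice(
        ["responder", "dying", "nonresponder"],
        size=params.n_cells,
        p=[
            params.responder_fraction,
            params.dying_fraction,
            1.0 - params.responder_fraction - params.dying_fraction,
        ],
    )
    traces: list[RatioTrace] = []
    truth_rows = []
    for i, cls in enumerate(classes):
        baseline = params.baseline_level + params.baseline_drift * t
        amp = np.nan
        tau = np.nan
        signal = np.zeros_like(t)
        if cls != "nonresponder":
            amp = max(
                rng.normal(params.peak_amplitude_mean, params.peak_amplitude_sd),
                0.05 * params.peak_amplitude_mean,
            )
        if cls == "responder":
            tau = max(rng.normal(params.tau_mean, params.tau_sd), 1.0)
            signal = _responder_waveform(t, sched, amp, tau, range(sched.n_pulses))
        elif cls == "dying":
            signal = _responder_waveform(
                t, sched, amp, params.tau_mean, [0], hold_after=0
            )
        noise = rng.normal(0.0, params.noise_sd, size=t.shape) if params.noise_sd else 0.0
        value = baseline + signal + noise
        cell_id = f"cell{i:04d}"
        traces.append(RatioTrace(cell_id=cell_id, cohort="sim", t=t, value=value))
        truth_rows.append(
            dict(
                cell_id=cell_id,
                cohort="sim",
                cell_class=cls,
                baseline=params.baseline_level,
                amplitude=amp,
                tau=tau,
            )
        )
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# In vivo dF/F recordings


@dataclass(frozen=True)
class TransientParams:
    """Shape of one stimulus-locked fluorescence transient.

    ``amplitude`` is the fractional fluorescence increase per pulse
    (dF/F of 0.3 means a 30% transient); transients rise instantaneously
    and decay exponentially, summating linearly across pulses.
    """

    amplitude_mean: float = 0.3
    amplitude_sd: float = 0.1
    decay_tau_s: float = 2.0
    f0_level: float = 100.0  # raw fluorescence units
    background_level: float = 10.0
    noise_sd: float = 1.0  # raw fluorescence units

    def __post_init__(self) -> None:
        if self.amplitude_mean < 0 or self.amplitude_sd < 0 or self.noise_sd < 0:
            raise ParameterError("amplitudes and noise_sd must be >= 0")
        if self.decay_tau_s <= 0 or self.f0_level <= 0:
            raise ParameterError("decay_tau_s and f0_level must be positive")


def gen_dff_recording(
    freq: float = 0.5,
    n_cells: int = 20,
    responder_fraction: float = 0.6,
    transient_params: TransientParams | None = None,
    seed: int = 0,
    n_stimuli: int = 16,
    sample_rate: float = 4.0,
    baseline_s: float = 120.0,
    animal_id: str = "animal0",
    cohort: str = "sim",
) -> tuple[DffRecording, pd.DataFrame]:
    """Simulate one in vivo recording: baseline then a 16-pulse train.

    Responder ROIs carry stimulus-locked transients superimposed on their
    baseline fluorescence; the background ROI is independent noise around
    its own level.  Returns the recording and a per-ROI ground-truth table
    (``roi_id, is_responder, amplitude``).
    """
    if freq <= 0:
        raise ParameterError("train frequency must be positive")
    if transient_params is None:
        transient_params = TransientParams()
    _check_prob("responder_fraction", responder_fraction)
    tp = transient_params
    rng = np.random.default_rng(seed)
    isi = 1.0 / freq
    duration = baseline_s + n_stimuli * isi + 10.0
    n_samples = int(round(duration * sample_rate))
    t = np.arange(n_samples) / sample_rate
    stim_times = baseline_s + np.arange(n_stimuli) * isi

    is_resp = rng.random(n_cells) < responder_fraction
    roi_traces: dict[str, np.ndarray] = {}
    truth_rows = []
    for i in range(n_cells):
        roi = f"roi{i:03d}"
        amp = 0.0
        signal = np.zeros_like(t)
        if is_resp[i]:
            amp = max(rng.normal(tp.amplitude_mean, tp.amplitude_sd), 0.0)
            for ts in stim_times:
                mask = t >= ts
                signal[mask] += amp * np.exp(-(t[mask] - ts) / tp.decay_tau_s)
        noise = rng.normal(0.0, tp.noise_sd, size=t.shape) if tp.noise_sd else 0.0
        roi_traces[roi] = tp.background_level + tp.f0_level * (1.0 + signal) + noise
        truth_rows.append(dict(roi_id=roi, is_responder=bool(is_resp[i]), amplitude=amp))
    bg_noise = rng.normal(0.0, tp.noise_sd, size=t.shape) if tp.noise_sd else np.zeros_like(t)
    background = tp.background_level + bg_noise
    rec = DffRecording(
        t=t,
        roi_traces=roi_traces,
        background=background,
        stim_times=stim_times,
        frequency=freq,
        animal_id=animal_id,
        cohort=cohort,
    )
    return rec, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Wind-up spike tables


def windup_growth_law(
    i: np.ndarray | float, y0: float, plateau: float, k: float
) -> np.ndarray | float:
    """Expected per-stimulus count: ``y0 + (plateau - y0)(1 - e^{-k(i-1)})``."""
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * (np.asarray(i, dtype=float) - 1.0)))


@dataclass(frozen=True)
class WindupSimParams:
    """Conditions of a simulated wind-up train.

    ``count_noise`` controls per-stimulus count dispersion: 0 gives
    deterministic (rounded) counts, 1 Poisson, and values above 1 a
    negative binomial with variance ``count_noise * mean``.
    ``band_fractions`` partitions spikes over the A / C / post-discharge
    latency bands.
    """

    first_pulse_count: float = 27.0
    plateau: float = 60.0
    rate_constant: float = 0.34
    band_fractions: tuple[float, float, float] = (0.25, 0.55, 0.20)
    count_noise: float = 1.0
    n_stimuli: int = 16
    isi: float = 2.0  # seconds (0.5 Hz train)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ParameterError("n_stimuli must be >= 2")
        if self.rate_constant < 0:
            raise ParameterError("rate_constant must be >= 0")
        if self.plateau < 0 or self.first_pulse_count < 0:
            raise ParameterError("spike counts must be >= 0")
        if self.count_noise < 0:
            raise ParameterError("count_noise must be >= 0")
        if self.isi <= 0.25:
            raise ParameterError("isi must exceed 0.25 s (the post-discharge band start)")
        fr = self.band_fractions
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ParameterError("band_fractions must be 3 non-negative values summing to 1")


_BAND_EDGES_MS = (0.0, 50.0, 250.0)  # A and C starts; PD runs to the ISI


def gen_spike_table(
    params: WindupSimParams, neuron_id: str = "neuron0"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one neuron's stimulus-aligned spike table.

    Returns ``(spikes, truth)``: ``spikes`` has one row per spike
    (``neuron_id, stimulus_index, latency_ms``), ``truth`` one row per
    stimulus with the growth-law expectation and the realised count.
    """
    rng = np.random.default_rng(params.seed)
    i = np.arange(1, params.n_stimuli + 1)
    mean = windup_growth_law(i, params.first_pulse_count, params.plateau, params.rate_constant)
    if params.count_noise == 0:
        counts = np.rint(mean).astype(int)
    elif params.count_noise <= 1.0:
        counts = rng.poisson(mean)
    else:
        c = params.count_noise
        r = mean / (c - 1.0)
        counts = rng.negative_binomial(np.maximum(r, 1e-9), 1.0 / c)
    pd_end = params.isi * 1000.0
    edges = list(_BAND_EDGES_MS) + [pd_end]
    rows = []
    for stim, count in zip(i, counts):
        if count == 0:
            continue
        bands = rng.choice(3, size=int(count), p=params.band_fractions)
        lat = np.empty(int(count))
        for b in range(3):
            m = bands == b
            lat[m] = rng.uniform(edges[b], edges[b + 1], size=int(m.sum()))
        for latency in np.sort(lat):
            rows.append(dict(neuron_id=neuron_id, stimulus_index=int(stim), latency_ms=float(latency)))
    spikes = pd.DataFrame(rows, columns=["neuron_id", "stimulus_index", "latency_ms"])
    truth = pd.DataFrame(
        dict(stimulus_index=i, expected_count=mean, realized_count=counts.astype(int))
    )
    return spikes, truth


# ---------------------------------------------------------------------------
# WUR rating cohorts


@dataclass(frozen=True)
class WurSimParams:
    """Conditions of a simulated wind-up-ratio cohort.

    True WUR per participant is log-normal:
    ``log(WUR) ~ N(log_wur_mean, log_wur_sd)``, giving the long right
    tail seen in temporal-summation cohorts.  ``outlier_fraction`` of
    participants report near-zero single-stimulus ratings, producing the
    WUR > 6 artefacts the QC rule targets.
    """

    n_participants: int = 1000
    log_wur_mean: float = float(np.log(1.27))
    log_wur_sd: float = 0.27
    single_rating_scale: float = 3.0
    between_subject_sd: float = 0.4  # log-scale spread of single-rating level
    rating_noise_sd: float = 0.1  # log-scale repeat-to-repeat noise
    n_repeats: int = 5
    outlier_fraction: float = 0.0
    outlier_single_rating: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_repeats < 1:
            raise ParameterError("n_participants and n_repeats must be >= 1")
        if self.single_rating_scale <= 0:
            raise ParameterError("single_rating_scale must be positive")
        if self.log_wur_sd < 0 or self.rating_noise_sd < 0 or self.between_subject_sd < 0:
            raise ParameterError("spread parameters must be >= 0")
        _check_prob("outlier_fraction", self.outlier_fraction)


def gen_wur_cohort(params: WurSimParams) -> tuple[list[WurRecord], pd.DataFrame]:
    """Simulate one rating cohort.

    Returns the records plus ground truth
    (``participant_id, true_wur, is_outlier``).
    """
    rng = np.random.default_rng(params.seed)
    records: list[WurRecord] = []
    truth_rows = []
    for i in range(params.n_participants):
        pid = f"P{i:04d}"
        true_wur = float(np.exp(rng.normal(params.log_wur_mean, params.log_wur_sd)))
        level = params.single_rating_scale * float(
            np.exp(rng.normal(0.0, params.between_subject_sd))
        )
        is_outlier = bool(rng.random() < params.outlier_fraction)
        noise_s = np.exp(rng.normal(0.0, params.rating_noise_sd, size=params.n_repeats))
        noise_t = np.exp(rng.normal(0.0, params.rating_noise_sd, size=params.n_repeats))
        if is_outlier:
            single = np.full(params.n_repeats, params.outlier_single_rating)
        else:
            single = np.clip(level * noise_s, 0.0, 100.0)
        train = np.clip(level * true_wur * noise_t, 0.0, 100.0)
        records.append(
            WurRecord(participant_id=pid, single_ratings=single, train_ratings=train)
        )
        truth_rows.append(dict(participant_id=pid, true_wur=true_wur, is_outlier=is_outlier))
    return records, pd.DataFrame(truth_rows)
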