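"""Per-pulse kinetic metrics of depolarisation-evoked calcium transients.

For each QC-passed cell the pipeline extracts, per high-K+ pulse:

* baselines — mean ratio over a short window before each pulse and at the
  end of the recording;
* peaks — the ratio at the fixed pulse-offset times (90, 180, 270 s under
  the default schedule), or optionally the within-window maximum;
* AUC — trapezoidal area of the trace above a caller-supplied reference
  (typically the cohort's mean start baseline, so AUC differences are not
  baseline-dependent);
* tau — the time constant of the single-exponential decay
  ``f(t) = A * exp(-t / tau)`` fitted to the washout segment after each
  peak, after shifting the segment so its final value is 0.  After one
  time constant the fitted curve retains ``exp(-1)`` (about 37%) of A.

Implausibly slow decays are removed by cohort-specific tau ceilings
(200 s for dorsal-horn, 100 s for DRG cultures by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from windupkit.errors import CoverageError, ParameterError
from windupkit.trace_qc import PulseSchedule, RatioTrace

__all__ = [
    "TauFit",
    "EpochMetrics",
    "extract_baselines",
    "extract_peaks",
    "compute_auc",
    "fit_tau",
    "remove_tau_outliers",
    "compute_epoch_metrics",
    "TAU_OUTLIER_THRESHOLDS",
]

#: Cohort-specific ceilings (s) above which a fitted tau is treated as an
#: outlier: dorsal horn (DH) and dorsal root ganglion (DRG) cultures.
TAU_OUTLIER_THRESHOLDS: dict[str, float] = {"DH": 200.0, "DRG": 100.0}


@dataclass(frozen=True)
class TauFit:
    """Result of a single-exponential decay fit.

    ``tau`` and ``amplitude`` are ``None`` when the fit fails (degenerate
    segment or no convergence); ``converged`` is then False.
    """

    tau: float | None
    amplitude: float | None
    residual_rms: float | None
    converged: bool
    message: str = ""


@dataclass
class EpochMetrics:
    """All per-pulse metrics for one cell."""

    cell_id: str
    cohort: str
    baselines: np.ndarray  # start, inter-pulse..., end
    peaks: np.ndarray  # one per pulse
    auc: np.ndarray  # one per pulse, ratio*s
    tau_fits: list[TauFit]  # one per pulse

    @property
    def taus(self) -> list[float | None]:
        return [f.tau for f in self.tau_fits]


def _slice(trace: RatioTrace, t_start: float, t_stop: float) -> np.ndarray:
    """Samples of ``trace`` with t_start <= t <= t_stop (grid-aligned)."""
    i0 = trace.index_at(t_start)
    i1 = trace.index_at(t_stop)
    if i0 < 0 or i1 >= trace.value.size or i1 < i0:
        raise CoverageError(
            f"trace {trace.cell_id}: window [{t_start}, {t_stop}] s not covered"
        )
    return trace.value[i0 : i1 + 1]


def extract_baselines(
    trace: RatioTrace, schedule: PulseSchedule | None = None, window: float = 15.0
) -> np.ndarray:
    """Baselines before each pulse and at the end of the recording.

    Each baseline is the mean of the last ``window`` seconds before the
    corresponding pulse onset; the final entry averages the last ``window``
    seconds of the trace.  Returns ``n_pulses + 1`` values.
    """
    if schedule is None:
        schedule = PulseSchedule()
    if window <= 0:
        raise ParameterError("window must be positive")
    dt = trace.sample_interval
    if window > schedule.pulse_onsets[0] + 1e-9:
        raise ParameterError(
            f"baseline window {window} s exceeds the {schedule.pulse_onsets[0]} s "
            "pre-pulse segment"
        )
    gaps = [
        b - (a + schedule.epoch_length)
        for a, b in zip(schedule.pulse_onsets, schedule.pulse_onsets[1:])
    ]
    # Inter-pulse baselines read the tail of the preceding epoch, which is
    # washout; the window only needs to fit inside the epoch.
    if window > schedule.epoch_length - schedule.pulse_duration + max(gaps, default=0.0) + 1e-9:
        raise ParameterError("baseline window overlaps the preceding pulse")
    out = []
    for onset in schedule.pulse_onsets:
        out.append(float(np.mean(_slice(trace, onset - window, onset - dt))))
    t_end = float(trace.t[-1])
    out.append(float(np.mean(_slice(trace, t_end - window + dt, t_end))))
    return np.asarray(out)


def extract_peaks(
    trace: RatioTrace,
    schedule: PulseSchedule | None = None,
    mode: str = "at_fixed_times",
) -> np.ndarray:
    """Per-pulse peak values.

    ``at_fixed_times`` reads the sample at each pulse-offset time
    (onset + duration); ``window_max`` takes the maximum over each pulse
    window instead, which is robust to transient overshoot.
    """
    if schedule is None:
        schedule = PulseSchedule()
    if mode not in ("at_fixed_times", "window_max"):
        raise ParameterError(f"unknown peak mode {mode!r}")
    peaks = []
    for onset, t_peak in zip(schedule.pulse_onsets, schedule.peak_times):
        if mode == "at_fixed_times":
            idx = trace.index_at(t_peak)
            if idx < 0 or idx >= trace.value.size:
                raise CoverageError(f"trace {trace.cell_id}: peak time {t_peak} s not covered")
            peaks.append(float(trace.value[idx]))
        else:
            peaks.append(float(np.max(_slice(trace, onset, t_peak))))
    return np.asarray(peaks)


def compute_auc(
    trace: RatioTrace,
    schedule: PulseSchedule | None = None,
    reference: float = 0.0,
) -> np.ndarray:
    """Trapezoidal area of (value - reference) over each epoch.

    The integral runs over ``[onset, onset + epoch_length]``; negative
    contributions (trace below the reference) are retained.  Units are
    ratio * s.
    """
    if schedule is None:
        schedule = PulseSchedule()
    dt = trace.sample_interval
    aucs = []
    for onset in schedule.pulse_onsets:
        t_stop = min(onset + schedule.epoch_length, float(trace.t[-1]))
        seg = _slice(trace, onset, t_stop)
        aucs.append(float(np.trapezoid(seg - reference, dx=dt)))
    return np.asarray(aucs)


def _decay_segment(
    trace: RatioTrace, schedule: PulseSchedule, pulse_index: int
) -> np.ndarray:
    """Washout samples from the peak time to the next onset (or trace end)."""
    if not 0 <= pulse_index < schedule.n_pulses:
        raise ParameterError(f"pulse_index {pulse_index} out of range")
    t_peak = schedule.peak_times[pulse_index]
    if pulse_index + 1 < schedule.n_pulses:
        t_stop = schedule.pulse_onsets[pulse_index + 1] - trace.sample_interval
    else:
        t_stop = float(trace.t[-1])
    return _slice(trace, t_peak, t_stop)


def fit_tau(
    trace: RatioTrace,
    schedule: PulseSchedule | None = None,
    pulse_index: int = 0,
    baseline: float | None = None,
) -> TauFit:
    """Fit ``A * exp(-t / tau)`` to the decay after one pulse.

    The decay segment runs from the peak sample to just before the next
    pulse onset (recording end for the last pulse); ``t`` is measured
    from the peak sample.  The response is normalised before fitting so
    the final decay value is 0: the resting level the decay relaxes to is
    subtracted.  That level is ``baseline`` when given, otherwise the
    mean over the cell's entire pre-stimulus baseline (every sample
    before the first pulse onset, which averages noise the hardest) —
    the washout may end before the trace has fully settled, so the
    literal last sample is not used.
    Initial guesses are A0 = first shifted value and tau0 = the linearly
    interpolated time for the shifted segment to fall to 37% of A0.
    Failures (non-decaying or degenerate segments, non-convergence) are
    reported in the returned :class:`TauFit`, never raised.
    """
    if schedule is None:
        schedule = PulseSchedule()
    seg = _decay_segment(trace, schedule, pulse_index)
    if seg.size < 5:
        return TauFit(None, None, None, False, "decay segment shorter than 5 samples")
    if baseline is None:
        i_first = trace.index_at(schedule.pulse_onsets[0])
        baseline = float(np.mean(trace.value[:i_first]))
    dt = trace.sample_interval
    y = seg - baseline  # normalise: decay asymptote at 0
    a0 = float(y[0])
    if a0 <= 0:
        return TauFit(None, None, None, False, "non-positive initial amplitude")
    if y[-1] >= a0:
        return TauFit(None, None, None, False, "segment does not decay")
    t = np.arange(seg.size) * dt
    target = a0 * math.exp(-1.0)
    below = np.nonzero(y <= target)[0]
    if below.size and below[0] > 0:
        j = below[0]
        frac = (y[j - 1] - target) / (y[j - 1] - y[j]) if y[j - 1] != y[j] else 0.0
        tau0 = float(t[j - 1] + frac * dt)
    else:
        tau0 = float(t[-1]) / 2.0
    tau0 = max(tau0, dt)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            y,
            p0=(a0, tau0),
            bounds=((0.0, dt * 1e-3), (np.inf, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return TauFit(None, None, None, False, f"no convergence: {exc}")
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    resid = y - a_hat * np.exp(-t / tau_hat)
    rms = float(np.sqrt(np.mean(resid**2)))
    return TauFit(tau=tau_hat, amplitude=a_hat, residual_rms=rms, converged=True)


def remove_tau_outliers(
    taus: Sequence[float],
    cohort: str,
    thresholds: dict[str, float] | None = None,
) -> tuple[list[float], list[float]]:
    """Split taus into (kept, removed) by the cohort's outlier ceiling."""
    table = thresholds if thresholds is not None else TAU_OUTLIER_THRESHOLDS
    if cohort not in table:
        raise ParameterError(
            f"unknown cohort {cohort!r}; expected one of {sorted(table)}"
        )
    ceiling = table[cohort]
    kept = [float(x) for x in taus if x <= ceiling]
    removed = [float(x) for x in taus if x > ceiling]
    return kept, removed


def compute_epoch_metrics(
    trace: RatioTrace,
    schedule: PulseSchedule | None = None,
    reference: float | None = None,
    baseline_window: float = 15.0,
    peak_mode: str = "at_fixed_times",
) -> EpochMetrics:
    """All per-pulse metrics for one cell.

    ``reference`` is the AUC baseline; when omitted, the cell's own start
    baseline is used (pipeline callers pass the cohort mean instead).
    """
    if schedule is None:
        schedule = PulseSchedule()
    baselines = extract_baselines(trace, schedule, window=baseline_window)
    peaks = extract_peaks(trace, schedule, mode=peak_mode)
    ref = float(baselines[0]) if reference is None else float(reference)
    auc = compute_auc(trace, schedule, reference=ref)
    fits = [fit_tau(trace, schedule, p) for p in range(schedule.n_pulses)]
    return EpochMetrics(
        cell_id=trace.cell_id,
        cohort=trace.cohort,
        baselines=baselines,
        peaks=peaks,
        auc=auc,
        tau_fits=fits,
    )
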