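"""Repeat-reliability quality control of three-pulse calcium traces.

Cultured dorsal-horn preparations mix neurons with glia and unhealthy cells,
so ratiometric (Fura-2 340/380) recordings are screened before any kinetic
analysis.  Each cell receives three identical high-K+ depolarising pulses;
a cell is kept only if its response repeats reliably across the three
epochs, measured by a signal-to-noise ratio

    SNR = signal power / noise power
        = explainable variance / (total variance - explainable variance)

where the explainable variance is the variance over time of the pointwise
mean across the three repeats, and the total variance is the variance of
all samples of all repeats pooled about the grand mean.  An SNR of 1 means
signal power equals noise power; cells strictly above the threshold
(default 1) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from windupkit.errors import CoverageError, FormatError, ParameterError, ShapeError

__all__ = [
    "PulseSchedule",
    "RatioTrace",
    "ReliabilityScore",
    "segment_epochs",
    "reliability_snr",
    "filter_reliable",
]


@dataclass(frozen=True)
class PulseSchedule:
    """Timing of the repeated depolarising pulses within one recording.

    The default schedule is 60 s of baseline, then three 30 s pulses at
    60, 150 and 240 s, each followed by a 60 s washout, sampled at 1 Hz
    for 340 s.  An epoch (pulse + washout, 90 s) is the unit over which
    repeat reliability is evaluated.
    """

    pulse_onsets: tuple[float, ...] = (60.0, 150.0, 240.0)
    pulse_duration: float = 30.0
    epoch_length: float = 90.0
    recording_length: float = 340.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        onsets = tuple(float(o) for o in self.pulse_onsets)
        object.__setattr__(self, "pulse_onsets", onsets)
        if len(onsets) < 1:
            raise ParameterError("schedule needs at least one pulse onset")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("pulse onsets must be strictly increasing")
        if self.pulse_duration <= 0 or self.epoch_length <= 0:
            raise ParameterError("pulse_duration and epoch_length must be positive")
        if self.sample_interval <= 0:
            raise ParameterError("sample_interval must be positive")
        if self.pulse_duration > self.epoch_length:
            raise ParameterError("epoch_length must cover the pulse")
        for a, b in zip(onsets, onsets[1:]):
            if a + self.epoch_length > b + 1e-9:
                raise ParameterError("epochs overlap: onset + epoch_length > next onset")
        if onsets[-1] + self.epoch_length > self.recording_length + 1e-9:
            raise ParameterError("epochs do not fit within recording_length")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets)

    @property
    def peak_times(self) -> tuple[float, ...]:
        """Pulse-offset times, where the response peak is read by default."""
        return tuple(o + self.pulse_duration for o in self.pulse_onsets)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length / self.sample_interval))

    def onset_index(self, pulse: int) -> int:
        return int(round(self.pulse_onsets[pulse] / self.sample_interval))


@dataclass
class RatioTrace:
    """One cell's ratiometric fluorescence time series.

    ``value`` is the background-free 340/380 ratio (dimensionless), sampled
    uniformly at the times in ``t`` (seconds).
    """

    cell_id: str
    cohort: str
    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.value.shape:
            raise FormatError(f"trace {self.cell_id}: t and value must be equal-length 1-D arrays")
        if self.t.size < 2:
            raise FormatError(f"trace {self.cell_id}: needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise FormatError(f"trace {self.cell_id}: time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError(f"trace {self.cell_id}: non-uniform sampling")
        if not np.all(np.isfinite(self.value)):
            raise FormatError(f"trace {self.cell_id}: non-finite values")

    @property
    def sample_interval(self) -> float:
        return float(self.t[1] - self.t[0])

    def index_at(self, time_s: float) -> int:
        """Sample index of ``time_s``, which must lie on the sampling grid."""
        idx = (time_s - self.t[0]) / self.sample_interval
        return int(round(idx))


@dataclass(frozen=True)
class ReliabilityScore:
    """Repeat-reliability decomposition of one cell's three epochs.

    ``snr`` may be ``inf`` when the repeats are identical and non-constant;
    a fully constant recording scores 0 by convention.
    """

    snr: float
    explainable_variance: float
    total_variance: float


def segment_epochs(trace: RatioTrace, schedule: PulseSchedule) -> np.ndarray:
    """Cut the repeat epochs out of a trace, aligned on pulse onset.

    Returns an array of shape ``(n_pulses, samples_per_epoch)``; row ``i``
    starts at the sample of pulse onset ``i``.
    """
    dt = trace.sample_interval
    if not np.isclose(dt, schedule.sample_interval, rtol=1e-6):
        raise FormatError(
            f"trace {trace.cell_id}: sample interval {dt} does not match "
            f"schedule ({schedule.sample_interval})"
        )
    n = schedule.samples_per_epoch
    rows = []
    for p in range(schedule.n_pulses):
        i0 = trace.index_at(schedule.pulse_onsets[p])
        if i0 < 0 or i0 + n > trace.value.size:
            raise CoverageError(
                f"trace {trace.cell_id}: epoch {p + 1} "
                f"[{schedule.pulse_onsets[p]}, +{schedule.epoch_length}s) "
                f"not covered by trace of {trace.value.size} samples"
            )
        rows.append(trace.value[i0 : i0 + n])
    return np.stack(rows)


def reliability_snr(epochs: np.ndarray | Sequence[np.ndarray]) -> ReliabilityScore:
    """Signal-to-noise ratio of repeated epochs.

    Explainable variance is the variance over time of the across-repeat
    mean; total variance is the pooled variance of all samples about the
    grand mean.  Population variances (divide by N) are used throughout,
    which makes explainable <= total an identity.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ShapeError("epochs must be a 2-D array (repeats x time)")
    if epochs.shape[0] < 2 or epochs.shape[1] < 2:
        raise ShapeError("need >= 2 repeats of >= 2 samples each")
    mean_trace = epochs.mean(axis=0)
    explainable = float(np.var(mean_trace))
    total = float(np.var(epochs))
    noise = total - explainable
    if total <= 0.0:
        snr = 0.0
    elif noise <= max(1e-12 * total, 0.0):
        snr = float("inf")
    else:
        snr = explainable / noise
    return ReliabilityScore(snr=snr, explainable_variance=explainable, total_variance=total)


def filter_reliable(
    traces: Iterable[RatioTrace],
    schedule: PulseSchedule | None = None,
    threshold: float = 1.0,
) -> tuple[list[RatioTrace], list[RatioTrace], dict[str, dict[str, int]]]:
    """Keep traces whose repeat-reliability SNR is strictly above ``threshold``.

    Returns ``(kept, discarded, summary)`` where ``summary`` maps each
    cohort label to ``{"n_in": ..., "n_kept": ...}``.
    """
    if schedule is None:
        schedule = PulseSchedule()
    if not np.isfinite(threshold) or threshold < 0:
        raise ParameterError("threshold must be a finite non-negative number")
    kept: list[RatioTrace] = []
    discarded: list[RatioTrace] = []
    summary: dict[str, dict[str, int]] = {}
    for trace in traces:
        score = reliability_snr(segment_epochs(trace, schedule))
        entry = summary.setdefault(trace.cohort, {"n_in": 0, "n_kept": 0})
        entry["n_in"] += 1
        if score.snr > threshold:
            kept.append(trace)
            entry["n_kept"] += 1
        else:
            discarded.append(trace)
    return kept, discarded, summary
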