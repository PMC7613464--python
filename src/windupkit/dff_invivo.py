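"""In vivo dF/F normalisation and stimulus-evoked response detection.

Recordings are ROI fluorescence traces (genetically encoded indicator,
~4 Hz) from anaesthetised animals receiving trains of 16 electrical pulses
after a 2 min baseline.  Processing follows four steps:

1. pointwise subtraction of a background ROI trace;
2. dF/F normalisation, ``100 * (F_t - F0) / F0`` with F0 the mean over a
   pre-stimulus window (the full 2 min baseline by default);
3. per-event response calling against the threshold
   ``1.2 * mean(B_E) + 2 * sd(B_E)`` where B_E is the 5 s baseline window
   starting 10 s before the event — i.e. 20% above the local baseline mean
   plus two standard deviations;
4. two-level aggregation of maximal dF/F: ROI max -> animal mean ->
   cohort mean +/- SEM, with the animal as the experimental unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from windupkit.errors import (
    AggregationError,
    CoverageError,
    NormalizationError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "DffRecording",
    "ResponseCall",
    "background_subtract",
    "compute_dff",
    "call_response",
    "call_train_responses",
    "summarize_animals",
]

#: B_E is a 5 s baseline period starting 10 s before the event.
BASELINE_EVENT_START = 10.0
BASELINE_EVENT_LENGTH = 5.0


@dataclass
class DffRecording:
    """ROI fluorescence traces sharing one time base, plus stimulus metadata.

    ``roi_traces`` maps ROI id to a raw fluorescence array (arbitrary
    units).  ``background`` is the background-ROI trace used for bleed
    subtraction.  ``stim_times`` are the onsets (s) of the electrical
    pulses of one train at ``frequency`` Hz.
    """

    t: np.ndarray
    roi_traces: dict[str, np.ndarray]
    background: np.ndarray
    stim_times: np.ndarray
    frequency: float
    animal_id: str = "animal0"
    cohort: str = "WT"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.roi_traces = {k: np.asarray(v, dtype=float) for k, v in self.roi_traces.items()}
        n = self.t.size
        if self.background.size != n:
            raise ShapeError("background trace length does not match time base")
        for roi, trace in self.roi_traces.items():
            if trace.size != n:
                raise ShapeError(f"ROI {roi}: trace length does not match time base")
        if self.stim_times.size and np.any(np.diff(self.stim_times) <= 0):
            raise ParameterError("stimulus times must be strictly increasing")
        if self.frequency <= 0:
            raise ParameterError("train frequency must be positive")

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of the threshold rule for one ROI and one event."""

    roi_id: str
    event_time: float
    threshold: float
    baseline_mean: float
    baseline_sd: float
    is_responder: bool
    max_dff: float


def background_subtract(recording: DffRecording) -> dict[str, np.ndarray]:
    """Subtract the background trace from every ROI trace, pointwise."""
    return {roi: trace - recording.background for roi, trace in recording.roi_traces.items()}


def compute_dff(corrected: np.ndarray, t: np.ndarray, f0_window: tuple[float, float]) -> np.ndarray:
    """dF/F in percent: ``100 * (F_t - F0) / F0``.

    F0 is the mean of the corrected trace over ``f0_window`` (seconds,
    inclusive bounds).  A non-positive F0 makes the normalisation
    meaningless and raises :class:`NormalizationError` so the caller can
    flag and exclude the ROI.
    """
    corrected = np.asarray(corrected, dtype=float)
    t = np.asarray(t, dtype=float)
    lo, hi = f0_window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise CoverageError(f"F0 window [{lo}, {hi}] s contains no samples")
    f0 = float(corrected[mask].mean())
    if f0 <= 0:
        raise NormalizationError(f"F0 = {f0:.4g} <= 0; ROI excluded")
    return 100.0 * (corrected - f0) / f0


def call_response(
    dff: np.ndarray,
    t: np.ndarray,
    event_time: float,
    window_after: float,
    roi_id: str = "roi",
) -> ResponseCall:
    """Apply the event-locked threshold rule to one dF/F trace.

    The threshold is ``1.2 * mean(B_E) + 2 * sd(B_E)`` computed over the
    5 s window starting 10 s before the event (population sd).  The ROI is
    a responder if any sample strictly exceeds the threshold within
    ``(event_time, event_time + window_after]``; ``max_dff`` is recorded
    over the same window.
    """
    dff = np.asarray(dff, dtype=float)
    t = np.asarray(t, dtype=float)
    if window_after < 0:
        raise ParameterError("window_after must be >= 0")
    b_lo = event_time - BASELINE_EVENT_START
    b_hi = b_lo + BASELINE_EVENT_LENGTH
    if b_lo < t[0] - 1e-9:
        raise CoverageError(
            f"baseline window [{b_lo:.1f}, {b_hi:.1f}] s precedes the recording"
        )
    b_mask = (t >= b_lo) & (t < b_hi)
    if b_mask.sum() < 2:
        raise CoverageError("baseline window B_E contains fewer than 2 samples")
    mu = float(dff[b_mask].mean())
    sd = float(dff[b_mask].std())  # population sd
    threshold = 1.2 * mu + 2.0 * sd
    w_mask = (t > event_time) & (t <= event_time + window_after)
    if w_mask.any():
        max_dff = float(dff[w_mask].max())
        is_resp = bool(max_dff > threshold)
    else:
        max_dff = float("nan")
        is_resp = False
    return ResponseCall(
        roi_id=roi_id,
        event_time=float(event_time),
        threshold=threshold,
        baseline_mean=mu,
        baseline_sd=sd,
        is_responder=is_resp,
        max_dff=max_dff,
    )


def call_train_responses(
    recording: DffRecording,
    f0_window: tuple[float, float] | None = None,
    window_after: float | None = None,
    per_pulse: bool = False,
) -> pd.DataFrame:
    """Background-subtract, normalise and call responses for a recording.

    The threshold rule runs on the background-corrected fluorescence
    trace, where "20% above baseline" is a meaningful margin (on a dF/F
    trace the pre-stimulus mean is ~0 and the 1.2x factor would do
    nothing); ``max_dff`` is read from the normalised dF/F trace over the
    same search window.  By default one call is made per ROI against the
    first stimulus of the train, with the search window spanning the
    train plus 5 s; with ``per_pulse=True`` every pulse is called
    separately with the inter-stimulus interval as the search window.
    ROIs whose F0 is non-positive are returned flagged (``excluded``
    True) rather than dropped silently.
    """
    if f0_window is None:
        f0_window = (float(recording.t[0]), float(recording.stim_times[0]) - recording.sample_interval)
    isi = 1.0 / recording.frequency
    corrected = background_subtract(recording)
    rows = []
    for roi, trace in corrected.items():
        try:
            dff = compute_dff(trace, recording.t, f0_window)
        except NormalizationError as exc:
            rows.append(
                dict(
                    roi_id=roi,
                    animal_id=recording.animal_id,
                    cohort=recording.cohort,
                    event_time=float(recording.stim_times[0]),
                    threshold=np.nan,
                    is_responder=False,
                    max_dff=np.nan,
                    excluded=True,
                    reason=str(exc),
                )
            )
            continue
        if per_pulse:
            events = list(recording.stim_times)
            window = window_after if window_after is not None else isi
        else:
            events = [float(recording.stim_times[0])]
            train_span = float(recording.stim_times[-1] - recording.stim_times[0])
            window = window_after if window_after is not None else train_span + isi + 5.0
        for ev in events:
            call = call_response(trace, recording.t, ev, window, roi_id=roi)
            w_mask = (recording.t > ev) & (recording.t <= ev + window)
            max_dff = float(dff[w_mask].max()) if w_mask.any() else float("nan")
            rows.append(
                dict(
                    roi_id=roi,
                    animal_id=recording.animal_id,
                    cohort=recording.cohort,
                    event_time=call.event_time,
                    threshold=call.threshold,
                    is_responder=call.is_responder,
                    max_dff=max_dff,
                    excluded=False,
                    reason="",
                )
            )
    return pd.DataFrame(rows)


def summarize_animals(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate maximal dF/F with the animal as the experimental unit.

    Per ROI the maximum dF/F across its calls is taken; ROI maxima are
    averaged within each animal; animal means are then summarised per
    cohort as mean +/- SEM (SEM reported as NaN for a single animal).
    Returns ``(per_animal, per_cohort)`` frames.
    """
    if calls.empty:
        raise AggregationError("no response calls to summarise")
    usable = calls[~calls["excluded"].astype(bool)].dropna(subset=["max_dff"])
    if usable.empty:
        raise AggregationError("no usable response calls to summarise")
    roi_max = (
        usable.groupby(["cohort", "animal_id", "roi_id"], sort=True)["max_dff"]
        .max()
        .reset_index()
    )
    per_animal = (
        roi_max.groupby(["cohort", "animal_id"], sort=True)["max_dff"]
        .mean()
        .reset_index()
        .rename(columns={"max_dff": "mean_max_dff"})
    )
    per_cohort = (
        per_animal.groupby("cohort", sort=True)["mean_max_dff"]
        .agg(mean="mean", sem=lambda x: x.sem(ddof=1), n_animals="count")
        .reset_index()
    )
    return per_animal, per_cohort
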