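"""Wind-up quantification from stimulus-aligned spike trains.

Wide-dynamic-range dorsal-horn neurons receive a train of 16 transcutaneous
electrical stimuli (0.2 or 0.5 Hz).  Evoked spikes are classed by
post-stimulus latency into fibre bands — A: [0, 50) ms, C: [50, 250) ms,
post-discharge (PD): [250 ms, inter-stimulus interval) — and summarised by

* ``Input`` — first-pulse spike count x number of pulses, the response
  expected without potentiation;
* ``wind-up`` — total spikes over the train minus Input (negative values
  indicate habituation);
* the rate constant ``k`` of a one-phase association curve
  ``y(i) = y0 + (plateau - y0) * (1 - exp(-k * (i - 1)))`` fitted to the
  per-stimulus counts, describing how fast firing accelerates toward its
  plateau.

Also provided: the receptive-field positivity criterion (>30 spikes over
5 s) and EMG conduction-velocity fibre classing (A-beta 20-100 m/s,
A-delta 2-20 m/s, C 0.05-2 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from windupkit.errors import ParameterError, ShapeError

__all__ = [
    "LatencyBands",
    "BandCounts",
    "RateConstantFit",
    "WindupResult",
    "band_counts",
    "input_windup",
    "fit_rate_constant",
    "analyze_neuron",
    "receptive_field_positive",
    "classify_fiber_velocity",
]

BAND_ORDER = ("A", "C", "PD")


@dataclass(frozen=True)
class LatencyBands:
    """Half-open post-stimulus latency bands, in ms.

    A spike at exactly 50 ms falls in the C band (lower-inclusive
    convention).  ``pd_end`` bounds the post-discharge band and defaults
    to the inter-stimulus interval.
    """

    a_end: float = 50.0
    c_end: float = 250.0
    pd_end: float = 5000.0

    def __post_init__(self) -> None:
        if not 0 < self.a_end < self.c_end < self.pd_end:
            raise ParameterError("bands must satisfy 0 < a_end < c_end < pd_end")

    @classmethod
    def for_isi(cls, isi_s: float) -> "LatencyBands":
        return cls(pd_end=isi_s * 1000.0)

    def assign(self, latency_ms: np.ndarray) -> np.ndarray:
        """Band label per spike; 'overflow' for latencies >= pd_end or < 0."""
        latency_ms = np.asarray(latency_ms, dtype=float)
        out = np.full(latency_ms.shape, "overflow", dtype=object)
        out[(latency_ms >= 0) & (latency_ms < self.a_end)] = "A"
        out[(latency_ms >= self.a_end) & (latency_ms < self.c_end)] = "C"
        out[(latency_ms >= self.c_end) & (latency_ms < self.pd_end)] = "PD"
        return out


@dataclass(frozen=True)
class BandCounts:
    """Spike counts split by latency band."""

    per_stimulus: pd.DataFrame  # index stimulus 1..n, columns A, C, PD
    totals: dict[str, int]
    overflow: int

    @property
    def total_spikes(self) -> int:
        return sum(self.totals.values()) + self.overflow


@dataclass(frozen=True)
class RateConstantFit:
    """One-phase association fit to per-stimulus counts."""

    k: float
    plateau: float
    y0: float
    converged: bool
    flat: bool = False
    message: str = ""


@dataclass(frozen=True)
class WindupResult:
    """Complete wind-up summary for one neuron."""

    neuron_id: str
    per_stimulus_counts: np.ndarray
    band_totals: dict[str, int]
    overflow: int
    input: float
    windup: float
    rate_fit: RateConstantFit | None


def band_counts(
    table: pd.DataFrame,
    bands: LatencyBands,
    n_stimuli: int = 16,
) -> BandCounts:
    """Count spikes per stimulus and latency band.

    ``table`` needs columns ``stimulus_index`` (1-based) and
    ``latency_ms``.  Latencies outside ``[0, pd_end)`` are excluded from
    the bands but reported as ``overflow`` so that the total spike count
    is conserved.
    """
    required = {"stimulus_index", "latency_ms"}
    missing = required - set(table.columns)
    if missing:
        raise ShapeError(f"spike table missing columns: {sorted(missing)}")
    idx = pd.RangeIndex(1, n_stimuli + 1, name="stimulus_index")
    per_stim = pd.DataFrame(0, index=idx, columns=list(BAND_ORDER))
    overflow = 0
    if len(table):
        stim = table["stimulus_index"].to_numpy()
        if stim.min() < 1 or stim.max() > n_stimuli:
            raise ParameterError("stimulus_index outside 1..n_stimuli")
        labels = bands.assign(table["latency_ms"].to_numpy())
        for band in BAND_ORDER:
            sel = stim[labels == band]
            if sel.size:
                counts = pd.Series(sel).value_counts()
                per_stim.loc[counts.index, band] += counts.to_numpy()
        overflow = int((labels == "overflow").sum())
    totals = {band: int(per_stim[band].sum()) for band in BAND_ORDER}
    return BandCounts(per_stimulus=per_stim, totals=totals, overflow=overflow)


def input_windup(per_stimulus_counts: Sequence[float]) -> tuple[float, float]:
    """Input and wind-up from per-stimulus spike counts.

    ``Input = counts[first] * n``; ``wind-up = sum(counts) - Input``.
    Wind-up can be negative when the response habituates.
    """
    counts = np.asarray(per_stimulus_counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ShapeError("per_stimulus_counts must be a non-empty 1-D sequence")
    n = counts.size
    inp = float(counts[0] * n)
    windup = float(counts.sum() - inp)
    return inp, windup


def _growth(i: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * (i - 1.0)))


def fit_rate_constant(per_stimulus_counts: Sequence[float]) -> RateConstantFit:
    """Fit the one-phase association growth law to per-stimulus counts.

    ``y(i) = y0 + (plateau - y0) * (1 - exp(-k * (i - 1)))`` with 1-based
    stimulus index, so ``y(1) = y0`` exactly.  Initial values: y0 at the
    first count, plateau at the mean of the last three counts, k at 0.3.
    A flat train leaves k unidentifiable; it is reported as 0 with the
    ``flat`` flag set instead of raising.
    """
    counts = np.asarray(per_stimulus_counts, dtype=float)
    if counts.size < 4:
        raise ParameterError("need at least 4 stimuli to fit a rate constant")
    i = np.arange(1, counts.size + 1, dtype=float)
    if np.allclose(counts, counts[0]):
        return RateConstantFit(
            k=0.0, plateau=float(counts[0]), y0=float(counts[0]),
            converged=True, flat=True, message="flat counts: k unidentifiable",
        )
    p0 = (float(counts[0]), float(counts[-3:].mean()), 0.3)
    try:
        popt, _ = curve_fit(_growth, i, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return RateConstantFit(
            k=float("nan"), plateau=float("nan"), y0=float("nan"),
            converged=False, message=f"no convergence: {exc}",
        )
    y0, plateau, k = (float(v) for v in popt)
    return RateConstantFit(k=k, plateau=plateau, y0=y0, converged=True)


def analyze_neuron(
    table: pd.DataFrame,
    neuron_id: str = "neuron",
    n_stimuli: int = 16,
    isi_s: float = 5.0,
    bands: LatencyBands | None = None,
    fit_curve: bool = True,
) -> WindupResult:
    """Full wind-up analysis of one neuron's spike table."""
    if bands is None:
        bands = LatencyBands.for_isi(isi_s)
    bc = band_counts(table, bands, n_stimuli=n_stimuli)
    counts = bc.per_stimulus.sum(axis=1).to_numpy(dtype=float)
    inp, wu = input_windup(counts)
    fit = fit_rate_constant(counts) if fit_curve and counts.size >= 4 else None
    return WindupResult(
        neuron_id=neuron_id,
        per_stimulus_counts=counts,
        band_totals=bc.totals,
        overflow=bc.overflow,
        input=inp,
        windup=wu,
        rate_fit=fit,
    )


def receptive_field_positive(
    spike_count: float, window: float = 5.0, rate_threshold: float = 30.0
) -> bool:
    """Receptive-field criterion: strictly more than 30 spikes over 5 s.

    For a different observation window the threshold scales
    proportionally (e.g. 15 spikes over 2.5 s).
    """
    if spike_count < 0:
        raise ParameterError("spike_count must be >= 0")
    if window <= 0:
        raise ParameterError("window must be positive")
    return spike_count > rate_threshold * (window / 5.0)


#: Conduction-velocity bands in m/s, half-open lower-inclusive.
FIBER_VELOCITY_BANDS: dict[str, tuple[float, float]] = {
    "Abeta": (20.0, 100.0),
    "Adelta": (2.0, 20.0),
    "C": (0.05, 2.0),
}


def classify_fiber_velocity(distance_m: float, latency_s: float) -> str:
    """Fibre class from conduction distance and latency.

    Velocity = distance / latency; bands: A-beta [20, 100) m/s, A-delta
    [2, 20) m/s, C [0.05, 2) m/s; anything outside is 'unclassified'.
    """
    if distance_m <= 0 or latency_s <= 0:
        raise ParameterError("distance and latency must be positive")
    v = distance_m / latency_s
    for name, (lo, hi) in FIBER_VELOCITY_BANDS.items():
        if lo <= v < hi:
            return name
    return "unclassified"
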