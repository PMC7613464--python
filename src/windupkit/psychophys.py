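"""Psychophysical wind-up ratio, up-down threshold and normality tuning.

Human temporal summation is quantified by the wind-up ratio (WUR): the
mean pain rating (0-100 numerical scale) for a 1 Hz train of 10 punctate
stimuli divided by the mean rating for a single identical stimulus, each
averaged over five repeats.  Records with WUR > 6 are excluded as
phenotypic outliers (such values arise almost exclusively from near-zero
single-stimulus ratings).

Rodent mechanical sensitivity uses the up-down method: von Frey filaments
from a logarithmic ladder are applied sequentially, stepping down after a
withdrawal and up after none; the 50% withdrawal threshold is
``10 ** (X_f + k * delta)`` grams, where X_f is log10 of the final force,
delta the mean log10 ladder spacing and k a pattern constant.  Here k is
obtained by maximum likelihood under the method's normal response-curve
model (response probability ``Phi((x - m) / delta)`` on the log10 scale),
which reproduces the tabulated-constant convention while covering every
admissible sequence; ladder-boundary runs return the ladder extreme.

For association analyses on the skewed WUR distribution, a Box-Cox power
transform is tuned by minimising the Lilliefors statistic (the
Kolmogorov-Smirnov distance to a normal with estimated mean and SD) over
a grid of exponents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from windupkit.errors import ParameterError, SequenceError

__all__ = [
    "WurRecord",
    "UpDownSequence",
    "BoxCoxResult",
    "compute_wur",
    "qc_exclude",
    "summarize_wur",
    "updown_threshold",
    "boxcox_transform",
    "boxcox_tune",
    "lilliefors_statistic",
    "WUR_EXCLUSION_MAX",
]

#: QC rule: records with WUR strictly above this are phenotypic outliers.
WUR_EXCLUSION_MAX = 6.0


@dataclass
class WurRecord:
    """One participant's ratings: five single-stimulus and five train means.

    Each train rating is already the mean over its 10-stimulus train.
    """

    participant_id: str
    single_ratings: np.ndarray
    train_ratings: np.ndarray
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.single_ratings = np.asarray(self.single_ratings, dtype=float)
        self.train_ratings = np.asarray(self.train_ratings, dtype=float)
        for name, arr in (("single", self.single_ratings), ("train", self.train_ratings)):
            if arr.ndim != 1 or arr.size < 1:
                raise ParameterError(f"{name} ratings must be a non-empty 1-D array")
            if np.any(arr < 0) or np.any(arr > 100):
                raise ParameterError(f"{name} ratings must lie in [0, 100]")


def compute_wur(record: WurRecord, method: str = "ratio_of_means") -> float | None:
    """Wind-up ratio of one record.

    ``ratio_of_means`` (default) divides the mean train rating by the mean
    single rating; ``mean_of_ratios`` averages the per-repeat ratios
    instead.  A zero mean single rating makes the ratio undefined: the
    record is flagged excluded and ``None`` is returned.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ParameterError(f"unknown WUR method {method!r}")
    mean_single = float(record.single_ratings.mean())
    if mean_single <= 0:
        record.excluded = True
        record.exclusion_reason = "mean single rating is zero; WUR undefined"
        return None
    if method == "ratio_of_means":
        return float(record.train_ratings.mean()) / mean_single
    if np.any(record.single_ratings <= 0):
        record.excluded = True
        record.exclusion_reason = "zero single rating; per-repeat ratio undefined"
        return None
    if record.single_ratings.size != record.train_ratings.size:
        raise ParameterError("mean_of_ratios needs paired repeats")
    return float(np.mean(record.train_ratings / record.single_ratings))


def qc_exclude(
    records: Sequence[WurRecord],
    wur_max: float = WUR_EXCLUSION_MAX,
    method: str = "ratio_of_means",
) -> tuple[list[tuple[WurRecord, float]], list[tuple[WurRecord, float | None]]]:
    """Partition records into kept and excluded by the WUR outlier rule.

    A record is excluded when its WUR is undefined or strictly above
    ``wur_max`` (boundary values are kept).  Returns ``(kept, excluded)``
    as lists of ``(record, wur)`` pairs; no record is lost.
    """
    kept: list[tuple[WurRecord, float]] = []
    excluded: list[tuple[WurRecord, float | None]] = []
    for rec in records:
        wur = compute_wur(rec, method=method)
        if wur is None:
            excluded.append((rec, None))
        elif wur > wur_max:
            rec.excluded = True
            rec.exclusion_reason = f"WUR {wur:.3g} > {wur_max:g}"
            excluded.append((rec, wur))
        else:
            kept.append((rec, wur))
    return kept, excluded


def summarize_wur(kept: Sequence[tuple[WurRecord, float]]) -> dict[str, float]:
    """Median and IQR of WUR and of the single/train rating means.

    Quantiles use linear interpolation; IQR is Q3 - Q1.
    """
    if not kept:
        raise ParameterError("need at least one record to summarise")
    wurs = np.array([w for _, w in kept], dtype=float)
    singles = np.array([r.single_ratings.mean() for r, _ in kept])
    trains = np.array([r.train_ratings.mean() for r, _ in kept])

    def med_iqr(x: np.ndarray) -> tuple[float, float]:
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        return float(q2), float(q3 - q1)

    m, i = med_iqr(wurs)
    ms, is_ = med_iqr(singles)
    mt, it = med_iqr(trains)
    return {
        "n": int(wurs.size),
        "wur_median": m,
        "wur_iqr": i,
        "single_median": ms,
        "single_iqr": is_,
        "train_median": mt,
        "train_iqr": it,
    }


# ---------------------------------------------------------------------------
# Up-down 50% withdrawal threshold


@dataclass
class UpDownSequence:
    """A sequence of von Frey trials following the up-down transition rule.

    ``trials`` is an ordered list of ``(force_g, withdrew)``; every force
    must be a member of ``ladder`` (ascending filament forces in grams).
    """

    trials: list[tuple[float, bool]]
    ladder: tuple[float, ...] = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)

    def __post_init__(self) -> None:
        self.ladder = tuple(sorted(float(f) for f in self.ladder))
        if len(self.ladder) < 2:
            raise ParameterError("ladder needs at least two filaments")
        if not self.trials:
            raise SequenceError("empty up-down sequence")
        positions = []
        for force, resp in self.trials:
            try:
                positions.append(self.ladder.index(float(force)))
            except ValueError:
                raise SequenceError(f"force {force} g is not on the ladder") from None
        for j in range(1, len(positions)):
            prev_pos, prev_resp = positions[j - 1], self.trials[j - 1][1]
            step = positions[j] - prev_pos
            at_top = prev_pos == len(self.ladder) - 1
            at_bottom = prev_pos == 0
            if prev_resp:  # withdrawal -> step down (or stay at the bottom)
                ok = step == -1 or (at_bottom and step == 0)
            else:  # no response -> step up (or stay at the top)
                ok = step == 1 or (at_top and step == 0)
            if not ok:
                raise SequenceError(
                    f"trial {j + 1}: force moved {'up' if step > 0 else 'down or stayed'} "
                    f"after a {'withdrawal' if prev_resp else 'non-response'}"
                )
        self._positions = positions

    @property
    def log_spacing(self) -> float:
        """Mean log10 spacing of the filament ladder."""
        logs = np.log10(self.ladder)
        return float(np.mean(np.diff(logs)))


def _updown_k(sequence: UpDownSequence) -> float:
    """Pattern constant by maximum likelihood under the normal model.

    The withdrawal probability at log-force x is Phi((x - m) / delta) with
    delta the ladder spacing; k = (m_hat - X_f) / delta.
    """
    logs = np.log10([f for f, _ in sequence.trials])
    resp = np.array([r for _, r in sequence.trials], dtype=bool)
    delta = sequence.log_spacing
    x = logs / delta  # work in units of the ladder spacing
    lo = x.min() - 6.0
    hi = x.max() + 6.0

    def nll(m: float) -> float:
        z = x - m
        logp = stats.norm.logcdf(z)
        logq = stats.norm.logcdf(-z)
        return -float(np.sum(np.where(resp, logp, logq)))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    x_f = x[-1]
    return float(res.x - x_f)


def updown_threshold(sequence: UpDownSequence) -> float:
    """50% withdrawal threshold in grams.

    ``10 ** (X_f + k * delta)`` with X_f the log10 of the final filament
    force, delta the mean log10 ladder spacing and k the pattern constant.
    Runs that pin to a ladder boundary (never withdrawing up to the
    heaviest filament, or always withdrawing down to the lightest) return
    the corresponding ladder extreme.
    """
    responses = [r for _, r in sequence.trials]
    positions = sequence._positions
    if not any(responses) and positions[-1] == len(sequence.ladder) - 1:
        return sequence.ladder[-1]
    if all(responses) and positions[-1] == 0:
        return sequence.ladder[0]
    if len(set(responses)) == 1:
        # Monotone run that did not reach a boundary: the MLE diverges in
        # the run's direction; report the final force as the best bracket.
        return sequence.trials[-1][0]
    k = _updown_k(sequence)
    x_f = math.log10(sequence.trials[-1][0])
    thr = 10.0 ** (x_f + k * sequence.log_spacing)
    return float(np.clip(thr, sequence.ladder[0], sequence.ladder[-1]))


# ---------------------------------------------------------------------------
# Box-Cox tuning by the Lilliefors statistic


@dataclass(frozen=True)
class BoxCoxResult:
    """Outcome of grid-search Box-Cox tuning."""

    lmbda: float
    lilliefors_statistic: float
    grid: np.ndarray
    statistics: np.ndarray
    transformed: np.ndarray


def boxcox_transform(values: np.ndarray, lmbda: float) -> np.ndarray:
    """Box-Cox power transform: ``(x**l - 1) / l``, or ``ln x`` at l = 0."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ParameterError("Box-Cox requires strictly positive values")
    if abs(lmbda) < 1e-12:
        return np.log(values)
    return (values**lmbda - 1.0) / lmbda


def lilliefors_statistic(
    values: Sequence[float],
    mc_reps: int | None = None,
    seed: int | None = None,
) -> float | tuple[float, float]:
    """Kolmogorov-Smirnov distance to a normal with estimated parameters.

    ``D = sup |ECDF(x) - Phi((x - mean) / sd)|`` with mean and sd (ddof=1)
    estimated from the sample.  With ``mc_reps`` a Monte-Carlo p-value is
    also returned, computed by re-running the same statistic on simulated
    standard-normal samples of equal size (the parameter-estimation step
    included, as the Lilliefors correction requires).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 5:
        raise ParameterError("need at least 5 observations")

    def stat(sample: np.ndarray) -> float:
        s = np.sort(sample)
        mu = s.mean()
        sd = s.std(ddof=1)
        if sd == 0:
            return 1.0
        z = stats.norm.cdf((s - mu) / sd)
        i = np.arange(1, s.size + 1)
        d_plus = np.max(i / s.size - z)
        d_minus = np.max(z - (i - 1) / s.size)
        return float(max(d_plus, d_minus))

    d = stat(x)
    if mc_reps is None:
        return d
    if mc_reps < 1:
        raise ParameterError("mc_reps must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.standard_normal(n)) for _ in range(mc_reps)])
    p = float((1 + np.sum(null >= d)) / (mc_reps + 1))
    return d, p


def boxcox_tune(
    values: Sequence[float],
    grid: Sequence[float] | None = None,
) -> BoxCoxResult:
    """Pick the Box-Cox exponent whose transform looks most normal.

    Each grid exponent is scored by the Lilliefors statistic of the
    transformed sample; the minimiser wins, with ties resolved toward the
    exponent closest to 1 (the identity family).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ParameterError("Box-Cox requires strictly positive values")
    if grid is None:
        grid = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty search grid")
    ds = np.array([lilliefors_statistic(boxcox_transform(x, lam)) for lam in grid])
    best = ds.min()
    candidates = np.flatnonzero(np.isclose(ds, best, rtol=0, atol=1e-12))
    winner = candidates[np.argmin(np.abs(grid[candidates] - 1.0))]
    lam = float(grid[winner])
    return BoxCoxResult(
        lmbda=lam,
        lilliefors_statistic=float(ds[winner]),
        grid=grid,
        statistics=ds,
        transformed=boxcox_transform(x, lam),
    )
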