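"""Readers and writers for the package's long-format CSV schemas.

Schemas (version 1):

* traces:  ``trace_id, cohort, t_s, value`` — one row per sample.
* spikes:  ``neuron_id, stimulus_index, latency_ms`` — one row per spike.
* ratings: ``participant_id, repeat, kind, rating`` with
  ``kind`` in {single, train} — one row per rating.

All files are UTF-8 CSV with a header row.  Readers validate columns and
types and raise :class:`~windupkit.errors.FormatError` naming the
offending column; an empty file with a header yields an empty collection.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from windupkit.errors import FormatError
from windupkit.psychophys import WurRecord
from windupkit.trace_qc import RatioTrace

__all__ = [
    "SCHEMA_VERSION",
    "write_traces_csv",
    "read_traces_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_ratings_csv",
    "read_ratings_csv",
]

SCHEMA_VERSION = 1

_TRACE_COLUMNS = ["trace_id", "cohort", "t_s", "value"]
_SPIKE_COLUMNS = ["neuron_id", "stimulus_index", "latency_ms"]
_RATING_COLUMNS = ["participant_id", "repeat", "kind", "rating"]


def _read_csv(path: str | Path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"{path}: non-numeric value in column '{col}' at row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise FormatError(f"{path}: missing value in column '{col}' at row {row}")
        df[col] = coerced
    return df


def write_traces_csv(traces: Iterable[RatioTrace], path: str | Path) -> None:
    """Write traces in long format, one row per sample, row order preserved."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.cell_id,
                    "cohort": tr.cohort,
                    "t_s": tr.t,
                    "value": tr.value,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_traces_csv(path: str | Path) -> list[RatioTrace]:
    """Read a long-format trace CSV back into :class:`RatioTrace` objects.

    Rows are grouped by ``trace_id`` in order of first appearance; each
    trace's samples keep their file order and must be uniformly spaced.
    """
    df = _read_csv(path, _TRACE_COLUMNS, ["t_s", "value"])
    traces: list[RatioTrace] = []
    if df.empty:
        return traces
    for trace_id, grp in df.groupby("trace_id", sort=False):
        cohorts = grp["cohort"].unique()
        if len(cohorts) != 1:
            raise FormatError(f"trace {trace_id}: inconsistent cohort labels {list(cohorts)}")
        try:
            traces.append(
                RatioTrace(
                    cell_id=str(trace_id),
                    cohort=str(cohorts[0]),
                    t=grp["t_s"].to_numpy(),
                    value=grp["value"].to_numpy(),
                )
            )
        except FormatError:
            raise
    return traces


def write_spikes_csv(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes.loc[:, _SPIKE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_spikes_csv(path: str | Path) -> pd.DataFrame:
    """Read a spike table; returns columns neuron_id, stimulus_index, latency_ms."""
    df = _read_csv(path, _SPIKE_COLUMNS, ["stimulus_index", "latency_ms"])
    if not df.empty:
        if (df["stimulus_index"] % 1 != 0).any():
            raise FormatError(f"{path}: stimulus_index must be integer")
        df["stimulus_index"] = df["stimulus_index"].astype(int)
        if (df["latency_ms"] < 0).any():
            row = int((df["latency_ms"] < 0).idxmax())
            raise FormatError(f"{path}: negative latency_ms at row {row}")
    return df.loc[:, _SPIKE_COLUMNS]


def write_ratings_csv(records: Iterable[WurRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for r, v in enumerate(rec.single_ratings, start=1):
            rows.append((rec.participant_id, r, "single", v))
        for r, v in enumerate(rec.train_ratings, start=1):
            rows.append((rec.participant_id, r, "train", v))
    pd.DataFrame(rows, columns=_RATING_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_ratings_csv(path: str | Path) -> list[WurRecord]:
    """Read a ratings CSV into per-participant records.

    Every participant needs at least one ``single`` and one ``train``
    rating; ``kind`` values other than single/train are a format error.
    """
    df = _read_csv(path, _RATING_COLUMNS, ["repeat", "rating"])
    records: list[WurRecord] = []
    if df.empty:
        return records
    bad_kind = ~df["kind"].isin(["single", "train"])
    if bad_kind.any():
        row = int(bad_kind.idxmax())
        raise FormatError(f"{path}: unknown kind {df['kind'].iloc[row]!r} at row {row}")
    for pid, grp in df.groupby("participant_id", sort=False):
        single = grp.loc[grp["kind"] == "single"].sort_values("repeat")["rating"].to_numpy()
        train = grp.loc[grp["kind"] == "train"].sort_values("repeat")["rating"].to_numpy()
        if single.size == 0 or train.size == 0:
            raise FormatError(f"participant {pid}: needs both single and train ratings")
        records.append(
            WurRecord(participant_id=str(pid), single_ratings=single, train_ratings=train)
        )
    return records
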