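"""Configuration and end-to-end orchestration of the analysis stages.

``run_pipeline`` simulates a seeded data bundle (or consumes files written
by the ``simulate`` stage), then runs the in vitro QC -> metrics chain,
the in vivo dF/F -> response-call chain, the wind-up spike analysis and
the WUR psychophysics, writing one CSV per stage plus a JSON manifest
that records every threshold, convention and version used, so a run can
be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import windupkit
from windupkit import calcium_metrics, dff_invivo, io as wio, psychophys, synthgen, trace_qc, windup_ephys
from windupkit.errors import ConfigError

__all__ = ["PipelineConfig", "run_pipeline", "simulate_bundle"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds, conventions and seeds of one pipeline run."""

    seed: int = 0
    snr_threshold: float = 1.0
    tau_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(calcium_metrics.TAU_OUTLIER_THRESHOLDS)
    )
    baseline_window_s: float = 15.0
    peak_mode: str = "at_fixed_times"
    wur_max: float = psychophys.WUR_EXCLUSION_MAX
    wur_method: str = "ratio_of_means"
    band_a_end_ms: float = 50.0
    band_c_end_ms: float = 250.0
    band_pd_end_ms: float | None = None  # None -> inter-stimulus interval
    n_cells_invitro: int = 120
    n_rois_invivo: int = 20
    n_neurons_windup: int = 12
    n_participants: int = 300
    outlier_fraction: float = 0.05
    dff_frequency_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.snr_threshold < 0:
            raise ConfigError("snr_threshold must be >= 0")
        for cohort, thr in self.tau_thresholds.items():
            if thr <= 0:
                raise ConfigError(f"tau threshold for {cohort} must be positive")
        if self.wur_max <= 0:
            raise ConfigError("wur_max must be positive")
        if self.baseline_window_s <= 0:
            raise ConfigError("baseline_window_s must be positive")
        if not 0 < self.band_a_end_ms < self.band_c_end_ms:
            raise ConfigError("latency bands must satisfy 0 < A end < C end")
        if self.peak_mode not in ("at_fixed_times", "window_max"):
            raise ConfigError(f"unknown peak_mode {self.peak_mode!r}")
        if self.wur_method not in ("ratio_of_means", "mean_of_ratios"):
            raise ConfigError(f"unknown wur_method {self.wur_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def simulate_bundle(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate and write the four synthetic input tables for one seed."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    traces, trace_truth = synthgen.gen_ratio_traces(
        synthgen.TraceSimParams(n_cells=config.n_cells_invitro, seed=config.seed)
    )
    paths["traces"] = outdir / "traces.csv"
    wio.write_traces_csv(traces, paths["traces"])
    trace_truth.to_csv(outdir / "traces_truth.csv", index=False)

    spike_frames = []
    truth_frames = []
    rng = np.random.default_rng(config.seed + 1)
    for j in range(config.n_neurons_windup):
        params = synthgen.WindupSimParams(seed=int(rng.integers(2**31 - 1)))
        spikes, truth = synthgen.gen_spike_table(params, neuron_id=f"neuron{j:03d}")
        spike_frames.append(spikes)
        truth_frames.append(truth.assign(neuron_id=f"neuron{j:03d}"))
    paths["spikes"] = outdir / "spikes.csv"
    wio.write_spikes_csv(pd.concat(spike_frames, ignore_index=True), paths["spikes"])
    pd.concat(truth_frames, ignore_index=True).to_csv(outdir / "spikes_truth.csv", index=False)

    records, wur_truth = synthgen.gen_wur_cohort(
        synthgen.WurSimParams(
            n_participants=config.n_participants,
            outlier_fraction=config.outlier_fraction,
            seed=config.seed + 2,
        )
    )
    paths["ratings"] = outdir / "ratings.csv"
    wio.write_ratings_csv(records, paths["ratings"])
    wur_truth.to_csv(outdir / "ratings_truth.csv", index=False)
    return paths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage on a freshly simulated seeded bundle.

    Writes stage outputs and ``manifest.json`` under ``outdir`` and
    returns the manifest.  Identical config (including seed) produces
    bit-identical outputs.
    """
    outdir = Path(outdir)
    inputs = simulate_bundle(config, outdir / "inputs")

    # --- in vitro: QC then kinetic metrics -------------------------------
    traces = wio.read_traces_csv(inputs["traces"])
    schedule = trace_qc.PulseSchedule()
    kept, discarded, qc_summary = trace_qc.filter_reliable(
        traces, schedule, threshold=config.snr_threshold
    )
    wio.write_traces_csv(kept, outdir / "qc_kept.csv")
    wio.write_traces_csv(discarded, outdir / "qc_discarded.csv")

    metric_rows = []
    start_baselines = {
        tr.cell_id: calcium_metrics.extract_baselines(
            tr, schedule, window=config.baseline_window_s
        )[0]
        for tr in kept
    }
    cohort_ref = float(np.mean(list(start_baselines.values()))) if kept else 0.0
    for tr in kept:
        m = calcium_metrics.compute_epoch_metrics(
            tr,
            schedule,
            reference=cohort_ref,
            baseline_window=config.baseline_window_s,
            peak_mode=config.peak_mode,
        )
        for p in range(schedule.n_pulses):
            fit = m.tau_fits[p]
            metric_rows.append(
                dict(
                    cell_id=m.cell_id,
                    cohort=m.cohort,
                    pulse=p + 1,
                    baseline_before=m.baselines[p],
                    peak=m.peaks[p],
                    auc=m.auc[p],
                    tau=fit.tau if fit.converged else np.nan,
                    fit_converged=fit.converged,
                )
            )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(outdir / "metrics.csv", index=False)

    # --- in vivo: dF/F and response calls --------------------------------
    recording, _ = synthgen.gen_dff_recording(
        freq=config.dff_frequency_hz,
        n_cells=config.n_rois_invivo,
        seed=config.seed + 3,
    )
    calls = dff_invivo.call_train_responses(recording)
    calls.to_csv(outdir / "dff_calls.csv", index=False)
    per_animal, per_cohort = dff_invivo.summarize_animals(calls)
    per_animal.to_csv(outdir / "dff_per_animal.csv", index=False)

    # --- wind-up electrophysiology ---------------------------------------
    spikes = wio.read_spikes_csv(inputs["spikes"])
    isi_s = 2.0
    pd_end = config.band_pd_end_ms if config.band_pd_end_ms is not None else isi_s * 1000.0
    bands = windup_ephys.LatencyBands(
        a_end=config.band_a_end_ms, c_end=config.band_c_end_ms, pd_end=pd_end
    )
    windup_rows = []
    for neuron_id, grp in spikes.groupby("neuron_id", sort=True):
        res = windup_ephys.analyze_neuron(grp, neuron_id=str(neuron_id), isi_s=isi_s, bands=bands)
        windup_rows.append(
            dict(
                neuron_id=res.neuron_id,
                input=res.input,
                windup=res.windup,
                total_spikes=float(res.per_stimulus_counts.sum()),
                a_total=res.band_totals["A"],
                c_total=res.band_totals["C"],
                pd_total=res.band_totals["PD"],
                overflow=res.overflow,
                rate_constant=res.rate_fit.k if res.rate_fit and res.rate_fit.converged else np.nan,
                plateau=res.rate_fit.plateau if res.rate_fit and res.rate_fit.converged else np.nan,
            )
        )
    windup_df = pd.DataFrame(windup_rows)
    windup_df.to_csv(outdir / "windup.csv", index=False)

    # --- psychophysics ----------------------------------------------------
    records = wio.read_ratings_csv(inputs["ratings"])
    kept_wur, excluded_wur = psychophys.qc_exclude(
        records, wur_max=config.wur_max, method=config.wur_method
    )
    wur_df = pd.DataFrame(
        [
            dict(participant_id=r.participant_id, wur=w, excluded=False)
            for r, w in kept_wur
        ]
        + [
            dict(participant_id=r.participant_id, wur=w, excluded=True)
            for r, w in excluded_wur
        ]
    )
    wur_df.to_csv(outdir / "wur.csv", index=False)
    wur_summary = psychophys.summarize_wur(kept_wur)

    manifest = {
        "package": "windupkit",
        "version": windupkit.__version__,
        "schema_version": wio.SCHEMA_VERSION,
        "config": _jsonable(dataclasses.asdict(config)),
        "conventions": {
            "snr": "explainable variance of repeat mean / (pooled - explainable); population variances; strict > threshold",
            "variance_decomposition": "pooled over all repeats about the grand mean",
            "peak_mode": config.peak_mode,
            "auc_reference": "cohort mean of start baselines",
            "tau_normalisation": "segment shifted so final decay value is 0",
            "band_intervals": "half-open, lower-inclusive; PD upper bound = inter-stimulus interval"
            if config.band_pd_end_ms is None
            else f"half-open, lower-inclusive; PD upper bound = {config.band_pd_end_ms} ms",
            "pd_end_ms_used": pd_end,
            "response_window": "train span + ISI + 5 s after first stimulus",
            "wur": config.wur_method,
            "iqr": "linear-interpolation quantiles (type 7)",
        },
        "summaries": {
            "qc": qc_summary,
            "n_metric_rows": int(len(metrics_df)),
            "dff_cohort": _jsonable(per_cohort.to_dict(orient="records")),
            "n_neurons": int(len(windup_df)),
            "wur": _jsonable(wur_summary),
            "n_wur_excluded": int(len(excluded_wur)),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
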