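"""Generators must match their closed-form models and be seed-deterministic."""

import numpy as np
import pandas as pd
import pytest

from windupkit import synthgen
from windupkit.errors import ParameterError
from windupkit.synthgen import (
    TraceSimParams,
    TransientParams,
    WindupSimParams,
    WurSimParams,
    gen_dff_recording,
    gen_ratio_traces,
    gen_spike_table,
    gen_wur_cohort,
    windup_growth_law,
)


class TestRatioTraces:
    def test_noiseless_responder_matches_exponential_decay(self):
        params = TraceSimParams(
            n_cells=1, responder_fraction=1.0, dying_fraction=0.0,
            noise_sd=0.0, peak_amplitude_mean=1.0, peak_amplitude_sd=0.0,
            tau_mean=20.0, tau_sd=0.0, baseline_level=0.5, seed=1,
        )
        traces, truth = gen_ratio_traces(params)
        tr = traces[0]
        # peak of pulse 1 is at 90 s; 30 s later the decay gives e^{-30/20}
        i_peak = tr.index_at(90.0)
        assert tr.value[i_peak] == pytest.approx(0.5 + 1.0)
        assert tr.value[tr.index_at(120.0)] == pytest.approx(0.5 + np.exp(-30 / 20))
        assert truth.loc[0, "tau"] == pytest.approx(20.0)

    def test_zero_responder_fraction_gives_only_nonresponders(self):
        params = TraceSimParams(n_cells=30, responder_fraction=0.0, dying_fraction=0.0, seed=3)
        _, truth = gen_ratio_traces(params)
        assert (truth["cell_class"] == "nonresponder").all()

    def test_dying_cells_stay_elevated_after_first_pulse(self):
        params = TraceSimParams(
            n_cells=10, responder_fraction=0.0, dying_fraction=1.0,
            noise_sd=0.0, peak_amplitude_sd=0.0, seed=2,
        )
        traces, truth = gen_ratio_traces(params)
        assert (truth["cell_class"] == "dying").all()
        tr = traces[0]
        after_first_peak = tr.value[tr.index_at(90.0):]
        assert np.all(after_first_peak == after_first_peak[0])
        assert after_first_peak[0] > params.baseline_level

    def test_same_seed_bit_identical_different_seed_differs(self):
        a1, t1 = gen_ratio_traces(TraceSimParams(n_cells=5, seed=7))
        a2, t2 = gen_ratio_traces(TraceSimParams(n_cells=5, seed=7))
        b, _ = gen_ratio_traces(TraceSimParams(n_cells=5, seed=8))
        pd.testing.assert_frame_equal(t1, t2)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.value, y.value)
        assert any(not np.array_equal(x.value, y.value) for x, y in zip(a1, b))

    def test_one_truth_row_per_cell(self):
        traces, truth = gen_ratio_traces(TraceSimParams(n_cells=17, seed=0))
        assert len(traces) == len(truth) == 17

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(responder_fraction=1.2),
            dict(noise_sd=-0.1),
            dict(tau_mean=-5.0),
            dict(n_cells=0),
            dict(responder_fraction=0.8, dying_fraction=0.5),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            TraceSimParams(**kwargs)


class TestDffRecording:
    def test_zero_amplitude_responder_is_flat(self):
        tp = TransientParams(amplitude_mean=0.0, amplitude_sd=0.0, noise_sd=0.0)
        rec, truth = gen_dff_recording(
            freq=0.5, n_cells=3, responder_fraction=1.0, transient_params=tp, seed=0
        )
        for trace in rec.roi_traces.values():
            assert np.allclose(trace, trace[0])

    def test_slow_transients_summate_at_1hz(self):
        # decay slower than the 1 s ISI: the response after pulse 16 exceeds pulse 1
        tp = TransientParams(amplitude_mean=0.3, amplitude_sd=0.0, decay_tau_s=3.0, noise_sd=0.0)
        rec, _ = gen_dff_recording(
            freq=1.0, n_cells=1, responder_fraction=1.0, transient_params=tp, seed=0
        )
        trace = next(iter(rec.roi_traces.values()))
        t = rec.t
        after_p1 = trace[(t >= rec.stim_times[0]) & (t < rec.stim_times[1])].max()
        after_p16 = trace[t >= rec.stim_times[-1]].max()
        assert after_p16 > after_p1

    def test_baseline_and_stimulus_layout(self):
        rec, truth = gen_dff_recording(freq=0.5, n_cells=4, seed=1)
        assert rec.stim_times[0] == pytest.approx(120.0)
        assert len(rec.stim_times) == 16
        assert np.allclose(np.diff(rec.stim_times), 2.0)
        assert len(truth) == 4

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ParameterError):
            gen_dff_recording(freq=0.0, n_cells=1)

    def test_seed_reproducibility(self):
        r1, _ = gen_dff_recording(freq=0.5, n_cells=3, seed=5)
        r2, _ = gen_dff_recording(freq=0.5, n_cells=3, seed=5)
        for roi in r1.roi_traces:
            np.testing.assert_array_equal(r1.roi_traces[roi], r2.roi_traces[roi])


class TestSpikeTable:
    def test_flat_growth_with_zero_rate_constant(self):
        params = WindupSimParams(
            first_pulse_count=12, plateau=50, rate_constant=0.0, count_noise=0.0, seed=0
        )
        _, truth = gen_spike_table(params)
        assert (truth["realized_count"] == 12).all()

    def test_growth_law_value_at_stimulus_three(self):
        # y(3) = 10 + 40 (1 - e^{-1}) = 35.28..., rounded to 35 under the count model
        params = WindupSimParams(
            first_pulse_count=10, plateau=50, rate_constant=0.5, count_noise=0.0, seed=0
        )
        spikes, truth = gen_spike_table(params)
        expected = 10 + 40 * (1 - np.exp(-1.0))
        assert truth.loc[2, "expected_count"] == pytest.approx(expected)
        assert truth.loc[2, "realized_count"] == round(expected)
        # spike rows agree with realised counts
        counts = spikes.groupby("stimulus_index").size()
        assert counts.loc[3] == round(expected)

    def test_pure_a_band_fractions_bound_latencies(self):
        params = WindupSimParams(band_fractions=(1.0, 0.0, 0.0), seed=4)
        spikes, _ = gen_spike_table(params)
        assert (spikes["latency_ms"] < 50.0).all()

    def test_latencies_respect_isi_bound(self):
        params = WindupSimParams(band_fractions=(0.1, 0.3, 0.6), isi=2.0, seed=9)
        spikes, _ = gen_spike_table(params)
        assert (spikes["latency_ms"] < 2000.0).all()

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ParameterError):
            WindupSimParams(plateau=-1.0)

    def test_determinism(self):
        s1, t1 = gen_spike_table(WindupSimParams(seed=3))
        s2, t2 = gen_spike_table(WindupSimParams(seed=3))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)


class TestWurCohort:
    def test_degenerate_lognormal_gives_unit_wur(self):
        params = WurSimParams(n_participants=20, log_wur_mean=0.0, log_wur_sd=0.0, seed=0)
        _, truth = gen_wur_cohort(params)
        assert np.allclose(truth["true_wur"], 1.0)

    def test_outlier_fraction_recovered(self):
        params = WurSimParams(n_participants=1000, outlier_fraction=0.1, seed=11)
        records, truth = gen_wur_cohort(params)
        from windupkit.psychophys import compute_wur

        wurs = np.array([compute_wur(r) for r in records])
        frac = float(np.mean(wurs > 6.0))
        # binomial 3-sigma band around 0.1 at n=1000
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 1000)
        assert truth["is_outlier"].mean() == pytest.approx(frac, abs=0.03)

    def test_determinism(self):
        r1, t1 = gen_wur_cohort(WurSimParams(n_participants=10, seed=2))
        r2, t2 = gen_wur_cohort(WurSimParams(n_participants=10, seed=2))
        pd.testing.assert_frame_equal(t1, t2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.single_ratings, b.single_ratings)
            np.testing.assert_array_equal(a.train_ratings, b.train_ratings)


def test_growth_law_closed_form():
    i = np.arange(1, 17)
    y = windup_growth_law(i, 10.0, 50.0, 0.5)
    assert y[0] == pytest.approx(10.0)
    assert y[-1] == pytest.approx(50.0, rel=0.01)
    assert np.all(np.diff(y) > 0)
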