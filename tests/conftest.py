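import numpy as np
import pytest

from windupkit.trace_qc import PulseSchedule, RatioTrace


@pytest.fixture
def schedule() -> PulseSchedule:
    return PulseSchedule()


def make_responder_trace(
    baseline: float = 0.5,
    amplitude: float = 1.0,
    tau: float = 20.0,
    schedule: PulseSchedule | None = None,
    cell_id: str = "cell",
    cohort: str = "DH",
) -> RatioTrace:
    """Noiseless three-pulse trace: linear ramp to peak, exponential decay."""
    if schedule is None:
        schedule = PulseSchedule()
    n = int(round(schedule.recording_length / schedule.sample_interval))
    t = np.arange(n) * schedule.sample_interval
    v = np.full(n, baseline)
    for p, onset in enumerate(schedule.pulse_onsets):
        offset = onset + schedule.pulse_duration
        end = (
            schedule.pulse_onsets[p + 1]
            if p + 1 < schedule.n_pulses
            else t[-1] + schedule.sample_interval
        )
        rising = (t >= onset) & (t < offset)
        v[rising] = baseline + amplitude * (t[rising] - onset) / schedule.pulse_duration
        decay = (t >= offset) & (t < end)
        v[decay] = baseline + amplitude * np.exp(-(t[decay] - offset) / tau)
    return RatioTrace(cell_id=cell_id, cohort=cohort, t=t, value=v)


@pytest.fixture
def responder_trace() -> RatioTrace:
    return make_responder_trace()
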