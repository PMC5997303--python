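import numpy as np
import pytest

from fastspike.sweep_model import Recording, RecordingMode, Sweep


def make_sweep(
    samples,
    rate=10_000.0,
    onset=100.0,
    duration=500.0,
    amplitude=0.0,
    mode=RecordingMode.CURRENT_CLAMP,
):
    return Sweep(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=rate,
        stimulus_onset=onset,
        stimulus_duration=duration,
        stimulus_amplitude=amplitude,
        mode=mode,
    )


def step_sweep(
    baseline, deflection, rate=10_000.0, onset=100.0, duration=500.0,
    post=100.0, amplitude=-100.0, tau=None,
):
    """Current-clamp step response: instant (tau=None) or exponential."""
    dt = 1000.0 / rate
    n = int(round((onset + duration + post) / dt))
    t = np.arange(n) * dt
    v = np.full(n, baseline, dtype=float)
    on = t >= onset
    off = t >= onset + duration
    if tau is None:
        v[on] = baseline + deflection
    else:
        v[on] = baseline + deflection * (1.0 - np.exp(-(t[on] - onset) / tau))
    v[off] = baseline
    return make_sweep(v, rate, onset, duration, amplitude)


def triangle_spike(v, t_ms, peak_t, rise_ms, peak_v, fall_ms=None, base=None):
    """Paint a triangular spike onto trace ``v`` in place."""
    if fall_ms is None:
        fall_ms = rise_ms
    if base is None:
        base = v[0]
    up = (t_ms >= peak_t - rise_ms) & (t_ms <= peak_t)
    down = (t_ms > peak_t) & (t_ms <= peak_t + fall_ms)
    v[up] = base + (peak_v - base) * (1.0 - (peak_t - t_ms[up]) / rise_ms)
    v[down] = base + (peak_v - base) * (1.0 - (t_ms[down] - peak_t) / fall_ms)
    return v


@pytest.fixture
def flat_recording():
    sweeps = [make_sweep(np.full(7000, -66.0)) for _ in range(2)]
    return Recording(sweeps=sweeps, cell_id="flat")
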