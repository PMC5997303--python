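"""Action-potential detection and single-AP / train-level feature extraction.

Spike detection is derivative-gated peak finding: a local maximum qualifies
if its peak exceeds -10 mV, the voltage derivative reached 20 V/s within the
preceding 2 ms, and it is at least 1 ms from the previously accepted spike.
The AP threshold is the membrane potential at which dV/dt first reaches
20 V/s on the upstroke; AP and fAHP amplitudes are measured relative to that
threshold.  The half-width is the duration at the voltage halfway between
threshold and peak, with linear interpolation between samples (0.1 ms
sampling is coarse relative to sub-millisecond fast-spiking half-widths).

Derivatives are forward differences at the native sampling interval, with no
smoothing: the forward difference localizes the onset of a fast upstroke at
the last sample before the supra-criterion interval, which is the sample a
manual cursor placement would pick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    MeasurementError,
    PreconditionError,
    ValidationError,
)
from .sweep_model import Recording, RecordingMode, Sweep

__all__ = [
    "SpikeFeatures",
    "TrainFeatures",
    "IfCurve",
    "detect_spikes",
    "ap_threshold",
    "ap_amplitude",
    "ap_half_width",
    "ap_latency",
    "fahp",
    "measure_spike",
    "first_evoked_ap",
    "ap_broadening",
    "max_firing_frequency",
    "if_curve",
    "accommodation_metrics",
    "train_features",
]

#: derivative criterion for threshold and detection, in V/s (= mV/ms)
DVDT_CRITERION = 20.0
#: minimum peak height for a detected AP, mV
PEAK_FLOOR = -10.0
#: detected peaks must be preceded by a supra-criterion derivative within this window, ms
RISE_LOOKBACK_MS = 2.0
#: minimum separation between detected APs, ms
MIN_SEPARATION_MS = 1.0
#: fAHP search window after the last spike of a train, ms
FAHP_LAST_SPIKE_WINDOW_MS = 10.0


@dataclass
class SpikeFeatures:
    """Features of a single action potential (voltages mV, times ms)."""

    threshold_v: float = float("nan")
    threshold_t: float = float("nan")
    peak_v: float = float("nan")
    peak_t: float = float("nan")
    amplitude: float = float("nan")
    half_width: float = float("nan")
    latency: float = float("nan")
    fahp_amplitude: float = float("nan")
    fahp_latency: float = float("nan")


@dataclass
class TrainFeatures:
    """Train-level features of one suprathreshold step."""

    spike_count: int
    firing_rate: float                       # Hz over the step window
    adaptation_ratio: float = float("nan")   # last-100ms rate / first-100ms rate
    amplitude_attenuation: float = float("nan")  # 1 - last/first mean amplitude


@dataclass
class IfCurve:
    """Population current-frequency curve (mean +/- sd across cells)."""

    currents: np.ndarray      # pA, ascending
    mean_rates: np.ndarray    # Hz
    sd_rates: np.ndarray      # Hz (nan where only one cell contributed)
    n_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "current_pa": self.currents,
                "rate_mean_hz": self.mean_rates,
                "rate_sd_hz": self.sd_rates,
                "n_cells": self.n_cells,
            }
        )


def _dvdt(sweep: Sweep) -> np.ndarray:
    """Forward-difference derivative in mV/ms (== V/s); last element repeated."""
    v = sweep.samples
    d = np.empty_like(v)
    d[:-1] = np.diff(v) / sweep.dt_ms
    d[-1] = d[-2] if v.size > 1 else 0.0
    return d


def detect_spikes(sweep: Sweep) -> list[tuple[float, float]]:
    """Detect action potentials; returns ``[(peak_t_ms, peak_v_mV), ...]``.

    Empty list for a silent sweep.
    """
    if sweep.mode is not RecordingMode.CURRENT_CLAMP:
        raise PreconditionError("spike detection requires a current-clamp sweep")
    v = sweep.samples
    if v.size < 3:
        return []
    # local maxima (plateau-tolerant on the left)
    cand = np.nonzero((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    cand = cand[v[cand] > PEAK_FLOOR]
    if cand.size == 0:
        return []
    d = _dvdt(sweep)
    lookback = max(1, int(round(RISE_LOOKBACK_MS / sweep.dt_ms)))
    min_sep = MIN_SEPARATION_MS
    out: list[tuple[float, float]] = []
    last_t = -np.inf
    for i in cand:
        t = i * sweep.dt_ms
        if t - last_t < min_sep:
            continue
        if not np.any(d[max(0, i - lookback):i] >= DVDT_CRITERION):
            continue
        out.append((t, float(v[i])))
        last_t = t
    return out


def ap_threshold(sweep: Sweep, spike: tuple[float, float]) -> tuple[float, float]:
    """AP threshold: membrane potential where dV/dt first reaches 20 V/s.

    Searches backward from the peak to the last sample whose derivative is
    below the criterion, then forward one sample.
    """
    peak_t, _ = spike
    i_peak = sweep.index_at(peak_t)
    d = _dvdt(sweep)
    # skip any sub-criterion samples at a rounded peak, back to the upstroke
    i = i_peak - 1
    while i >= 0 and d[i] < DVDT_CRITERION:
        i -= 1
    if i < 0:
        raise MeasurementError(
            f"dV/dt never reached {DVDT_CRITERION:g} V/s before the peak at "
            f"{peak_t:g} ms"
        )
    # walk back through the supra-criterion upstroke to the last sample below
    # the criterion, then forward one sample
    while i >= 0 and d[i] >= DVDT_CRITERION:
        i -= 1
    i_thr = i + 1
    return float(sweep.samples[i_thr]), float(i_thr * sweep.dt_ms)


def ap_amplitude(f: SpikeFeatures) -> float:
    """Spike amplitude relative to threshold: peak_v - threshold_v."""
    return f.peak_v - f.threshold_v


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_half_width(sweep: Sweep, f: SpikeFeatures) -> float:
    """Duration at the half level between threshold and peak, ms.

    Crossings are linearly interpolated between samples.  A spike whose
    falling phase never re-crosses the half level (truncated at the end of
    the trace) raises :class:`MeasurementError`.
    """
    level = f.threshold_v + 0.5 * (f.peak_v - f.threshold_v)
    v = sweep.samples
    dt = sweep.dt_ms
    i_peak = sweep.index_at(f.peak_t)
    i_thr = sweep.index_at(f.threshold_t)
    # rising crossing: last sub-level sample between threshold and peak
    rise_t = None
    for i in range(i_peak, i_thr, -1):
        if v[i - 1] < level <= v[i]:
            rise_t = _interp_crossing((i - 1) * dt, v[i - 1], i * dt, v[i], level)
            break
    if rise_t is None:
        rise_t = f.threshold_t  # upstroke starts at/above the half level
    # falling crossing: first sub-level sample after the peak
    fall_t = None
    for i in range(i_peak + 1, v.size):
        if v[i] < level <= v[i - 1]:
            fall_t = _interp_crossing((i - 1) * dt, v[i - 1], i * dt, v[i], level)
            break
        if v[i] > f.peak_v:  # next spike began before we fell below the level
            break
    if fall_t is None:
        raise MeasurementError(
            f"falling half-level crossing absent for the spike at {f.peak_t:g} ms"
        )
    return float(fall_t - rise_t)


def ap_latency(sweep: Sweep, f: SpikeFeatures) -> float:
    """Time from current onset to the AP peak, ms."""
    if f.peak_t < sweep.stimulus_onset:
        raise ValidationError("AP peak precedes the stimulus onset")
    return f.peak_t - sweep.stimulus_onset


def fahp(
    sweep: Sweep, f: SpikeFeatures, next_spike_t: float | None = None
) -> tuple[float, float]:
    """Fast after-hyperpolarization (amplitude mV, latency ms).

    Amplitude is threshold_v minus the post-peak trough; latency is the time
    from the threshold crossing to the trough.  If the trace never dips below
    threshold before the next spike, returns ``(0.0, nan)`` with a warning.
    """
    dt = sweep.dt_ms
    i0 = sweep.index_at(f.peak_t) + 1
    t_end = next_spike_t if next_spike_t is not None else f.peak_t + FAHP_LAST_SPIKE_WINDOW_MS
    i1 = min(sweep.n_samples, sweep.index_at(t_end) + 1)
    if i1 <= i0:
        warnings.warn("no post-peak segment to search for an fAHP trough")
        return 0.0, float("nan")
    seg = sweep.samples[i0:i1]
    i_min = int(np.argmin(seg))
    trough_v = float(seg[i_min])
    if trough_v >= f.threshold_v:
        warnings.warn(
            f"no trough below threshold after the spike at {f.peak_t:g} ms; "
            "fAHP amplitude set to 0"
        )
        return 0.0, float("nan")
    trough_t = (i0 + i_min) * dt
    return f.threshold_v - trough_v, trough_t - f.threshold_t


def measure_spike(
    sweep: Sweep,
    spike: tuple[float, float],
    next_spike_t: float | None = None,
) -> SpikeFeatures:
    """All single-AP features for one detected spike."""
    f = SpikeFeatures(peak_t=spike[0], peak_v=spike[1])
    f.threshold_v, f.threshold_t = ap_threshold(sweep, spike)
    f.amplitude = ap_amplitude(f)
    f.half_width = ap_half_width(sweep, f)
    f.latency = ap_latency(sweep, f)
    f.fahp_amplitude, f.fahp_latency = fahp(sweep, f, next_spike_t)
    return f


# ---------------------------------------------------------------------------
# protocol-level features
# ---------------------------------------------------------------------------

FIRST_AP_RANGE_PA = (20.0, 100.0)


def _first_evoked_sweep(rec: Recording) -> tuple[Sweep, list[tuple[float, float]]]:
    """Lowest-amplitude step of the 20-100 pA series that elicits >= 1 spike."""
    candidates = [
        s
        for s in rec.sweeps
        if FIRST_AP_RANGE_PA[0] - 0.5 <= s.stimulus_amplitude <= FIRST_AP_RANGE_PA[1] + 0.5
    ]
    for sweep in sorted(candidates, key=lambda s: s.stimulus_amplitude):
        spikes = detect_spikes(sweep)
        if spikes:
            return sweep, spikes
    raise PreconditionError("no spike evoked in the 20-100 pA series")


def first_evoked_ap(rec: Recording) -> SpikeFeatures:
    """Single-AP features from the first AP of the first suprathreshold
    20-100 pA step (the convention for reporting AP properties)."""
    sweep, spikes = _first_evoked_sweep(rec)
    next_t = spikes[1][0] if len(spikes) > 1 else None
    return measure_spike(sweep, spikes[0], next_t)


def ap_broadening(rec: Recording) -> float | None:
    """(HW2 - HW1) / HW1 at twice the first-evoked-AP current.

    If the doubled amplitude was not part of the protocol, the nearest
    available suprathreshold amplitude is used with a warning.  Returns
    ``None`` when fewer than two spikes are available.
    """
    first_sweep, _ = _first_evoked_sweep(rec)
    target = 2.0 * first_sweep.stimulus_amplitude
    depol = [s for s in rec.sweeps if s.stimulus_amplitude > 0]
    sweep = min(depol, key=lambda s: abs(s.stimulus_amplitude - target))
    if abs(sweep.stimulus_amplitude - target) > 0.5:
        warnings.warn(
            f"no step at {target:g} pA; using nearest available "
            f"{sweep.stimulus_amplitude:g} pA for AP broadening"
        )
    spikes = detect_spikes(sweep)
    if len(spikes) < 2:
        return None
    hw = []
    for k in (0, 1):
        next_t = spikes[k + 1][0] if len(spikes) > k + 1 else None
        hw.append(measure_spike(sweep, spikes[k], next_t).half_width)
    return (hw[1] - hw[0]) / hw[0]


def _step_failed(sweep: Sweep, spikes: list[tuple[float, float]]) -> bool:
    """AP-failure heuristic for the maximal-firing-frequency rule.

    A step fails if (a) an inter-spike interval contains an aborted spike — a
    local maximum above the measured threshold that misses the -10 mV
    detection bar — or (b) spiking ceases for the last 100 ms of the step
    despite earlier spikes (depolarization block).
    """
    if not spikes:
        return False
    stim_end = sweep.stimulus_onset + sweep.stimulus_duration
    if len(spikes) >= 3 and spikes[-1][0] < stim_end - 100.0:
        return True  # block: a sustained train that falls silent late in the step
    thresholds = []
    for sp in spikes:
        try:
            thresholds.append(ap_threshold(sweep, sp)[0])
        except MeasurementError:
            continue
    if not thresholds:
        return False  # cannot assess aborted spikes without a threshold
    thr = float(np.median(thresholds))
    v = sweep.samples
    dt = sweep.dt_ms
    peak_idx = {sweep.index_at(t) for t, _ in spikes}
    # inter-spike intervals only: between the first and last detected spike
    i0 = sweep.index_at(spikes[0][0]) + 1
    i1 = sweep.index_at(spikes[-1][0]) - 1
    maxima = np.nonzero((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    for i in maxima:
        if not (i0 <= i <= i1) or i in peak_idx:
            continue
        if any(abs(i - j) * dt < MIN_SEPARATION_MS for j in peak_idx):
            continue
        if thr < v[i] <= PEAK_FLOOR:
            return True  # aborted spike between full-height APs
    return False


def max_firing_frequency(rec: Recording) -> float | None:
    """Spike rate (Hz) on the largest depolarizing step below the first step
    showing AP failures; ``None`` if no step elicits spikes."""
    spiking: list[tuple[float, int, bool]] = []
    for sweep in rec.sweeps:
        if sweep.stimulus_amplitude <= 0:
            continue
        spikes = detect_spikes(sweep)
        if not spikes:
            continue
        spiking.append(
            (sweep.stimulus_amplitude, len(spikes), _step_failed(sweep, spikes))
        )
    if not spiking:
        return None
    failing = [amp for amp, _, failed in spiking if failed]
    cutoff = min(failing) if failing else float("inf")
    eligible = [(amp, n) for amp, n, _ in spiking if amp < cutoff]
    if not eligible:
        return None
    amp, n = max(eligible)
    window_s = rec.sweeps[0].stimulus_duration / 1000.0
    return n / window_s


def _cell_rates(rec: Recording) -> dict[float, float]:
    """Firing rate (Hz) per depolarizing step amplitude for one cell."""
    rates: dict[float, list[float]] = {}
    for sweep in rec.sweeps:
        if sweep.stimulus_amplitude < 0:
            continue
        window_s = sweep.stimulus_duration / 1000.0
        rates.setdefault(sweep.stimulus_amplitude, []).append(
            len(detect_spikes(sweep)) / window_s
        )
    return {amp: float(np.mean(r)) for amp, r in rates.items()}


def if_curve(recs: list[Recording]) -> IfCurve:
    """Population current-frequency curve.

    Cells lacking a given amplitude are omitted from that point (each cell
    may have been tested on a subset of amplitudes).  The sd is the
    across-cell sample standard deviation (nan where n = 1).
    """
    if not recs:
        raise ValidationError("if_curve needs at least one recording")
    per_cell = [_cell_rates(r) for r in recs]
    currents = sorted({amp for cell in per_cell for amp in cell})
    means, sds, ns = [], [], []
    for amp in currents:
        vals = [cell[amp] for cell in per_cell if amp in cell]
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"))
        ns.append(len(vals))
    return IfCurve(
        currents=np.array(currents),
        mean_rates=np.array(means),
        sd_rates=np.array(sds),
        n_cells=np.array(ns, dtype=int),
    )


def accommodation_metrics(sweep: Sweep) -> tuple[float, float] | None:
    """Spike-frequency adaptation and amplitude attenuation over one step.

    adaptation_ratio = rate in the last 100 ms / rate in the first 100 ms of
    the step; amplitude_attenuation = 1 - (mean AP amplitude in the last
    100 ms / mean AP amplitude in the first 100 ms).  These summarize the
    qualitative "accommodation and attenuation" phenomenon; they are not
    published quantities.  Returns ``None`` with < 4 spikes or an empty
    first window.
    """
    spikes = detect_spikes(sweep)
    if len(spikes) < 4:
        return None
    onset = sweep.stimulus_onset
    end = onset + sweep.stimulus_duration
    first = [sp for sp in spikes if onset <= sp[0] < onset + 100.0]
    last = [sp for sp in spikes if end - 100.0 <= sp[0] < end]
    if not first:
        return None
    adaptation = len(last) / len(first)

    def _amplitudes(group):
        amps, fallback_thr = [], None
        for sp in group:
            try:
                thr_v, _ = ap_threshold(sweep, sp)
                fallback_thr = thr_v
            except MeasurementError:
                thr_v = fallback_thr
            if thr_v is not None:
                amps.append(sp[1] - thr_v)
        return amps

    first_amp = _amplitudes(first)
    last_amp = _amplitudes(last)
    if not first_amp or not last_amp:
        return adaptation, float("nan")
    attenuation = 1.0 - float(np.mean(last_amp)) / float(np.mean(first_amp))
    return adaptation, attenuation


def train_features(sweep: Sweep) -> TrainFeatures:
    """Spike count, rate and accommodation metrics for one step sweep."""
    spikes = detect_spikes(sweep)
    window_s = sweep.stimulus_duration / 1000.0
    tf = TrainFeatures(
        spike_count=len(spikes), firing_rate=len(spikes) / window_s
    )
    metrics = accommodation_metrics(sweep)
    if metrics is not None:
        tf.adaptation_ratio, tf.amplitude_attenuation = metrics
    return tf
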