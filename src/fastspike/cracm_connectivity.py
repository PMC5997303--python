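"""Optogenetic circuit-mapping (CRACM) EPSC analysis.

Light-pulse-aligned voltage-clamp sweeps are averaged (ten consecutive
sweeps by convention), the evoked EPSC amplitude is measured on the average
as the baseline-to-trough magnitude within a 1-20 ms monosynaptic window
after light onset, pharmacological block is quantified as the blocked /
control amplitude ratio, and population connectivity is summarized with an
exact binomial (Clopper-Pearson) 95% confidence interval.

Sign convention: inward currents are negative in stored traces; amplitudes
are reported as positive magnitudes.  The connectivity criterion (amplitude
above ``max(4 pA, 5 x baseline sd)``) is a configurable operational choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import PreconditionError, ValidationError
from .sweep_model import Recording, RecordingMode, Sweep, baseline_window

__all__ = [
    "EpscMeasurement",
    "ConnectivityResult",
    "average_aligned_sweeps",
    "measure_epsc",
    "classify_connected",
    "block_ratio",
    "connectivity_summary",
    "analyze_cell",
]

#: pre-light baseline window, ms
BASELINE_MS = 50.0
#: monosynaptic detection window after light onset, ms
DETECTION_WINDOW_MS = (1.0, 20.0)
#: connectivity criterion: amplitude floor (pA) and baseline-sd multiple
AMPLITUDE_FLOOR_PA = 4.0
SD_MULTIPLE = 5.0


@dataclass
class EpscMeasurement:
    """Evoked-EPSC measurement on an averaged sweep."""

    mean_amplitude: float        # pA, positive magnitude of the inward current
    onset_latency: float         # ms after light onset (nan if no deflection)
    baseline_sd: float           # pA, sd of the pre-light baseline
    n_sweeps_averaged: int
    connected: bool = False

    def __post_init__(self) -> None:
        if self.mean_amplitude < 0:
            raise ValidationError("mean_amplitude must be >= 0")
        if self.n_sweeps_averaged < 1:
            raise ValidationError("n_sweeps_averaged must be >= 1")


@dataclass
class ConnectivityResult:
    """Population connectivity: counts, percentage, exact 95% CI."""

    n_connected: int
    n_tested: int
    fraction_percent: float
    ci95: tuple[float, float]    # percent


def average_aligned_sweeps(rec: Recording, n: int) -> Sweep:
    """Pointwise mean of the first ``n`` light-aligned sweeps.

    With fewer than ``n`` sweeps, all available sweeps are used with a
    warning.  Stimulus metadata of the first sweep is preserved.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not rec.sweeps:
        raise PreconditionError("recording has no sweeps")
    onsets = {s.stimulus_onset for s in rec.sweeps}
    if len(onsets) != 1:
        raise PreconditionError("sweeps do not share a common light-onset time")
    use = rec.sweeps[:n]
    if len(use) < n:
        warnings.warn(
            f"only {len(use)} sweeps available; averaging all instead of {n}"
        )
    mean = np.mean([s.samples for s in use], axis=0)
    return use[0].with_samples(mean)


def measure_epsc(avg: Sweep, n_sweeps_averaged: int = 1) -> EpscMeasurement:
    """Measure the light-evoked EPSC on an averaged voltage-clamp sweep.

    Baseline is the 50 ms pre-light mean; the amplitude is the baseline
    minus the minimum in the 1-20 ms post-light window (positive magnitude,
    floored at 0); onset latency is the first post-light time the trace
    deviates 3 baseline-sd below baseline (nan if it never does).
    """
    if avg.mode is not RecordingMode.VOLTAGE_CLAMP:
        raise PreconditionError("EPSC measurement requires a voltage-clamp sweep")
    light = avg.stimulus_onset
    w0, w1 = light + DETECTION_WINDOW_MS[0], light + DETECTION_WINDOW_MS[1]
    if w1 > avg.duration_ms:
        raise PreconditionError("sweep ends before the post-light detection window")
    base_mean, base_sd = baseline_window(avg, min(BASELINE_MS, light))
    window = avg.window(w0, w1)
    amplitude = max(0.0, base_mean - float(np.min(window)))

    onset_latency = float("nan")
    deviation_floor = max(3.0 * base_sd, 1e-9)
    post = avg.window(light, w1)
    below = np.nonzero(post < base_mean - deviation_floor)[0]
    if below.size:
        onset_latency = float(below[0]) * avg.dt_ms

    m = EpscMeasurement(
        mean_amplitude=amplitude,
        onset_latency=onset_latency,
        baseline_sd=base_sd,
        n_sweeps_averaged=n_sweeps_averaged,
    )
    m.connected = classify_connected(m)
    return m


def classify_connected(
    m: EpscMeasurement,
    amplitude_floor: float = AMPLITUDE_FLOOR_PA,
    sd_multiple: float = SD_MULTIPLE,
) -> bool:
    """True iff the amplitude strictly exceeds max(floor, sd_multiple x sd)."""
    return m.mean_amplitude > max(amplitude_floor, sd_multiple * m.baseline_sd)


def block_ratio(
    control: EpscMeasurement, blocked: EpscMeasurement
) -> float | None:
    """Residual amplitude fraction under antagonists: blocked / control.

    Returns ``None`` (not applicable) when the control amplitude is 0.
    """
    if control.mean_amplitude == 0.0:
        return None
    return blocked.mean_amplitude / control.mean_amplitude


def connectivity_summary(flags: list[bool]) -> ConnectivityResult:
    """Counts, percentage (2 decimals) and exact binomial 95% CI (percent)."""
    if not flags:
        raise ValidationError("connectivity_summary needs a non-empty flag list")
    n = len(flags)
    k = int(sum(bool(f) for f in flags))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return ConnectivityResult(
        n_connected=k,
        n_tested=n,
        fraction_percent=round(100.0 * k / n, 2),
        ci95=(100.0 * lo, 100.0 * hi),
    )


def analyze_cell(
    control: Recording,
    blocked: Recording | None = None,
    n_average: int = 10,
) -> dict:
    """Average, measure and (optionally) compute the block ratio for one cell."""
    avg = average_aligned_sweeps(control, n_average)
    m_control = measure_epsc(avg, n_sweeps_averaged=min(n_average, len(control.sweeps)))
    out = {"control": m_control, "blocked": None, "block_ratio": None}
    if blocked is not None:
        avg_b = average_aligned_sweeps(blocked, n_average)
        m_blocked = measure_epsc(avg_b, n_sweeps_averaged=min(n_average, len(blocked.sweeps)))
        out["blocked"] = m_blocked
        out["block_ratio"] = block_ratio(m_control, m_blocked)
    return out
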