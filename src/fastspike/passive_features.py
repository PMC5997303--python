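"""Subthreshold (passive) membrane properties from current-clamp recordings.

Definitions follow standard whole-cell practice: resting potential is the
pre-stimulus baseline; input resistance is the OLS slope of the steady-state
voltage-current relation over hyperpolarizing steps; the membrane time
constant is a single-exponential fit to the rising phase (up to 63.2% of the
steady deflection) of the mean -100 pA response; the sag ratio is
V_steady / V_hyp with both deflections measured relative to the per-sweep
baseline.  Membrane capacitance is derived as tau_m / R_in and labelled as
such (an amplifier capacitance readout is a different measurement and will
not numerically agree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitError,
    InsufficientDataError,
    MeasurementError,
    PreconditionError,
    ValidationError,
)
from .sweep_model import Recording, RecordingMode, Sweep, baseline_window

__all__ = [
    "PassiveProperties",
    "resting_potential",
    "input_resistance",
    "membrane_time_constant",
    "sag_ratio",
    "capacitance",
    "extract_passive",
]

#: fraction of the step used as the steady-state window (final 10%,
#: i.e. 50 ms of a 500 ms step)
STEADY_FRACTION = 0.1


@dataclass
class PassiveProperties:
    """Extracted passive properties of one cell."""

    v_rmp: float        # mV
    r_in: float         # MOhm
    tau_m: float        # ms
    sag_ratio: float    # dimensionless, (0, 1]
    c_mem: float = float("nan")  # pF, derived as tau_m / r_in

    def __post_init__(self) -> None:
        if not self.r_in > 0:
            raise ValidationError("r_in must be > 0")
        if not self.tau_m > 0:
            raise ValidationError("tau_m must be > 0")
        if not self.sag_ratio > 0:
            raise ValidationError("sag_ratio must be > 0")
        if self.sag_ratio > 1.0:
            if self.sag_ratio <= 1.05:
                warnings.warn(
                    f"sag_ratio {self.sag_ratio:.4f} marginally exceeds 1; clipping to 1.0"
                )
                self.sag_ratio = 1.0
            else:
                raise ValidationError(f"sag_ratio {self.sag_ratio:.4f} is not plausible")


def _require_current_clamp(rec: Recording) -> None:
    if not rec.sweeps:
        raise PreconditionError("recording has no sweeps")
    if rec.mode is not RecordingMode.CURRENT_CLAMP:
        raise PreconditionError("passive properties require a current-clamp recording")


def _steady_window(sweep: Sweep) -> np.ndarray:
    t1 = sweep.stimulus_onset + sweep.stimulus_duration
    t0 = t1 - STEADY_FRACTION * sweep.stimulus_duration
    return sweep.window(t0, t1)


def _baseline(sweep: Sweep) -> float:
    return baseline_window(sweep, sweep.stimulus_onset)[0]


def resting_potential(rec: Recording) -> float:
    """Mean pre-stimulus membrane potential over all sweeps (mV)."""
    _require_current_clamp(rec)
    means = []
    for sweep in rec.sweeps:
        if sweep.stimulus_onset < 50.0:
            raise PreconditionError(
                "resting potential needs >= 50 ms of pre-stimulus baseline"
            )
        means.append(_baseline(sweep))
    return float(np.mean(means))


def input_resistance(rec: Recording) -> float:
    """OLS slope of steady-state deflection vs injected current, in MOhm.

    Uses hyperpolarizing (and 0 pA) subthreshold steps; sweeps containing
    spikes are excluded with a warning.  mV/pA = GOhm, hence the x1000.
    """
    from .spike_features import detect_spikes  # local import, avoids cycle

    _require_current_clamp(rec)
    currents, deflections = [], []
    for sweep in rec.sweeps:
        if sweep.stimulus_amplitude > 0:
            continue
        if detect_spikes(sweep):
            warnings.warn(
                f"excluding spiking sweep at {sweep.stimulus_amplitude:g} pA "
                "from the passive fit"
            )
            continue
        currents.append(sweep.stimulus_amplitude)
        deflections.append(float(np.mean(_steady_window(sweep))) - _baseline(sweep))
    if len(currents) < 3:
        raise InsufficientDataError(
            f"input resistance needs >= 3 subthreshold steps, got {len(currents)}"
        )
    fit = stats.linregress(currents, deflections)
    slope_mohm = fit.slope * 1000.0
    if not slope_mohm > 0:
        raise MeasurementError("non-positive V-I slope; traces are not passive")
    return float(slope_mohm)


def _mean_minus100_sweep(rec: Recording) -> Sweep:
    sweeps = rec.sweeps_at(-100.0)
    if not sweeps:
        raise PreconditionError("no -100 pA sweep in recording")
    mean = np.mean([s.samples for s in sweeps], axis=0)
    return sweeps[0].with_samples(mean)


def membrane_time_constant(rec: Recording) -> float:
    """Single-exponential fit to the onset-to-63.2% rising phase of the mean
    -100 pA response; returns tau in ms."""
    _require_current_clamp(rec)
    sweep = _mean_minus100_sweep(rec)
    base = _baseline(sweep)
    steady = float(np.mean(_steady_window(sweep))) - base
    if abs(steady) < 0.5:  # mV; no resolvable deflection
        raise FitError(f"steady-state deflection {steady:.3f} mV too small to fit")
    onset = sweep.stimulus_onset
    target = base + 0.632 * steady
    seg = sweep.window(onset, onset + sweep.stimulus_duration)
    # first sample at/past 63.2% of the deflection (deflection is negative)
    reached = np.nonzero(seg <= target if steady < 0 else seg >= target)[0]
    if reached.size == 0:
        raise FitError("response never reaches 63.2% of its steady deflection")
    i63 = max(int(reached[0]), 3)
    t = np.arange(i63 + 1) * sweep.dt_ms
    v = seg[: i63 + 1]

    # V0 and the deflection are taken from their long, well-averaged windows;
    # only tau is free.  Fitting all three on a segment spanning ~one time
    # constant leaves dV and tau nearly collinear and inflates the variance.
    def model(t, tau):
        return base + steady * (1.0 - np.exp(-t / tau))

    tau0 = max(t[-1], sweep.dt_ms)
    try:
        popt, _ = optimize.curve_fit(model, t, v, p0=(tau0,), maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    tau = float(popt[0])
    if not (0 < tau < 10 * sweep.stimulus_duration):
        raise FitError(f"implausible fitted time constant {tau:.3g} ms")
    return tau


def sag_ratio(rec: Recording) -> float:
    """V_steady / V_hyp on the -100 pA step (deflections from baseline).

    Both deflections are negative; the ratio is positive and <= 1 when an
    H-current relaxes the initial hyperpolarization.  Marginal values just
    above 1 (noise) are clipped to 1.0 with a warning.
    """
    _require_current_clamp(rec)
    sweep = _mean_minus100_sweep(rec)
    base = _baseline(sweep)
    stim = sweep.window(
        sweep.stimulus_onset, sweep.stimulus_onset + sweep.stimulus_duration
    )
    v_hyp = float(np.min(stim)) - base
    v_steady = float(np.mean(_steady_window(sweep))) - base
    if v_hyp >= -0.5:
        raise MeasurementError("no hyperpolarizing deflection on the -100 pA step")
    ratio = v_steady / v_hyp
    if ratio > 1.0:
        if ratio <= 1.05:
            warnings.warn(f"sag ratio {ratio:.4f} marginally exceeds 1; clipping")
            return 1.0
        raise MeasurementError(f"implausible sag ratio {ratio:.4f}")
    if ratio <= 0:
        raise MeasurementError("steady-state deflection changed sign during the step")
    return float(ratio)


def capacitance(props: PassiveProperties) -> float:
    """Derived membrane capacitance tau_m / R_in, in pF (ms/MOhm = nF)."""
    return props.tau_m / props.r_in * 1000.0


def extract_passive(rec: Recording) -> PassiveProperties:
    """Run the full passive extraction on one recording."""
    props = PassiveProperties(
        v_rmp=resting_potential(rec),
        r_in=input_resistance(rec),
        tau_m=membrane_time_constant(rec),
        sag_ratio=sag_ratio(rec),
    )
    props.c_mem = capacitance(props)
    return props
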