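"""Ground-truth generators for every analysis stage.

Three simulators live here:

* :func:`simulate_current_clamp` — an adaptive exponential integrate-and-fire
  (AdEx) neuron with a first-order H-current, integrated with fixed-step
  Euler on the sample grid, driven by a family of 500 ms current steps.  The
  default parameter preset is a fast-spiking cell (narrow spikes, high
  maximal rate, little accommodation, small sag).
* :func:`simulate_cracm_sweeps` — voltage-clamp sweeps with a light-evoked
  inward synaptic transient (difference-of-exponentials kernel), with and
  without pharmacological block, emulating 1 ms light pulses delivered at
  0.1 Hz to a cell held at -70 mV.
* :func:`simulate_qpcr_plate` — triplicate Ct values per cell x gene with a
  configurable detection limit (default Ct 37) and per-gene dropout.

Every generator is bit-reproducible given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .sweep_model import Recording, RecordingMode, StepProtocol, Sweep

__all__ = [
    "NeuronModelParams",
    "EpscSimParams",
    "QpcrSimParams",
    "QpcrPlate",
    "simulate_current_clamp",
    "simulate_cracm_sweeps",
    "simulate_qpcr_plate",
]

# H-current activation curve (fixed gate shape; only g_h/E_h/tau_h are tunable)
_H_VHALF = -80.0  # mV
_H_K = 6.0  # mV


def _h_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - _H_VHALF) / _H_K))


@dataclass
class NeuronModelParams:
    """AdEx + H-current parameters.

    The defaults are the fast-spiking preset: C = 40 pF, g_L = 3 nS (giving
    R_in = 333 MOhm and tau_m = 13.3 ms), threshold parameter V_T = -42 mV
    with a 1 mV slope factor, reset -55 mV, spike drawn at 0 mV.  A small
    spike-triggered adaptation (b = 5 pA) produces mild accommodation; the
    weak H-conductance (g_h = 0.1 nS) yields a sag ratio near 0.95 on a
    -100 pA step.  The preset is configuration, not ground truth.
    """

    C: float = 40.0          # pF
    g_L: float = 3.0         # nS
    E_L: float = -66.0       # mV
    V_T: float = -42.0       # mV
    Delta_T: float = 1.0     # mV
    a: float = 0.0           # nS, subthreshold adaptation
    b: float = 5.0           # pA, spike-triggered adaptation
    tau_w: float = 50.0      # ms
    V_reset: float = -55.0   # mV
    V_peak: float = 0.0      # mV, drawn spike height
    g_h: float = 0.1         # nS, >= 0
    E_h: float = -30.0       # mV
    tau_h: float = 50.0      # ms
    noise_sd: float = 0.0    # pA, per-sample white current noise
    t_ref: float = 2.0       # ms, absolute refractory (clamped at V_reset)

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "tau_w", "tau_h", "Delta_T"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.V_reset >= self.V_peak:
            raise ValidationError("V_reset must be < V_peak")
        if self.g_h < 0 or self.noise_sd < 0 or self.t_ref < 0:
            raise ValidationError("g_h, noise_sd and t_ref must be >= 0")

    @property
    def spike_cutoff(self) -> float:
        """Voltage at which the upstroke is considered to have escaped
        (standard AdEx numerical cutoff, V_T + 5*Delta_T)."""
        return self.V_T + 5.0 * self.Delta_T

    def resting_state(self) -> tuple[float, float, float]:
        """Zero-current fixed point (V, w, h) of the subthreshold system."""
        v = self.E_L
        for _ in range(200):
            v_new = self.E_L - self.g_h * _h_inf(v) * (v - self.E_h) / self.g_L
            if abs(v_new - v) < 1e-12:
                v = v_new
                break
            v = v_new
        return v, self.a * (v - self.E_L), _h_inf(v)


def simulate_current_clamp(
    params: NeuronModelParams,
    protocol: StepProtocol,
    seed: int,
) -> Recording:
    """Simulate one current-clamp sweep per protocol step.

    Membrane dynamics (pA / pF / nS / mV / ms units, so nS*mV = pA):

        C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
                  - w - g_h * h * (V - E_h) + I(t) + noise
        tau_w dw/dt = a (V - E_L) - w
        tau_h dh/dt = h_inf(V) - h

    When an Euler step would carry V past the cutoff V_T + 5*Delta_T the
    sample is drawn at V_peak, w is incremented by b, and V is clamped at
    V_reset for t_ref.  Spike times (sample-aligned, ms) are logged per sweep
    in ``annotations["spike_times_ms"]``.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / protocol.sampling_rate
    n_pre = int(round(protocol.pre_ms / dt))
    n_stim = int(round(protocol.step_duration / dt))
    n_post = int(round(protocol.post_ms / dt))
    n = n_pre + n_stim + n_post
    n_ref = int(round(params.t_ref / dt))

    v0, w0, h0 = params.resting_state()
    cut = params.spike_cutoff

    C, g_L, E_L = params.C, params.g_L, params.E_L
    V_T, Delta_T = params.V_T, params.Delta_T
    a, tau_w = params.a, params.tau_w
    g_h, E_h, tau_h = params.g_h, params.E_h, params.tau_h
    exp = math.exp

    sweeps: list[Sweep] = []
    spike_log: list[list[float]] = []
    for amp in protocol.step_amplitudes:
        noise = (
            rng.normal(0.0, params.noise_sd, size=n)
            if params.noise_sd > 0
            else np.zeros(n)
        )
        out = np.empty(n)
        out[0] = v = v0
        w, h = w0, h0
        spikes: list[float] = []
        ref_left = 0
        for i in range(1, n):
            stim = amp if n_pre <= i - 1 < n_pre + n_stim else 0.0
            if ref_left > 0:
                ref_left -= 1
                out[i] = v = params.V_reset
                w += dt * (a * (v - E_L) - w) / tau_w
                h += dt * (_h_inf(v) - h) / tau_h
                continue
            ex = (v - V_T) / Delta_T
            i_exp = g_L * Delta_T * exp(min(ex, 30.0))
            dv = (-g_L * (v - E_L) + i_exp - w
                  - g_h * h * (v - E_h) + stim + noise[i - 1]) / C
            v_new = v + dt * dv
            w += dt * (a * (v - E_L) - w) / tau_w
            h += dt * (_h_inf(v) - h) / tau_h
            if not math.isfinite(v_new):
                raise SimulationError(
                    f"non-finite voltage at sample {i} of the {amp:g} pA step"
                )
            if v_new >= cut:
                out[i] = params.V_peak
                spikes.append(i * dt)
                w += params.b
                v = params.V_reset
                ref_left = n_ref
            else:
                out[i] = v = v_new
        sweeps.append(
            Sweep(
                samples=out,
                sampling_rate=protocol.sampling_rate,
                stimulus_onset=protocol.pre_ms,
                stimulus_duration=protocol.step_duration,
                stimulus_amplitude=float(amp),
                mode=RecordingMode.CURRENT_CLAMP,
            )
        )
        spike_log.append(spikes)

    return Recording(
        sweeps=sweeps,
        cell_id=f"adex-seed{seed}",
        annotations={
            "generator": "adex_current_clamp",
            "seed": int(seed),
            "model_params": asdict(params),
            "spike_times_ms": spike_log,
        },
    )


# ---------------------------------------------------------------------------
# CRACM sweeps
# ---------------------------------------------------------------------------

@dataclass
class EpscSimParams:
    """Light-evoked EPSC generator parameters.

    ``true_amplitude`` is the peak magnitude (pA) of the inward transient in
    stored traces (which are signed: inward = negative).  ``block_fraction``
    is the residual amplitude fraction under glutamatergic antagonists.
    Pulses are 1 ms; at the 0.1 Hz stimulation rate sweeps are independent,
    so each stored sweep covers only the peri-pulse window.
    """

    true_amplitude: float = 69.0   # pA
    rise_tau: float = 0.5          # ms
    decay_tau: float = 4.0         # ms
    onset_latency: float = 3.0     # ms after light onset
    latency_jitter_sd: float = 0.3  # ms
    failure_prob: float = 0.0
    noise_sd: float = 4.0          # pA per sample
    n_sweeps: int = 10
    light_period: float = 10.0     # s (0.1 Hz)
    block_fraction: float = 0.036
    sampling_rate: float = 10_000.0
    sweep_ms: float = 300.0
    light_onset_ms: float = 100.0
    light_duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValidationError("require 0 < rise_tau < decay_tau")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValidationError("failure_prob must be in [0, 1]")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ValidationError("block_fraction must be in [0, 1]")
        if self.true_amplitude < 0 or self.noise_sd < 0 or self.n_sweeps < 1:
            raise ValidationError("invalid amplitude/noise/n_sweeps")


def _epsc_kernel(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials, unit peak, zero before t = 0."""
    k = np.where(t_ms > 0, np.exp(-t_ms / decay) - np.exp(-t_ms / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return k / peak


def simulate_cracm_sweeps(
    params: EpscSimParams, seed: int
) -> tuple[Recording, Recording]:
    """Simulate (control, blocked) voltage-clamp recordings.

    Each sweep has a downward (inward) synaptic transient after the light
    marker; the blocked recording scales the transient by ``block_fraction``.
    Noise is white Gaussian on every sample.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / params.sampling_rate
    n = int(round(params.sweep_ms / dt))
    t = np.arange(n) * dt

    def _one_recording(amplitude: float, label: str) -> Recording:
        sweeps = []
        for _ in range(params.n_sweeps):
            latency = params.onset_latency
            if params.latency_jitter_sd > 0:
                latency += params.latency_jitter_sd * rng.standard_normal()
            latency = max(latency, 0.05)
            amp = 0.0 if rng.random() < params.failure_prob else amplitude
            trace = -amp * _epsc_kernel(
                t - params.light_onset_ms - latency, params.rise_tau, params.decay_tau
            )
            if params.noise_sd > 0:
                trace = trace + params.noise_sd * rng.standard_normal(n)
            sweeps.append(
                Sweep(
                    samples=trace,
                    sampling_rate=params.sampling_rate,
                    stimulus_onset=params.light_onset_ms,
                    stimulus_duration=params.light_duration_ms,
                    stimulus_amplitude=1.0,  # light-pulse marker
                    mode=RecordingMode.VOLTAGE_CLAMP,
                )
            )
        return Recording(
            sweeps=sweeps,
            cell_id=f"cracm-{label}-seed{seed}",
            annotations={
                "generator": "cracm_epsc",
                "condition": label,
                "seed": int(seed),
                "true_amplitude_pa": amplitude,
                "light_period_s": params.light_period,
            },
        )

    control = _one_recording(params.true_amplitude, "control")
    blocked = _one_recording(params.true_amplitude * params.block_fraction, "blocked")
    return control, blocked


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

_DEFAULT_GENES = ("Pvalb", "Vglut2", "Vgat", "Kv3.1", "Kv3.2", "Hcn2")


@dataclass
class QpcrSimParams:
    """Single-cell RT-qPCR plate generator.

    Ct = base_ct - log2(abundance) + N(0, replicate_sd), three technical
    replicates per cell x gene.  Dropouts (no amplification curve) are
    emitted as missing; Ct values beyond ``max_cycles`` (the run length of
    the qPCR program, 40 cycles) are also missing.  Values above ``lod_ct``
    are retained in the plate but censored downstream.

    The default cohort emulates eight Pvalb+/Vglut2+/Vgat- cells: the Vgat
    abundance is so low its expected Ct exceeds the 40-cycle run, and Kv3.2
    drops out in 3/8 of cells on average.
    """

    genes: Sequence[str] = _DEFAULT_GENES
    true_relative_abundance: Mapping[str, float] = field(
        default_factory=lambda: {
            "Pvalb": 1.0,
            "Vglut2": 1.0,
            "Vgat": 1e-6,
            "Kv3.1": 0.25,
            "Kv3.2": 0.20,
            "Hcn2": 0.30,
        }
    )
    reference_genes: Sequence[str] = ("Pvalb", "Vglut2")
    replicate_sd: float = 0.25       # Ct cycles
    dropout_prob: float | Mapping[str, float] = field(
        default_factory=lambda: {"Kv3.2": 0.375}
    )
    lod_ct: float = 37.0
    n_cells: int = 8
    base_ct: float = 24.0            # Ct of a unit-abundance gene
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        genes = list(self.genes)
        if not set(self.reference_genes) <= set(genes):
            raise ValidationError("reference_genes must be a subset of genes")
        for g in genes:
            if self.true_relative_abundance.get(g, 0.0) <= 0:
                raise ValidationError(f"abundance for {g!r} must be > 0")
        if self.replicate_sd < 0 or self.n_cells < 1:
            raise ValidationError("invalid replicate_sd or n_cells")
        self.genes = genes

    def dropout_for(self, gene: str) -> float:
        if isinstance(self.dropout_prob, Mapping):
            p = float(self.dropout_prob.get(gene, 0.0))
        else:
            p = float(self.dropout_prob)
        if not 0.0 <= p <= 1.0:
            raise ValidationError("dropout probabilities must be in [0, 1]")
        return p


@dataclass
class QpcrPlate:
    """Long-format Ct table: columns cell_id, gene, replicate, ct (NaN = missing)."""

    data: pd.DataFrame
    lod_ct: float = 37.0

    def __post_init__(self) -> None:
        required = {"cell_id", "gene", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ValidationError(f"plate table needs columns {sorted(required)}")
        reps = self.data["replicate"]
        if not reps.isin([1, 2, 3]).all():
            raise ValidationError("replicate index must be 1, 2 or 3")
        cts = self.data["ct"]
        if (cts.dropna() <= 0).any():
            raise ValidationError("ct values must be > 0 when present")


def simulate_qpcr_plate(params: QpcrSimParams, seed: int) -> QpcrPlate:
    """Generate a triplicate single-cell Ct plate with known ground truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(params.n_cells):
        cell = f"cell{c + 1:02d}"
        for gene in params.genes:
            abundance = params.true_relative_abundance[gene]
            p_drop = params.dropout_for(gene)
            # dropout models a failed amplification for the whole sample-gene
            # reaction, as seen in real single-cell plates
            dropped = rng.random() < p_drop
            for rep in (1, 2, 3):
                ct: float = math.nan
                if not dropped:
                    ct = params.base_ct - math.log2(abundance)
                    if params.replicate_sd > 0:
                        ct += params.replicate_sd * rng.standard_normal()
                    if ct > params.max_cycles:
                        ct = math.nan  # no amplification within the run
                rows.append((cell, gene, rep, ct))
    frame = pd.DataFrame(rows, columns=["cell_id", "gene", "replicate", "ct"])
    return QpcrPlate(data=frame, lod_ct=params.lod_ct)
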