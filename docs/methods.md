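# Methods

## Scope and data model

All analyses operate on `Recording` objects: lists of time-aligned sweeps
sharing a sampling rate and clamp mode. Time is in milliseconds from sweep
start, current-clamp samples in mV, voltage-clamp samples in pA, injected
currents in pA. Stimulus timing (onset, duration, amplitude or light-pulse
marker) is metadata on each sweep and is never inferred from the trace.
Voltages are reported as measured, with no liquid-junction-potential
correction. The on-disk format is `#`-headed delimited text with one column
per sweep and `%.17g` floats, so a write/read round trip is bit-exact and
fixtures are diff-able. The default digitization rate is 10 kHz (0.1 ms
samples).

## The model neuron

The current-clamp generator is an adaptive exponential integrate-and-fire
(AdEx) neuron extended with a first-order H-current:

    C dV/dt = −g_L (V − E_L) + g_L Δ_T e^((V − V_T)/Δ_T) − w − g_h h (V − E_h) + I(t) + ξ
    τ_w dw/dt = a (V − E_L) − w
    τ_h dh/dt = h_∞(V) − h,   h_∞(V) = 1 / (1 + e^((V + 80)/6))

AdEx was chosen because it reproduces high-frequency, minimally
accommodating fast-spiking trains with very few parameters; a
conductance-based Kv3 model is deliberately out of scope. The H-gate
activates with hyperpolarization (half-activation −80 mV, 6 mV slope,
fixed) and produces the sag on hyperpolarizing steps; with `g_h = 0` the
subthreshold system is a single-compartment RC cell with exact analytic
limits (steady deflection I/g_L, time constant C/g_L) used by the recovery
tests.

Integration is fixed-step forward Euler at the sampling interval, so the
simulated trace *is* the sampled trace the extractors see — there is no
resampling step to smear alignment. Spikes follow the standard AdEx
numerical convention: when an Euler step would carry V past the cutoff
Θ = V_T + 5Δ_T (where the exponential term outruns any stable step), the
sample is drawn at `V_peak`, `w` is incremented by `b`, and V is clamped at
`V_reset` for an absolute refractory period `t_ref` (2 ms by default).
Detecting the crossing at Θ rather than at the drawn peak keeps the sampled
upstroke stereotyped: the last sub-cutoff sample always lies in the
slow-crawl region where per-sample increments are ≲1 mV, so interpolated
half-widths are reproducible from spike to spike instead of depending
chaotically on sub-sample phase. `t_ref` also bounds the inter-spike
interval away from the detector's 1 ms separation rule, so on noiseless
traces the detector and the simulator spike log agree spike-for-spike by
construction — which is exactly what the detector-fidelity test asserts.
Spike times are logged per sweep in `annotations["spike_times_ms"]`.

Current noise `ξ` is per-sample white Gaussian with standard deviation
`noise_sd` (pA) at the native sampling interval. The `simulate_*` functions
are bit-reproducible given (params, seed); all randomness flows through one
`numpy` generator per call.

### Default preset

C = 40 pF, g_L = 3 nS (R_in = 333 MΩ, τ_m = 13.3 ms), E_L = −66 mV,
V_T = −42 mV, Δ_T = 1 mV, V_reset = −55 mV, V_peak = 0 mV, a = 0,
b = 5 pA, τ_w = 50 ms, g_h = 0.1 nS (E_h = −30 mV, τ_h = 50 ms),
t_ref = 2 ms. The preset was placed by design in the fast-spiking regime —
resting potential near −66 mV, sag ratio just below 1 (g_h was sized from a
linearized steady-state estimate of the −100 pA response), sub-millisecond
spikes, maximal rates of a few hundred Hz, near-zero broadening and mild
adaptation. It is configuration, not ground truth: recovery tests draw
their own parameters and compare against those.

The standard protocol is 500 ms steps with 100 ms pre/post holding:
−100…100 pA in 20 pA increments (the hyperpolarizing family plus the
first-evoked-AP series) followed by 150…1500 pA in 50 pA increments. A
39-sweep recording at 10 kHz simulates in well under a second, which is
what keeps the 20-cell recovery sweeps and the 200-run detection-power
studies comfortably inside an interactive test run.

## Feature extraction

**Derivative convention.** dV/dt is the forward difference at native
sampling, with no smoothing (10 kHz is adequate for half-widths of ~0.5 ms
and the criterion derivative of 20 V/s is far below fast-spiking upstroke
slopes). The forward difference attributes the derivative of the interval
[i, i+1] to sample i, so the threshold search — backward from the peak
through the supra-criterion upstroke, then forward one sample — lands on
the last sample *before* the upstroke interval: the foot of the spike, the
sample a manual cursor placement picks. A central difference would smear a
corner across two samples and bias the threshold late by one sample.

**Detection.** Local maxima with peak above −10 mV, a ≥20 V/s derivative
within the preceding 2 ms, and ≥1 ms separation (first-come). Silent sweeps
return an empty list rather than an error.

**Single-AP features** are measured on the first AP of the lowest 20–100 pA
step that elicits a spike. Amplitude and fAHP amplitude are relative to
threshold; fAHP latency runs from the threshold-crossing time on the rising
phase (not the falling-phase threshold re-crossing — the definition is
ambiguous in common usage and the rising-phase time is the reproducible
one) to the post-peak trough, searched up to the next spike or 10 ms. A
spike with no trough below threshold yields amplitude 0 with a warning
rather than an error, since that is a property of the cell, not a
measurement failure. Half-level crossings are linearly interpolated.

**AP failures.** The maximal firing frequency is the rate on the largest
step below the first "failing" step. Failure is operationalized two ways,
since aborted spikes have no universal definition: (a) an inter-spike
interval contains a local maximum above the (median measured) threshold
that misses the −10 mV detection bar — an aborted spike; (b) a sustained
train (≥3 spikes) falls silent for the final 100 ms of the step —
depolarization block. A single early spike is not "block".

**Accommodation metrics.** adaptation_ratio = rate in the last 100 ms of
the step over the rate in the first 100 ms; amplitude_attenuation =
1 − (mean AP amplitude, last 100 ms)/(mean, first 100 ms). These are this
package's operational summaries of a qualitative phenomenon (reports label
them as such); they need ≥4 spikes and a non-empty first window.

**Passive fits.** Steady state is the final 10% of the step (50 ms of a
500 ms step). Spiking sweeps are excluded from the V–I regression
automatically. In the τ_m fit, V₀ and ΔV are taken from the long baseline
and steady windows and only τ is free: on a segment spanning roughly one
time constant, a free ΔV is nearly collinear with τ and inflates the
variance several-fold. C_mem is reported as τ_m/R_in and labelled
"derived"; an amplifier's capacitance-compensation readout is a different
measurement and the two need not agree numerically.

## CRACM analysis

The average of ten consecutive light-aligned sweeps (0.1 Hz stimulation
makes sweeps independent; no within-train dynamics are modeled) is measured
as: baseline = 50 ms pre-light mean; amplitude = baseline minus the trace
minimum in the 1–20 ms post-light window (a monosynaptic latency range —
the window is a design choice), reported as a positive magnitude; onset
latency = first post-light deviation 3 baseline-sd below baseline. The
connectivity criterion — amplitude strictly greater than
max(4 pA, 5 × baseline sd) — is an operational choice, configurable and
recorded with the result. At the measured scale (69 pA connections, ~4 pA
sweep noise, √10 averaging gain) it detects essentially every true
connection with a false-positive rate far below 1%, which the power test
verifies on 200 simulated cells per condition. The population summary uses
the exact Clopper–Pearson binomial interval (via statsmodels) because
tested cohorts are small. Note the amplitude estimator has a small positive
bias for near-zero signals (a minimum over a noisy window), so block ratios
of strongly blocked cells run a few hundredths high of the true residual
fraction; the recovery tests budget for this.

## qPCR analysis

The plate generator draws Ct = base_ct − log₂(abundance) + N(0, sd) in
triplicate; reactions whose expected Ct exceeds the 40-cycle run, and
per-gene dropouts, are emitted as missing. The default cohort emulates
eight Pvalb⁺/Vglut2⁺/Vgat⁻ cells with Kv3.1/Kv3.2/Hcn2 at comparable
abundance, a Vgat abundance below the run length, and a 3/8 dropout rate
for Kv3.2 — mirroring the observed exclusion pattern in single-cell plates
of this cell type.

Censoring treats "above the limit of detection" strictly: Ct = 37.0
survives, 37.01 does not. Reference aggregation is the arithmetic mean of
the reference Cts, equivalent to normalizing expression by the geometric
mean of the reference genes. The ΔΔCt calibrator defaults to the cohort
mean ΔCt per target (values are fold changes relative to the cohort
average, which is the only well-defined population-level choice when no
calibrator sample is designated); a designated calibrator cell or no
calibrator (values relative to references) are available. ΔΔCt is invariant
to any global Ct shift, a property the tests assert to machine precision.
Cells with a censored reference are excluded with a warning; a censored
target censors only that gene's value.

## What the simulators do and do not establish

The generators provide *known-truth* data, so green tests establish that
the estimators are unbiased and correctly implemented under the stated
noise models: white current noise, Gaussian Ct replicate error, Gaussian
latency jitter, Bernoulli failures. Real recordings additionally contain
series-resistance and bridge-balance artifacts, electrode drift, 50/60 Hz
pickup, temperature sensitivity, biological cell-to-cell covariance, and
amplification-efficiency differences between qPCR probes — none of which
are modeled. Passing recovery tests therefore validate the analysis code,
not the hardware-facing robustness of the measurements. The AdEx spike
shape is also narrower than a biological AP waveform (half-widths of
~0.1 ms against ~0.5 ms for real fast-spiking cells), so absolute AP
amplitude/half-width values from the preset are not biological targets;
ordering and regime checks (sub-millisecond, non-accommodating, >100 Hz)
are what the phenotype test asserts.

## Numerical choices and degenerate inputs

- Euler at 0.1 ms biases recovered time constants by −dt/2τ per step
  (≈1.5% at τ = 3.3 ms), inside the 5% recovery budget; the exponential
  term's argument is capped at 30 to avoid overflow before the cutoff test.
- Sag ratios marginally above 1 (noise on a sag-free cell) are clipped to
  1.0 with a warning; values above 1.05 are errors.
- Zero steady deflection fails the τ fit with `FitError`; fewer than three
  subthreshold steps fail R_in with `InsufficientDataError`; a truncated
  spike (no falling half-level crossing) fails half-width with
  `MeasurementError`; a 0/0 block ratio is `None` (not applicable).
- Ties: the connectivity criterion is strictly greater (4.0 pA at the 4 pA
  floor is unconnected); detection separation keeps the earlier spike.
- Connectivity percentages are rounded to two decimals; nothing else is
  rounded before reporting.
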