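# fastspike

Quantitative analysis of fast-spiking neurons: intrinsic electrophysiology,
optogenetic connectivity mapping, and single-cell qPCR.

Fast-spiking cells — classically parvalbumin-expressing interneurons, but
also glutamatergic populations such as the parvalbumin-positive cluster of
the lateral hypothalamus — are characterized in slice experiments by three
complementary assays: current-clamp step protocols for intrinsic membrane
and action-potential (AP) properties, channelrhodopsin-assisted circuit
mapping (CRACM) for synaptic connectivity, and single-cell RT-qPCR for the
ion-channel transcripts (Kv3.1, Kv3.2, Hcn2) that underlie the phenotype.
`fastspike` implements the full analysis chain for all three, together with
a ground-truth simulator so that every extraction stage has a recovery test.

## What it computes

**Passive properties** (`fastspike.passive_features`), from 500 ms current
steps (−100 pA … 1500 pA):

- resting potential V_rmp (pre-stimulus baseline mean),
- input resistance R_in = slope of the steady-state V–I relation over
  hyperpolarizing steps (OLS, MΩ),
- membrane time constant τ_m from a single-exponential fit
  V(t) = V₀ + ΔV·(1 − e^(−t/τ)) restricted to the onset-to-63.2% rising
  phase of the mean −100 pA response,
- sag ratio V_steady / V_hyp (deflections from baseline; < 1 indicates an
  H-current),
- derived capacitance C_mem = τ_m / R_in.

**AP and train properties** (`fastspike.spike_features`): spikes are local
maxima above −10 mV preceded within 2 ms by dV/dt ≥ 20 V/s; the AP
threshold is the potential where dV/dt first reaches 20 V/s; amplitude and
fAHP are measured relative to threshold; half-width is the duration at the
threshold-to-peak half level (linear interpolation between samples); AP
broadening is (HW₂ − HW₁)/HW₁ at twice the first-evoked-AP current; the
maximal firing frequency is the rate on the largest step below the first
step with AP failures; I–f curves aggregate rates across cells per current.

**CRACM** (`fastspike.cracm_connectivity`): ten consecutive light-aligned
voltage-clamp sweeps are averaged; the EPSC amplitude is the baseline-to-
trough magnitude in a 1–20 ms post-light window; a cell is connected when
that amplitude exceeds max(4 pA, 5 × baseline sd); pharmacological block is
the blocked/control amplitude ratio; population connectivity gets an exact
binomial (Clopper–Pearson) 95% CI.

**qPCR** (`fastspike.qpcr_ddct`): triplicate Ct values are collapsed after
the limit-of-detection rule (Ct > 37 censored), and relative expression is
2^−ΔΔCt with ΔCt taken against the mean of the reference genes (Pvalb,
Vglut2 by default) and a configurable calibrator.

**Simulators** (`fastspike.synthetic_data`): an adaptive exponential
integrate-and-fire (AdEx) neuron with a first-order H-current (fixed-step
Euler on the 10 kHz sample grid, logged spike times), a light-evoked EPSC
generator with latency jitter, failures and pharmacological block, and a
triplicate Ct-plate generator with dropout and detection limits.

## Worked example

```python
from fastspike import NeuronModelParams, StepProtocol, simulate_current_clamp, characterize

rec = simulate_current_clamp(NeuronModelParams(), StepProtocol.standard(), seed=3)
print(characterize(rec))
```

```
v_rmp_mv                   -65.895888
r_in_mohm                  312.000280
tau_m_ms                    12.191872
sag_ratio                    0.981079
c_mem_pf_derived            39.076478
ap_threshold_mv            -37.455320
ap_latency_ms               37.100000
ap_amplitude_mv             37.455320
ap_half_width_ms             0.084050
fahp_amplitude_mv           17.544680
fahp_latency_ms              0.200000
ap_broadening               -0.001517
max_firing_frequency_hz    386.000000
```

The default preset is a fast-spiking cell: the resting potential sits near
−66 mV, the −100 pA step shows a small sag (ratio 0.98), spikes are
sub-millisecond and minimally accommodating (broadening ≈ 0), and the cell
sustains rates well above 100 Hz without depolarization block.  The same
extraction runs on recorded sweeps loaded with
`fastspike.read_recording` (plain delimited text with a `#`-header; see
`docs/methods.md`).

The same chain is available from the shell:

```
fastspike simulate iclamp --seed 3 --out cell.tsv
fastspike extract spikes cell.tsv --out report.tsv
fastspike simulate cracm --seed 4 --out cr
fastspike cracm cr.control.tsv --blocked cr.blocked.tsv --out epsc.tsv
fastspike simulate qpcr --seed 5 --out plate.tsv
fastspike qpcr plate.tsv --targets Kv3.1,Kv3.2,Hcn2 --references Pvalb,Vglut2 --out ra.tsv
```

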