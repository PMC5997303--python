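"""One-call intrinsic-property report for a full step-protocol recording.

Produces the standard characterization table of a cell: passive properties
(resting potential, input resistance, time constant, sag ratio, derived
capacitance) plus single-AP and train-level properties (threshold, latency,
amplitude, half-width, fAHP, broadening, maximal firing frequency).
Capacitance is flagged "derived" because it is computed as tau_m / R_in
rather than read from an amplifier dialog; the accommodation metrics are
operational summaries of a qualitative phenomenon, not published formulas.
"""

from __future__ import annotations

import pandas as pd

from . import passive_features, spike_features
from .sweep_model import Recording

__all__ = ["characterize"]


def characterize(rec: Recording) -> pd.Series:
    """Extract the full intrinsic-property report from one recording."""
    passive = passive_features.extract_passive(rec)
    first_ap = spike_features.first_evoked_ap(rec)
    broadening = spike_features.ap_broadening(rec)
    max_ff = spike_features.max_firing_frequency(rec)
    return pd.Series(
        {
            "v_rmp_mv": passive.v_rmp,
            "r_in_mohm": passive.r_in,
            "tau_m_ms": passive.tau_m,
            "sag_ratio": passive.sag_ratio,
            "c_mem_pf_derived": passive.c_mem,
            "ap_threshold_mv": first_ap.threshold_v,
            "ap_latency_ms": first_ap.latency,
            "ap_amplitude_mv": first_ap.amplitude,
            "ap_half_width_ms": first_ap.half_width,
            "fahp_amplitude_mv": first_ap.fahp_amplitude,
            "fahp_latency_ms": first_ap.fahp_latency,
            "ap_broadening": float("nan") if broadening is None else broadening,
            "max_firing_frequency_hz": float("nan") if max_ff is None else max_ff,
        }
    )
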