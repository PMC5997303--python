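"""Data model and text I/O for protocolized sweep recordings.

Conventions used throughout the package:

* time is in milliseconds with t = 0 at the start of each sweep;
* current-clamp samples are membrane potential in mV, voltage-clamp samples
  are current in pA;
* injected currents / command steps are in pA;
* the default digitization rate is 10 kHz.

Stimulus timing is carried as metadata on each sweep, never inferred from the
trace itself.  Voltages are stored as measured; no liquid-junction-potential
correction is applied.

The on-disk format is plain delimited text: ``#``-prefixed ``key=value``
header lines followed by one column per sweep, one row per sample.  Floats
are written with ``%.17g`` so a write/read round trip reproduces samples
bit-exactly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, PreconditionError, ValidationError

__all__ = [
    "RecordingMode",
    "Sweep",
    "StepProtocol",
    "Recording",
    "baseline_window",
    "read_recording",
    "write_recording",
]

_MAGIC = "# fastspike-recording v1"


class RecordingMode(str, enum.Enum):
    CURRENT_CLAMP = "current_clamp"
    VOLTAGE_CLAMP = "voltage_clamp"


@dataclass
class Sweep:
    """A single time-aligned trace plus its stimulus metadata.

    Parameters
    ----------
    samples
        Trace samples (mV in current clamp, pA in voltage clamp).
    sampling_rate
        Digitization rate in Hz.
    stimulus_onset, stimulus_duration
        Stimulus timing in ms from sweep start.  For light-pulse protocols the
        "stimulus" is the light pulse.
    stimulus_amplitude
        Current-step command in pA, or a light-pulse marker (1.0) for
        optogenetic sweeps.
    mode
        Recording configuration; determines the sample units.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    stimulus_onset: float = 0.0
    stimulus_duration: float = 0.0
    stimulus_amplitude: float = 0.0
    mode: RecordingMode = RecordingMode.CURRENT_CLAMP

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.stimulus_onset < 0:
            raise ValidationError("stimulus_onset must be >= 0")
        if self.stimulus_duration < 0:
            raise ValidationError("stimulus_duration must be >= 0")
        self.mode = RecordingMode(self.mode)
        # allow the stimulus to end exactly at the last sample (half-sample slack)
        if self.stimulus_onset + self.stimulus_duration > self.duration_ms + 0.5 * self.dt_ms:
            raise ValidationError(
                "stimulus window extends past the end of the sweep "
                f"({self.stimulus_onset} + {self.stimulus_duration} ms > "
                f"{self.duration_ms:.3f} ms)"
            )

    # -- geometry helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms``, clipped to the valid range."""
        return int(np.clip(round(t_ms / self.dt_ms), 0, self.n_samples - 1))

    def window(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        """Samples in the half-open time window [t0, t1) ms."""
        i0 = max(0, int(math.ceil(t0_ms / self.dt_ms - 1e-9)))
        i1 = min(self.n_samples, int(math.ceil(t1_ms / self.dt_ms - 1e-9)))
        return self.samples[i0:i1]

    def with_samples(self, samples: np.ndarray) -> "Sweep":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class StepProtocol:
    """An ordered family of current steps delivered from a holding level.

    The default geometry is the standard characterization protocol: 500 ms
    steps with 100 ms of pre- and post-stimulus holding at rest, digitized at
    10 kHz.
    """

    step_amplitudes: Sequence[float]
    step_duration: float = 500.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    sampling_rate: float = 10_000.0
    holding: str = "rest"

    def __post_init__(self) -> None:
        amps = [float(a) for a in self.step_amplitudes]
        if len(amps) == 0:
            raise ValidationError("step_amplitudes must be non-empty")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValidationError("step_amplitudes must be strictly increasing")
        if self.step_duration <= 0 or self.pre_ms < 0 or self.post_ms < 0:
            raise ValidationError("invalid protocol geometry")
        self.step_amplitudes = amps

    @classmethod
    def standard(cls, **kwargs) -> "StepProtocol":
        """Full characterization protocol: -100..100 pA in 20 pA increments
        (hyperpolarizing family plus the first-AP series), then 150..1500 pA
        in 50 pA increments."""
        amps = list(range(-100, 101, 20)) + list(range(150, 1501, 50))
        return cls(step_amplitudes=amps, **kwargs)

    @classmethod
    def first_ap(cls, **kwargs) -> "StepProtocol":
        """First-evoked-AP series: 20-100 pA in 20 pA increments."""
        return cls(step_amplitudes=list(range(20, 101, 20)), **kwargs)

    @classmethod
    def hyperpolarizing(cls, **kwargs) -> "StepProtocol":
        """Subthreshold family for passive properties: -100..-20 pA."""
        return cls(step_amplitudes=list(range(-100, -19, 20)), **kwargs)


@dataclass
class Recording:
    """A list of sweeps from one cell sharing sampling rate and mode."""

    sweeps: list[Sweep] = field(default_factory=list)
    cell_id: str = "cell"
    temperature: float = 32.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sweeps:
            rate = self.sweeps[0].sampling_rate
            mode = self.sweeps[0].mode
            for i, s in enumerate(self.sweeps):
                if s.sampling_rate != rate:
                    raise ValidationError(f"sweep {i} has a different sampling_rate")
                if s.mode != mode:
                    raise ValidationError(f"sweep {i} has a different recording mode")

    @property
    def sampling_rate(self) -> float:
        if not self.sweeps:
            raise ValidationError("empty recording has no sampling_rate")
        return self.sweeps[0].sampling_rate

    @property
    def mode(self) -> RecordingMode:
        if not self.sweeps:
            raise ValidationError("empty recording has no mode")
        return self.sweeps[0].mode

    def sweeps_at(self, amplitude: float, tol: float = 0.5) -> list[Sweep]:
        """All sweeps whose stimulus amplitude is within ``tol`` pA."""
        return [s for s in self.sweeps if abs(s.stimulus_amplitude - amplitude) <= tol]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def baseline_window(sweep: Sweep, length_ms: float) -> tuple[float, float]:
    """Mean and sample standard deviation over the pre-stimulus window.

    The window is the ``length_ms`` interval ending at ``stimulus_onset``.
    """
    if length_ms <= 0:
        raise PreconditionError("baseline window length must be > 0")
    if length_ms > sweep.stimulus_onset + 0.5 * sweep.dt_ms:
        raise PreconditionError(
            f"baseline window ({length_ms} ms) exceeds pre-stimulus segment "
            f"({sweep.stimulus_onset} ms)"
        )
    seg = sweep.window(sweep.stimulus_onset - length_ms, sweep.stimulus_onset)
    if seg.size == 0:
        raise PreconditionError("baseline window contains no samples")
    sd = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
    return float(np.mean(seg)), sd


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as ``#``-headed delimited text (one column/sweep)."""
    path = Path(path)
    n_sweeps = len(rec.sweeps)
    if n_sweeps:
        lengths = {s.n_samples for s in rec.sweeps}
        if len(lengths) != 1:
            raise ValidationError("all sweeps in a file must have equal length")

    def _csv(vals):
        return ",".join("%.17g" % v for v in vals)

    lines = [
        _MAGIC,
        f"# cell_id={rec.cell_id}",
        f"# mode={rec.mode.value if n_sweeps else RecordingMode.CURRENT_CLAMP.value}",
        "# sampling_rate_hz=%.17g" % (rec.sampling_rate if n_sweeps else 10_000.0),
        "# temperature_c=%.17g" % rec.temperature,
        f"# n_sweeps={n_sweeps}",
    ]
    if n_sweeps:
        lines += [
            "# stimulus_onset_ms=" + _csv(s.stimulus_onset for s in rec.sweeps),
            "# stimulus_duration_ms=" + _csv(s.stimulus_duration for s in rec.sweeps),
            "# stimulus_amplitude_pa=" + _csv(s.stimulus_amplitude for s in rec.sweeps),
        ]
    lines.append("# annotations=" + json.dumps(rec.annotations, sort_keys=True))
    body = []
    if n_sweeps:
        data = np.column_stack([s.samples for s in rec.sweeps])
        body = ["\t".join("%.17g" % v for v in row) for row in data]
    path.write_text("\n".join(lines + body) + "\n")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending line for malformed
    headers, and :class:`ValidationError` if the declared metadata is
    inconsistent (e.g. mixed modes cannot occur, a single mode is declared
    per file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if lineno == 1:
                    if line.strip() != _MAGIC:
                        raise FormatError(f"{path}, line 1: not a fastspike recording file")
                    continue
                payload = line.lstrip("#").strip()
                if "=" not in payload:
                    raise FormatError(f"{path}, line {lineno}: malformed header line {line!r}")
                key, _, value = payload.partition("=")
                header[key.strip()] = value.strip()
            else:
                if lineno == 1:
                    raise FormatError(f"{path}, line 1: not a fastspike recording file")
                data_lines.append(line)

    def _require(key: str) -> str:
        if key not in header:
            raise FormatError(f"{path}: header lacks required field {key!r}")
        return header[key]

    try:
        rate = float(_require("sampling_rate_hz"))
    except ValueError as exc:
        raise FormatError(f"{path}: sampling_rate_hz is not a number") from exc
    mode_str = _require("mode")
    try:
        mode = RecordingMode(mode_str)
    except ValueError as exc:
        raise FormatError(f"{path}: unknown mode {mode_str!r}") from exc
    try:
        n_sweeps = int(_require("n_sweeps"))
    except ValueError as exc:
        raise FormatError(f"{path}: n_sweeps is not an integer") from exc
    cell_id = header.get("cell_id", path.stem)
    temperature = float(header.get("temperature_c", "32"))
    try:
        annotations = json.loads(header.get("annotations", "{}"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: annotations header is not valid JSON") from exc

    def _floats(key: str, default: float) -> list[float]:
        if key not in header:
            return [default] * n_sweeps
        vals = [float(v) for v in header[key].split(",") if v != ""]
        if len(vals) != n_sweeps:
            raise FormatError(f"{path}: {key} lists {len(vals)} values for {n_sweeps} sweeps")
        return vals

    onsets = _floats("stimulus_onset_ms", 0.0)
    durations = _floats("stimulus_duration_ms", 0.0)
    amplitudes = _floats("stimulus_amplitude_pa", 0.0)

    if n_sweeps == 0:
        return Recording(sweeps=[], cell_id=cell_id, temperature=temperature,
                         annotations=annotations)

    try:
        data = np.array([[float(v) for v in line.split()] for line in data_lines])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample value in data block") from exc
    if data.ndim != 2 or data.shape[1] != n_sweeps:
        raise FormatError(
            f"{path}: data block has {0 if data.size == 0 else data.shape[1]} columns "
            f"for {n_sweeps} declared sweeps"
        )
    sweeps = [
        Sweep(
            samples=data[:, k],
            sampling_rate=rate,
            stimulus_onset=onsets[k],
            stimulus_duration=durations[k],
            stimulus_amplitude=amplitudes[k],
            mode=mode,
        )
        for k in range(n_sweeps)
    ]
    return Recording(sweeps=sweeps, cell_id=cell_id, temperature=temperature,
                     annotations=annotations)
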