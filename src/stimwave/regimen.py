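"""Digital twin of the electrical-stimulation signal generator.

Models charge-balanced pulse trains (biphasic, monophasic, alternating
monophasic), static and linearly ramped stimulation schedules, waveform
sampling, and signal-fidelity assessment against nominal pulse parameters.

Conventions
-----------
* ``phase_duration_ms`` is the duration of ONE phase, so a biphasic pulse
  occupies ``2 * phase_duration_ms`` of each period.  Use
  :meth:`PulseSpec.from_total_width` when a protocol states the total
  biphasic width instead.
* The cathodic (+V) phase leads; the anodic (-V) phase follows.
* Ramped schedules interpolate linearly in time between the start and end
  specification; rates are exposed per minute and per day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PulseShape",
    "PulseSpec",
    "RegimenSchedule",
    "SampledWaveform",
    "FidelityReport",
    "PulseDetectionError",
    "build_schedule",
    "param_at",
    "sample_waveform",
    "measure_pulse",
    "fidelity_report",
]

#: Device operating range, enforced only when device realism is requested.
DEVICE_PHASE_RANGE_MS = (2.0, 1000.0)
DEVICE_MAX_FREQUENCY_HZ = 50.0


class PulseShape(str, enum.Enum):
    BIPHASIC = "biphasic"
    MONOPHASIC = "monophasic"
    ALTERNATING_MONOPHASIC = "alternating_monophasic"


class PulseDetectionError(RuntimeError):
    """Raised when a waveform contains no threshold crossings (no pulse)."""


@dataclass(frozen=True)
class PulseSpec:
    """Nominal parameters of a periodic stimulation pulse train.

    voltage is the pulse amplitude in volts; phase_duration_ms the duration
    of a single phase in milliseconds; frequency_hz the pulse repetition
    rate.
    """

    shape: PulseShape
    voltage: float
    phase_duration_ms: float
    frequency_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", PulseShape(self.shape))
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if self.phase_duration_ms <= 0:
            raise ValueError("phase_duration_ms must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.frequency_hz * self.total_width_ms > 1000.0 + 1e-9:
            raise ValueError(
                f"pulse of {self.total_width_ms} ms does not fit in a "
                f"{1000.0 / self.frequency_hz} ms period"
            )

    @classmethod
    def from_total_width(cls, shape: PulseShape | str, voltage: float,
                         total_width_ms: float, frequency_hz: float) -> "PulseSpec":
        """Build a spec from the TOTAL pulse width (both phases for biphasic)."""
        shape = PulseShape(shape)
        per_phase = total_width_ms / 2 if shape is PulseShape.BIPHASIC else total_width_ms
        return cls(shape, voltage, per_phase, frequency_hz)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def total_width_ms(self) -> float:
        """Width of one pulse: both phases for biphasic, one otherwise."""
        if self.shape is PulseShape.BIPHASIC:
            return 2.0 * self.phase_duration_ms
        return self.phase_duration_ms

    def validate_device_limits(self) -> None:
        """Check the spec against the physical device's operating range."""
        lo, hi = DEVICE_PHASE_RANGE_MS
        if not (lo <= self.phase_duration_ms <= hi):
            raise ValueError(
                f"phase duration {self.phase_duration_ms} ms outside device range [{lo}, {hi}] ms"
            )
        if self.frequency_hz > DEVICE_MAX_FREQUENCY_HZ:
            raise ValueError(
                f"frequency {self.frequency_hz} Hz exceeds device maximum {DEVICE_MAX_FREQUENCY_HZ} Hz"
            )


#: Fields of a PulseSpec a schedule may ramp.
RAMPABLE_FIELDS = ("frequency_hz", "phase_duration_ms")


@dataclass(frozen=True)
class RegimenSchedule:
    """A stimulation regimen: pulse parameters evolving linearly over days."""

    start_spec: PulseSpec
    end_spec: PulseSpec
    duration_days: float
    ramped_fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        object.__setattr__(self, "ramped_fields", tuple(self.ramped_fields))
        for f in self.ramped_fields:
            if f not in RAMPABLE_FIELDS:
                raise ValueError(f"cannot ramp field {f!r}; rampable: {RAMPABLE_FIELDS}")
        if self.start_spec.shape is not self.end_spec.shape:
            raise ValueError("shape may not change over a schedule")
        for f in ("voltage", *RAMPABLE_FIELDS):
            if f in self.ramped_fields:
                continue
            a, b = getattr(self.start_spec, f), getattr(self.end_spec, f)
            if a != b:
                raise ValueError(f"non-ramped field {f!r} differs between endpoints ({a} != {b})")

    @property
    def duration_minutes(self) -> float:
        return self.duration_days * 1440.0

    def rate_per_minute(self, field: str) -> float:
        """Linear ramp rate of ``field`` in its unit per minute (0 if static)."""
        if field not in self.ramped_fields:
            return 0.0
        delta = getattr(self.end_spec, field) - getattr(self.start_spec, field)
        return delta / self.duration_minutes

    def rate_per_day(self, field: str) -> float:
        return self.rate_per_minute(field) * 1440.0


def build_schedule(kind: str, start: PulseSpec, end: PulseSpec,
                   duration_days: float) -> RegimenSchedule:
    """Construct a static or ramped stimulation schedule.

    ``kind`` is one of ``static``, ``ramped_frequency``, ``ramped_duration``.
    For a static schedule the endpoints must be identical; ramped schedules
    interpolate the named field linearly between the endpoints while all
    other fields stay fixed.
    """
    kinds = {
        "static": (),
        "ramped_frequency": ("frequency_hz",),
        "ramped_duration": ("phase_duration_ms",),
    }
    if kind not in kinds:
        raise ValueError(f"unknown schedule kind {kind!r}; expected one of {sorted(kinds)}")
    if kind == "static" and start != end:
        raise ValueError("static schedule requires identical start and end specs")
    return RegimenSchedule(start, end, duration_days, kinds[kind])


def param_at(schedule: RegimenSchedule, t_minutes: float) -> PulseSpec:
    """Pulse parameters in effect ``t_minutes`` into the schedule.

    Linear interpolation of the ramped fields; exact endpoints at t = 0 and
    t = duration.  Raises ``ValueError`` outside the schedule span.
    """
    total = schedule.duration_minutes
    if not (0.0 <= t_minutes <= total):
        raise ValueError(f"t = {t_minutes} min outside schedule span [0, {total}] min")
    if t_minutes == 0.0:
        return schedule.start_spec
    if t_minutes == total:
        return schedule.end_spec
    frac = t_minutes / total
    updates = {}
    for f in schedule.ramped_fields:
        a = getattr(schedule.start_spec, f)
        b = getattr(schedule.end_spec, f)
        updates[f] = a + frac * (b - a)
    return replace(schedule.start_spec, **updates)


@dataclass(frozen=True)
class SampledWaveform:
    """A uniformly sampled voltage trace (oscilloscope-style recording)."""

    times: np.ndarray       # seconds, strictly increasing
    voltages: np.ndarray    # volts
    sample_rate: float      # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def charge(self) -> float:
        """Net charge proxy: integral of voltage over time (V * s)."""
        return float(self.voltages.sum() / self.sample_rate)


def sample_waveform(spec: PulseSpec, window_s: float, sample_rate: float) -> SampledWaveform:
    """Render a pulse train as a uniformly sampled voltage trace.

    Pulse edges are snapped to the nearest sample index, computed per pulse
    from the nominal period (no cumulative drift).  Snapping gives the
    cathodic and anodic phases identical sample counts, so a biphasic
    train is charge balanced exactly, and any measured duration is within
    half a sample period of nominal.
    """
    phase_s = spec.phase_duration_ms / 1000.0
    if sample_rate < 100.0 / phase_s:
        raise ValueError("sample_rate must give at least 100 samples per phase")
    period_s = 1.0 / spec.frequency_hz
    if window_s < period_s:
        raise ValueError("window must cover at least one pulse period")

    n = int(round(window_s * sample_rate))
    v = np.zeros(n)
    phase_n = int(round(phase_s * sample_rate))
    n_pulses = int(np.floor(window_s / period_s))
    for k in range(n_pulses):
        start = int(round(k * period_s * sample_rate))
        if spec.shape is PulseShape.BIPHASIC:
            v[start:start + phase_n] = spec.voltage
            v[start + phase_n:start + 2 * phase_n] = -spec.voltage
        elif spec.shape is PulseShape.MONOPHASIC:
            v[start:start + phase_n] = spec.voltage
        else:  # alternating monophasic: polarity flips on successive periods
            polarity = 1.0 if k % 2 == 0 else -1.0
            v[start:start + phase_n] = polarity * spec.voltage
    t = np.arange(n) / sample_rate
    return SampledWaveform(t, v, sample_rate)


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of contiguous True runs in a boolean array."""
    if not mask.any():
        return np.array([], dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return stops - starts


def measure_pulse(waveform: SampledWaveform,
                  amplitude_threshold_fraction: float = 0.5) -> tuple[float, float, float]:
    """Measure cathodic, anodic, and total pulse durations (ms) from a trace.

    Durations are taken between crossings of ``amplitude_threshold_fraction``
    times the observed amplitude (mid-amplitude timing by default) and
    averaged over all detected pulses.  The anodic duration is 0 for purely
    positive (monophasic) trains.  Total = cathodic + anodic.
    """
    if not (0.0 < amplitude_threshold_fraction < 1.0):
        raise ValueError("threshold fraction must be in (0, 1)")
    v = waveform.voltages
    amp = float(np.max(np.abs(v))) if v.size else 0.0
    if amp == 0.0:
        raise PulseDetectionError("no pulse detected: waveform is flat")
    thr = amplitude_threshold_fraction * amp
    pos = _run_lengths(v > thr)
    neg = _run_lengths(v < -thr)
    if pos.size == 0 and neg.size == 0:
        raise PulseDetectionError("no pulse detected: no threshold crossings")
    to_ms = 1000.0 / waveform.sample_rate
    cathodic = float(pos.mean() * to_ms) if pos.size else 0.0
    anodic = float(neg.mean() * to_ms) if neg.size else 0.0
    return cathodic, anodic, cathodic + anodic


@dataclass(frozen=True)
class FidelityReport:
    """Measured vs expected pulse durations with per-quantity percent error."""

    cathodic_ms: float
    anodic_ms: float
    total_ms: float
    expected_cathodic_ms: float
    expected_anodic_ms: float
    expected_total_ms: float
    percent_error_cathodic: float
    percent_error_anodic: float
    percent_error_total: float

    @property
    def max_percent_error(self) -> float:
        return max(self.percent_error_cathodic, self.percent_error_anodic,
                   self.percent_error_total)


def _percent_error(measured: float, expected: float) -> float:
    if expected == 0.0:
        if measured == 0.0:
            return 0.0  # e.g. anodic phase of a monophasic pulse: nothing to miss
        raise ZeroDivisionError("percent error undefined for zero expected duration")
    if expected < 0:
        raise ValueError("expected durations must be non-negative")
    return abs(measured - expected) / expected * 100.0


def fidelity_report(measured: tuple[float, float, float],
                    expected: tuple[float, float, float]) -> FidelityReport:
    """Percent error of measured pulse durations against nominal values.

    ``measured`` and ``expected`` are (cathodic_ms, anodic_ms, total_ms)
    triples, as returned by :func:`measure_pulse`.
    """
    m_c, m_a, m_t = measured
    e_c, e_a, e_t = expected
    return FidelityReport(
        m_c, m_a, m_t, e_c, e_a, e_t,
        _percent_error(m_c, e_c),
        _percent_error(m_a, e_a),
        _percent_error(m_t, e_t),
    )


def expected_durations(spec: PulseSpec) -> tuple[float, float, float]:
    """Nominal (cathodic_ms, anodic_ms, total_ms) for a pulse spec."""
    pd = spec.phase_duration_ms
    if spec.shape is PulseShape.BIPHASIC:
        return pd, pd, 2 * pd
    if spec.shape is PulseShape.MONOPHASIC:
        return pd, 0.0, pd
    # alternating monophasic: half the pulses are positive, half negative
    return pd, pd, 2 * pd
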