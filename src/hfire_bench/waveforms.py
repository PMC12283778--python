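"""Ideal H-FIRE burst waveform construction and spectral characterization.

An H-FIRE burst is a train of ``cycles`` repetitions of the pattern

    +pulse (PW) | interphase delay d1 | -pulse (PW) | interpulse delay d2

written in the field's shorthand ``"PW-d1-PW-d2"`` (all in microseconds),
e.g. ``"2-5-2-5"``.  One cycle lasts ``2*PW + d1 + d2``; the reciprocal of
that period is the burst's characteristic frequency, which coincides with
the dominant nonzero peak of the burst's magnitude spectrum for ideal
square bursts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BurstProtocol",
    "IdealTrace",
    "Spectrum",
    "build_burst",
    "cycle_period",
    "characteristic_frequency",
    "power_spectrum",
    "cycles_for_ontime",
    "pulse_windows",
]

#: default burst on-time target (µs) used when a protocol does not fix cycles;
#: short bipolar pulses are repeated until their summed on-time is comparable
#: with a conventional long monopolar IRE pulse.
DEFAULT_ONTIME_US = 100.0

#: oscilloscope sampling period (ns) guaranteeing >= 500 points on the
#: shortest (1 µs) pulse.
DEFAULT_SAMPLING_PERIOD_NS = 2.0

_LABEL_RE = re.compile(r"^\s*([0-9.]+)\s*-\s*([0-9.]+)\s*-\s*([0-9.]+)\s*-\s*([0-9.]+)\s*$")


def cycles_for_ontime(pulse_width_us: float, target_ontime_us: float = DEFAULT_ONTIME_US) -> int:
    """Smallest cycle count whose total on-time (2*PW per cycle) reaches the target."""
    if pulse_width_us <= 0 or target_ontime_us <= 0:
        raise ValueError("pulse width and target on-time must be positive")
    return math.ceil(target_ontime_us / (2.0 * pulse_width_us))


@dataclass(frozen=True)
class BurstProtocol:
    """Full parameterization of an H-FIRE burst train.

    Durations are in microseconds except the sampling period (ns) and the
    optional burst interval (s).  ``cycles=None`` resolves to the smallest
    count giving >= 100 µs total on-time.
    """

    pulse_width_us: float
    d1_us: float
    d2_us: float
    cycles: int | None = None
    n_bursts: int = 1
    amplitude_v: float = 1.0
    sampling_period_ns: float = DEFAULT_SAMPLING_PERIOD_NS
    burst_interval_s: float | None = None

    def __post_init__(self) -> None:
        if self.pulse_width_us <= 0:
            raise ValueError(f"pulse width must be positive, got {self.pulse_width_us}")
        if self.d1_us < 0 or self.d2_us < 0:
            raise ValueError("delays must be non-negative")
        if self.sampling_period_ns <= 0:
            raise ValueError("sampling period must be positive")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if self.cycles is None:
            object.__setattr__(self, "cycles", cycles_for_ontime(self.pulse_width_us))
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    # -- label round-trip ---------------------------------------------------

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "BurstProtocol":
        """Parse the canonical ``"PW-d1-PW-d2"`` shorthand (µs)."""
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"cannot parse protocol label {label!r}")
        pw1, d1, pw2, d2 = (float(g) for g in m.groups())
        if pw1 != pw2:
            raise ValueError(
                f"asymmetric pulse widths in label {label!r}; positive and "
                "negative phases must share one pulse width"
            )
        return cls(pulse_width_us=pw1, d1_us=d1, d2_us=d2, **kwargs)

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return "-".join(
            [fmt(self.pulse_width_us), fmt(self.d1_us), fmt(self.pulse_width_us), fmt(self.d2_us)]
        )

    @property
    def cycle_period_us(self) -> float:
        return 2.0 * self.pulse_width_us + self.d1_us + self.d2_us

    @property
    def duration_us(self) -> float:
        """Duration of one burst."""
        return self.cycles * self.cycle_period_us

    @property
    def dt_us(self) -> float:
        return self.sampling_period_ns * 1e-3

    @property
    def n_samples(self) -> int:
        return round(self.duration_us / self.dt_us)

    @property
    def samples_per_pulse(self) -> int:
        return round(self.pulse_width_us / self.dt_us)

    def with_amplitude(self, amplitude_v: float) -> "BurstProtocol":
        return replace(self, amplitude_v=amplitude_v)


@dataclass(frozen=True)
class IdealTrace:
    """Uniformly sampled voltage series for one ideal square burst."""

    sampling_period_ns: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sampling_period_ns <= 0:
            raise ValueError("sampling period must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_period_ns * 1e-9


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum; frequencies start at 0 Hz, increasing."""

    frequencies_hz: np.ndarray = field(repr=False)
    magnitude: np.ndarray = field(repr=False)
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.frequencies_hz.size != self.magnitude.size:
            raise ValueError("frequency and magnitude arrays must align")

    @property
    def peak_frequency_hz(self) -> float:
        """Frequency of the largest nonzero-frequency magnitude."""
        if self.frequencies_hz.size < 2:
            raise ValueError("spectrum has no nonzero-frequency bins")
        i = 1 + int(np.argmax(self.magnitude[1:]))
        return float(self.frequencies_hz[i])


def cycle_period(protocol: BurstProtocol) -> float:
    """Duration of one full cycle, 2*PW + d1 + d2, in µs."""
    return protocol.cycle_period_us


def characteristic_frequency(protocol: BurstProtocol) -> float:
    """Fundamental frequency of the repeating cycle, in kHz.

    Defined as the reciprocal of one full cycle period; for ideal square
    bursts this matches the dominant nonzero peak of :func:`power_spectrum`
    within one frequency bin.
    """
    period_us = cycle_period(protocol)
    if period_us <= 0:
        raise ValueError("cycle period must be positive")
    return 1e3 / period_us  # 1/µs = MHz -> kHz


def pulse_windows(protocol: BurstProtocol) -> list[tuple[int, int, int, int]]:
    """Sample-index windows of every pulse in one burst.

    Returns ``(start, end, polarity, cycle_index)`` half-open tuples, two per
    cycle, ordered in time.  Pulse starts are placed by rounding the ideal
    start times to the sample grid; every pulse spans exactly
    ``round(PW/dt)`` samples so positive and negative on-times match.
    """
    dt = protocol.dt_us
    n_pw = protocol.samples_per_pulse
    if n_pw < 1:
        raise ValueError("sampling period too coarse: pulse shorter than one sample")
    out: list[tuple[int, int, int, int]] = []
    for k in range(protocol.cycles):
        t0 = k * protocol.cycle_period_us
        pos = round(t0 / dt)
        neg = round((t0 + protocol.pulse_width_us + protocol.d1_us) / dt)
        out.append((pos, pos + n_pw, +1, k))
        out.append((neg, neg + n_pw, -1, k))
    return out


def build_burst(protocol: BurstProtocol) -> IdealTrace:
    """Construct one ideal square burst: values in {+A, 0, -A}.

    The burst begins with a positive pulse; total duration is
    ``cycles * (2*PW + d1 + d2)`` and the sample count is
    ``round(duration / dt)``.
    """
    n = protocol.n_samples
    if n < 2:
        raise ValueError("protocol too short for its sampling period")
    v = np.zeros(n)
    for start, end, pol, _ in pulse_windows(protocol):
        v[start:min(end, n)] = pol * protocol.amplitude_v
    return IdealTrace(sampling_period_ns=protocol.sampling_period_ns, samples=v)


def power_spectrum(trace: IdealTrace, normalization: str = "none") -> Spectrum:
    """One-sided discrete Fourier magnitude spectrum of a burst.

    ``normalization="unit-energy"`` rescales so the squared magnitudes sum
    to 1, leaving only relative frequency content.  Charge-balanced bursts
    have zero magnitude in the DC bin.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    if normalization not in ("none", "unit-energy"):
        raise ValueError(f"unknown normalization {normalization!r}")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=trace.sampling_period_ns * 1e-9)
    if normalization == "unit-energy":
        energy = math.sqrt(float(np.sum(mag**2)))
        if energy > 0:
            mag = mag / energy
    return Spectrum(frequencies_hz=freqs, magnitude=mag, normalization=normalization)
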