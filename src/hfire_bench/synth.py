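"""Synthetic tissue + virtual oscilloscope: seeded voltage/current traces with
the biophysical structure the analysis pipeline assumes.

The generator emulates what the bench setup records: an ideal square bipolar
burst on the voltage channel, and a current channel derived from a lumped
tissue resistance ``R = 1/(sigma * S)`` where ``S`` is the electrode
geometry's shape factor and ``sigma`` is a nonlinear, pulse-width-dependent,
electroporation-dependent conductivity.  Two conductivity modes exist:

* ``phenomenological`` — sigma depends only on the applied distance-normalized
  voltage (V/cm) and the pulse width, through a sigmoidal rise from the
  non-electroporated bulk value to an electroporated plateau.  This is the
  contract surface: it encodes the apparent quantities the experiments
  measure (bulk ~0.13 S/m at 1 µs vs ~0.04 S/m at 10 µs; plateaus
  ~0.55 / 0.67 S/m).
* ``mechanistic`` — sigma additionally relaxes in time within each pulse with
  the membrane-charging time constant (~1 µs), qualitatively explaining why
  short pulses see a higher apparent conductivity (the membrane is still
  charging and shunts current).  Qualitative only.

Interphase and interpulse delays are deliberately *not* inputs to either
conductivity model, and no state is carried across bursts or ramp levels:
delay invariance and ramp memorylessness hold by construction, and the
statistics modules test whether the pipeline recovers those facts.

Noise is additive zero-mean Gaussian per channel, with s.d. equal to
``noise_rel`` times the channel's pulse plateau.  Each pulse and each gap
draws its noise from its own seeded substream, so traces that differ only in
delay durations share identical per-pulse noise for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GeometrySpec, PlateGeometry, voltage_for_field
from .waveforms import BurstProtocol, build_burst, pulse_windows

__all__ = [
    "TissueParams",
    "Trace",
    "apparent_conductivity",
    "mechanistic_conductivity",
    "simulate_trace",
    "simulate_ramp",
    "draw_plate_sample",
]


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    """C2 quintic smoothstep on [-1, 1]: 0 below, 1 above, 0.5 at 0."""
    v = np.clip((np.asarray(u, dtype=float) + 1.0) / 2.0, 0.0, 1.0)
    out = v**3 * (10.0 + v * (-15.0 + 6.0 * v))
    return float(out) if np.isscalar(u) else out


def _as_pw_map(value) -> dict[float, float]:
    if isinstance(value, dict):
        return {float(k): float(v) for k, v in value.items()}
    return {0.0: float(value)}  # scalar: flat in pulse width


def _interp_pw(pw_map: dict[float, float], pulse_width_us: float) -> float:
    """Linear interpolation over pulse width, clamped at the map's ends."""
    keys = sorted(pw_map)
    vals = [pw_map[k] for k in keys]
    if len(keys) == 1:
        return vals[0]
    return float(np.interp(pulse_width_us, keys, vals))


@dataclass(frozen=True)
class TissueParams:
    """Lumped nonlinear tissue model parameters.

    ``sigma_bulk_by_pw`` and ``sigma_max_by_pw`` map pulse width (µs) to the
    non-electroporated and electroporated-plateau conductivities (S/m);
    scalars are accepted and treated as flat in pulse width.  The sigmoid
    transition is centred at ``e_th_v_per_cm`` with half-width
    ``transition_width_v_per_cm``: conductivity equals the bulk value exactly
    below ``E_th - w`` and the plateau exactly above ``E_th + w``.

    ``delay_effect_frac_at_100us`` is a test hook (default 0): a fractional
    conductivity increase proportional to the interpulse delay, used to
    verify the delay-invariance statistics have power against a real effect.
    """

    sigma_bulk_by_pw: dict[float, float] | float
    sigma_max_by_pw: dict[float, float] | float
    e_th_v_per_cm: float = 500.0
    transition_width_v_per_cm: float = 150.0
    tau_mem_us: float = 1.0
    cap_transient_frac: float = 0.10
    cap_transient_tau_us: float = 0.2
    noise_rel: float = 0.01
    mode: str = "phenomenological"
    delay_effect_frac_at_100us: float = 0.0

    def __post_init__(self) -> None:
        bulk = _as_pw_map(self.sigma_bulk_by_pw)
        smax = _as_pw_map(self.sigma_max_by_pw)
        object.__setattr__(self, "sigma_bulk_by_pw", bulk)
        object.__setattr__(self, "sigma_max_by_pw", smax)
        if any(v <= 0 for v in bulk.values()) or any(v <= 0 for v in smax.values()):
            raise ValueError("conductivities must be positive")
        for pw in bulk:
            if _interp_pw(smax, pw) < bulk[pw]:
                raise ValueError("sigma_max must be >= sigma_bulk at every pulse width")
        if self.e_th_v_per_cm <= 0:
            raise ValueError("transition field must be positive")
        if self.transition_width_v_per_cm <= 0:
            raise ValueError("transition width must be positive")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.mode not in ("phenomenological", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def shortest_pw_us(self) -> float:
        return min(self.sigma_bulk_by_pw)

    @property
    def longest_pw_us(self) -> float:
        return max(self.sigma_bulk_by_pw)


def apparent_conductivity(
    e_app_v_per_cm: float, pulse_width_us: float, params: TissueParams
) -> float:
    """Field- and pulse-width-dependent apparent conductivity (S/m).

    sigma(E) = sigma_bulk(PW) + (sigma_max(PW) - sigma_bulk(PW)) * s((E-E_th)/w)
    with ``s`` a quintic smoothstep: exactly the bulk value at low field,
    exactly the plateau at high field, the midpoint at E = E_th.  Delays are
    not inputs.
    """
    if e_app_v_per_cm < 0:
        raise ValueError("applied field must be non-negative")
    bulk = _interp_pw(params.sigma_bulk_by_pw, pulse_width_us)
    smax = _interp_pw(params.sigma_max_by_pw, pulse_width_us)
    u = (e_app_v_per_cm - params.e_th_v_per_cm) / params.transition_width_v_per_cm
    return bulk + (smax - bulk) * _smoothstep(u)


def mechanistic_conductivity(
    t_since_pulse_onset_us: float | np.ndarray,
    e_app_v_per_cm: float,
    pulse_width_us: float,
    params: TissueParams,
) -> float | np.ndarray:
    """Time-resolved conductivity during one pulse (mechanistic mode).

    While the membrane charges (time constant ``tau_mem_us``) it shunts
    current and the tissue looks more conductive; sigma relaxes from the
    short-time value ``sigma_hf`` (bulk conductivity at the shortest modelled
    pulse width) to the steady-state sigmoid ``sigma_ss(E)`` (evaluated at
    the longest modelled pulse width):

        sigma(t, E) = sigma_ss(E) + (sigma_hf - sigma_ss(E)) * exp(-t/tau_mem)
    """
    if params.tau_mem_us <= 0:
        raise ValueError("membrane charging time constant must be positive")
    t = np.asarray(t_since_pulse_onset_us, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since pulse onset must be non-negative")
    sigma_hf = _interp_pw(params.sigma_bulk_by_pw, params.shortest_pw_us)
    sigma_ss = apparent_conductivity(e_app_v_per_cm, params.longest_pw_us, params)
    out = sigma_ss + (sigma_hf - sigma_ss) * np.exp(-t / params.tau_mem_us)
    return float(out) if np.isscalar(t_since_pulse_onset_us) else out


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled voltage/current recording of one burst."""

    sampling_period_ns: float
    voltage_v: np.ndarray = field(repr=False)
    current_a: np.ndarray = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voltage_v.shape != self.current_a.shape:
            raise ValueError("voltage and current series must have equal length")
        if self.sampling_period_ns <= 0:
            raise ValueError("sampling period must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.voltage_v.size)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_period_ns * 1e-9


def _segments(protocol: BurstProtocol, n: int):
    """Alternating (kind, index, start, end, polarity) regions covering [0, n).

    kind 0 = pulse, kind 1 = gap.  Pulses are indexed by position within the
    burst so traces differing only in delays share pulse indices and lengths.
    """
    segs = []
    prev = 0
    gap_i = 0
    for j, (start, end, pol, _) in enumerate(pulse_windows(protocol)):
        end = min(end, n)
        if start > prev:
            segs.append((1, gap_i, prev, start, 0))
            gap_i += 1
        segs.append((0, j, start, end, pol))
        prev = end
    if prev < n:
        segs.append((1, gap_i, prev, n, 0))
    return segs


def _segment_noise(n: int, segs, sd: float, trace_seed: int, channel: int) -> np.ndarray:
    """Per-segment substream Gaussian noise; pulse streams are delay-invariant."""
    out = np.zeros(n)
    if sd <= 0:
        return out
    for kind, idx, start, end, _ in segs:
        rng = np.random.default_rng(np.random.SeedSequence([trace_seed, channel, kind, idx]))
        out[start:end] = rng.normal(0.0, sd, end - start)
    return out


def simulate_trace(
    protocol: BurstProtocol,
    geometry: GeometrySpec,
    params: TissueParams,
    seed: int,
    rise_tau_us: float = 0.0,
    resistance_scale: float = 1.0,
    metadata: dict | None = None,
) -> Trace:
    """Simulate one burst recording.

    The voltage channel is the ideal square burst (optionally smoothed by a
    first-order generator rise-time lag); the current channel is
    ``V * sigma * S`` with a capacitive charging overshoot at each pulse
    onset, plus seeded Gaussian noise on both channels.  Fully reproducible
    from ``seed``; ``resistance_scale`` is a test hook for injecting a ramp
    memory effect.
    """
    if not isinstance(geometry, (PlateGeometry,)) and getattr(geometry, "kind", None) != "needle_pair":
        raise ValueError(f"unknown geometry kind: {geometry!r}")
    dt_us = protocol.dt_us
    ideal = build_burst(protocol).samples
    n = ideal.size
    e_app = protocol.amplitude_v / (geometry.distance_m * 100.0)  # V/cm
    segs = _segments(protocol, n)

    voltage = ideal
    if rise_tau_us > 0:
        from .pipeline import lowpass_first_order

        voltage = lowpass_first_order(ideal, dt_us, rise_tau_us)

    delay_gain = 1.0 + params.delay_effect_frac_at_100us * (protocol.d2_us / 100.0)
    s_geom = geometry.shape_factor_m
    sigma_ss = apparent_conductivity(e_app, protocol.pulse_width_us, params) * delay_gain
    conduct_scale = s_geom / resistance_scale

    if params.mode == "phenomenological":
        current = voltage * (sigma_ss * conduct_scale)
    else:
        current = np.zeros(n)
        for kind, _, start, end, _ in segs:
            if kind != 0:
                continue
            t_rel = np.arange(end - start) * dt_us
            sig = mechanistic_conductivity(t_rel, e_app, protocol.pulse_width_us, params)
            current[start:end] = voltage[start:end] * (np.asarray(sig) * delay_gain * conduct_scale)

    i_plateau = protocol.amplitude_v * sigma_ss * conduct_scale
    if params.cap_transient_frac > 0 and params.cap_transient_tau_us > 0:
        for kind, _, start, end, pol in segs:
            if kind != 0:
                continue
            t_rel = np.arange(end - start) * dt_us
            current[start:end] += (
                pol * i_plateau * params.cap_transient_frac
                * np.exp(-t_rel / params.cap_transient_tau_us)
            )

    sd_v = params.noise_rel * protocol.amplitude_v
    sd_i = params.noise_rel * abs(i_plateau)
    voltage = voltage + _segment_noise(n, segs, sd_v, seed, channel=0)
    current = current + _segment_noise(n, segs, sd_i, seed, channel=1)

    meta = {
        "protocol": protocol.label,
        "geometry": geometry.kind,
        "amplitude_v": protocol.amplitude_v,
        "e_app_v_per_cm": e_app,
        "seed": int(seed),
    }
    if metadata:
        meta.update(metadata)
    return Trace(
        sampling_period_ns=protocol.sampling_period_ns,
        voltage_v=voltage,
        current_a=current,
        metadata=meta,
    )


def _child_seed(*keys: int) -> int:
    """Stable 32-bit child seed from an integer key path."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0])


def simulate_ramp(
    protocol: BurstProtocol,
    geometry: GeometrySpec,
    params: TissueParams,
    levels: list[float],
    bursts_per_level: int = 3,
    seed: int = 0,
    memory_frac: float = 0.0,
    metadata: dict | None = None,
) -> list[Trace]:
    """Simulate a voltage ramp: ``bursts_per_level`` bursts at each ascending
    distance-normalized voltage level (V/cm).

    The tissue carries no state across levels (each level's conductivity
    depends only on that level's field), matching the observed equivalence of
    ramped and standalone measurements.  ``memory_frac`` is a test hook: a
    fractional resistance change applied to every level after the first,
    emulating a hypothetical carry-over effect.
    """
    levels = list(levels)
    if any(b >= a for b, a in zip(levels, levels[1:])):
        raise ValueError("ramp levels must be strictly increasing")
    traces = []
    for i, level in enumerate(levels):
        amp = voltage_for_field(level, geometry)
        scale = (1.0 + memory_frac) if i > 0 else 1.0
        for b in range(bursts_per_level):
            meta = {"level_v_per_cm": level, "burst": b, "level_index": i}
            if metadata:
                meta.update(metadata)
            traces.append(
                simulate_trace(
                    protocol.with_amplitude(amp),
                    geometry,
                    params,
                    seed=_child_seed(seed, i, b),
                    resistance_scale=scale,
                    metadata=meta,
                )
            )
    return traces


def draw_plate_sample(
    base: PlateGeometry, rng: np.random.Generator, thickness_sd_m: float = 0.2e-3
) -> PlateGeometry:
    """Draw one plate sample with caliper-style thickness variation.

    Thickness ~ Normal(base.thickness, sd) truncated positive; emulates the
    slice-to-slice variation corrected by measuring each cylinder.
    """
    for _ in range(100):
        t = rng.normal(base.thickness_m, thickness_sd_m)
        if t > 0:
            return replace(base, thickness_m=float(t))
    raise RuntimeError("could not draw a positive thickness")
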