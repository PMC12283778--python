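"""End-to-end recovery benchmarks on the synthetic bench.

Each function wires the generator, the trace pipeline, and the statistics
into one seeded, reproducible experiment mirroring the study designs:
plate-ramp conductivity recovery, delay-invariance ANOVA rates, and the
ramp-vs-standalone memory check.  They are used both by the test suite and
by the repository's acceptance script.

Monte Carlo repetitions run with scaled-down traces (10 ns sampling, short
bursts) to keep hundreds of repetitions tractable; the single-shot
conductivity recovery uses the full recording conditions (2 ns sampling,
100 µs on-time bursts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiment import DesignSpec, delay_invariance_report, ramp_memory_test, run_design
from .geometry import PlateGeometry, NeedlePairGeometry, ramp_levels
from .synth import TissueParams, _child_seed
from .waveforms import BurstProtocol

__all__ = [
    "potato_params",
    "plate_conductivity_recovery",
    "delay_invariance_rates",
    "ramp_memory_rates",
]


def potato_params(**overrides) -> TissueParams:
    """Tuber tissue preset (see presets/tissues.yaml) as TissueParams."""
    base = dict(
        sigma_bulk_by_pw={1.0: 0.13, 10.0: 0.04},
        sigma_max_by_pw={1.0: 0.55, 10.0: 0.67},
        e_th_v_per_cm=500.0,
        transition_width_v_per_cm=150.0,
        noise_rel=0.01,
    )
    base.update(overrides)
    return TissueParams(**base)


def plate_conductivity_recovery(
    pulse_width_us: float,
    delay_us: float = 10.0,
    n_replicates: int = 8,
    base_seed: int = 0,
    sampling_period_ns: float = 2.0,
    ontime_us: float = 100.0,
    params: TissueParams | None = None,
) -> pd.DataFrame:
    """Simulate plate voltage ramps and recover conductivity per level.

    Full chain: per-replicate sample thickness, ramp simulation with 1%
    measurement noise, tau = PW/3 filtering, per-pulse maxima, per-burst
    medians, Ohm's law, 3-burst averaging, prism shape-factor inversion
    with the recorded per-sample thickness.  Returns one row per
    (replicate, level) with the recovered ``sigma_s_per_m``.
    """
    params = params or potato_params()
    plate = PlateGeometry(thickness_m=0.006, diameter_m=0.006)
    design = DesignSpec(
        pulse_widths_us=(pulse_width_us,),
        delays_us=(delay_us,),
        geometry=plate,
        levels=tuple(ramp_levels("plate")),
        n_replicates=n_replicates,
        base_seed=base_seed,
        sampling_period_ns=sampling_period_ns,
        ontime_us=ontime_us,
    )
    table = run_design(design, params)
    table["sigma_s_per_m"] = table["thickness_m"] / (plate.area_m2 * table["R_ohm"])
    return table


def delay_invariance_rates(
    n_runs: int = 100,
    base_seed: int = 0,
    delay_effect: float = 0.0,
    levels: tuple[float, ...] = (100.0, 2000.0),
    delays: tuple[float, ...] = (1.0, 10.0, 100.0),
    pulse_width_us: float = 1.0,
    n_replicates: int = 8,
) -> dict:
    """Repeated delay-invariance ANOVAs over seeded generator runs.

    Returns the fraction of significant (pulse width, level) cells across
    all runs and the fraction of runs with at least one significant cell.
    ``delay_effect`` > 0 injects a conductivity increase proportional to the
    interpulse delay (fraction at d2 = 100 µs), for power checks.
    """
    params = potato_params(delay_effect_frac_at_100us=delay_effect)
    plate = PlateGeometry(thickness_m=0.006, diameter_m=0.006)
    n_sig = 0
    n_cells = 0
    runs_with_hit = 0
    for run in range(n_runs):
        design = DesignSpec(
            pulse_widths_us=(pulse_width_us,),
            delays_us=delays,
            geometry=plate,
            levels=levels,
            n_replicates=n_replicates,
            base_seed=_child_seed(base_seed, run),
            sampling_period_ns=10.0,
            ontime_us=20.0,
        )
        _, summary = delay_invariance_report(run_design(design, params))
        n_sig += summary["n_significant"]
        n_cells += summary["n_cells"]
        runs_with_hit += summary["n_significant"] > 0
    return {
        "n_runs": n_runs,
        "cell_significance_rate": n_sig / n_cells,
        "run_detection_rate": runs_with_hit / n_runs,
    }


def ramp_memory_rates(
    n_runs: int = 100,
    base_seed: int = 0,
    memory_frac: float = 0.0,
    targets: tuple[float, ...] = (1000.0, 1500.0, 2000.0),
    n_replicates: int = 8,
) -> dict:
    """Repeated ramp-vs-standalone Welch tests over seeded generator runs.

    Uses the two-needle 1.0 cm geometry and its voltage-ramp schedule.
    Returns the fraction of (run, target) comparisons that are
    non-significant and the fraction significant (power when
    ``memory_frac`` != 0).
    """
    params = potato_params()
    needles = NeedlePairGeometry(center_spacing_m=0.01, electrode_radius_m=5e-4, exposure_m=0.01)
    protocol = BurstProtocol.from_label("10-1-10-1", cycles=2, sampling_period_ns=10.0)
    schedule = ramp_levels("potato_1cm")
    n_null = 0
    n_total = 0
    for run in range(n_runs):
        results = ramp_memory_test(
            target_levels=list(targets),
            params=params,
            geometry=needles,
            protocol=protocol,
            ramp_levels=schedule,
            n=n_replicates,
            seed=_child_seed(base_seed, run),
            memory_frac=memory_frac,
        )
        for res in results.values():
            n_null += res.p_value > 0.05
            n_total += 1
    return {
        "n_runs": n_runs,
        "non_significant_rate": n_null / n_total,
        "significant_rate": 1.0 - n_null / n_total,
    }
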