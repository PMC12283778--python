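"""Experiment orchestration and delay-invariance statistics.

Runs the full factorial design (pulse widths x delays x replicates x ramp
levels) through the synthetic generator and the trace pipeline, and applies
the study's statistics: Welch's unequal-variance t-test for two-group
comparisons (ramp vs standalone memory check) and one-way ANOVA with Tukey's
HSD post hoc test across delay groups.  All randomness flows from a single
base seed; reruns are bit-identical.

The test statistics are computed from their closed forms here (Welch t with
Welch-Satterthwaite degrees of freedom; F = MS_between/MS_within; Tukey's
studentized-range p-values); scipy supplies only the reference
distributions.  Significance level alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import GeometrySpec, PlateGeometry
from .pipeline import process_traces, results_table
from .synth import TissueParams, draw_plate_sample, simulate_ramp, _child_seed
from .waveforms import BurstProtocol

__all__ = [
    "DesignSpec",
    "StatResult",
    "run_design",
    "welch_t_test",
    "oneway_anova_tukey",
    "delay_invariance_report",
    "ramp_memory_test",
    "significance_markers",
]

ALPHA = 0.05


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design: pulse widths x delays, replicated ramps.

    ``delays_us`` entries are either a scalar d (applied as d1 = d2 = d, the
    convention behind labels like "10-1-10-1") or an explicit (d1, d2) pair
    for reciprocal-waveform comparisons.
    """

    pulse_widths_us: tuple[float, ...]
    delays_us: tuple
    geometry: GeometrySpec
    levels: tuple[float, ...]
    n_replicates: int = 8
    base_seed: int = 0
    bursts_per_level: int = 3
    sampling_period_ns: float = 2.0
    ontime_us: float | None = None  # None -> 100 µs on-time default

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not self.pulse_widths_us or not self.delays_us:
            raise ValueError("design grid is empty")

    def protocols(self):
        from .waveforms import cycles_for_ontime

        for pw, d in itertools.product(self.pulse_widths_us, self.delays_us):
            d1, d2 = (d, d) if np.isscalar(d) else d
            cycles = None if self.ontime_us is None else cycles_for_ontime(pw, self.ontime_us)
            yield BurstProtocol(
                pulse_width_us=pw,
                d1_us=d1,
                d2_us=d2,
                cycles=cycles,
                sampling_period_ns=self.sampling_period_ns,
            )


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test, with Tukey pairwise table when relevant."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def significance_markers(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, thr in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < thr:
            return stars
    return "ns"


# -- hypothesis tests ---------------------------------------------------------


def welch_t_test(x, y) -> StatResult:
    """Unpaired two-tailed Welch's t-test (unequal variances).

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny), with Welch-Satterthwaite
    degrees of freedom; two-tailed p from Student's t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate data: both groups have zero variance")
    se2x, se2y = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(test="welch_t", statistic=float(t), df=float(df), p_value=float(p))


def oneway_anova_tukey(groups, labels=None) -> StatResult:
    """One-way ANOVA (F = MS_between / MS_within) with Tukey's HSD post hoc.

    Tukey-Kramer adjusted p-values come from the studentized range
    distribution with k groups and N-k error degrees of freedom; the
    pairwise table covers all k(k-1)/2 pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in groups])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 values")
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise ValueError("degenerate data: zero within-group variance everywhere")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))

    if labels is None:
        labels = list(range(k))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "p_adj": min(p_adj, 1.0),
            }
        )
    return StatResult(
        test="oneway_anova_tukey",
        statistic=float(f),
        df=(float(df_b), float(df_w)),
        p_value=p,
        pairwise=pd.DataFrame(rows),
    )


# -- orchestration ------------------------------------------------------------


def run_design(design: DesignSpec, params: TissueParams) -> pd.DataFrame:
    """Simulate and process the full design; one row per (waveform, replicate,
    level), deterministic given ``base_seed``.

    For plate geometry each replicate gets its own caliper-measured sample
    thickness (drawn around the nominal value), recorded in the table and
    used for the field normalization, mirroring the per-sample correction.
    """
    frames = []
    for w_idx, protocol in enumerate(design.protocols()):
        for rep in range(design.n_replicates):
            rep_seed = _child_seed(design.base_seed, w_idx, rep)
            geom = design.geometry
            thickness = None
            if isinstance(geom, PlateGeometry):
                rng = np.random.default_rng(np.random.SeedSequence([rep_seed, 9]))
                geom = draw_plate_sample(geom, rng)
                thickness = geom.thickness_m
            traces = simulate_ramp(
                protocol,
                geom,
                params,
                levels=list(design.levels),
                bursts_per_level=design.bursts_per_level,
                seed=rep_seed,
            )
            try:
                results = process_traces(
                    traces, protocol, bursts_per_level=design.bursts_per_level,
                    thickness_m=thickness,
                )
            except ValueError as err:
                raise ValueError(
                    f"pipeline failed for waveform {protocol.label}, replicate {rep}: {err}"
                ) from err
            frames.append(
                results_table(
                    results,
                    waveform=protocol.label,
                    pulse_width_us=protocol.pulse_width_us,
                    d1_us=protocol.d1_us,
                    d2_us=protocol.d2_us,
                    geometry=design.geometry.kind,
                    replicate=rep,
                )
            )
    return pd.concat(frames, ignore_index=True)


def delay_invariance_report(
    table: pd.DataFrame, response: str = "R_ohm", alpha: float = ALPHA
) -> tuple[pd.DataFrame, dict]:
    """Per-(pulse width, level) one-way ANOVA across delay groups.

    Returns the per-cell table (F, p, significance) and a summary with the
    count and fraction of significant cells at ``alpha``.  Cells with fewer
    than two delay groups are reported as missing, not imputed.
    """
    rows = []
    missing = []
    for (pw, level), cell in table.groupby(["pulse_width_us", "level_v_per_cm"]):
        groups = [g[response].to_numpy() for _, g in cell.groupby(["d1_us", "d2_us"])]
        if len(groups) < 2:
            missing.append((pw, level))
            continue
        res = oneway_anova_tukey(groups)
        rows.append(
            {
                "pulse_width_us": pw,
                "level_v_per_cm": level,
                "F": res.statistic,
                "p": res.p_value,
                "significant": res.p_value < alpha,
                "marker": significance_markers(res.p_value),
            }
        )
    cells = pd.DataFrame(rows)
    summary = {
        "n_cells": len(cells),
        "n_significant": int(cells["significant"].sum()) if len(cells) else 0,
        "fraction_significant": float(cells["significant"].mean()) if len(cells) else float("nan"),
        "alpha": alpha,
        "missing_cells": missing,
    }
    return cells, summary


def ramp_memory_test(
    target_levels: list[float],
    params: TissueParams,
    geometry: GeometrySpec,
    protocol: BurstProtocol,
    ramp_levels: list[float],
    n: int = 8,
    seed: int = 0,
    memory_frac: float = 0.0,
) -> dict[float, StatResult]:
    """Compare full-ramp vs standalone resistance at each target level.

    For each target: ``n`` replicates experience the full ascending ramp
    (truncated at the target) and ``n`` replicates the target level alone;
    the final-level per-burst-averaged resistances are compared with Welch's
    t-test.  ``memory_frac`` injects a carry-over resistance change in the
    ramp arm only (0 = memoryless null).
    """
    out = {}
    for t_idx, target in enumerate(target_levels):
        sub_levels = [lv for lv in ramp_levels if lv < target] + [target]
        arms = {}
        for arm_idx, (arm, levels, mem) in enumerate(
            [("ramp", sub_levels, memory_frac), ("standalone", [target], 0.0)]
        ):
            r_vals = []
            for rep in range(n):
                rep_seed = _child_seed(seed, t_idx, arm_idx, rep)
                traces = simulate_ramp(
                    protocol, geometry, params, levels=levels, seed=rep_seed, memory_frac=mem
                )
                final = [tr for tr in traces if tr.metadata["level_v_per_cm"] == target]
                results = process_traces(final, protocol)
                r_vals.append(results[-1].r_mean_ohm)
            arms[arm] = np.array(r_vals)
        out[target] = welch_t_test(arms["ramp"], arms["standalone"])
    return out
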