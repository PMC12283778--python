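"""Electrode geometry, distance-normalized voltage schedules, and shape-factor
conductivity inversion.

Two geometries are supported: a cylindrical tissue sample between parallel
flat plates (uniform field; prism shape factor ``S = A/l`` so that
``sigma = l / (A * R)``), and a pair of parallel needle electrodes
(non-uniform field; two-cylinder shape factor
``S = pi * L / acosh(D / 2a)``, an infinite-medium approximation).

Conductivity inversion from measured resistance is only well-posed for the
plate geometry, where the applied field is uniform; needle-pair resistances
mix the non-linear field distribution with the electroporated volume, so
:func:`conductivity_curve` refuses needle input unless explicitly overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateGeometry",
    "NeedlePairGeometry",
    "GeometrySpec",
    "ConductivityCurve",
    "plate_area",
    "prism_conductivity",
    "needle_pair_shape_factor",
    "voltage_for_field",
    "ramp_levels",
    "conductivity_curve",
    "shape_factor",
]


def plate_area(diameter_m: float) -> float:
    """Circular cross-section area (m^2) of the cylindrical plate sample."""
    if diameter_m <= 0:
        raise ValueError("plate diameter must be positive")
    return math.pi * (diameter_m / 2.0) ** 2


@dataclass(frozen=True)
class PlateGeometry:
    """Cylindrical tissue sample between parallel flat plate electrodes."""

    thickness_m: float
    diameter_m: float

    def __post_init__(self) -> None:
        if self.thickness_m <= 0 or self.diameter_m <= 0:
            raise ValueError("plate dimensions must be positive")

    kind = "plate"

    @property
    def area_m2(self) -> float:
        return plate_area(self.diameter_m)

    @property
    def distance_m(self) -> float:
        """Distance used for V/cm normalization: sample thickness."""
        return self.thickness_m

    @property
    def shape_factor_m(self) -> float:
        """Prism shape factor S = A/l so that R = 1/(sigma*S)."""
        return self.area_m2 / self.thickness_m


@dataclass(frozen=True)
class NeedlePairGeometry:
    """Two parallel cylindrical needle electrodes inserted into tissue."""

    center_spacing_m: float
    electrode_radius_m: float
    exposure_m: float
    insertion_depth_m: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if min(self.center_spacing_m, self.electrode_radius_m, self.exposure_m) <= 0:
            raise ValueError("needle dimensions must be positive")
        if self.center_spacing_m <= 2 * self.electrode_radius_m:
            raise ValueError("needle spacing must exceed electrode diameter")

    kind = "needle_pair"

    @property
    def distance_m(self) -> float:
        """Distance used for V/cm normalization: center-to-center spacing."""
        return self.center_spacing_m

    @property
    def shape_factor_m(self) -> float:
        return needle_pair_shape_factor(self)


GeometrySpec = PlateGeometry | NeedlePairGeometry


def needle_pair_shape_factor(geom: NeedlePairGeometry) -> float:
    """Two-parallel-cylinder shape factor S = pi*L/acosh(D/2a), in meters.

    Infinite-medium approximation: predicted resistance is ``1/(sigma*S)``.
    """
    ratio = geom.center_spacing_m / (2.0 * geom.electrode_radius_m)
    if ratio <= 1.0:
        raise ValueError("spacing must exceed electrode diameter")
    return math.pi * geom.exposure_m / math.acosh(ratio)


def shape_factor(geom: GeometrySpec) -> float:
    """Shape factor S (m) of either geometry: R = 1/(sigma*S)."""
    return geom.shape_factor_m


def prism_conductivity(r_ohm: float, thickness_m: float, area_m2: float) -> float:
    """Invert a plate-geometry resistance to conductivity: sigma = l/(A*R)."""
    if r_ohm <= 0:
        raise ValueError("resistance must be positive")
    if thickness_m <= 0 or area_m2 <= 0:
        raise ValueError("geometry dimensions must be positive")
    return thickness_m / (area_m2 * r_ohm)


def voltage_for_field(level_v_per_cm: float, geom: GeometrySpec) -> float:
    """Applied voltage (V) achieving a distance-normalized voltage (V/cm).

    Plate: level x thickness; needle pair: level x center spacing.
    """
    if level_v_per_cm < 0:
        raise ValueError("field level must be non-negative")
    return level_v_per_cm * geom.distance_m * 100.0  # V/cm * m -> V


# Voltage-ramp schedules (V/cm) used in the tuber and cardiac experiments.
_RAMP_LEVELS: dict[str, list[float]] = {
    # needle pair at 1.0 cm spacing
    "potato_1cm": [50, 100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000],
    # 1.5 cm spacing draws more current; ramp truncated at 1500 V/cm
    "potato_1.5cm": [50, 100, 250, 500, 750, 1000, 1250, 1500],
    # cardiac needles: generator floor lifts the lowest level to 100 V/cm,
    # smaller spacing allows up to 2500 V/cm
    "cardiac": [100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000, 2250, 2500],
    # parallel plates: generator floor (50 V = ~83 V/cm at 6 mm) lifts the
    # lowest uniform level to 100 V/cm
    "plate": [100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000],
}


def ramp_levels(setting: str) -> list[float]:
    """Distance-normalized voltage schedule (V/cm) for a named experiment."""
    try:
        return list(_RAMP_LEVELS[setting])
    except KeyError:
        raise ValueError(
            f"unknown ramp setting {setting!r}; known: {sorted(_RAMP_LEVELS)}"
        ) from None


@dataclass(frozen=True)
class ConductivityCurve:
    """Per-level conductivity recovered from a plate voltage ramp."""

    table: pd.DataFrame  # columns: level_v_per_cm, sigma_s_per_m (+ passthrough)

    def __post_init__(self) -> None:
        levels = self.table["level_v_per_cm"].to_numpy()
        if not np.all(np.diff(levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if not np.all(self.table["sigma_s_per_m"].to_numpy() > 0):
            raise ValueError("conductivities must be positive")

    @property
    def levels(self) -> np.ndarray:
        return self.table["level_v_per_cm"].to_numpy()

    @property
    def sigma(self) -> np.ndarray:
        return self.table["sigma_s_per_m"].to_numpy()


def conductivity_curve(
    results,
    geom: GeometrySpec,
    allow_needle: bool = False,
) -> ConductivityCurve:
    """Invert ramp-level resistances to a conductivity-vs-field curve.

    ``results`` is an iterable of level results (see
    :class:`hfire_bench.pipeline.LevelResult`) or a DataFrame with columns
    ``level_v_per_cm`` and ``R_ohm`` (optional per-sample ``thickness_m``).
    Only valid for plate geometry, where the prism inversion applies; the
    needle-pair override exists for exploratory use only and uses the
    infinite-medium shape factor, which conflates the non-uniform field with
    conductivity dynamics.
    """
    if geom.kind == "needle_pair" and not allow_needle:
        raise ValueError(
            "conductivity inversion from needle-pair resistance mixes the "
            "non-uniform field distribution with conductivity dynamics; use "
            "plate geometry, or pass allow_needle=True for a shape-factor "
            "estimate with that caveat"
        )
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "level_v_per_cm": r.level_v_per_cm,
                    "R_ohm": r.r_mean_ohm,
                    **({"thickness_m": r.thickness_m} if getattr(r, "thickness_m", None) else {}),
                }
                for r in results
            ]
        )
    df = df.sort_values("level_v_per_cm").reset_index(drop=True)
    if geom.kind == "plate":
        # per-sample caliper thickness, when recorded, corrects both the area
        # divisor and the field normalization
        thickness = df["thickness_m"] if "thickness_m" in df else geom.thickness_m
        sigma = thickness / (geom.area_m2 * df["R_ohm"])
    else:
        sigma = 1.0 / (df["R_ohm"] * geom.shape_factor_m)
    out = df[["level_v_per_cm"]].copy()
    out["sigma_s_per_m"] = np.asarray(sigma, dtype=float)
    return ConductivityCurve(table=out)
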