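"""Electric field and ablation-area forward model for the needle-pair
geometry.

Two routes to the field map on the electrode-midline cross-section:

* :func:`bipolar_field_map` — closed-form potential of two parallel
  conducting cylinders in a uniform medium (image line sources at
  ``+-sqrt((D/2)^2 - a^2)``), exact for constant conductivity.
* :func:`fd_laplace` — finite-difference solution of
  ``div(sigma(E) grad phi) = 0`` with Dirichlet electrodes and an insulating
  outer boundary, Picard-iterated for field-dependent conductivity.  Serves
  as the numerical oracle for the analytic shape factor and as the only
  route once electroporation makes sigma depend on the local field.

Ablation area is the area enclosed by the lethal electric-field-threshold
(EFT) contour: cells with ``E >= EFT`` outside the electrodes.  Areas are 2D
midline-slice areas (cm^2), directly comparable with stained cross sections.

Because neither route takes the burst's delays as input, the field map and
the predicted ablation area are delay-invariant by construction; combined
with the delay-invariant conductivity model this reproduces the structural
finding that delays leave the field distribution unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import GeometrySpec, NeedlePairGeometry, PlateGeometry

__all__ = [
    "FieldMap",
    "AblationEstimate",
    "bipolar_field_map",
    "ablation_area",
    "fd_laplace",
    "LETHAL_EFT_PRESETS",
]

#: Lethal EFT presets per pulse width (V/cm): literature-informed
#: placeholders (longer pulses ablate at lower fields); synthetic values,
#: not measurements.
LETHAL_EFT_PRESETS: dict[float, float] = {1.0: 1000.0, 2.0: 900.0, 5.0: 750.0, 10.0: 600.0}


@dataclass(frozen=True)
class FieldMap:
    """Potential and field magnitude on a uniform 2D grid."""

    spacing_m: float
    x_m: np.ndarray = field(repr=False)
    y_m: np.ndarray = field(repr=False)
    potential_v: np.ndarray = field(repr=False)  # shape (nx, ny)
    e_field_v_per_cm: np.ndarray = field(repr=False)
    electrode_mask: np.ndarray = field(repr=False)
    method: str = "analytic"

    def __post_init__(self) -> None:
        if self.spacing_m <= 0:
            raise ValueError("grid spacing must be positive")


@dataclass(frozen=True)
class AblationEstimate:
    area_cm2: float
    lethal_eft_v_per_cm: float
    method: str

    def __post_init__(self) -> None:
        if self.area_cm2 < 0:
            raise ValueError("area must be non-negative")


def _grid(domain_m: float, spacing_m: float):
    half = domain_m / 2.0
    n = int(round(domain_m / spacing_m)) + 1
    x = np.linspace(-half, half, n)
    return x, x.copy()


def _check_resolution(geom: NeedlePairGeometry, spacing_m: float) -> None:
    if spacing_m * 5 > geom.electrode_radius_m:
        raise ValueError(
            f"grid spacing {spacing_m} m too coarse: need >= 5 cells across the "
            f"{geom.electrode_radius_m} m electrode radius"
        )


def bipolar_field_map(
    geom: NeedlePairGeometry,
    applied_v: float,
    spacing_m: float = 50e-6,
    domain_m: float = 0.04,
) -> FieldMap:
    """Closed-form field of two parallel cylinders at +-V/2 in a uniform medium.

    Potential: ``phi = k * ln(r_minus / r_plus)`` with image line sources at
    ``x = +-c``, ``c = sqrt((D/2)^2 - a^2)`` and ``k = (V/2)/acosh(D/2a)``;
    the cylinder surfaces are exact equipotentials at +-V/2.  The field
    magnitude is evaluated analytically; electrode interiors are masked with
    E = 0.
    """
    _check_resolution(geom, spacing_m)
    a = geom.electrode_radius_m
    half_d = geom.center_spacing_m / 2.0
    c = math.sqrt(half_d**2 - a**2)
    k = (applied_v / 2.0) / math.acosh(half_d / a)

    x, y = _grid(domain_m, spacing_m)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r_plus2 = (xx - c) ** 2 + yy**2
    r_minus2 = (xx + c) ** 2 + yy**2
    mask = ((xx - half_d) ** 2 + yy**2 <= a**2) | ((xx + half_d) ** 2 + yy**2 <= a**2)

    eps = (spacing_m * 1e-6) ** 2
    phi = 0.5 * k * np.log((r_minus2 + eps) / (r_plus2 + eps))
    phi[mask] = np.sign(xx[mask]) * applied_v / 2.0

    # |grad phi| of k*ln(r-/r+): each line source contributes k/r radially
    ex = k * ((xx + c) / (r_minus2 + eps) - (xx - c) / (r_plus2 + eps))
    ey = k * (yy / (r_minus2 + eps) - yy / (r_plus2 + eps))
    e_mag = np.hypot(ex, ey) / 100.0  # V/m -> V/cm
    e_mag[mask] = 0.0
    return FieldMap(
        spacing_m=spacing_m,
        x_m=x,
        y_m=y,
        potential_v=phi,
        e_field_v_per_cm=e_mag,
        electrode_mask=mask,
        method="analytic",
    )


def midpoint_field_v_per_cm(geom: NeedlePairGeometry, applied_v: float) -> float:
    """Closed-form |E| at the midpoint between the electrodes (V/cm)."""
    a = geom.electrode_radius_m
    half_d = geom.center_spacing_m / 2.0
    c = math.sqrt(half_d**2 - a**2)
    k = (applied_v / 2.0) / math.acosh(half_d / a)
    return (2.0 * k / c) / 100.0


def ablation_area(fmap: FieldMap, lethal_eft_v_per_cm: float) -> AblationEstimate:
    """Area (cm^2) of the midline region at or above the lethal threshold.

    Cell-counting estimate excluding electrode interiors; monotone
    non-increasing in the threshold.
    """
    if lethal_eft_v_per_cm <= 0:
        raise ValueError("lethal threshold must be positive")
    inside = (fmap.e_field_v_per_cm >= lethal_eft_v_per_cm) & ~fmap.electrode_mask
    area_m2 = float(inside.sum()) * fmap.spacing_m**2
    return AblationEstimate(
        area_cm2=area_m2 * 1e4, lethal_eft_v_per_cm=lethal_eft_v_per_cm, method=fmap.method
    )


# -- finite-difference nonlinear Laplace solver -------------------------------


def _assemble_and_solve(sigma: np.ndarray, dirichlet: np.ndarray, values: np.ndarray):
    """Solve div(sigma grad phi) = 0 on a uniform grid.

    ``sigma`` is cell-centred (nx, ny); faces take harmonic means; outer
    boundary is insulating (missing neighbours carry no flux); ``dirichlet``
    nodes are pinned to ``values``.
    """
    nx, ny = sigma.shape
    n = nx * ny
    idx = np.arange(n).reshape(nx, ny)

    def harm(s1, s2):
        return 2.0 * s1 * s2 / (s1 + s2)

    rows, cols, data = [], [], []
    diag = np.zeros(n)
    free = ~dirichlet

    for axis, (sl_a, sl_b) in enumerate(
        [((slice(0, -1), slice(None)), (slice(1, None), slice(None))),
         ((slice(None), slice(0, -1)), (slice(None), slice(1, None)))]
    ):
        s_face = harm(sigma[sl_a], sigma[sl_b])
        ia, ib = idx[sl_a].ravel(), idx[sl_b].ravel()
        w = s_face.ravel()
        # face contributes to both adjacent node equations (free nodes only)
        fa, fb = free.ravel()[ia], free.ravel()[ib]
        rows.extend([ia[fa], ib[fb]])
        cols.extend([ib[fa], ia[fb]])
        data.extend([w[fa], w[fb]])
        np.add.at(diag, ia[fa], -w[fa])
        np.add.at(diag, ib[fb], -w[fb])

    rows = np.concatenate([np.concatenate(rows), np.arange(n)])
    cols = np.concatenate([np.concatenate(cols), np.arange(n)])
    dvals = np.where(free.ravel(), diag, 1.0)
    data = np.concatenate([np.concatenate(data), dvals])
    # zero out off-diagonals of dirichlet rows
    keep = free.ravel()[rows] | (rows == cols)
    A = sp.csr_matrix((data[keep], (rows[keep], cols[keep])), shape=(n, n))
    b = np.where(dirichlet.ravel(), values.ravel(), 0.0)
    phi = spsolve(A, b)
    return phi.reshape(nx, ny)


def fd_laplace(
    geom: GeometrySpec,
    applied_v: float,
    sigma_fn,
    spacing_m: float = 100e-6,
    domain_m: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
    relax: float = 0.7,
) -> tuple[FieldMap, float]:
    """Finite-difference solve of ``div(sigma(E) grad phi) = 0``; returns the
    field map and the total tissue resistance (Ohm).

    ``sigma_fn`` maps field magnitude (V/cm) to conductivity (S/m); constants
    converge in one Picard iteration.  Needle pair: 2D midline cross-section
    per unit length, scaled by the electrode exposure.  Plate: rectangular
    section between the plates, scaled by the sample's circular area.
    Under-relaxed (default 0.7) fixed-point iteration on phi to relative
    tolerance ``tol``; non-convergence raises with the residual.
    """
    if isinstance(geom, NeedlePairGeometry):
        _check_resolution(geom, spacing_m)
        x, y = _grid(domain_m, spacing_m)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        half_d = geom.center_spacing_m / 2.0
        # a pinned node represents a half-cell of conductor around it, so the
        # discrete conductor surface sits ~h/2 beyond the outermost pinned
        # node; masking at a + h/2 restores an effective radius of a
        a = geom.electrode_radius_m + spacing_m / 2.0
        pos = (xx - half_d) ** 2 + yy**2 <= a**2
        neg = (xx + half_d) ** 2 + yy**2 <= a**2
        dirichlet = pos | neg
        values = np.where(pos, applied_v / 2.0, np.where(neg, -applied_v / 2.0, 0.0))
        depth_m = geom.exposure_m
    elif isinstance(geom, PlateGeometry):
        # rectangle: thickness along x between the plates, sample width along y
        nx = max(int(round(geom.thickness_m / spacing_m)) + 1, 5)
        ny = max(int(round(geom.diameter_m / spacing_m)) + 1, 5)
        x = np.linspace(0.0, geom.thickness_m, nx)
        y = np.linspace(0.0, geom.diameter_m, ny)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        dirichlet = np.zeros((nx, ny), dtype=bool)
        dirichlet[0, :] = True
        dirichlet[-1, :] = True
        pos = np.zeros_like(dirichlet)
        pos[0, :] = True
        values = np.where(pos, applied_v, 0.0)
        depth_m = geom.area_m2 / geom.diameter_m  # equivalent depth: w*depth = A
    else:
        raise ValueError(f"unsupported geometry: {geom!r}")

    nxy = xx.shape
    phi = np.where(dirichlet, values, 0.0)
    sigma = np.full(nxy, float(np.asarray(sigma_fn(0.0)).item()))
    residual = np.inf
    residuals = []
    e_mag = np.zeros(nxy)
    relax_eff = relax
    for _ in range(max_iter):
        phi_new = _assemble_and_solve(sigma, dirichlet, values)
        residual = float(np.max(np.abs(phi_new - phi))) / max(abs(applied_v), 1e-300)
        # sharply nonlinear sigma(E) can make the full Picard step oscillate;
        # halve the damping whenever the residual fails to shrink
        if residuals and residual >= residuals[-1]:
            relax_eff = max(relax_eff * 0.5, 0.05)
        residuals.append(residual)
        phi = phi_new
        gx, gy = np.gradient(phi, spacing_m)  # axes: (x, y)
        e_mag = np.hypot(gx, gy) / 100.0  # V/cm
        if residual <= tol:
            break
        # under-relaxed Picard update of the conductivity field
        sigma_new = np.asarray(sigma_fn(e_mag), dtype=float)
        if sigma_new.shape != nxy:
            sigma_new = np.full(nxy, float(sigma_new))
        if np.any(sigma_new <= 0) or not np.all(np.isfinite(sigma_new)):
            raise ValueError("sigma_fn must return positive finite conductivities")
        sigma = (1.0 - relax_eff) * sigma + relax_eff * sigma_new
    else:
        raise RuntimeError(
            f"Picard iteration did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )

    e_mag = np.where(dirichlet, 0.0, e_mag)
    # current off the positive electrode: sum of face fluxes to free nodes,
    # with half-width transverse weights for faces on the outer boundary
    i_per_depth = 0.0
    nx_, ny_ = nxy
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        src_i = slice(max(0, -dx), nx_ - max(0, dx))
        src_j = slice(max(0, -dy), ny_ - max(0, dy))
        dst_i = slice(max(0, dx), nx_ - max(0, -dx))
        dst_j = slice(max(0, dy), ny_ - max(0, -dy))
        s_face = 2.0 * sigma[src_i, src_j] * sigma[dst_i, dst_j] / (
            sigma[src_i, src_j] + sigma[dst_i, dst_j]
        )
        wt = np.ones(nxy)
        if dx != 0:  # transverse direction is y
            wt[:, 0] = wt[:, -1] = 0.5
        else:  # transverse direction is x
            wt[0, :] = wt[-1, :] = 0.5
        flux = s_face * (phi[src_i, src_j] - phi[dst_i, dst_j]) * wt[src_i, src_j]
        sel = pos[src_i, src_j] & ~dirichlet[dst_i, dst_j]
        i_per_depth += float(flux[sel].sum())
    if i_per_depth <= 0:
        raise RuntimeError("no current off the positive electrode; check setup")
    resistance = applied_v / (i_per_depth * depth_m)

    fmap = FieldMap(
        spacing_m=spacing_m,
        x_m=x,
        y_m=y,
        potential_v=phi,
        e_field_v_per_cm=e_mag,
        electrode_mask=dirichlet,
        method="fd",
    )
    object.__setattr__(fmap, "residuals", residuals)  # convergence history
    return fmap, float(resistance)
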