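"""Synthetic phantom geometry with analytically known ablation margins.

A phantom case is a pair of (optionally ellipsoidal) tumor and ablation masks
rasterized on one grid, plus — for the sphere-pair case — a closed-form oracle
for the margin field.  For a spherical tumor (radius ``r``, center ``o``) and
spherical ablation zone (radius ``R``, center ``c``, center offset
``d = |o - c|``), the margin at a tumor-surface point ``p`` is ``R - |p - c|``,
so the minimal ablation margin is ``R - (r + d)`` and the fraction of tumor
surface with margin below ``x`` is a spherical-cap area fraction::

    P(margin < x) = (1 + u) / 2,   u = (r^2 + d^2 - rho^2) / (2 r d),  rho = R - x

(with ``u`` clipped to [-1, 1]; the concentric case ``d = 0`` degenerates to a
step at ``x = R - r``).  This gives every downstream stage an exact ground
truth against which voxel-based computations can be bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridError, LabelMask, VoxelGrid

__all__ = [
    "EmptyPhantomError",
    "PhantomSpec",
    "SphereMarginOracle",
    "PhantomCase",
    "rasterize_ellipsoid",
    "make_phantom_case",
    "sphere_pair_grid",
]


class EmptyPhantomError(GridError):
    """Requested shape does not intersect the grid."""


def rasterize_ellipsoid(
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
    label_name: str = "ellipsoid",
) -> LabelMask:
    """Occupy every voxel whose center lies inside the ellipsoid.

    A voxel center ``x`` is occupied iff ``sum(((x_i - c_i)/r_i)^2) <= 1``.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise GridError(f"nonpositive radius: {radii_mm}")
    c = np.asarray(center_mm, dtype=float)
    wx, wy, wz = grid.world_coordinates()
    q = (
        ((wx - c[0]) / radii[0]) ** 2
        + ((wy - c[1]) / radii[1]) ** 2
        + ((wz - c[2]) / radii[2]) ** 2
    )
    occ = q <= 1.0
    if not occ.any():
        raise EmptyPhantomError(
            f"empty phantom: ellipsoid at {tuple(c)} radii {tuple(radii)} "
            "does not cover any voxel center"
        )
    return LabelMask(grid=grid, occupancy=occ, label_name=label_name)


@dataclass(frozen=True)
class SphereMarginOracle:
    """Closed-form margin distribution for a sphere-pair phantom.

    All quantities are exact properties of the continuous geometry; voxelized
    results are expected to agree within one voxel diagonal (minimum margin)
    and a few surface-area percent (coverage fractions).
    """

    tumor_radius_mm: float
    ablation_radius_mm: float
    offset_mm: float

    @property
    def min_margin_mm(self) -> float:
        return self.ablation_radius_mm - (self.tumor_radius_mm + self.offset_mm)

    @property
    def max_margin_mm(self) -> float:
        return self.ablation_radius_mm - abs(self.offset_mm - self.tumor_radius_mm)

    def margin_at(self, points_mm: np.ndarray, ablation_center_mm: np.ndarray) -> np.ndarray:
        """Margin ``R - |p - c|`` at arbitrary points ``p`` (used in tests)."""
        p = np.atleast_2d(points_mm)
        return self.ablation_radius_mm - np.linalg.norm(
            p - np.asarray(ablation_center_mm, dtype=float), axis=1
        )

    def fraction_below(self, x_mm: float) -> float:
        """Exact fraction of the tumor surface with margin strictly below ``x``."""
        r, R, d = self.tumor_radius_mm, self.ablation_radius_mm, self.offset_mm
        rho = R - x_mm
        if d == 0.0:
            # constant margin R - r; strict inequality
            return 1.0 if x_mm > R - r else 0.0
        if rho <= 0.0:
            return 1.0
        u = (r * r + d * d - rho * rho) / (2.0 * r * d)
        u = min(1.0, max(-1.0, u))
        return (1.0 + u) / 2.0


@dataclass
class PhantomSpec:
    """Geometry of one synthetic case (stands in for patient CT segmentations)."""

    grid: VoxelGrid
    tumor_center_mm: tuple[float, float, float]
    ablation_center_mm: tuple[float, float, float]
    tumor_radii_mm: tuple[float, float, float]
    ablation_radii_mm: tuple[float, float, float]
    # liver modeled as the half-space {x : normal . x <= offset}
    liver_normal: tuple[float, float, float] | None = None
    liver_offset_mm: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tumor_radii_mm) <= 0) or np.any(
            np.asarray(self.ablation_radii_mm) <= 0
        ):
            raise GridError("phantom radii must be positive")


@dataclass
class PhantomCase:
    tumor: LabelMask
    ablation: LabelMask
    liver: LabelMask | None
    oracle: SphereMarginOracle | None


def make_phantom_case(spec: PhantomSpec) -> PhantomCase:
    """Rasterize a phantom triplet; attach the analytic oracle for sphere pairs."""
    tumor = rasterize_ellipsoid(spec.grid, spec.tumor_center_mm, spec.tumor_radii_mm, "tumor")
    ablation = rasterize_ellipsoid(
        spec.grid, spec.ablation_center_mm, spec.ablation_radii_mm, "ablation"
    )
    liver = None
    if spec.liver_normal is not None:
        n = np.asarray(spec.liver_normal, dtype=float)
        n = n / np.linalg.norm(n)
        wx, wy, wz = spec.grid.world_coordinates()
        occ = (n[0] * wx + n[1] * wy + n[2] * wz) <= float(spec.liver_offset_mm)
        liver = LabelMask(grid=spec.grid, occupancy=occ, label_name="liver")
    oracle = None
    tr = np.asarray(spec.tumor_radii_mm)
    ar = np.asarray(spec.ablation_radii_mm)
    if np.ptp(tr) == 0 and np.ptp(ar) == 0:
        d = float(
            np.linalg.norm(
                np.asarray(spec.tumor_center_mm) - np.asarray(spec.ablation_center_mm)
            )
        )
        oracle = SphereMarginOracle(
            tumor_radius_mm=float(tr[0]), ablation_radius_mm=float(ar[0]), offset_mm=d
        )
    return PhantomCase(tumor=tumor, ablation=ablation, liver=liver, oracle=oracle)


def sphere_pair_grid(
    tumor_radius_mm: float,
    ablation_radius_mm: float,
    offset_mm: float,
    spacing_mm: float,
    pad_mm: float = 3.0,
) -> PhantomSpec:
    """Convenience: a tight axis-aligned grid holding a z-offset sphere pair."""
    r, R, d = tumor_radius_mm, ablation_radius_mm, offset_mm
    half_xy = max(r, R) + pad_mm
    z_lo = min(-r, d - R) - pad_mm
    z_hi = max(r, d + R) + pad_mm
    n_xy = int(np.ceil(2 * half_xy / spacing_mm)) + 1
    n_z = int(np.ceil((z_hi - z_lo) / spacing_mm)) + 1
    grid = VoxelGrid(
        shape=(n_xy, n_xy, n_z),
        spacing_mm=(spacing_mm, spacing_mm, spacing_mm),
        origin_mm=(-half_xy, -half_xy, z_lo),
    )
    return PhantomSpec(
        grid=grid,
        tumor_center_mm=(0.0, 0.0, 0.0),
        ablation_center_mm=(0.0, 0.0, d),
        tumor_radii_mm=(r, r, r),
        ablation_radii_mm=(R, R, R),
    )
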