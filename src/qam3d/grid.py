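"""Physical-space voxel grids and binary label masks with NIfTI-1 I/O.

Masks live on a regular grid in millimetre space: a voxel is represented by
its center point, world coordinates are ``origin + direction @ (index * spacing)``
with 0-based indices.  All downstream margin computations are done in mm, so
anisotropic grids (e.g. 0.7 x 0.7 x 1.0 mm CT) are handled transparently.

No registration is performed here: inputs must arrive co-registered on one
grid, and :func:`validate_coregistration` refuses near-matching grids rather
than silently resampling them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridError",
    "IncompatibleGridsError",
    "EmptyMaskError",
    "VoxelGrid",
    "LabelMask",
    "CoregReport",
    "load_labelmask",
    "save_labelmask",
    "validate_coregistration",
]

_DIRECTION_TOL = 1e-6


class GridError(ValueError):
    """Invalid grid geometry or mask input."""


class IncompatibleGridsError(GridError):
    """Masks do not share a common voxel grid."""


class EmptyMaskError(GridError):
    """Operation requires a non-empty mask."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid in physical (mm) space.

    Parameters
    ----------
    shape
        Voxels per axis; every component >= 1.
    spacing_mm
        Voxel edge lengths in mm; every component > 0.
    origin_mm
        World coordinate of the center of voxel (0, 0, 0).
    direction
        3x3 orthonormal axis-direction matrix (rows of nested tuples).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        object.__setattr__(
            self, "direction", tuple(tuple(float(v) for v in row) for row in self.direction)
        )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GridError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GridError(f"spacing must be a positive triple, got {self.spacing_mm}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d.T @ d, np.eye(3), atol=_DIRECTION_TOL):
            raise GridError("direction matrix is not orthonormal within 1e-6")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix * np.asarray(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def diagonal_mm(self) -> float:
        """Physical diagonal of the whole grid (upper bound on any distance)."""
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm)
        return float(np.linalg.norm(extent))

    @property
    def voxel_diagonal_mm(self) -> float:
        """Diagonal of a single voxel — the accuracy budget of voxel-center sampling."""
        return float(np.linalg.norm(self.spacing_mm))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) 0-based voxel indices to (N, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = idx * np.asarray(self.spacing_mm)
        return pts @ self.direction_matrix.T + np.asarray(self.origin_mm)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, as three ``shape``-shaped arrays."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        w = self.voxel_to_world(idx).reshape(*self.shape, 3)
        return w[..., 0], w[..., 1], w[..., 2]


@dataclass
class LabelMask:
    """Binary occupancy on a :class:`VoxelGrid` (tumor / ablation / liver)."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label_name: str = "mask"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.shape:
            raise GridError(
                f"occupancy shape {occ.shape} does not match grid shape {self.grid.shape}"
            )
        self.occupancy = occ.astype(bool)

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()


@dataclass
class CoregReport:
    """Outcome of co-registration compatibility checks across masks."""

    compatible: bool
    max_spacing_rel_diff: float
    max_origin_diff_mm: float
    messages: list[str] = field(default_factory=list)


def load_labelmask(
    path: str | Path, binarize_threshold: float = 0.5, label_name: str | None = None
) -> LabelMask:
    """Load a NIfTI-1 volume as a binary mask.

    Occupancy is ``voxel value > binarize_threshold`` (default 0.5, which
    handles 0/1, 0/255 and probabilistic masks deterministically).  Trailing
    singleton dimensions are squeezed; a genuine 4D volume is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim > 3:
        if all(s == 1 for s in data.shape[3:]):
            data = data.reshape(data.shape[:3])
        else:
            raise GridError(f"non-3D volume: {path} has shape {data.shape}")
    if data.ndim != 3:
        raise GridError(f"non-3D volume: {path} has shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise GridError(f"degenerate voxel spacing in {path}")
    direction = lin / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise GridError(f"non-orthonormal direction matrix in {path}")
    # re-orthonormalize tiny float32 header noise so VoxelGrid's strict check passes
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    grid = VoxelGrid(
        shape=tuple(data.shape),
        spacing_mm=tuple(float(s) for s in spacing),
        origin_mm=tuple(float(v) for v in affine[:3, 3]),
        direction=tuple(tuple(float(v) for v in row) for row in direction),
    )
    occ = np.asarray(data, dtype=float) > binarize_threshold
    name = label_name if label_name is not None else path.name.split(".")[0]
    return LabelMask(grid=grid, occupancy=occ, label_name=name)


def save_labelmask(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as uint8 NIfTI-1; round-trips occupancy bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine=mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing_mm)
    nib.save(img, str(path))
    return path


def validate_coregistration(
    masks: list[LabelMask],
    spacing_rel_tol: float = 1e-3,
    origin_tol_mm: float = 0.1,
    direction_tol: float = 1e-6,
) -> CoregReport:
    """Check that all masks live on one common grid.

    Compatibility requires identical shapes, spacing within ``spacing_rel_tol``
    (relative), origins within ``origin_tol_mm`` and directions within
    ``direction_tol``, pairwise over every mask pair (hence symmetric in the
    argument order).  Failures are reported, one message per violated check,
    never fixed by resampling.
    """
    if len(masks) < 2:
        raise GridError("validate_coregistration needs at least 2 masks")
    messages: list[str] = []
    max_sp = 0.0
    max_or = 0.0
    compatible = True
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            ga, gb = masks[a].grid, masks[b].grid
            na, nb = masks[a].label_name, masks[b].label_name
            if ga.shape != gb.shape:
                compatible = False
                messages.append(f"shape mismatch: {na} {ga.shape} vs {nb} {gb.shape}")
            sp_a, sp_b = np.asarray(ga.spacing_mm), np.asarray(gb.spacing_mm)
            rel = float(np.max(np.abs(sp_a - sp_b) / np.maximum(sp_a, sp_b)))
            max_sp = max(max_sp, rel)
            if rel > spacing_rel_tol:
                compatible = False
                messages.append(
                    f"spacing mismatch: {na} {ga.spacing_mm} vs {nb} {gb.spacing_mm}"
                )
            od = float(
                np.linalg.norm(np.asarray(ga.origin_mm) - np.asarray(gb.origin_mm))
            )
            max_or = max(max_or, od)
            if od > origin_tol_mm:
                compatible = False
                messages.append(
                    f"origin mismatch: {na} {ga.origin_mm} vs {nb} {gb.origin_mm} "
                    f"({od:.4g} mm apart)"
                )
            dd = float(np.max(np.abs(ga.direction_matrix - gb.direction_matrix)))
            if dd > direction_tol:
                compatible = False
                messages.append(f"direction mismatch between {na} and {nb}")
    return CoregReport(
        compatible=compatible,
        max_spacing_rel_diff=max_sp,
        max_origin_diff_mm=max_or,
        messages=messages,
    )
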