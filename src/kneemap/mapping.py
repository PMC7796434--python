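"""Phase 2: carry calibrated BMD voxels through the surface warp and
average them on the reference bone's fixed cell grid.

Voxels are treated as points at their centers; BMD values are carried
unchanged through the warp (no resampling, no Jacobian correction) and
each 2 mm isotropic cell of the reference grid reports the arithmetic
mean of the registered voxel values falling inside its half-open
bounds.  Cells with no voxels are reported missing, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import points_in_mesh
from .io import CtVolume, SurfaceMesh, get_logger
from .transforms import CompositeWarp

__all__ = [
    "BmdPointCloud",
    "CellGrid",
    "BmdMap",
    "extract_bone_voxels",
    "warp_points",
    "build_cell_grid",
    "aggregate_bmd",
]

_LOG = get_logger("kneemap.mapping")


@dataclass
class BmdPointCloud:
    """Voxel-center positions (mm) with their BMD values (mg/cc)."""

    points: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.values = np.asarray(self.values, float).reshape(-1)
        if len(self.points) != len(self.values):
            raise ValueError("points and values lengths differ")
        if len(self.points) and not (
            np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.values))
        ):
            raise ValueError("non-finite point or value")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellGrid:
    """Axis-aligned isotropic cell grid over the reference bone.

    Cells are half-open cubes [lo, hi) of edge ``cell_size`` anchored at
    the reference bounding-box minimum corner; ``interior_mask`` is True
    where the cell center lies strictly inside the reference surface.
    """

    cell_size: float
    origin: np.ndarray
    shape: tuple
    interior_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.shape = tuple(int(s) for s in self.shape)
        self.interior_mask = np.asarray(self.interior_mask, bool).reshape(self.shape)

    @property
    def n_interior(self) -> int:
        return int(self.interior_mask.sum())

    def cell_centers(self) -> np.ndarray:
        """Centers of all cells (interior or not), shape (prod(shape), 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.cell_size

    def point_cells(self, points: np.ndarray) -> np.ndarray:
        """Cell index triple of each point (may fall outside the grid)."""
        return np.floor(
            (np.asarray(points, float) - self.origin) / self.cell_size
        ).astype(np.int64)

    def compatible_with(self, other: "CellGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


@dataclass
class BmdMap:
    """Mean BMD per interior cell of a :class:`CellGrid`.

    ``mean`` is NaN where ``count`` is 0 (missing, not zero);
    ``n_outside`` counts registered voxels that fell outside the grid or
    in non-interior cells, so counts are conserved:
    ``count.sum() + n_outside == total registered voxels``.
    """

    grid: CellGrid
    mean: np.ndarray
    count: np.ndarray
    n_outside: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).reshape(self.grid.shape)
        self.count = np.asarray(self.count, np.int64).reshape(self.grid.shape)
        bad = (self.count == 0) & np.isfinite(self.mean)
        if bad.any():
            raise ValueError("mean defined on cells with zero count")

    def to_frame(self) -> pd.DataFrame:
        """One row per interior cell: index triple, center mm, mean, count."""
        idx = np.argwhere(self.grid.interior_mask)
        centers = self.grid.origin + (idx + 0.5) * self.grid.cell_size
        return pd.DataFrame(
            {
                "i": idx[:, 0],
                "j": idx[:, 1],
                "k": idx[:, 2],
                "x_mm": centers[:, 0],
                "y_mm": centers[:, 1],
                "z_mm": centers[:, 2],
                "mean_bmd_mgcc": self.mean[tuple(idx.T)],
                "voxel_count": self.count[tuple(idx.T)],
            }
        )

    def interior_values(self, min_count: int = 1) -> np.ndarray:
        sel = self.grid.interior_mask & (self.count >= min_count)
        return self.mean[sel]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_bone_voxels(volume: CtVolume, mesh: SurfaceMesh) -> BmdPointCloud:
    """Voxel centers strictly inside the (watertight) bone surface,
    with their values, in moving space."""
    mesh.require_watertight()
    centers = volume.voxel_centers()
    values = volume.voxels.reshape(-1)
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    near = np.all((centers >= lo - 1e-9) & (centers <= hi + 1e-9), axis=1)
    inside_near = points_in_mesh(centers[near], mesh.vertices, mesh.faces)
    keep = np.zeros(len(centers), dtype=bool)
    keep[np.nonzero(near)[0][inside_near]] = True
    return BmdPointCloud(points=centers[keep], values=values[keep])


def warp_points(cloud: BmdPointCloud, warp: CompositeWarp) -> BmdPointCloud:
    """Map the cloud through the chain; values carried unchanged."""
    return BmdPointCloud(points=warp.apply(cloud.points), values=cloud.values.copy())


def build_cell_grid(reference: SurfaceMesh, cell_size: float = 2.0) -> CellGrid:
    """Isotropic cell grid covering the reference bounding box, anchored
    at the bounding-box minimum corner (deterministic)."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    reference.require_watertight()
    lo = reference.vertices.min(axis=0)
    hi = reference.vertices.max(axis=0)
    shape = tuple(np.maximum(1, np.ceil((hi - lo) / cell_size)).astype(int))
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = lo + (idx + 0.5) * cell_size
    inside = points_in_mesh(centers, reference.vertices, reference.faces)
    return CellGrid(
        cell_size=float(cell_size),
        origin=lo,
        shape=shape,
        interior_mask=inside.reshape(shape),
    )


def aggregate_bmd(cloud: BmdPointCloud, grid: CellGrid) -> BmdMap:
    """Per-cell arithmetic mean of the registered values whose points
    fall inside interior cells (half-open bounds); everything else is
    counted as outside and logged."""
    shape = np.asarray(grid.shape)
    idx = grid.point_cells(cloud.points)
    in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)
    flat = np.zeros(len(cloud.points), dtype=np.int64)
    flat[in_bounds] = np.ravel_multi_index(tuple(idx[in_bounds].T), grid.shape)
    interior = np.zeros(len(cloud.points), dtype=bool)
    interior[in_bounds] = grid.interior_mask.reshape(-1)[flat[in_bounds]]

    n_cells = int(np.prod(grid.shape))
    counts = np.bincount(flat[interior], minlength=n_cells)
    sums = np.bincount(
        flat[interior], weights=cloud.values[interior], minlength=n_cells
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_outside = int(len(cloud.points) - interior.sum())
    if n_outside:
        _LOG.info(
            "aggregate_bmd: %d of %d registered voxels fell outside the "
            "interior cell grid",
            n_outside,
            len(cloud.points),
        )
    return BmdMap(
        grid=grid,
        mean=mean.reshape(grid.shape),
        count=counts.reshape(grid.shape),
        n_outside=n_outside,
    )
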