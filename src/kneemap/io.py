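"""Reading and writing the package's standard formats.

All geometry is expressed in millimetres in a right-handed patient
coordinate frame.  Meshes travel as PLY (preferred, with a per-vertex
``subchondral`` attribute) or STL with a plain-text sidecar listing the
subchondral vertex indices.  Volumes travel as NIfTI (via nibabel) or
MetaImage (via SimpleITK).  BMD cell maps are CSV tables.

Left knees are mirrored across the sagittal (x) plane on load, so every
downstream registration runs in a right-knee convention.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

__all__ = [
    "SurfaceMesh",
    "CtVolume",
    "AnchorSet",
    "RunConfig",
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "write_bmd_map",
    "read_bmd_map",
    "get_logger",
]

_LOG = logging.getLogger("kneemap")


def get_logger(name: str = "kneemap") -> logging.Logger:
    """Package logger; configure level via ``logging`` or the CLI."""
    return logging.getLogger(name)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Labeled triangular bone surface in scanner mm coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array indexing ``vertices``
    subchondral_mask : (n,) bool array, True for vertices on the
        subchondral bone area (the registration anchor patch)
    bone : {"femur", "tibia"}
    side : {"left", "right"}
    """

    vertices: np.ndarray
    faces: np.ndarray
    subchondral_mask: np.ndarray
    bone: str
    side: str = "right"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.subchondral_mask = np.asarray(self.subchondral_mask, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of triangles")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("faces index vertices out of range")
        if self.subchondral_mask.shape != (len(self.vertices),):
            raise ValueError(
                f"subchondral_mask has {self.subchondral_mask.size} entries "
                f"for {len(self.vertices)} vertices"
            )
        if self.bone not in ("femur", "tibia"):
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")

    # -- derived views ------------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def require_watertight(self) -> None:
        if not self.is_watertight:
            raise ValueError("mesh is not watertight (open surface)")

    def subchondral_points(self) -> np.ndarray:
        pts = self.vertices[self.subchondral_mask]
        if len(pts) == 0:
            raise ValueError("subchondral_mask selects no vertices")
        return pts

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices=np.asarray(vertices, float),
            faces=self.faces.copy(),
            subchondral_mask=self.subchondral_mask.copy(),
            bone=self.bone,
            side=self.side,
        )

    def mirrored_x(self) -> "SurfaceMesh":
        """Mirror across the sagittal plane, flipping winding so outward
        normals are preserved; the side label is toggled."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return SurfaceMesh(
            vertices=v,
            faces=self.faces[:, ::-1].copy(),
            subchondral_mask=self.subchondral_mask.copy(),
            bone=self.bone,
            side="right" if self.side == "left" else "left",
        )


@dataclass
class CtVolume:
    """Scalar voxel grid (HU or mg/cc) with spacing/origin/direction.

    The world position of voxel center ``(i, j, k)`` is
    ``origin + axes @ (index * spacing)``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive in all axes")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-6):
            raise ValueError("direction axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("direction axes are left-handed (det < 0)")

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> world (mm) affine."""
        a = np.eye(4)
        a[:3, :3] = self.axes * self.spacing[None, :]
        a[:3, 3] = self.origin
        return a

    def voxel_centers(self) -> np.ndarray:
        """World mm coordinates of every voxel center, shape (n, 3)."""
        nx, ny, nz = self.voxels.shape
        idx = np.stack(
            np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
            ),
            axis=-1,
        ).reshape(-1, 3)
        return self.index_to_world(idx)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return (self.axes @ (idx * self.spacing).T).T + self.origin

    def with_voxels(self, voxels: np.ndarray) -> "CtVolume":
        return CtVolume(
            voxels=np.asarray(voxels, float),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            axes=self.axes.copy(),
        )


@dataclass
class AnchorSet:
    """Manually identified anatomical anchors.

    Femur: trochlear notch and the medial/lateral epicondyles.
    Tibia: the longitudinal (shaft) axis as a unit vector pointing
    proximally (towards the plateau).
    """

    trochlear_notch: np.ndarray | None = None
    medial_epicondyle: np.ndarray | None = None
    lateral_epicondyle: np.ndarray | None = None
    longitudinal_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("trochlear_notch", "medial_epicondyle", "lateral_epicondyle"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).reshape(3)
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} contains non-finite values")
                setattr(self, name, v)
        if self.longitudinal_axis is not None:
            a = np.asarray(self.longitudinal_axis, dtype=float).reshape(3)
            n = np.linalg.norm(a)
            if not np.isfinite(n) or n == 0:
                raise ValueError("longitudinal_axis must be a nonzero vector")
            self.longitudinal_axis = a / n

    def require_femur(self) -> None:
        for name in ("trochlear_notch", "medial_epicondyle", "lateral_epicondyle"):
            if getattr(self, name) is None:
                raise ValueError(f"femur anchors missing {name}")

    def require_tibia(self) -> None:
        if self.longitudinal_axis is None:
            raise ValueError("tibia anchors missing longitudinal_axis")

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = [float(x) for x in v]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorSet":
        return cls(**{k: v for k, v in d.items() if v is not None})


@dataclass
class RunConfig:
    """Run configuration for registration and mapping.

    cell_size is the isotropic edge of the standard BMD cells (mm);
    the default 2 mm reproduces the method's reporting grid.
    """

    cell_size: float = 2.0
    icp_stiffness_schedule: tuple = (100.0, 10.0, 1.0, 0.1)
    icp_iterations_per_level: int = 5
    icp_control_points: int = 500
    distill_control_points: int = 1000
    tps_regularization: float = 0.0
    rotation_search_resolution: float = 1.0  # degrees
    displacement_tol: float = 1e-3  # mm, nonrigid ICP termination
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if len(self.icp_stiffness_schedule) == 0:
            raise ValueError("stiffness schedule must be non-empty")
        if self.icp_iterations_per_level < 1:
            raise ValueError("icp_iterations_per_level must be >= 1")
        if self.tps_regularization < 0:
            raise ValueError("tps_regularization must be non-negative")
        if self.rotation_search_resolution <= 0:
            raise ValueError("rotation_search_resolution must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "icp_stiffness_schedule" in data:
            data["icp_stiffness_schedule"] = tuple(data["icp_stiffness_schedule"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["icp_stiffness_schedule"] = list(self.icp_stiffness_schedule)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# mesh IO
# ---------------------------------------------------------------------------

_SIDEcar_SUFFIX = ".labels.txt"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDEcar_SUFFIX)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a labeled mesh.

    PLY is written in ASCII with double-precision vertices and a
    ``subchondral`` uchar vertex property (trimesh's writer would cast
    to float32 and lose sub-micrometre precision).  STL is written via
    trimesh with a sidecar ``<file>.labels.txt`` listing subchondral
    vertex indices.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply_double(mesh, path)
    elif path.suffix.lower() == ".stl":
        # STL is a triangle soup: emit unshared vertices so the sidecar
        # indices match the file's own vertex order on reload.
        soup_v = mesh.vertices[mesh.faces].reshape(-1, 3)
        soup_f = np.arange(len(soup_v)).reshape(-1, 3)
        trimesh.Trimesh(soup_v, soup_f, process=False).export(path)
        soup_mask = mesh.subchondral_mask[mesh.faces].reshape(-1)
        np.savetxt(_sidecar_path(path), np.nonzero(soup_mask)[0], fmt="%d")
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def _write_ply_double(mesh: SurfaceMesh, path: Path) -> None:
    n, m = len(mesh.vertices), len(mesh.faces)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"comment bone={mesh.bone} side={mesh.side}\n"
            f"element vertex {n}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "property uchar subchondral\n"
            f"element face {m}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v, s in zip(mesh.vertices, mesh.subchondral_mask.astype(int)):
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g} {s}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path, bone: str, side: str = "right") -> SurfaceMesh:
    """Read a labeled bone mesh; left knees are mirrored to the
    right-knee convention (side is recorded as given)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = trimesh.load(str(path), process=False, force="mesh")
    if loaded.faces.shape[1] != 3:
        raise ValueError("mesh faces are not triangles")
    mask = _load_labels(path, loaded)
    mesh = SurfaceMesh(
        vertices=np.asarray(loaded.vertices, float),
        faces=np.asarray(loaded.faces, np.int64),
        subchondral_mask=mask,
        bone=bone,
        side=side,
    )
    if side == "left":
        m = mesh.mirrored_x()
        m.side = "left"  # keep provenance; geometry is right-convention
        return m
    return mesh


def _load_labels(path: Path, loaded: trimesh.Trimesh) -> np.ndarray:
    n = len(loaded.vertices)
    raw = loaded.metadata.get("_ply_raw", {})
    vdata = raw.get("vertex", {}).get("data") if raw else None
    # trimesh exposes vertex properties as either a structured array or
    # a column dict depending on the file layout
    if isinstance(vdata, dict):
        names = tuple(vdata.keys())
    else:
        names = getattr(getattr(vdata, "dtype", None), "names", None) or ()
    if vdata is not None and "subchondral" in names:
        lab = np.asarray(vdata["subchondral"]).reshape(-1)
        if lab.size != n:
            raise ValueError(
                f"label channel has {lab.size} entries for {n} vertices"
            )
        return lab.astype(bool)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        idx = np.loadtxt(sidecar, dtype=int, ndmin=1)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("sidecar label indices out of range")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        return mask
    raise ValueError(
        f"{path} carries no 'subchondral' vertex attribute and no sidecar "
        f"{sidecar.name}"
    )


# ---------------------------------------------------------------------------
# volume IO
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> CtVolume:
    """Read a scalar volume (NIfTI via nibabel, MetaImage via SimpleITK)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        aff = np.asarray(img.affine, float)
        lin = aff[:3, :3]
        spacing = np.linalg.norm(lin, axis=0)
        if np.any(spacing <= 0):
            raise ValueError("volume has non-positive spacing")
        axes = lin / spacing[None, :]
        return CtVolume(
            voxels=np.asarray(img.get_fdata(), float),
            spacing=spacing,
            origin=aff[:3, 3],
            axes=axes,
        )
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        return CtVolume(
            voxels=np.transpose(arr, (2, 1, 0)).astype(float),
            spacing=np.asarray(img.GetSpacing(), float),
            origin=np.asarray(img.GetOrigin(), float),
            axes=np.asarray(img.GetDirection(), float).reshape(3, 3),
        )
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(volume: CtVolume, path: str | Path) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(volume.voxels, volume.affine), str(path))
        return
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(volume.voxels, (2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        img.SetDirection(tuple(float(d) for d in volume.axes.reshape(-1)))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# BMD map IO
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["i", "j", "k", "x_mm", "y_mm", "z_mm", "mean_bmd_mgcc", "voxel_count"]


def write_bmd_map(bmd_map, path: str | Path) -> None:
    """Write a BMD cell map as CSV, one row per interior cell.

    Empty cells (no registered voxels) keep their row with an explicit
    ``NA`` token in ``mean_bmd_mgcc`` — missingness is distinct from 0.
    """
    df = bmd_map.to_frame()
    df.to_csv(path, index=False, na_rep="NA")


def read_bmd_map(path: str | Path) -> pd.DataFrame:
    """Read a BMD map table back; ``mean_bmd_mgcc`` is NaN where the
    cell was empty."""
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"BMD map table missing columns: {missing}")
    return df
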