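"""Spatial transforms composing the surface-to-voxel warp chain.

The registration of a moving bone onto the reference bone is represented
as an ordered chain (:class:`CompositeWarp`) of invertible global
transforms — similarity, per-condyle region scaling, axial rotation —
followed by a forward-only thin-plate-spline (TPS) warp distilled from
the nonrigid surface matching.  The same chain later carries the CT
voxel centers into reference space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SimilarityTransform",
    "RegionScaling",
    "AxialRotation",
    "TpsWarp",
    "ThinPlateSpline",
    "fit_tps",
    "CompositeWarp",
]


@dataclass
class SimilarityTransform:
    """p' = scale * R p + t, with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return self.scale * (p @ self.rotation.T) + self.translation

    def inverse(self) -> "SimilarityTransform":
        rot = self.rotation.T
        return SimilarityTransform(
            rotation=rot,
            translation=-(rot @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def to_dict(self) -> dict:
        return {
            "type": "similarity",
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale": float(self.scale),
        }


@dataclass
class RegionScaling:
    """Cylinder-frame scaling: radial scaling about the axis, and
    separate axial scalings on either side of ``boundary_coordinate``
    (the trochlear-notch projection for the femur).  The mapping is
    continuous at the boundary by construction.  The axis direction
    points medial to lateral, so the negative-axial side is medial.
    """

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radial_scale: float = 1.0
    medial_axial_scale: float = 1.0
    lateral_axial_scale: float = 1.0
    boundary_coordinate: float = 0.0

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, float).reshape(3)
        self.axis_dir = np.asarray(self.axis_dir, float).reshape(3)
        n = np.linalg.norm(self.axis_dir)
        if n == 0:
            raise ValueError("axis_dir must be nonzero")
        self.axis_dir = self.axis_dir / n
        for s in (self.radial_scale, self.medial_axial_scale, self.lateral_axial_scale):
            if s <= 0:
                raise ValueError("all scales must be > 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        q = p - self.axis_point
        t = q @ self.axis_dir
        radial = q - np.outer(t, self.axis_dir)
        tb = t - self.boundary_coordinate
        ax_scale = np.where(tb < 0, self.medial_axial_scale, self.lateral_axial_scale)
        t_new = self.boundary_coordinate + tb * ax_scale
        return self.axis_point + np.outer(t_new, self.axis_dir) + self.radial_scale * radial

    def inverse(self) -> "RegionScaling":
        return RegionScaling(
            axis_point=self.axis_point,
            axis_dir=self.axis_dir,
            radial_scale=1.0 / self.radial_scale,
            medial_axial_scale=1.0 / self.medial_axial_scale,
            lateral_axial_scale=1.0 / self.lateral_axial_scale,
            boundary_coordinate=self.boundary_coordinate,
        )

    def to_dict(self) -> dict:
        return {
            "type": "region_scaling",
            "axis_point": self.axis_point.tolist(),
            "axis_dir": self.axis_dir.tolist(),
            "radial_scale": float(self.radial_scale),
            "medial_axial_scale": float(self.medial_axial_scale),
            "lateral_axial_scale": float(self.lateral_axial_scale),
            "boundary_coordinate": float(self.boundary_coordinate),
        }


@dataclass
class AxialRotation:
    """Rotation by ``angle_deg`` about the axis through ``axis_point``
    with direction ``axis_dir`` (right-hand rule)."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, float).reshape(3)
        self.axis_dir = np.asarray(self.axis_dir, float).reshape(3)
        n = np.linalg.norm(self.axis_dir)
        if n == 0:
            raise ValueError("axis_dir must be nonzero")
        self.axis_dir = self.axis_dir / n

    @property
    def matrix(self) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        k = self.axis_dir
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        return np.eye(3) + np.sin(a) * kx + (1 - np.cos(a)) * (kx @ kx)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p - self.axis_point) @ self.matrix.T + self.axis_point

    def inverse(self) -> "AxialRotation":
        return AxialRotation(self.axis_point, self.axis_dir, -self.angle_deg)

    def to_dict(self) -> dict:
        return {
            "type": "axial_rotation",
            "axis_point": self.axis_point.tolist(),
            "axis_dir": self.axis_dir.tolist(),
            "angle_deg": float(self.angle_deg),
        }


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------


@dataclass
class TpsWarp:
    """3D thin-plate-spline warp with the biharmonic kernel U(r) = r.

    p' = A [p; 1] + sum_i w_i |p - c_i|.  With ``regularization`` 0 the
    warp interpolates every control pair exactly; larger values trade
    interpolation for smoothness and in the limit tend to the
    least-squares affine map.  Forward-only (no closed-form inverse).
    """

    control_points_source: np.ndarray
    control_points_target: np.ndarray
    affine_part: np.ndarray  # (3, 4), acts on [x, y, z, 1]
    kernel_weights: np.ndarray  # (n, 3)
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.control_points_source = np.asarray(self.control_points_source, float)
        self.control_points_target = np.asarray(self.control_points_target, float)
        self.affine_part = np.asarray(self.affine_part, float).reshape(3, 4)
        self.kernel_weights = np.asarray(self.kernel_weights, float)
        n = len(self.control_points_source)
        if len(self.control_points_target) != n or len(self.kernel_weights) != n:
            raise ValueError("control point / weight counts differ")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    def apply(self, points: np.ndarray, chunk: int = 4096) -> np.ndarray:
        p = np.asarray(points, float)
        flat = p.reshape(-1, 3)
        out = np.empty_like(flat)
        c = self.control_points_source
        for lo in range(0, len(flat), chunk):
            block = flat[lo : lo + chunk]
            r = np.sqrt(
                np.maximum(
                    ((block[:, None, :] - c[None, :, :]) ** 2).sum(-1), 0.0
                )
            )
            out[lo : lo + chunk] = (
                block @ self.affine_part[:, :3].T
                + self.affine_part[:, 3]
                + r @ self.kernel_weights
            )
        return out.reshape(p.shape)

    @property
    def bending_energy(self) -> float:
        """Quadratic form w^T K w summed over output dimensions."""
        c = self.control_points_source
        k = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        return float(
            np.einsum("id,ij,jd->", self.kernel_weights, k, self.kernel_weights)
        )

    def to_dict(self) -> dict:
        return {
            "type": "tps",
            "control_points_source": self.control_points_source.tolist(),
            "control_points_target": self.control_points_target.tolist(),
            "affine_part": self.affine_part.tolist(),
            "kernel_weights": self.kernel_weights.tolist(),
            "regularization": float(self.regularization),
        }


class ThinPlateSpline(BaseEstimator, TransformerMixin):
    """sklearn-style TPS estimator.

    Parameters
    ----------
    regularization : float, default 0.0
        Smoothing added to the kernel diagonal; 0 gives exact landmark
        interpolation.

    Attributes
    ----------
    warp_ : TpsWarp
        The fitted warp; ``transform`` evaluates it.
    """

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThinPlateSpline":
        src = np.asarray(X, float)
        tgt = np.asarray(y, float)
        if src.ndim != 2 or src.shape[1] != 3:
            raise ValueError("source points must be (n, 3)")
        if src.shape != tgt.shape:
            raise ValueError("source and target shapes differ")
        n = len(src)
        if n < 4:
            raise ValueError("need at least 4 control points")
        d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
        off = d2[~np.eye(n, dtype=bool)]
        if off.min() < 1e-20:
            raise ValueError("duplicate source control points")
        # coplanarity makes the polynomial block rank-deficient
        q = src - src.mean(axis=0)
        if np.linalg.svd(q, compute_uv=False)[-1] < 1e-9 * max(
            np.abs(q).max(), 1.0
        ):
            raise ValueError("source control points are coplanar")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

        k = np.sqrt(d2)
        p = np.hstack([np.ones((n, 1)), src])
        lhs = np.zeros((n + 4, n + 4))
        lhs[:n, :n] = k + self.regularization * np.eye(n)
        lhs[:n, n:] = p
        lhs[n:, :n] = p.T
        rhs = np.zeros((n + 4, 3))
        rhs[:n] = tgt
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular TPS system: {exc}") from exc
        w = sol[:n]
        a = sol[n:]  # rows: [1, x, y, z] coefficients per output via columns
        affine = np.zeros((3, 4))
        affine[:, 3] = a[0]
        affine[:, :3] = a[1:].T
        self.warp_ = TpsWarp(
            control_points_source=src.copy(),
            control_points_target=tgt.copy(),
            affine_part=affine,
            kernel_weights=w,
            regularization=self.regularization,
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "warp_"):
            raise AttributeError("ThinPlateSpline is not fitted")
        return self.warp_.apply(X)


def fit_tps(
    source_points: np.ndarray,
    target_points: np.ndarray,
    regularization: float = 0.0,
) -> TpsWarp:
    """Fit a 3D TPS mapping source landmarks to target landmarks."""
    return (
        ThinPlateSpline(regularization=regularization)
        .fit(source_points, target_points)
        .warp_
    )


# ---------------------------------------------------------------------------
# composite warp
# ---------------------------------------------------------------------------

_TYPES = {
    "similarity": SimilarityTransform,
    "region_scaling": RegionScaling,
    "axial_rotation": AxialRotation,
    "tps": TpsWarp,
}


@dataclass
class CompositeWarp:
    """Ordered transform chain; application order is list order."""

    chain: list

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        for t in self.chain:
            p = t.apply(p)
        return p

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"chain": [t.to_dict() for t in self.chain]})
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CompositeWarp":
        if isinstance(source, Path) or (
            isinstance(source, str)
            and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = json.loads(text)
        chain = []
        for item in data["chain"]:
            kind = item.pop("type")
            chain.append(_TYPES[kind](**{k: np.asarray(v) if isinstance(v, list) else v for k, v in item.items()}))
        return cls(chain=chain)
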