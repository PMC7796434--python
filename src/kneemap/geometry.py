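"""Geometric primitives shared by registration and voxel mapping.

Everything here is plain computational geometry on mm coordinates:
orthogonal-distance cylinder fitting, watertight point-in-mesh tests by
ray parity, exact point-to-triangle surface distances, and farthest-point
subsampling.  These are deliberately dependency-light and fully
vectorized so CT-sized point sets stay fast on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "CylinderFit",
    "fit_cylinder",
    "points_in_mesh",
    "surface_distances",
    "closest_points_on_surface",
    "farthest_point_indices",
    "sample_surface_points",
]


# ---------------------------------------------------------------------------
# cylinder fitting
# ---------------------------------------------------------------------------


@dataclass
class CylinderFit:
    """Least-squares cylinder: axis through ``axis_point`` with unit
    direction ``axis_dir`` and radius ``radius`` (mm)."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, float).reshape(3)
        self.axis_dir = np.asarray(self.axis_dir, float).reshape(3)
        n = np.linalg.norm(self.axis_dir)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis_dir must be a nonzero vector")
        self.axis_dir = self.axis_dir / n
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.axis_point) @ self.axis_dir

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, float) - self.axis_point
        t = d @ self.axis_dir
        return np.linalg.norm(d - np.outer(t, self.axis_dir), axis=1)


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _cylinder_residuals(params, points, centroid):
    theta, phi, c1, c2, r = params
    d = _dir_from_angles(theta, phi)
    # two basis vectors spanning the plane perpendicular to d
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    c = centroid + c1 * e1 + c2 * e2
    q = points - c
    t = q @ d
    rad = np.linalg.norm(q - np.outer(t, d), axis=1)
    return rad - r


def fit_cylinder(
    points: np.ndarray,
    orient: np.ndarray | None = None,
    init_dir: np.ndarray | None = None,
) -> CylinderFit:
    """Fit a cylinder to a curved point patch by orthogonal-distance
    least squares (residual = distance-to-axis minus radius).

    The optimiser is started from each principal axis of the patch (the
    subchondral patch of a femur is elongated along the flexion axis, so
    the principal axis is an excellent start) and the best local optimum
    is kept.  ``orient`` optionally fixes the sign of ``axis_dir`` (e.g.
    the medial-to-lateral epicondyle direction).
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 6:
        raise ValueError("need at least 6 three-dimensional points")
    centroid = points.mean(axis=0)
    q = points - centroid
    u, s, vt = np.linalg.svd(q, full_matrices=False)
    scale = np.linalg.norm(q, axis=1).max()
    if s[2] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate geometry: points are coplanar")

    starts = [vt[0], vt[1], vt[2]] if init_dir is None else [np.asarray(init_dir, float)]
    best = None
    for d0 in starts:
        d0 = d0 / np.linalg.norm(d0)
        theta0 = float(np.arccos(np.clip(d0[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(d0[1], d0[0]))
        # initial radius/center: mean radial distance about the centroid axis
        t = q @ d0
        rad = np.linalg.norm(q - np.outer(t, d0), axis=1)
        r0 = max(rad.mean(), 1e-3)
        res = least_squares(
            _cylinder_residuals,
            x0=[theta0, phi0, 0.0, 0.0, r0],
            args=(points, centroid),
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("cylinder fit did not converge")

    theta, phi, c1, c2, r = best.x
    d = _dir_from_angles(theta, phi)
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    c = centroid + c1 * e1 + c2 * e2
    if r < 0:
        r = -r
    if r <= 0 or r > 100 * scale:
        raise RuntimeError("cylinder fit degenerate (radius out of range)")
    if orient is not None and np.dot(d, np.asarray(orient, float)) < 0:
        d = -d
    rms = float(np.sqrt(np.mean(best.fun**2)))
    # anchor the axis point at the projection of the patch centroid
    c = c + ((centroid - c) @ d) * d
    return CylinderFit(axis_point=c, axis_dir=d, radius=float(r), rms_residual=rms)


# ---------------------------------------------------------------------------
# point-in-mesh (ray parity)
# ---------------------------------------------------------------------------


def points_in_mesh(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Strict interior test for a watertight mesh by +z ray parity.

    Points sharing an (x, y) column (CT voxel centers do) are grouped so
    each column's triangle crossings are computed once.  Column
    coordinates are nudged by a fixed sub-nanometre offset so rays do not
    pass exactly through shared triangle edges.
    """
    points = np.asarray(points, float)
    if points.size == 0:
        return np.zeros(0, dtype=bool)
    tri = np.asarray(vertices, float)[np.asarray(faces, np.int64)]  # (m, 3, 3)

    # tiny fixed irrational nudge breaks edge/vertex coincidences
    eps = np.array([1.1920928955078125e-6, 2.1073424255447017e-6])
    xy = points[:, :2] + eps
    cols, inv = np.unique(np.round(xy, 6), axis=0, return_inverse=True)
    # crossings per unique column, as (column_id, z) pairs
    ax, ay = tri[:, :, 0], tri[:, :, 1]  # (m, 3)
    az = tri[:, :, 2]
    v0x, v0y, v0z = ax[:, 0], ay[:, 0], az[:, 0]
    e1x, e1y = ax[:, 1] - v0x, ay[:, 1] - v0y
    e2x, e2y = ax[:, 2] - v0x, ay[:, 2] - v0y
    det = e1x * e2y - e1y * e2x  # 2x projected signed area
    ok = np.abs(det) > 1e-300
    inside = np.zeros(len(points), dtype=bool)

    for lo in range(0, len(cols), chunk):
        cxy = cols[lo : lo + chunk]  # (c, 2)
        px = cxy[:, 0][:, None] - v0x[None, :]
        py = cxy[:, 1][:, None] - v0y[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (px * e2y[None, :] - py * e2x[None, :]) / det[None, :]
            t = (e1x[None, :] * py - e1y[None, :] * px) / det[None, :]
            hit = ok[None, :] & (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0)
            zc = (
                v0z[None, :]
                + s * (az[:, 1] - v0z)[None, :]
                + t * (az[:, 2] - v0z)[None, :]
            )
        ci, tj = np.nonzero(hit)
        if len(ci) == 0:
            continue
        zhit = zc[ci, tj]
        # for every point mapped to these columns, parity of crossings above
        sel = np.nonzero((inv >= lo) & (inv < lo + len(cxy)))[0]
        if len(sel) == 0:
            continue
        order = np.argsort(ci, kind="stable")
        ci_s, z_s = ci[order], zhit[order]
        bounds = np.searchsorted(ci_s, np.arange(len(cxy) + 1))
        for p in sel:
            c = inv[p] - lo
            zs = z_s[bounds[c] : bounds[c + 1]]
            inside[p] = (np.count_nonzero(zs > points[p, 2]) % 2) == 1
    return inside


# ---------------------------------------------------------------------------
# point-to-surface distance
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for paired (n, 3) points and
    (n, 3, 3) triangles (Ericson's barycentric region walk, vectorized)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    reg = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[reg] = a[reg]
    done |= reg
    reg = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[reg] = b[reg]
    done |= reg
    reg = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[reg] = c[reg]
    done |= reg

    vc = d1 * d4 - d3 * d2
    reg = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[reg] = a[reg] + v[reg, None] * ab[reg]
    done |= reg

    vb = d5 * d2 - d1 * d6
    reg = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[reg] = a[reg] + w[reg, None] * ac[reg]
    done |= reg

    va = d3 * d6 - d5 * d4
    reg = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[reg] = b[reg] + w[reg, None] * (c[reg] - b[reg])
    done |= reg

    reg = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[reg] = a[reg] + v[reg, None] * ab[reg] + w[reg, None] * ac[reg]
    return out


class _SurfaceIndex:
    """KD-tree over triangle centroids + vertex incidence for candidate
    face lookup; exact point-to-triangle distance on the candidates."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 12):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, np.int64)
        if len(self.faces) == 0:
            raise ValueError("surface has zero faces")
        self.tri = self.vertices[self.faces]
        self.centroid_tree = cKDTree(self.tri.mean(axis=1))
        self.vertex_tree = cKDTree(self.vertices)
        # faces incident to each vertex (ragged, stored flat)
        order = np.argsort(self.faces.reshape(-1), kind="stable")
        self.incident_faces = order // 3
        self.incident_bounds = np.searchsorted(
            self.faces.reshape(-1)[order], np.arange(len(self.vertices) + 1)
        )
        self.k = min(k, len(self.faces))

    def closest(self, points: np.ndarray):
        points = np.asarray(points, float)
        _, cand = self.centroid_tree.query(points, k=self.k)
        cand = np.asarray(cand).reshape(len(points), self.k)
        _, nv = self.vertex_tree.query(points, k=1)
        best_d2 = np.full(len(points), np.inf)
        best_pt = np.zeros_like(points)

        def consider(face_idx, mask=None):
            rows = np.arange(len(points)) if mask is None else np.nonzero(mask)[0]
            if len(rows) == 0:
                return
            cp = _closest_point_on_triangles(points[rows], self.tri[face_idx])
            d2 = np.einsum("ij,ij->i", points[rows] - cp, points[rows] - cp)
            better = d2 < best_d2[rows]
            rr = rows[better]
            best_d2[rr] = d2[better]
            best_pt[rr] = cp[better]

        for j in range(cand.shape[1]):
            consider(cand[:, j])
        # also faces incident to the nearest vertex (guards against
        # candidate misses when triangle sizes vary)
        counts = self.incident_bounds[nv + 1] - self.incident_bounds[nv]
        for j in range(int(counts.max(initial=0))):
            has = counts > j
            fidx = self.incident_faces[self.incident_bounds[nv[has]] + j]
            consider(fidx, mask=has)
        return best_pt, np.sqrt(best_d2)


def closest_points_on_surface(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
):
    """Closest surface points and distances for each query point."""
    return _SurfaceIndex(vertices, faces).closest(points)


def surface_distances(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    return closest_points_on_surface(points, vertices, faces)[1]


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------


def farthest_point_indices(points: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point subsample; deterministic given the seed."""
    points = np.asarray(points, float)
    n = min(n, len(points))
    rng = np.random.default_rng(seed)
    idx = np.empty(n, dtype=np.int64)
    idx[0] = rng.integers(len(points))
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for i in range(1, n):
        idx[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[idx[i]], axis=1))
    return idx


def sample_surface_points(
    vertices: np.ndarray, faces: np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """Uniform-by-area random points on a triangle surface."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    tri = vertices[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    rng = np.random.default_rng(seed)
    f = rng.choice(len(faces), size=n, p=area / area.sum())
    r1, r2 = rng.random(n), rng.random(n)
    s = np.sqrt(r1)
    u, v = 1 - s, s * (1 - r2)
    w = 1 - u - v
    return u[:, None] * tri[f, 0] + v[:, None] * tri[f, 1] + w[:, None] * tri[f, 2]
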