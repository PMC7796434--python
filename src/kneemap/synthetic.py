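"""Synthetic fixtures: bone-like labeled meshes, rasterized CT volumes
with calibration rods, smooth ground-truth deformations, and
repeated-measures BMD tables.

The shapes are idealized — a cylinder-patch femur whose subchondral
area lies *exactly* on a cylinder of known radius (with a
compact-support intercondylar groove separating two condylar patches),
and an ellipse-plateau tibia with two disjoint subchondral areas — so
every registration step has analytic ground truth.  Every generator is
a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import PhantomSample
from .geometry import points_in_mesh
from .io import AnchorSet, CtVolume, SurfaceMesh
from .stats import RepeatedMeasures
from .transforms import SimilarityTransform

__all__ = [
    "SyntheticBoneSpec",
    "DeformationSpec",
    "make_bone_mesh",
    "make_ct",
    "make_repeated_dataset",
    "default_bmd_field",
    "apply_deformation",
]

DEFAULT_SETTINGS = (
    "intra_operator_inter_scan",
    "inter_operator_intra_scan",
    "inter_operator_inter_scan",
)


@dataclass
class SyntheticBoneSpec:
    """Parameters of an idealized synthetic bone.

    Femur: condyle_radius is the exact radius of the subchondral
    cylinder; medial/lateral_length the axial half-extents (mm).
    Tibia: plateau_radii the (ML, AP) semi-axes of the plateau ellipse;
    shaft_length the proximal segment height (mm).
    """

    bone: str = "femur"
    condyle_radius: float = 20.0
    medial_length: float = 33.0
    lateral_length: float = 37.0
    notch_half_width: float = 5.0
    notch_depth: float = 4.0
    plateau_radii: tuple = (36.0, 24.0)
    shaft_length: float = 60.0
    resolution: tuple = (40, 48)  # (axial rings, circumferential points)
    vertex_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone not in ("femur", "tibia"):
            raise ValueError(f"unknown bone {self.bone!r}")
        for name in ("condyle_radius", "medial_length", "lateral_length",
                     "shaft_length", "notch_half_width", "notch_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.plateau_radii) <= 0:
            raise ValueError("plateau_radii must be positive")
        if min(self.resolution) < 12:
            raise ValueError("resolution too low for a watertight bone mesh")
        if self.vertex_jitter < 0:
            raise ValueError("vertex_jitter must be >= 0")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _close_tube(rings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate an (n_rings, n_theta, 3) tube and close both ends
    with fans to the ring centroids (watertight)."""
    n_r, n_t, _ = rings.shape
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n_r - 1):
        for j in range(n_t):
            a = i * n_t + j
            b = i * n_t + (j + 1) % n_t
            c = (i + 1) * n_t + j
            d = (i + 1) * n_t + (j + 1) % n_t
            faces.append((a, b, d))
            faces.append((a, d, c))
    start_apex = len(verts)
    end_apex = len(verts) + 1
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    for j in range(n_t):
        faces.append((start_apex, (j + 1) % n_t, j))
        base = (n_r - 1) * n_t
        faces.append((end_apex, base + j, base + (j + 1) % n_t))
    return verts, np.asarray(faces, np.int64)


def _make_femur(spec: SyntheticBoneSpec):
    n_x, n_t = spec.resolution
    R = spec.condyle_radius
    xs = np.linspace(-spec.medial_length, spec.lateral_length, n_x)
    thetas = np.linspace(-np.pi, np.pi, n_t, endpoint=False)
    X, T = np.meshgrid(xs, thetas, indexing="ij")

    # subchondral angular half-width varies along the axis so the patch
    # breaks rotational symmetry (unique axial-rotation optimum)
    w = np.deg2rad(70.0 + 18.0 * np.sin(1.8 * X / spec.lateral_length + 0.6))
    f = np.ones_like(X)
    outside = np.abs(T) > w
    t_out = (np.abs(T) - w) / (np.pi - w)
    f = np.where(outside, 1.0 - 0.35 * _smoothstep(t_out), f)

    # compact-support intercondylar groove: exactly zero for |x| >= notch_half_width
    bump_x = np.where(
        np.abs(X) < spec.notch_half_width,
        np.cos(np.pi * X / (2.0 * spec.notch_half_width)) ** 2,
        0.0,
    )
    bump_t = np.where(np.abs(T) < 0.6, np.cos(np.pi * T / 1.2) ** 2, 0.0)
    groove = spec.notch_depth / R * bump_x * bump_t
    radius = R * (f - groove)

    # radial direction: theta = 0 points inferior (-z)
    rings = np.stack(
        [X, radius * np.sin(T), -radius * np.cos(T)], axis=-1
    )  # (n_x, n_t, 3)
    verts, faces = _close_tube(rings)

    mask = np.zeros(len(verts), dtype=bool)
    on_cyl = (np.abs(T) <= w) & (np.abs(X) >= spec.notch_half_width)
    mask[: n_x * n_t] = on_cyl.reshape(-1)

    notch_r = R - spec.notch_depth
    anchors = AnchorSet(
        trochlear_notch=np.array([0.0, 0.0, -notch_r]),
        medial_epicondyle=verts[-2] + np.array([-3.0, 0.0, 0.0]),
        lateral_epicondyle=verts[-1] + np.array([3.0, 0.0, 0.0]),
    )
    # move the cap apexes out to the epicondyles so the anchors lie on
    # the surface and the condylar extents differ medially/laterally
    verts[-2] = anchors.medial_epicondyle
    verts[-1] = anchors.lateral_epicondyle
    return verts, faces, mask, anchors


def _make_tibia(spec: SyntheticBoneSpec):
    n_z, n_t = spec.resolution
    a0, b0 = spec.plateau_radii
    H = spec.shaft_length
    thetas = np.linspace(-np.pi, np.pi, n_t, endpoint=False)

    # side wall: tapered elliptical rings from the distal end up to z=0
    zs = np.linspace(-H, 0.0, n_z)
    taper = 0.45 + 0.55 * np.exp(zs / 25.0)
    side = np.stack(
        [
            np.outer(taper * a0, np.cos(thetas)),
            np.outer(taper * b0, np.sin(thetas)),
            np.repeat(zs[:, None], n_t, axis=1),
        ],
        axis=-1,
    )

    # plateau cap: elliptical rings shrinking inward with a gentle dome
    n_cap = max(6, n_t // 6)
    rhos = np.linspace(1.0, 0.0, n_cap + 1)[1:-1]  # exclude outer ring & center
    cap = np.stack(
        [
            np.outer(rhos * a0, np.cos(thetas)),
            np.outer(rhos * b0, np.sin(thetas)),
            1.0 * (1.0 - np.repeat(rhos[:, None] ** 2, n_t, axis=1)),
        ],
        axis=-1,
    )
    rings = np.concatenate([side, cap], axis=0)
    verts, faces = _close_tube(rings)
    # _close_tube put the top apex at the centroid of the last cap ring;
    # lift it onto the dome
    verts[-1] = np.array([0.0, 0.0, 1.0])

    # subchondral: plateau vertices inside the medial or lateral ellipse
    mask = np.zeros(len(verts), dtype=bool)
    top = verts[:, 2] > 0.0
    x, y = verts[:, 0], verts[:, 1]
    med = ((x + 0.36 * a0) / 11.0) ** 2 + (y / 9.0) ** 2 <= 1.0
    lat = ((x - 0.36 * a0) / 9.0) ** 2 + (y / 7.5) ** 2 <= 1.0
    mask[top & (med | lat)] = True
    anchors = AnchorSet(longitudinal_axis=np.array([0.0, 0.0, 1.0]))
    return verts, faces, mask, anchors


def make_bone_mesh(spec: SyntheticBoneSpec) -> tuple[SurfaceMesh, AnchorSet]:
    """Generate a watertight labeled bone mesh with ground-truth
    anchors; deterministic per spec + seed."""
    if spec.bone == "femur":
        verts, faces, mask, anchors = _make_femur(spec)
    else:
        verts, faces, mask, anchors = _make_tibia(spec)
    if spec.vertex_jitter > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.vertex_jitter, verts.shape)
    mesh = SurfaceMesh(
        vertices=verts, faces=faces, subchondral_mask=mask, bone=spec.bone
    )
    return mesh, anchors


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


@dataclass
class DeformationSpec:
    """Known similarity plus a smooth sum-of-Gaussian-bumps warp.

    The warp stays diffeomorphic while amplitude/width stays well below
    1 (gradient bound a/width * e^-1/2 < 1)."""

    scale: float = 1.0
    rotation_deg: tuple = (0.0, 0.0, 0.0)  # about x, y, z through the centroid
    translation: tuple = (0.0, 0.0, 0.0)
    n_bumps: int = 6
    amplitude: float = 1.5  # mm, max bump displacement
    width: float = 25.0  # mm, Gaussian sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude / self.width > 0.5:
            raise ValueError("amplitude/width too large to stay invertible")

    def similarity(self, center: np.ndarray) -> SimilarityTransform:
        rx, ry, rz = np.deg2rad(self.rotation_deg)

        def rot(axis, ang):
            c, s = np.cos(ang), np.sin(ang)
            if axis == 0:
                return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
            if axis == 1:
                return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

        R = rot(2, rz) @ rot(1, ry) @ rot(0, rx)
        t = (
            np.asarray(self.translation, float)
            + np.asarray(center, float)
            - self.scale * R @ np.asarray(center, float)
        )
        return SimilarityTransform(rotation=R, translation=t, scale=self.scale)

    def bumps(self, bounds_lo: np.ndarray, bounds_hi: np.ndarray):
        rng = np.random.default_rng(self.seed)
        centers = rng.uniform(bounds_lo, bounds_hi, size=(self.n_bumps, 3))
        dirs = rng.normal(size=(self.n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amps = rng.uniform(0.3, 1.0, self.n_bumps) * self.amplitude
        return centers, dirs * amps[:, None]

    def displacement(self, points: np.ndarray, centers, vecs) -> np.ndarray:
        p = np.asarray(points, float)
        d2 = ((p[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        wgt = np.exp(-d2 / (2.0 * self.width**2))
        return wgt @ vecs


class DeformationMap:
    """Forward map p -> similarity(p + bump displacement(p)), with a
    fixed-point inverse (the bump warp is a small-Lipschitz
    perturbation of the identity, so iteration converges fast)."""

    def __init__(self, spec: DeformationSpec, sim, centers, vecs):
        self.spec = spec
        self.similarity = sim
        self.centers = centers
        self.vecs = vecs

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.forward(points)

    def forward(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        warped = p + self.spec.displacement(p, self.centers, self.vecs)
        return self.similarity.apply(warped)

    def inverse(self, points: np.ndarray, tol: float = 1e-10, max_iter: int = 200):
        w = self.similarity.inverse().apply(np.asarray(points, float))
        p = w.copy()
        for _ in range(max_iter):
            nxt = w - self.spec.displacement(p, self.centers, self.vecs)
            if np.abs(nxt - p).max() < tol:
                p = nxt
                break
            p = nxt
        return p


def apply_deformation(
    mesh: SurfaceMesh, spec: DeformationSpec, anchors: AnchorSet | None = None
):
    """Apply the spec's similarity + smooth warp to a mesh (and its
    anchors); returns (deformed mesh, deformed anchors, point_map)
    where point_map is a :class:`DeformationMap` (callable = forward)."""
    center = mesh.vertices.mean(axis=0)
    sim = spec.similarity(center)
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    centers, vecs = spec.bumps(lo, hi)
    point_map = DeformationMap(spec, sim, centers, vecs)

    new_mesh = mesh.with_vertices(point_map(mesh.vertices))
    new_anchors = None
    if anchors is not None:
        kw = {}
        for name in ("trochlear_notch", "medial_epicondyle", "lateral_epicondyle"):
            v = getattr(anchors, name)
            if v is not None:
                kw[name] = point_map(v[None])[0]
        if anchors.longitudinal_axis is not None:
            kw["longitudinal_axis"] = sim.rotation @ anchors.longitudinal_axis
        new_anchors = AnchorSet(**kw)
    return new_mesh, new_anchors, point_map


# ---------------------------------------------------------------------------
# CT rasterization with calibration rods
# ---------------------------------------------------------------------------


def default_bmd_field(points: np.ndarray) -> np.ndarray:
    """Smooth spatial BMD field, 120-380 mg/cc, low-frequency."""
    p = np.asarray(points, float)
    return (
        250.0
        + 80.0 * np.sin(p[:, 0] / 18.0)
        + 40.0 * np.cos(p[:, 1] / 14.0 + 0.5)
        + 10.0 * np.sin(p[:, 2] / 22.0)
    )


def make_ct(
    mesh: SurfaceMesh,
    bmd_field=default_bmd_field,
    spacing=(1.0, 1.0, 1.0),
    calibration_truth: tuple[float, float] = (0.8, -5.0),
    rod_densities: tuple = (0.0, 50.0, 100.0, 200.0, 400.0),
    noise_sigma: float = 0.0,
    background_hu: float = -80.0,
    rod_radius: float = 5.0,
    seed: int = 0,
) -> tuple[CtVolume, list[PhantomSample], CtVolume]:
    """Rasterize a bone + multi-rod calibration phantom into an HU
    volume.

    Voxels inside the bone get HU = (bmd_field - intercept) / slope
    (plus optional Gaussian noise); rods are constant-density cylinders
    laid beside the bone along x.  Returns the HU volume, the
    PhantomSamples measured from the (noisy) rod interiors, and the
    ground-truth BMD volume (NaN outside bone and rods).
    """
    mesh.require_watertight()
    spacing = np.asarray(spacing, float)
    slope, intercept = calibration_truth
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    if np.any(spacing > (hi - lo)):
        raise ValueError("spacing larger than the bone")

    rod_y0 = lo[1] - 2.0 * rod_radius
    rod_z = lo[2] - 2.5 * rod_radius
    rod_ys = rod_y0 - np.arange(len(rod_densities)) * (2.6 * rod_radius)

    margin = 4.0
    vol_lo = np.array(
        [lo[0] - margin, min(rod_ys.min() - rod_radius, lo[1]) - margin, rod_z - rod_radius - margin]
    )
    vol_hi = np.array([hi[0] + margin, hi[1] + margin, hi[2] + margin])
    shape = np.ceil((vol_hi - vol_lo) / spacing).astype(int)
    origin = vol_lo + spacing / 2.0

    vol = CtVolume(
        voxels=np.full(tuple(shape), background_hu), spacing=spacing, origin=origin
    )
    centers = vol.voxel_centers()

    hu = np.full(len(centers), background_hu)
    truth = np.full(len(centers), np.nan)

    near = np.all((centers >= lo - 1e-9) & (centers <= hi + 1e-9), axis=1)
    inside = np.zeros(len(centers), dtype=bool)
    inside[np.nonzero(near)[0]] = points_in_mesh(
        centers[near], mesh.vertices, mesh.faces
    )
    bmd = np.asarray(bmd_field(centers[inside]), float)
    hu[inside] = (bmd - intercept) / slope
    truth[inside] = bmd

    in_x = (centers[:, 0] >= lo[0]) & (centers[:, 0] <= hi[0])
    rod_masks = []
    for y, dens in zip(rod_ys, rod_densities):
        r2 = (centers[:, 1] - y) ** 2 + (centers[:, 2] - rod_z) ** 2
        m = in_x & (r2 <= rod_radius**2)
        hu[m] = (dens - intercept) / slope
        truth[m] = dens
        core = in_x & (r2 <= (rod_radius - spacing.max()) ** 2)
        rod_masks.append(core)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sigma, hu.shape)

    samples = [
        PhantomSample(
            mean_hu=float(hu[core].mean()),
            known_density=float(dens),
            n_voxels=int(core.sum()),
        )
        for core, dens in zip(rod_masks, rod_densities)
        if core.sum() >= 1
    ]
    hu_vol = vol.with_voxels(hu.reshape(tuple(shape)))
    truth_vol = vol.with_voxels(truth.reshape(tuple(shape)))
    return hu_vol, samples, truth_vol


# ---------------------------------------------------------------------------
# repeated-measures tables
# ---------------------------------------------------------------------------


def make_repeated_dataset(
    n_cells: int = 2000,
    n_knees: int = 10,
    n_repeats: int = 2,
    sigma_between: float = 30.0,
    sigma_error: float = 10.0,
    per_setting_sigmas: dict[str, float] | None = None,
    seed: int = 0,
):
    """Simulate per-cell repeated BMD measurements for one or more
    experimental settings.

    value(cell, knee, repeat) = cell mean + knee effect N(0, sigma_b^2)
    + error N(0, sigma_e^2); knee effects are shared across settings
    (the same knees are measured in every setting).  Returns
    (dict setting -> RepeatedMeasures, dict setting -> ground-truth ICC
    sigma_b^2/(sigma_b^2+sigma_e^2)).
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    if n_cells < 1 or n_knees < 2:
        raise ValueError("need n_cells >= 1 and n_knees >= 2")
    if sigma_between < 0 or sigma_error < 0:
        raise ValueError("variances must be non-negative")
    sigmas = per_setting_sigmas or {"default": sigma_error}
    rng = np.random.default_rng(seed)
    cell_means = rng.uniform(100.0, 400.0, n_cells)
    knee_effects = rng.normal(0.0, sigma_between, (n_cells, n_knees))
    base = cell_means[:, None, None] + knee_effects[:, :, None]

    measures, truth = {}, {}
    for name, sig in sigmas.items():
        noise = rng.normal(0.0, sig, (n_cells, n_knees, n_repeats))
        measures[name] = RepeatedMeasures(values=base + noise)
        denom = sigma_between**2 + sig**2
        truth[name] = sigma_between**2 / denom if denom > 0 else float("nan")
    return measures, truth
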