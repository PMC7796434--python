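"""Phase 1: surface registration of a moving bone onto the reference.

Femur (distal): a cylinder is fitted to the subchondral bone area of
both femurs; the moving femur is (1a) translated/rotated so the cylinder
axes are colinear and the trochlear-notch projections coincide, (1b)
scaled radially so the cylinder radii match and axially per condyle
(notch-to-epicondyle extents), (1c) rotated about the cylinder axis to
minimise the distance between subchondral areas, then (3) locally
deformed by nonrigid ICP with a TPS deformation model.

Tibia (proximal): (1) similarity alignment driven by the medial and
lateral subchondral plateau areas, (2) scaling along the longitudinal
axis anchored at the plateau, then (3) the same nonrigid step.

The result is a :class:`~kneemap.transforms.CompositeWarp` whose final
element is a TPS distilled from the nonrigid surface match, ready to
carry CT voxels in phase 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .geometry import (
    CylinderFit,
    _SurfaceIndex,
    farthest_point_indices,
    fit_cylinder,
)
from .io import AnchorSet, RunConfig, SurfaceMesh, get_logger
from .transforms import (
    AxialRotation,
    CompositeWarp,
    RegionScaling,
    SimilarityTransform,
    fit_tps,
)

__all__ = [
    "femur_align_step1a",
    "femur_scale_step1b",
    "femur_rotate_step1c",
    "tibia_align_step1",
    "tibia_scale_step2",
    "NonRigidICP",
    "nonrigid_icp",
    "register_bone",
    "BoneRegistration",
    "split_plateau_patches",
]

_LOG = get_logger("kneemap.registration")


def _subchondral_submesh(mesh: SurfaceMesh):
    """Faces whose three vertices are all subchondral (the patch surface)."""
    mask = mesh.subchondral_mask
    keep = mask[mesh.faces].all(axis=1)
    if not keep.any():
        raise ValueError("subchondral patch has no faces")
    return mesh.vertices, mesh.faces[keep]


# ---------------------------------------------------------------------------
# femur steps
# ---------------------------------------------------------------------------


def _femur_cylinder(mesh: SurfaceMesh, anchors: AnchorSet) -> CylinderFit:
    anchors.require_femur()
    pts = mesh.subchondral_points()
    orient = anchors.lateral_epicondyle - anchors.medial_epicondyle
    return fit_cylinder(pts, orient=orient)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return -np.eye(3) + 2.0 * np.outer(perp, perp)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def femur_align_step1a(
    moving: SurfaceMesh,
    reference: SurfaceMesh,
    moving_anchors: AnchorSet,
    reference_anchors: AnchorSet,
    fits: tuple[CylinderFit, CylinderFit] | None = None,
) -> SimilarityTransform:
    """Rigid alignment of the condylar cylinder axes (scale fixed to 1).

    After the transform the moving cylinder axis is colinear with the
    reference axis and the trochlear-notch projections onto the common
    axis coincide.
    """
    if fits is None:
        fits = (
            _femur_cylinder(moving, moving_anchors),
            _femur_cylinder(reference, reference_anchors),
        )
    mov_fit, ref_fit = fits
    moving_anchors.require_femur()
    reference_anchors.require_femur()

    def proj(fit: CylinderFit, p: np.ndarray) -> np.ndarray:
        return fit.axis_point + (fit.axial_coordinate(p[None])[0]) * fit.axis_dir

    m_notch = proj(mov_fit, moving_anchors.trochlear_notch)
    r_notch = proj(ref_fit, reference_anchors.trochlear_notch)
    rot = _rotation_between(mov_fit.axis_dir, ref_fit.axis_dir)
    translation = r_notch - rot @ m_notch
    return SimilarityTransform(rotation=rot, translation=translation, scale=1.0)


def femur_scale_step1b(
    moving: SurfaceMesh,
    reference: SurfaceMesh,
    fits: tuple[CylinderFit, CylinderFit],
    anchors: tuple[AnchorSet, AnchorSet],
) -> RegionScaling:
    """Per-condyle scaling after step 1a.

    ``moving``/``fits[0]``/``anchors[0]`` must already be expressed in
    the step-1a-aligned frame (common cylinder axis).  Radial scale
    matches the cylinder radii; each condyle is scaled axially so its
    notch-to-epicondyle extent matches the reference, continuously at
    the notch projection.
    """
    mov_fit, ref_fit = fits
    mov_anchors, ref_anchors = anchors
    mov_anchors.require_femur()
    ref_anchors.require_femur()

    axis_dir = ref_fit.axis_dir
    t_notch = float(ref_fit.axial_coordinate(ref_anchors.trochlear_notch[None])[0])

    def extents(fit_anchors: AnchorSet, notch_t: float):
        t_med = float(ref_fit.axial_coordinate(fit_anchors.medial_epicondyle[None])[0])
        t_lat = float(ref_fit.axial_coordinate(fit_anchors.lateral_epicondyle[None])[0])
        return notch_t - t_med, t_lat - notch_t  # medial extent, lateral extent

    m_notch_t = float(ref_fit.axial_coordinate(mov_anchors.trochlear_notch[None])[0])
    med_m, lat_m = extents(mov_anchors, m_notch_t)
    med_r, lat_r = extents(ref_anchors, t_notch)
    if med_m <= 0 or lat_m <= 0 or med_r <= 0 or lat_r <= 0:
        raise ValueError("non-positive condylar axial extent")

    return RegionScaling(
        axis_point=ref_fit.axis_point,
        axis_dir=axis_dir,
        radial_scale=ref_fit.radius / mov_fit.radius,
        medial_axial_scale=med_r / med_m,
        lateral_axial_scale=lat_r / lat_m,
        boundary_coordinate=t_notch,
    )


def _axial_msd(
    angle_deg: float,
    sub_pts: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    ref_tree: cKDTree,
) -> float:
    rot = AxialRotation(axis_point, axis_dir, angle_deg)
    d, _ = ref_tree.query(rot.apply(sub_pts), k=1)
    return float(np.mean(d**2))


def femur_rotate_step1c(
    moving: SurfaceMesh,
    reference: SurfaceMesh,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    resolution_deg: float = 1.0,
) -> float:
    """Axial rotation (degrees) minimising the mean squared
    nearest-neighbour distance between the moving and reference
    subchondral areas: coarse grid at ``resolution_deg`` refined by
    bounded scalar minimisation; ties broken toward the smallest
    |angle|.

    The distance is point-to-nearest-subchondral-vertex (the standard
    ICP objective): on an exactly cylindrical patch a point-to-facet
    distance is almost rotation-invariant in the patch interior,
    whereas the vertex objective is sharply quadratic at alignment.
    """
    sub_pts = moving.subchondral_points()
    ref_tree = cKDTree(reference.subchondral_points())

    angles = np.arange(-180.0, 180.0, resolution_deg)
    vals = np.array(
        [_axial_msd(a, sub_pts, axis_point, axis_dir, ref_tree) for a in angles]
    )
    best = vals.min()
    near = np.nonzero(vals <= best * (1 + 1e-12) + 1e-18)[0]
    i = near[np.argmin(np.abs(angles[near]))]
    lo, hi = angles[i] - resolution_deg, angles[i] + resolution_deg
    res = minimize_scalar(
        _axial_msd,
        bounds=(lo, hi),
        args=(sub_pts, axis_point, axis_dir, ref_tree),
        method="bounded",
        options={"xatol": 1e-5},
    )
    # a bounded search can stall on facet-scale ripples; keep the better
    # of the refined point and the coarse grid optimum
    if _axial_msd(res.x, sub_pts, axis_point, axis_dir, ref_tree) > vals[i]:
        return float(angles[i])
    return float(res.x)


# ---------------------------------------------------------------------------
# tibia steps
# ---------------------------------------------------------------------------


def split_plateau_patches(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Split the subchondral mask into the medial and lateral plateau
    patches by connected components of the patch submesh.

    Returns (medial_vertex_indices, lateral_vertex_indices); the larger
    patch is taken as medial (the medial plateau is the larger one both
    anatomically and in the synthetic generator).
    """
    mask = mesh.subchondral_mask
    if not mask.any():
        raise ValueError("subchondral_mask selects no vertices")
    sub_idx = np.nonzero(mask)[0]
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[sub_idx] = np.arange(len(sub_idx))
    faces = mesh.faces[mask[mesh.faces].all(axis=1)]
    if len(faces) == 0:
        raise ValueError("subchondral patch has no faces")
    f = remap[faces]
    from scipy.sparse import coo_matrix

    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = len(sub_idx)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp < 2:
        raise ValueError(
            "expected two subchondral plateau patches, found one component"
        )
    sizes = np.bincount(labels)
    order = np.argsort(sizes)[::-1]
    med, lat = order[0], order[1]
    return sub_idx[labels == med], sub_idx[labels == lat]


def _plateau_frame(mesh: SurfaceMesh):
    """Deterministic orthonormal frame + descriptors of the two plateau
    patches: (combined centroid, RMS spread, 3x3 frame columns)."""
    med_idx, lat_idx = split_plateau_patches(mesh)
    c_med = mesh.vertices[med_idx].mean(axis=0)
    c_lat = mesh.vertices[lat_idx].mean(axis=0)
    both = np.concatenate([med_idx, lat_idx])
    pts = mesh.vertices[both]
    c = pts.mean(axis=0)
    spread = float(np.sqrt(np.mean(((pts - c) ** 2).sum(axis=1))))
    if spread <= 0:
        raise ValueError("degenerate plateau geometry (zero spread)")
    # patch normal = smallest principal axis, oriented away from the bone body
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    normal = vt[2]
    outward = c - mesh.vertices.mean(axis=0)
    if np.dot(normal, outward) < 0:
        normal = -normal
    e1 = c_lat - c_med
    e1 = e1 - np.dot(e1, normal) * normal
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        raise ValueError("plateau patch centroids are degenerate")
    e1 /= n1
    e2 = np.cross(normal, e1)
    frame = np.column_stack([e1, e2, normal])
    return c, spread, frame


def tibia_align_step1(
    moving: SurfaceMesh, reference: SurfaceMesh
) -> SimilarityTransform:
    """Similarity alignment (translation + rotation + isotropic scale)
    based on the medial and lateral subchondral plateau areas.

    Correspondence-free: each bone contributes a deterministic frame
    (medial-to-lateral direction, plateau normal) plus centroid and RMS
    spread; the transform maps the moving descriptors onto the
    reference's.  Exact for similarity-related noise-free inputs.
    """
    c_m, s_m, f_m = _plateau_frame(moving)
    c_r, s_r, f_r = _plateau_frame(reference)
    rot = f_r @ f_m.T
    # numerical clean-up to a proper rotation
    u, _, vt = np.linalg.svd(rot)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    scale = s_r / s_m
    translation = c_r - scale * (rot @ c_m)
    return SimilarityTransform(rotation=rot, translation=translation, scale=scale)


def tibia_scale_step2(
    moving: SurfaceMesh,
    reference: SurfaceMesh,
    longitudinal_axis: np.ndarray,
) -> RegionScaling:
    """Scale the moving tibia along the longitudinal axis so its
    proximal-segment extent matches the reference, anchored at the
    subchondral plateau so the plateau does not move.

    ``moving`` must already be step-1 aligned; ``longitudinal_axis`` is
    the reference tibia's unit axis (pointing proximally).
    """
    axis = np.asarray(longitudinal_axis, float)
    axis = axis / np.linalg.norm(axis)

    def extent(mesh: SurfaceMesh) -> float:
        t = mesh.vertices @ axis
        return float(t.max() - t.min())

    ext_m, ext_r = extent(moving), extent(reference)
    if ext_m <= 0 or ext_r <= 0:
        raise ValueError("zero axial extent")
    anchor = moving.subchondral_points().mean(axis=0)
    scale = ext_r / ext_m
    return RegionScaling(
        axis_point=anchor,
        axis_dir=axis,
        radial_scale=1.0,
        medial_axial_scale=scale,
        lateral_axial_scale=scale,
        boundary_coordinate=0.0,
    )


# ---------------------------------------------------------------------------
# nonrigid ICP
# ---------------------------------------------------------------------------


class NonRigidICP(BaseEstimator):
    """Nonrigid ICP with a TPS deformation model.

    Alternates (i) closest-point correspondences from the moving
    vertices to the reference surface (exact point-to-triangle
    projection) with (ii) a TPS update fitted on a fixed farthest-point
    control subset, over a decreasing stiffness (regularization)
    schedule.  An update that would increase the mean surface distance
    is rejected and the schedule advances, so the accepted distance
    sequence is non-increasing.

    Attributes (after ``fit``)
    --------------------------
    deformed_vertices_ : (n, 3) final moving vertex positions
    correspondences_ : (n, 3) closest reference-surface point per vertex
    mean_distance_ : final mean surface-to-surface distance (mm)
    history_ : accepted mean distances, one per accepted iteration
    converged_ : whether the displacement tolerance was reached
    """

    def __init__(
        self,
        stiffness_schedule: tuple = (100.0, 10.0, 1.0, 0.1),
        iterations_per_level: int = 5,
        n_control: int = 500,
        displacement_tol: float = 1e-3,
        seed: int = 0,
    ):
        self.stiffness_schedule = stiffness_schedule
        self.iterations_per_level = iterations_per_level
        self.n_control = n_control
        self.displacement_tol = displacement_tol
        self.seed = seed

    def fit(self, moving: SurfaceMesh, reference: SurfaceMesh) -> "NonRigidICP":
        if len(moving.vertices) == 0 or len(moving.faces) == 0:
            raise ValueError("moving mesh is empty")
        if len(reference.faces) == 0:
            raise ValueError("reference mesh has zero faces")
        ref_index = _SurfaceIndex(reference.vertices, reference.faces)
        verts = moving.vertices.copy()
        control = farthest_point_indices(verts, self.n_control, seed=self.seed)

        closest, dist = ref_index.closest(verts)
        mean_dist = float(dist.mean())
        self.history_ = [mean_dist]
        self.converged_ = False

        for lam in self.stiffness_schedule:
            for _ in range(self.iterations_per_level):
                warp = fit_tps(verts[control], closest[control], regularization=lam)
                cand = warp.apply(verts)
                cand_closest, cand_dist = ref_index.closest(cand)
                cand_mean = float(cand_dist.mean())
                displacement = float(np.linalg.norm(cand - verts, axis=1).mean())
                if cand_mean > mean_dist + 1e-12:
                    # reject; if the update is no longer moving anything
                    # we are at a fixed point, otherwise try the next
                    # stiffness level
                    if displacement < self.displacement_tol:
                        self.converged_ = True
                    break
                verts, closest, mean_dist = cand, cand_closest, cand_mean
                self.history_.append(mean_dist)
                if displacement < self.displacement_tol:
                    self.converged_ = True
                    break
            if self.converged_:
                break

        self.deformed_vertices_ = verts
        self.correspondences_ = closest
        self.mean_distance_ = mean_dist
        _LOG.info(
            "nonrigid ICP: mean surface distance %.4f mm after %d accepted "
            "iterations (converged=%s)",
            mean_dist,
            len(self.history_) - 1,
            self.converged_,
        )
        return self


def nonrigid_icp(
    moving: SurfaceMesh, reference: SurfaceMesh, config: RunConfig | None = None
):
    """Functional wrapper: returns (correspondences, deformed mesh,
    fitted NonRigidICP estimator)."""
    config = config or RunConfig()
    est = NonRigidICP(
        stiffness_schedule=config.icp_stiffness_schedule,
        iterations_per_level=config.icp_iterations_per_level,
        n_control=config.icp_control_points,
        displacement_tol=config.displacement_tol,
        seed=config.seed,
    ).fit(moving, reference)
    return est.correspondences_, moving.with_vertices(est.deformed_vertices_), est


# ---------------------------------------------------------------------------
# full phase-1 chain
# ---------------------------------------------------------------------------


def _transform_anchors(anchors: AnchorSet, transform) -> AnchorSet:
    kw = {}
    for name in ("trochlear_notch", "medial_epicondyle", "lateral_epicondyle"):
        v = getattr(anchors, name)
        if v is not None:
            kw[name] = transform.apply(v[None])[0]
    if anchors.longitudinal_axis is not None:
        a = anchors.longitudinal_axis
        if hasattr(transform, "rotation"):
            a = transform.rotation @ a
        kw["longitudinal_axis"] = a
    return AnchorSet(**kw)


@dataclass
class RegistrationReport:
    """Per-step residuals logged during register_bone."""

    steps: list = field(default_factory=list)

    def add(self, name: str, residual: float) -> None:
        self.steps.append((name, float(residual)))
        _LOG.info("step %-12s residual %.4f mm", name, residual)


def register_bone(
    moving: SurfaceMesh,
    reference: SurfaceMesh,
    moving_anchors: AnchorSet | None = None,
    reference_anchors: AnchorSet | None = None,
    config: RunConfig | None = None,
) -> CompositeWarp:
    """Register a moving bone surface to the reference bone surface and
    return the composite moving-to-reference warp (femur: steps 1a, 1b,
    1c, 3; tibia: steps 1, 2, 3).  The nonrigid step is distilled into a
    TPS on a farthest-point control subset so the chain can be applied
    to arbitrary points in phase 2.
    """
    est = BoneRegistration(config=config).fit(
        moving, reference, moving_anchors, reference_anchors
    )
    return est.warp_


class BoneRegistration(BaseEstimator):
    """Estimator form of the full phase-1 registration.

    ``fit(moving, reference, moving_anchors, reference_anchors)``
    computes the chain; ``transform(points)`` maps moving-space points
    (e.g. CT voxel centers) into reference space.

    Attributes
    ----------
    warp_ : CompositeWarp
    report_ : RegistrationReport with per-step residuals
    final_rms_ : RMS surface distance of the registered surface (mm)
    """

    def __init__(self, config: RunConfig | None = None):
        self.config = config

    def fit(
        self,
        moving: SurfaceMesh,
        reference: SurfaceMesh,
        moving_anchors: AnchorSet | None = None,
        reference_anchors: AnchorSet | None = None,
    ) -> "BoneRegistration":
        if moving.bone != reference.bone:
            raise ValueError(
                f"bone mismatch: moving is {moving.bone}, reference is "
                f"{reference.bone}"
            )
        cfg = self.config or RunConfig()
        report = RegistrationReport()
        chain: list = []
        current = moving
        cur_anchors = moving_anchors

        if moving.bone == "femur":
            if moving_anchors is None or reference_anchors is None:
                raise ValueError("femur registration requires anchor sets")
            mov_fit = _femur_cylinder(moving, moving_anchors)
            ref_fit = _femur_cylinder(reference, reference_anchors)
            t1a = femur_align_step1a(
                moving, reference, moving_anchors, reference_anchors,
                fits=(mov_fit, ref_fit),
            )
            chain.append(t1a)
            current = current.with_vertices(t1a.apply(current.vertices))
            cur_anchors = _transform_anchors(moving_anchors, t1a)
            # moving cylinder in the aligned frame
            mov_fit_aligned = CylinderFit(
                axis_point=t1a.apply(mov_fit.axis_point[None])[0],
                axis_dir=t1a.rotation @ mov_fit.axis_dir,
                radius=mov_fit.radius,
                rms_residual=mov_fit.rms_residual,
            )
            report.add("femur_1a", _mean_subchondral_distance(current, reference))

            t1b = femur_scale_step1b(
                current, reference,
                fits=(mov_fit_aligned, ref_fit),
                anchors=(cur_anchors, reference_anchors),
            )
            chain.append(t1b)
            current = current.with_vertices(t1b.apply(current.vertices))
            cur_anchors = _transform_anchors(cur_anchors, t1b)
            report.add("femur_1b", _mean_subchondral_distance(current, reference))

            angle = femur_rotate_step1c(
                current, reference,
                axis_point=ref_fit.axis_point,
                axis_dir=ref_fit.axis_dir,
                resolution_deg=cfg.rotation_search_resolution,
            )
            t1c = AxialRotation(ref_fit.axis_point, ref_fit.axis_dir, angle)
            chain.append(t1c)
            current = current.with_vertices(t1c.apply(current.vertices))
            report.add("femur_1c", _mean_subchondral_distance(current, reference))
        else:
            t1 = tibia_align_step1(moving, reference)
            chain.append(t1)
            current = current.with_vertices(t1.apply(current.vertices))
            if cur_anchors is not None:
                cur_anchors = _transform_anchors(cur_anchors, t1)
            report.add("tibia_1", _mean_subchondral_distance(current, reference))

            if reference_anchors is None or reference_anchors.longitudinal_axis is None:
                raise ValueError("tibia registration requires the reference "
                                 "longitudinal axis anchor")
            t2 = tibia_scale_step2(
                current, reference, reference_anchors.longitudinal_axis
            )
            chain.append(t2)
            current = current.with_vertices(t2.apply(current.vertices))
            report.add("tibia_2", _mean_subchondral_distance(current, reference))

        pre_icp = current.vertices.copy()
        _, deformed, icp = nonrigid_icp(current, reference, cfg)

        control = farthest_point_indices(
            pre_icp, cfg.distill_control_points, seed=cfg.seed
        )
        tps = fit_tps(
            pre_icp[control],
            deformed.vertices[control],
            regularization=cfg.tps_regularization,
        )
        chain.append(tps)
        report.add("nonrigid_3", icp.mean_distance_)

        warped = CompositeWarp(chain=chain)
        final = warped.apply(moving.vertices)
        from .geometry import surface_distances

        d = surface_distances(final, reference.vertices, reference.faces)
        self.final_rms_ = float(np.sqrt(np.mean(d**2)))
        report.add("final_rms", self.final_rms_)
        self.warp_ = warped
        self.report_ = report
        self.icp_ = icp
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        if not hasattr(self, "warp_"):
            raise AttributeError("BoneRegistration is not fitted")
        return self.warp_.apply(points)


def _mean_subchondral_distance(moving: SurfaceMesh, reference: SurfaceMesh) -> float:
    from .geometry import surface_distances

    v, f = _subchondral_submesh(reference)
    return float(np.mean(surface_distances(moving.subchondral_points(), v, f)))
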