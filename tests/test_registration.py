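"""Global registration steps: femur 1a/1b/1c and tibia 1/2."""

import numpy as np
import pytest

from kneemap import (
    AnchorSet,
    SurfaceMesh,
    SyntheticBoneSpec,
    fit_cylinder,
    make_bone_mesh,
)
from kneemap.registration import (
    femur_align_step1a,
    femur_rotate_step1c,
    femur_scale_step1b,
    split_plateau_patches,
    tibia_align_step1,
    tibia_scale_step2,
)
from kneemap.synthetic import DeformationSpec, apply_deformation
from kneemap.transforms import AxialRotation, SimilarityTransform


def _umeyama(src, dst):
    """Closed-form similarity (Procrustes/Umeyama) oracle on
    corresponding points."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    u, s, vt = np.linalg.svd(cov)
    sgn = np.eye(3)
    if np.linalg.det(u @ vt) < 0:
        sgn[2, 2] = -1
    rot = u @ sgn @ vt
    var = (sc**2).sum() / len(src)
    scale = np.trace(np.diag(s) @ sgn) / var
    t = mu_d - scale * rot @ mu_s
    return rot, scale, t


# ---------------------------------------------------------------------------
# femur
# ---------------------------------------------------------------------------


class TestFemurStep1a:
    def test_pure_translation_inverted(self, femur):
        mesh, anchors = femur
        shift = np.array([10.0, -5.0, 3.0])
        moved = mesh.with_vertices(mesh.vertices + shift)
        moved_anchors = AnchorSet(
            trochlear_notch=anchors.trochlear_notch + shift,
            medial_epicondyle=anchors.medial_epicondyle + shift,
            lateral_epicondyle=anchors.lateral_epicondyle + shift,
        )
        t = femur_align_step1a(moved, mesh, moved_anchors, anchors)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(t.translation, -shift, atol=1e-6)

    def test_transverse_rotation_postconditions(self, femur):
        mesh, anchors = femur
        rot = AxialRotation(np.zeros(3), np.array([0.0, 1.0, 0.0]), 15.0)
        moved = mesh.with_vertices(rot.apply(mesh.vertices))
        moved_anchors = AnchorSet(
            trochlear_notch=rot.apply(anchors.trochlear_notch[None])[0],
            medial_epicondyle=rot.apply(anchors.medial_epicondyle[None])[0],
            lateral_epicondyle=rot.apply(anchors.lateral_epicondyle[None])[0],
        )
        t = femur_align_step1a(moved, mesh, moved_anchors, anchors)
        # verify the post-conditions numerically, not the matrix
        back = moved.with_vertices(t.apply(moved.vertices))
        fit_m = fit_cylinder(back.subchondral_points())
        fit_r = fit_cylinder(mesh.subchondral_points())
        cos = abs(np.dot(fit_m.axis_dir, fit_r.axis_dir))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-5
        notch_m = t.apply(moved_anchors.trochlear_notch[None])[0]
        tm = fit_r.axial_coordinate(notch_m[None])[0]
        tr = fit_r.axial_coordinate(anchors.trochlear_notch[None])[0]
        assert abs(tm - tr) < 1e-4

    def test_missing_notch_rejected(self, femur):
        mesh, anchors = femur
        bad = AnchorSet(
            medial_epicondyle=anchors.medial_epicondyle,
            lateral_epicondyle=anchors.lateral_epicondyle,
        )
        with pytest.raises(ValueError, match="trochlear_notch"):
            femur_align_step1a(mesh, mesh, bad, anchors)


class TestFemurStep1b:
    def _fits_and_anchors(self, mesh, anchors):
        fit = fit_cylinder(
            mesh.subchondral_points(),
            orient=anchors.lateral_epicondyle - anchors.medial_epicondyle,
        )
        return fit, anchors

    def test_radial_and_axial_ratios(self, femur):
        mesh, anchors = femur
        fit, _ = self._fits_and_anchors(mesh, anchors)
        # pretend the moving bone has radius 25 and 30 mm medial extent
        mov_fit = fit.__class__(fit.axis_point, fit.axis_dir, 25.0, 0.0)
        scaling = femur_scale_step1b(
            mesh, mesh, fits=(mov_fit, fit.__class__(fit.axis_point, fit.axis_dir, 20.0, 0.0)),
            anchors=(anchors, anchors),
        )
        assert scaling.radial_scale == pytest.approx(0.8)
        assert scaling.medial_axial_scale == pytest.approx(1.0)
        assert scaling.lateral_axial_scale == pytest.approx(1.0)

    def test_uniform_magnification_recovered(self, femur):
        mesh, anchors = femur
        k = 1.2
        mag = SimilarityTransform(scale=k)
        moved = mesh.with_vertices(mag.apply(mesh.vertices))
        moved_anchors = AnchorSet(
            trochlear_notch=mag.apply(anchors.trochlear_notch[None])[0],
            medial_epicondyle=mag.apply(anchors.medial_epicondyle[None])[0],
            lateral_epicondyle=mag.apply(anchors.lateral_epicondyle[None])[0],
        )
        t1a = femur_align_step1a(moved, mesh, moved_anchors, anchors)
        aligned = moved.with_vertices(t1a.apply(moved.vertices))
        al_anchors = AnchorSet(
            trochlear_notch=t1a.apply(moved_anchors.trochlear_notch[None])[0],
            medial_epicondyle=t1a.apply(moved_anchors.medial_epicondyle[None])[0],
            lateral_epicondyle=t1a.apply(moved_anchors.lateral_epicondyle[None])[0],
        )
        fit_r = fit_cylinder(
            mesh.subchondral_points(),
            orient=anchors.lateral_epicondyle - anchors.medial_epicondyle,
        )
        fit_m = fit_cylinder(
            aligned.subchondral_points(),
            orient=al_anchors.lateral_epicondyle - al_anchors.medial_epicondyle,
        )
        scaling = femur_scale_step1b(
            aligned, mesh, fits=(fit_m, fit_r), anchors=(al_anchors, anchors)
        )
        assert scaling.radial_scale == pytest.approx(1 / k, rel=1e-6)
        assert scaling.medial_axial_scale == pytest.approx(1 / k, rel=1e-6)
        assert scaling.lateral_axial_scale == pytest.approx(1 / k, rel=1e-6)
        # applying the scaling superimposes the subchondral patches
        back = scaling.apply(aligned.subchondral_points())
        d = np.linalg.norm(back - mesh.subchondral_points(), axis=1)
        assert np.sqrt((d**2).mean()) < 0.01

    def test_zero_extent_rejected(self, femur):
        mesh, anchors = femur
        fit = fit_cylinder(
            mesh.subchondral_points(),
            orient=anchors.lateral_epicondyle - anchors.medial_epicondyle,
        )
        bad = AnchorSet(
            trochlear_notch=anchors.medial_epicondyle,  # notch on the epicondyle
            medial_epicondyle=anchors.medial_epicondyle,
            lateral_epicondyle=anchors.lateral_epicondyle,
        )
        with pytest.raises(ValueError, match="extent"):
            femur_scale_step1b(mesh, mesh, fits=(fit, fit), anchors=(bad, anchors))


class TestFemurStep1c:
    AXIS_P = np.zeros(3)
    AXIS_D = np.array([1.0, 0.0, 0.0])

    def test_self_alignment_is_zero(self, femur):
        mesh, _ = femur
        ang = femur_rotate_step1c(mesh, mesh, self.AXIS_P, self.AXIS_D)
        assert abs(ang) < 1e-3

    def test_known_rotation_recovered_vs_brute_force(self, femur):
        from kneemap.registration import _axial_msd
        from scipy.spatial import cKDTree

        mesh, _ = femur
        rot = AxialRotation(self.AXIS_P, self.AXIS_D, 10.0)
        moved = mesh.with_vertices(rot.apply(mesh.vertices))
        ang = femur_rotate_step1c(moved, mesh, self.AXIS_P, self.AXIS_D,
                                  resolution_deg=1.0)
        assert ang == pytest.approx(-10.0, abs=0.05)
        # brute-force 0.01 degree sweep oracle around the optimum
        tree = cKDTree(mesh.subchondral_points())
        sweep = np.arange(-11.5, -8.5, 0.01)
        vals = [
            _axial_msd(a, moved.subchondral_points(), self.AXIS_P, self.AXIS_D, tree)
            for a in sweep
        ]
        assert ang == pytest.approx(sweep[int(np.argmin(vals))], abs=0.05)

    def test_empty_subchondral_rejected(self, femur):
        mesh, _ = femur
        bare = SurfaceMesh(
            mesh.vertices, mesh.faces, np.zeros(len(mesh.vertices), bool), "femur"
        )
        with pytest.raises(ValueError):
            femur_rotate_step1c(bare, mesh, self.AXIS_P, self.AXIS_D)


# ---------------------------------------------------------------------------
# tibia
# ---------------------------------------------------------------------------


class TestTibiaStep1:
    def test_self_registration_is_identity(self, tibia):
        mesh, _ = tibia
        t = tibia_align_step1(mesh, mesh)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(t.translation).max() < 1e-9
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        sub = mesh.subchondral_points()
        assert np.abs(t.apply(sub).mean(0) - sub.mean(0)).max() < 1e-6

    def test_known_similarity_recovered_vs_procrustes_oracle(self, tibia):
        mesh, anchors = tibia
        spec = DeformationSpec(
            scale=1.2, rotation_deg=(0.0, 0.0, 20.0), translation=(5.0, 5.0, 0.0),
            amplitude=0.0,
        )
        moved, _, _ = apply_deformation(mesh, spec, anchors)
        t = tibia_align_step1(moved, mesh)
        rot_o, scale_o, tr_o = _umeyama(moved.vertices, mesh.vertices)
        ang = np.rad2deg(
            np.arccos(np.clip((np.trace(t.rotation @ rot_o.T) - 1) / 2, -1, 1))
        )
        assert ang < 0.5
        assert t.scale == pytest.approx(scale_o, rel=0.01)
        assert np.abs(t.translation - tr_o).max() < 0.1

    def test_missing_mask_rejected(self, tibia):
        mesh, _ = tibia
        bare = SurfaceMesh(
            mesh.vertices, mesh.faces, np.zeros(len(mesh.vertices), bool), "tibia"
        )
        with pytest.raises(ValueError):
            tibia_align_step1(bare, mesh)

    def test_plateau_split_gives_two_patches(self, tibia):
        mesh, _ = tibia
        med, lat = split_plateau_patches(mesh)
        assert len(med) > len(lat) > 0
        # medial patch lies on the negative-x side in the generator
        assert mesh.vertices[med, 0].mean() < mesh.vertices[lat, 0].mean()


class TestTibiaStep2:
    def test_extent_ratio(self, tibia):
        mesh, anchors = tibia
        stretched = mesh.with_vertices(
            mesh.vertices * np.array([1.0, 1.0, 60.0 / 45.0])
        )
        scaling = tibia_scale_step2(stretched, mesh, anchors.longitudinal_axis)
        assert scaling.medial_axial_scale == pytest.approx(45.0 / 60.0, rel=1e-9)

    def test_identity_for_same_mesh(self, tibia):
        mesh, anchors = tibia
        scaling = tibia_scale_step2(mesh, mesh, anchors.longitudinal_axis)
        assert scaling.medial_axial_scale == pytest.approx(1.0)
        assert np.abs(scaling.apply(mesh.vertices) - mesh.vertices).max() < 1e-9

    def test_axial_stretch_recovered_and_plateau_fixed(self, tibia):
        mesh, anchors = tibia
        k = 1.3
        axis = anchors.longitudinal_axis
        anchor_t = (mesh.subchondral_points().mean(0) @ axis)
        t = mesh.vertices @ axis
        stretched_v = mesh.vertices + np.outer((t - anchor_t) * (k - 1), axis)
        stretched = mesh.with_vertices(stretched_v)
        scaling = tibia_scale_step2(stretched, mesh, axis)
        assert scaling.medial_axial_scale == pytest.approx(1 / k, rel=0.01)
        back = scaling.apply(stretched.subchondral_points())
        # the plateau is anchored: subchondral points barely move
        d = np.linalg.norm(back - stretched.subchondral_points(), axis=1)
        assert d.mean() < 0.5
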