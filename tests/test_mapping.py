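"""Phase 2: interior voxel extraction, warping, cell grid, aggregation."""

import numpy as np
import pytest

from kneemap import (
    BmdPointCloud,
    CtVolume,
    SurfaceMesh,
    aggregate_bmd,
    build_cell_grid,
    extract_bone_voxels,
    fit_tps,
    warp_points,
)
from kneemap.transforms import CompositeWarp, SimilarityTransform


def _cube_surface(half=10.0):
    v = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        float,
    ) * half
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
            [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
            [1, 2, 6], [1, 6, 5], [0, 4, 7], [0, 7, 3],
        ]
    )
    mask = np.ones(8, bool)
    return SurfaceMesh(v, f, mask, bone="femur")


class TestExtractBoneVoxels:
    def test_cube_count_matches_brute_force(self):
        cube = _cube_surface(10.0)  # [-10, 10]^3
        vol = CtVolume(
            voxels=np.ones((30, 30, 30)), spacing=(1, 1, 1),
            origin=(-14.5, -14.5, -14.5),
        )
        cloud = extract_bone_voxels(vol, cube)
        centers = vol.voxel_centers()
        oracle = np.all(np.abs(centers) < 10.0, axis=1)
        assert len(cloud) == oracle.sum() == 20**3

    def test_mesh_outside_volume_gives_empty_cloud(self):
        cube = _cube_surface(5.0)
        far = cube.with_vertices(cube.vertices + 1000.0)
        vol = CtVolume(np.ones((10, 10, 10)), (1, 1, 1), (0, 0, 0))
        assert len(extract_bone_voxels(vol, far)) == 0

    def test_open_mesh_rejected(self):
        cube = _cube_surface(5.0)
        open_mesh = SurfaceMesh(
            cube.vertices, cube.faces[:-1], cube.subchondral_mask, "femur"
        )
        vol = CtVolume(np.ones((5, 5, 5)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="watertight"):
            extract_bone_voxels(vol, open_mesh)


class TestWarpPoints:
    def test_identity_chain(self, rng):
        cloud = BmdPointCloud(rng.normal(size=(50, 3)), rng.uniform(0, 400, 50))
        out = warp_points(cloud, CompositeWarp(chain=[]))
        assert np.array_equal(out.points, cloud.points)
        assert np.array_equal(out.values, cloud.values)

    def test_pure_translation(self, rng):
        cloud = BmdPointCloud(rng.normal(size=(50, 3)), rng.uniform(0, 400, 50))
        t = SimilarityTransform(translation=[3.0, 0.0, 0.0])
        out = warp_points(cloud, CompositeWarp(chain=[t]))
        assert np.allclose(out.points - cloud.points, [3.0, 0.0, 0.0])
        assert np.array_equal(out.values, cloud.values)

    def test_chain_matches_sequential_oracle(self, rng):
        sim = SimilarityTransform(
            rotation=np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float),
            translation=[1.0, 2.0, 3.0],
            scale=1.1,
        )
        src = rng.uniform(-20, 20, (12, 3))
        tps = fit_tps(src, src + rng.normal(0, 1, (12, 3)))
        chain = CompositeWarp(chain=[sim, tps])
        cloud = BmdPointCloud(rng.uniform(-20, 20, (200, 3)), rng.uniform(0, 400, 200))
        out = warp_points(cloud, chain)
        # independent per-point sequential evaluation
        expected = np.array([tps.apply(sim.apply(p[None]))[0] for p in cloud.points])
        assert np.abs(out.points - expected).max() < 1e-9


class TestCellGrid:
    def test_cube_cell_count_analytic(self):
        cube = _cube_surface(10.0)
        grid = build_cell_grid(cube, 2.0)
        assert grid.shape == (10, 10, 10)
        assert grid.n_interior == 1000

    def test_sphere_interior_matches_brute_force(self):
        import trimesh

        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = SurfaceMesh(
            np.asarray(sph.vertices), np.asarray(sph.faces),
            np.ones(len(sph.vertices), bool), "femur",
        )
        grid = build_cell_grid(mesh, 2.0)
        from kneemap import points_in_mesh

        oracle = points_in_mesh(grid.cell_centers(), mesh.vertices, mesh.faces)
        assert np.array_equal(grid.interior_mask.reshape(-1), oracle)

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ValueError, match="cell_size"):
            build_cell_grid(_cube_surface(), 0.0)

    def test_grid_is_deterministic(self):
        cube = _cube_surface(10.0)
        g1 = build_cell_grid(cube, 2.0)
        g2 = build_cell_grid(cube, 2.0)
        assert g1.compatible_with(g2)
        assert np.array_equal(g1.origin, cube.vertices.min(axis=0))


class TestAggregateBmd:
    def test_constant_field(self, rng):
        cube = _cube_surface(10.0)
        grid = build_cell_grid(cube, 2.0)
        pts = rng.uniform(-9.9, 9.9, (5000, 3))
        out = aggregate_bmd(BmdPointCloud(pts, np.full(5000, 100.0)), grid)
        occ = out.count > 0
        assert np.allclose(out.mean[occ], 100.0)

    def test_mean_of_two(self):
        cube = _cube_surface(10.0)
        grid = build_cell_grid(cube, 2.0)
        pts = np.array([[-9.5, -9.5, -9.5], [-9.1, -9.1, -9.1]])
        out = aggregate_bmd(BmdPointCloud(pts, np.array([80.0, 120.0])), grid)
        assert out.mean[0, 0, 0] == pytest.approx(100.0)
        assert out.count[0, 0, 0] == 2

    def test_random_cloud_matches_binning_oracle(self, rng):
        cube = _cube_surface(10.0)
        grid = build_cell_grid(cube, 2.0)
        pts = rng.uniform(-14, 14, (3000, 3))
        vals = rng.uniform(0, 400, 3000)
        out = aggregate_bmd(BmdPointCloud(pts, vals), grid)
        # brute-force bin-then-average oracle
        oracle_sum = np.zeros(grid.shape)
        oracle_cnt = np.zeros(grid.shape, int)
        n_out = 0
        for p, v in zip(pts, vals):
            idx = tuple(np.floor((p - grid.origin) / grid.cell_size).astype(int))
            if all(0 <= i < s for i, s in zip(idx, grid.shape)) and grid.interior_mask[idx]:
                oracle_sum[idx] += v
                oracle_cnt[idx] += 1
            else:
                n_out += 1
        assert np.array_equal(out.count, oracle_cnt)
        occ = oracle_cnt > 0
        assert np.abs(out.mean[occ] - oracle_sum[occ] / oracle_cnt[occ]).max() < 1e-9
        assert out.n_outside == n_out

    def test_conservation_property(self, rng):
        """Per-cell counts + outside count equals the number of
        registered voxels, for arbitrary clouds."""
        cube = _cube_surface(10.0)
        grid = build_cell_grid(cube, 2.0)
        for n in (0, 1, 777, 4321):
            pts = rng.uniform(-25, 25, (n, 3))
            out = aggregate_bmd(BmdPointCloud(pts, np.ones(n)), grid)
            assert int(out.count.sum()) + out.n_outside == n

    def test_self_mapping_identity(self, femur):
        """Identity warp then aggregation equals direct aggregation."""
        mesh, _ = femur
        grid = build_cell_grid(mesh, 4.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(mesh.vertices.min(0), mesh.vertices.max(0), (2000, 3))
        cloud = BmdPointCloud(pts, rng.uniform(0, 400, 2000))
        direct = aggregate_bmd(cloud, grid)
        warped = aggregate_bmd(warp_points(cloud, CompositeWarp(chain=[])), grid)
        assert np.array_equal(direct.count, warped.count)
        occ = direct.count > 0
        assert np.array_equal(direct.mean[occ], warped.mean[occ])
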