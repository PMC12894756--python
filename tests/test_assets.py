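"""Grids, isosurfaces, label surfaces, mesh files and the scene manifest."""

import math
import os

import numpy as np
import pytest

import voxelbridge as vb


def ball_volume(shape=32, radius=10.0):
    c = (shape - 1) / 2.0
    zz, yy, xx = np.meshgrid(*([np.arange(shape)] * 3), indexing="ij")
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(
        np.float32
    )


class TestVolumeGrid:
    def test_uint8_becomes_float32_with_equal_values(self, tmp_path, unit_transform):
        vol = np.arange(4 * 4 * 4, dtype=np.uint8).reshape(4, 4, 4)
        path = tmp_path / "g.vxgrid"
        vb.export_volume_grid(vol, unit_transform, path)
        grid = vb.read_volume_grid(path)
        assert grid.values.dtype == np.float32
        assert np.array_equal(grid.values, vol.astype(np.float32))

    def test_random_float32_round_trip_bit_identical(self, tmp_path, unit_transform):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(20, 17, 33)).astype(np.float32)
        path = tmp_path / "g.vxgrid"
        vb.export_volume_grid(vol, unit_transform, path)
        grid = vb.read_volume_grid(path)
        assert np.array_equal(
            grid.values.view(np.uint32), vol.view(np.uint32)
        )  # byte identical
        assert grid.transform == unit_transform

    def test_all_zero_volume_stores_no_bricks(self, tmp_path, unit_transform):
        path = tmp_path / "z.vxgrid"
        grid = vb.export_volume_grid(np.zeros((32, 32, 32)), unit_transform, path)
        assert grid.n_stored_bricks == 0
        assert os.path.getsize(path) < 1024  # header only
        assert np.array_equal(vb.read_volume_grid(path).values, np.zeros((32, 32, 32)))

    def test_sparsity_bound(self, tmp_path, unit_transform):
        vol = np.zeros((33, 16, 16), np.float32)
        vol[0, 0, 0] = 5.0  # one touched brick
        grid = vb.export_volume_grid(vol, unit_transform, tmp_path / "s.vxgrid")
        max_bricks = 3 * 1 * 1  # ceil(33/16) * 1 * 1
        assert 1 == grid.n_stored_bricks <= max_bricks
        dense = vb.export_volume_grid(
            np.ones((33, 16, 16)), unit_transform, tmp_path / "d.vxgrid"
        )
        assert dense.n_stored_bricks == max_bricks

    def test_nonzero_background_elision(self, tmp_path, unit_transform):
        vol = np.full((16, 16, 16), 7.0, np.float32)
        grid = vb.export_volume_grid(
            vol, unit_transform, tmp_path / "b.vxgrid", background=7.0
        )
        assert grid.n_stored_bricks == 0

    def test_vdb_container_requires_codec(self, tmp_path, unit_transform):
        with pytest.raises(vb.FeatureUnavailableError):
            vb.export_volume_grid(
                np.ones((4, 4, 4)), unit_transform, tmp_path / "x", container="vdb"
            )

    def test_non_finite_rejected(self, tmp_path, unit_transform):
        vol = np.ones((4, 4, 4))
        vol[0, 0, 0] = np.nan
        with pytest.raises(vb.ValidationError):
            vb.export_volume_grid(vol, unit_transform, tmp_path / "n.vxgrid")


class TestIsosurface:
    def test_ball_vertices_at_radius(self, unit_transform):
        vol = ball_volume(32, 10.0)
        mesh = vb.extract_isosurface(vol, 0.5, unit_transform)
        center = unit_transform.voxel_to_world((15.5, 15.5, 15.5))
        dist = np.linalg.norm(mesh.vertices - center, axis=1) / 0.01  # voxels
        assert len(mesh.vertices) > 0
        assert dist.min() > 9.0 and dist.max() < 11.0

    def test_ball_volume_within_five_percent(self, unit_transform):
        mesh = vb.extract_isosurface(ball_volume(32, 10.0), 0.5, unit_transform)
        expected = 4.0 / 3.0 * math.pi * (10.0 * 0.01) ** 3
        assert mesh.enclosed_volume() == pytest.approx(expected, rel=0.05)
        assert mesh.is_watertight

    def test_threshold_outside_range_empty_mesh(self, unit_transform):
        vol = np.full((8, 8, 8), 3.0, np.float32)
        assert vb.extract_isosurface(vol, 10.0, unit_transform).is_empty

    def test_all_above_threshold_closed_box_at_padding(self, unit_transform):
        vol = np.full((8, 8, 8), 10.0, np.float32)
        mesh = vb.extract_isosurface(vol, 5.0, unit_transform)
        assert not mesh.is_empty and mesh.is_watertight
        # the surface hugs the padded boundary: enclosed volume ~ whole box
        assert mesh.enclosed_volume() == pytest.approx(0.08**3, rel=0.3)

    def test_vertex_count_iff_threshold_strictly_inside(self, unit_transform):
        vol = ball_volume(16, 5.0)
        padded_min, padded_max = 0.0, 1.0
        assert not vb.extract_isosurface(vol, 0.5, unit_transform).is_empty
        assert vb.extract_isosurface(vol, padded_min, unit_transform).is_empty
        assert vb.extract_isosurface(vol, padded_max, unit_transform).is_empty

    def test_normals_unit_length(self, unit_transform):
        mesh = vb.extract_isosurface(ball_volume(16, 5.0), 0.5, unit_transform)
        lengths = np.linalg.norm(mesh.normals, axis=1)
        assert np.allclose(lengths, 1.0, atol=1e-6)


class TestLabelSurfaces:
    def test_key_set_matches_identities(self, unit_transform):
        labels = np.zeros((16, 16, 16), np.uint8)
        labels[2:6, 2:6, 2:6] = 3
        labels[9:13, 9:13, 9:13] = 7
        surfaces = vb.extract_label_surfaces(labels, unit_transform)
        assert surfaces.ids() == [3, 7]

    def test_revolving_colors_and_override(self, unit_transform):
        labels = np.zeros((40, 8, 8), np.uint8)
        labels[1:4, 2:5, 2:5] = 1
        labels[10:13, 2:5, 2:5] = 11
        labels[20:23, 2:5, 2:5] = 3
        surfaces = vb.extract_label_surfaces(labels, unit_transform)
        assert surfaces.entries[1][1] == surfaces.entries[11][1]
        override = vb.extract_label_surfaces(
            labels, unit_transform, overrides={3: (0.9, 0.8, 0.7)}
        )
        assert override.entries[3][1] == (0.9, 0.8, 0.7)

    def test_disjoint_cubes_watertight_meshes(self, unit_transform):
        spec = vb.PhantomSpec(kind="label_cubes", shape_zyx=(48, 48, 48),
                              n_objects=4, cube_size=8)
        volume, _ = vb.make_phantom(spec)
        surfaces = vb.extract_label_surfaces(volume[0, 0], unit_transform)
        assert len(surfaces.entries) == 4
        for mesh, _ in surfaces.entries.values():
            assert mesh.is_watertight

    def test_negative_identities_rejected(self, unit_transform):
        labels = np.zeros((4, 4, 4), np.int16)
        labels[0, 0, 0] = -1
        with pytest.raises(vb.ValidationError):
            vb.extract_label_surfaces(labels, unit_transform)


class TestMeshFiles:
    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_single_triangle_round_trip(self, tmp_path, fmt):
        mesh = vb.Mesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2]],
            normals=[[0, 0, 1]] * 3,
        )
        path = tmp_path / f"tri.{fmt}"
        vb.write_mesh(mesh, path, fmt)
        back = vb.read_mesh(path)
        assert len(back.vertices) == 3 and len(back.faces) == 1
        assert np.allclose(back.vertices, mesh.vertices)

    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_empty_mesh_round_trip(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        vb.write_mesh(vb.Mesh.empty(), path, fmt)
        back = vb.read_mesh(path)
        assert back.is_empty

    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_sphere_round_trip_float32_precision(self, tmp_path, unit_transform, fmt):
        mesh = vb.extract_isosurface(ball_volume(16, 5.0), 0.5, unit_transform)
        path = tmp_path / f"sphere.{fmt}"
        vb.write_mesh(mesh, path, fmt)
        back = vb.read_mesh(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-5)
        assert np.array_equal(back.faces, mesh.faces)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(vb.ValidationError):
            vb.write_mesh(vb.Mesh.empty(), tmp_path / "m.stl", "stl")


class TestManifest:
    def make_scene(self, tmp_path, unit_transform):
        grid_name = "c0_t0_l0.vxgrid"
        vb.export_volume_grid(
            np.ones((4, 4, 4)), unit_transform, tmp_path / grid_name
        )
        ch_a = vb.ChannelAssets(
            name="fluo", mode="volumetric", emissive=True,
            transfer=vb.TransferFunction(0.0, 1.0), grids={"0": grid_name},
        )
        ch_b = vb.ChannelAssets(
            name="em", mode="volumetric", emissive=False,
            transfer=vb.TransferFunction(0.0, 255.0, emissive=False),
            grids={"0": grid_name},
        )
        return vb.Scene(
            channels=[ch_a, ch_b],
            base_transform=unit_transform,
            slice_boxes=[vb.SliceBox((0, 0, 0), (1, 1, 1), applies_to=[0])],
        )

    def test_load_save_byte_identical(self, tmp_path, unit_transform):
        scene = self.make_scene(tmp_path, unit_transform)
        path = tmp_path / "manifest.json"
        vb.write_manifest(scene, path)
        first = path.read_bytes()
        vb.write_manifest(vb.load_manifest(path), path)
        assert path.read_bytes() == first

    def test_emissive_absorptive_flags_round_trip(self, tmp_path, unit_transform):
        scene = self.make_scene(tmp_path, unit_transform)
        path = tmp_path / "manifest.json"
        vb.write_manifest(scene, path)
        again = vb.load_manifest(path)
        assert [c.emissive for c in again.channels] == [True, False]
        assert again.channels[1].transfer.emissive is False
        assert again.slice_boxes[0].applies_to == frozenset({0})

    def test_dangling_reference_rejected(self, tmp_path, unit_transform):
        scene = self.make_scene(tmp_path, unit_transform)
        scene.channels[0].grids["0"] = "missing.vxgrid"
        with pytest.raises(vb.ValidationError, match="missing.vxgrid"):
            vb.write_manifest(scene, tmp_path / "manifest.json")
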