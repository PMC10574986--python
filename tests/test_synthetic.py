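"""Synthetic knee generation: determinism, topology, STL IO, implant rotation."""

import numpy as np
import pytest
import trimesh

from kneesim.errors import ParameterError, StlFormatError
from kneesim.model import load_model, save_model
from kneesim.synthetic import (
    SyntheticKneeParams,
    apply_implant_ie_rotation,
    generate_synthetic_knee,
    point_mesh_distance,
    read_stl,
    write_stl,
)


class TestGeneration:
    def test_deterministic_under_fixed_seed(self):
        a = generate_synthetic_knee(SyntheticKneeParams(seed=7))
        b = generate_synthetic_knee(SyntheticKneeParams(seed=7))
        for name in a.bodies:
            assert np.array_equal(a.bodies[name].mesh.vertices, b.bodies[name].mesh.vertices)
            for site in a.bodies[name].attachment_sites:
                assert np.array_equal(
                    a.bodies[name].attachment_sites[site], b.bodies[name].attachment_sites[site]
                )

    def test_jitter_depends_on_seed(self):
        a = generate_synthetic_knee(SyntheticKneeParams(seed=1, attachment_jitter_mm=0.5))
        b = generate_synthetic_knee(SyntheticKneeParams(seed=2, attachment_jitter_mm=0.5))
        assert not np.array_equal(
            a.bodies["femur"].attachment_sites["MCL_ant_origin"],
            b.bodies["femur"].attachment_sites["MCL_ant_origin"],
        )

    def test_soft_tissue_counts(self, default_model):
        """Two MCL bundles, one LCL, one MPFL, one LPFL, three patellar
        bundles; three quadriceps bundles and two hamstring actuators."""
        by_lig = {}
        for b in default_model.bundles:
            by_lig.setdefault(b.ligament, []).append(b)
        assert {k: len(v) for k, v in by_lig.items()} == {
            "MCL": 2,
            "LCL": 1,
            "MPFL": 1,
            "LPFL": 1,
            "PL": 3,
        }
        quad = default_model.actuator("quadriceps")
        assert len(quad.bundles) == 3
        hams = [a for a in default_model.actuators if a.kind == "hamstring"]
        assert len(hams) == 2

    def test_no_interpenetration_at_generated_pose(self, default_model):
        """Brute-force check: every insert vertex clears both condyle spheres."""
        verts = default_model.implant.tibial_insert.mesh.vertices
        for prim in default_model.contact_primitives[:2]:
            center = np.asarray(prim.sphere_center)
            signed = np.linalg.norm(verts - center, axis=1) - prim.sphere_radius
            assert signed.min() >= -1e-9

    def test_meshes_watertight(self, default_model):
        for body in default_model.bodies.values():
            assert body.mesh.is_watertight
        for comp in default_model.implant.components().values():
            assert comp.mesh.is_watertight

    def test_attachments_near_host_surface(self, default_model):
        for body in default_model.bodies.values():
            pts = np.array(list(body.attachment_sites.values()))
            assert point_mesh_distance(body.mesh, pts).max() <= 5.0

    def test_anatomical_frames_orthonormal_right_handed(self, default_model):
        for body in default_model.bodies.values():
            axes = body.anatomical_frame.axes
            assert np.allclose(axes.T @ axes, np.eye(3), atol=1e-12)
            assert np.linalg.det(axes) == pytest.approx(1.0)

    def test_invalid_params_name_offending_field(self):
        with pytest.raises(ParameterError, match="insert_dish_radii"):
            SyntheticKneeParams(condyle_radii=(25.0, 25.0), insert_dish_radii=(20.0, 30.0))
        with pytest.raises(ParameterError, match="condyle_spacing"):
            SyntheticKneeParams(condyle_spacing=-1.0)


class TestStlRoundTrip:
    def test_unit_cube_binary_round_trip(self, tmp_path):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        path = tmp_path / "cube.stl"
        write_stl(cube, path)
        back = read_stl(path)
        assert len(back.faces) == 12
        orig = np.sort(cube.triangles.reshape(-1, 3), axis=0).astype(np.float32)
        got = np.sort(back.triangles.reshape(-1, 3), axis=0).astype(np.float32)
        assert np.array_equal(orig, got)

    def test_ascii_and_binary_encode_same_soup(self, tmp_path):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=3.0)
        write_stl(mesh, tmp_path / "b.stl", ascii=False)
        write_stl(mesh, tmp_path / "a.stl", ascii=True)
        vb = np.sort(read_stl(tmp_path / "b.stl").triangles.reshape(-1, 3), axis=0)
        va = np.sort(read_stl(tmp_path / "a.stl").triangles.reshape(-1, 3), axis=0)
        assert np.allclose(vb, va, atol=1e-4)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.write_bytes(b"")
        with pytest.raises(StlFormatError) as err:
            read_stl(path)
        assert err.value.byte_offset == 0

    def test_truncated_binary_reports_offset(self, tmp_path):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        path = tmp_path / "trunc.stl"
        write_stl(cube, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 30])
        with pytest.raises(StlFormatError) as err:
            read_stl(path)
        assert err.value.byte_offset == len(data) - 30


class TestImplantRotation:
    def test_zero_angle_is_identity(self, default_model):
        rotated = apply_implant_ie_rotation(default_model, 0.0)
        for key, comp in rotated.implant.components().items():
            orig = default_model.implant.components()[key]
            assert comp.pose.almost_equal(orig.pose, tol=0)

    def test_plus_minus_cancel(self, default_model):
        back = apply_implant_ie_rotation(apply_implant_ie_rotation(default_model, 3.2), -3.2)
        for key, comp in back.implant.components().items():
            orig = default_model.implant.components()[key]
            assert comp.pose.almost_equal(orig.pose, tol=1e-9)

    def test_group_action_composition(self, default_model):
        a = apply_implant_ie_rotation(apply_implant_ie_rotation(default_model, 1.6), 1.6)
        b = apply_implant_ie_rotation(default_model, 3.2)
        assert a.implant.tibial_insert.pose.almost_equal(b.implant.tibial_insert.pose, tol=1e-12)

    def test_radii_preserved_and_bones_untouched(self, default_model):
        rotated = apply_implant_ie_rotation(default_model, 3.2)
        axis_xy = np.asarray(default_model.geometry["baseplate_center"])[:2]
        for model in (default_model, rotated):
            poses = model.frame_poses(model.generation_poses())
            verts = poses["tibial_insert"].transform_points(model.implant.tibial_insert.mesh.vertices)
            radii = np.linalg.norm(verts[:, :2] - axis_xy, axis=1)
            if model is default_model:
                ref = radii
            else:
                assert np.allclose(np.sort(radii), np.sort(ref), atol=1e-9)
        assert np.array_equal(
            rotated.bodies["femur"].mesh.vertices, default_model.bodies["femur"].mesh.vertices
        )
        for site, pt in default_model.bodies["tibia"].attachment_sites.items():
            assert np.array_equal(rotated.bodies["tibia"].attachment_sites[site], pt)

    def test_out_of_bounds_angle_rejected(self, default_model):
        with pytest.raises(ParameterError):
            apply_implant_ie_rotation(default_model, 20.0)


def test_model_directory_round_trip(tmp_path, default_model):
    save_model(default_model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert set(back.bodies) == set(default_model.bodies)
    assert [b.name for b in back.bundles] == [b.name for b in default_model.bundles]
    for b0, b1 in zip(default_model.bundles, back.bundles):
        assert b1.k == b0.k and b1.eps_r == b0.eps_r
        assert np.allclose(b1.origin_pt, b0.origin_pt)
    assert len(back.contact_primitives) == len(default_model.contact_primitives)
    assert back.geometry["knee_z"] == default_model.geometry["knee_z"]
    assert len(back.bodies["femur"].mesh.faces) == len(default_model.bodies["femur"].mesh.faces)
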