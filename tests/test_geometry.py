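"""Parametric implant geometry, placement and the ligament attachment set."""
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tkrsim
from tkrsim.errors import ConfigurationError, ParameterError
from tkrsim.geometry import (AnatomicalFrame, ImplantParams, PlacementOffsets,
                             apply_offsets, export_ligament_csv,
                             load_ligament_csv, make_femoral_component,
                             make_ligament_set, make_reference_placement,
                             make_tibial_insert)
from tkrsim.pose import Pose


class TestImplantParams:
    def test_defaults_valid(self):
        ImplantParams().validate()

    @pytest.mark.parametrize("kwargs", [
        {"posterior_radius": 40.0},                # not multi-radius
        {"dish_sagittal_radius": 30.0},            # conforming sagittal
        {"dish_coronal_radius": 10.0},             # conforming coronal
        {"slope_deg": -2.0},
        {"distal_radius": -1.0},
        {"thickness": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ImplantParams(**kwargs).validate()


class TestFemoralComponent:
    def test_mirror_symmetry(self, femoral_mesh):
        v = femoral_mesh.vertices
        mirrored = v * np.array([1.0, 1.0, -1.0])
        # the medial half is the exact mirror image of the lateral half
        half = len(v) // 2
        assert np.array_equal(mirrored[:half], v[half:])

    def test_arc_tangency_centre_distance(self, femoral_mesh, implant_params):
        o_d = femoral_mesh.metadata["O_distal"]
        o_p = femoral_mesh.metadata["O_posterior"]
        expected = implant_params.distal_radius - implant_params.posterior_radius
        assert np.linalg.norm(o_d - o_p) == pytest.approx(expected, abs=1e-12)

    def test_surface_area_converges_under_refinement(self, implant_params):
        coarse = make_femoral_component(implant_params).area()
        fine_params = ImplantParams(mesh_edge=implant_params.mesh_edge / 2)
        fine = make_femoral_component(fine_params).area()
        assert abs(fine - coarse) / fine < 0.01

    def test_distance_field_matches_surface(self, femoral_mesh):
        # sampled mesh vertices lie on the analytic zero level set
        v = femoral_mesh.vertices[::37]
        d = femoral_mesh.distance_field(v)
        assert np.abs(d).max() < 1e-9

    def test_no_degenerate_triangles(self, femoral_mesh, insert_mesh):
        for mesh in (femoral_mesh, insert_mesh):
            _, areas = mesh.face_normals_areas()
            assert areas.min() > 0


class TestTibialInsert:
    def test_built_in_slope_angle(self, insert_mesh, implant_params):
        n = insert_mesh.metadata["dish_floor_normal"]
        angle = np.degrees(np.arccos(np.clip(n[1], -1, 1)))
        assert angle == pytest.approx(implant_params.slope_deg, abs=1e-9)

    def test_zero_slope_floor_normal_parallel_proximal(self):
        mesh = make_tibial_insert(ImplantParams(slope_deg=0.0))
        n = mesh.metadata["dish_floor_normal"]
        assert np.allclose(n, [0.0, 1.0, 0.0], atol=1e-12)

    def test_thickness_bounds_vertical_extent(self, insert_mesh, implant_params):
        y = insert_mesh.vertices[:, 1]
        assert y.max() - y.min() >= implant_params.thickness

    def test_compartments_watertight(self, insert_mesh):
        tm = insert_mesh.to_trimesh()
        parts = tm.split(only_watertight=False)
        assert len(parts) == 2
        assert all(p.is_watertight for p in parts)
        assert all(p.volume > 0 for p in parts)

    def test_conforming_dish_rejected(self):
        with pytest.raises(ParameterError):
            make_tibial_insert(ImplantParams(dish_sagittal_radius=20.0))


class TestPlacement:
    def test_identity_frames_give_identity_poses(self):
        f = AnatomicalFrame.identity()
        pf, pt = make_reference_placement(f, f)
        assert pf.almost_equal(Pose.identity())
        assert pt.almost_equal(Pose.identity())

    def test_zero_offsets_reproduce_reference_bit_identically(self):
        f = AnatomicalFrame.identity()
        _, ref = make_reference_placement(f, f)
        out = apply_offsets(ref, PlacementOffsets(0.0, 0.0), f)
        assert np.array_equal(out.R, ref.R) and np.array_equal(out.t, ref.t)

    def test_offsets_invert_to_identity(self):
        f = AnatomicalFrame.identity()
        ref = Pose.identity()
        fwd = apply_offsets(ref, PlacementOffsets(rotation_deg=3.0), f)
        back = apply_offsets(fwd, PlacementOffsets(rotation_deg=-3.0), f,
                             about=ref.t)
        assert back.almost_equal(ref, tol=1e-12)

    def test_slope_offset_composes_with_built_in_slope(self, insert_mesh):
        f = AnatomicalFrame.identity()
        pose = apply_offsets(Pose.identity(), PlacementOffsets(slope_deg=3.0), f)
        n = pose.apply_vector(insert_mesh.metadata["dish_floor_normal"])
        angle = np.degrees(np.arccos(np.clip(n[1], -1, 1)))
        assert angle == pytest.approx(10.0, abs=1e-9)

    def test_out_of_range_requires_override(self):
        f = AnatomicalFrame.identity()
        with pytest.raises(ParameterError):
            apply_offsets(Pose.identity(), PlacementOffsets(slope_deg=9.0), f)
        apply_offsets(Pose.identity(),
                      PlacementOffsets(slope_deg=9.0, override=True), f)

    @settings(max_examples=25, deadline=None)
    @given(slope=st.floats(-6, 6), rot=st.floats(-6, 6))
    def test_offsets_form_group_action(self, slope, rot):
        f = AnatomicalFrame.identity()
        ref = Pose.identity()
        fwd = apply_offsets(ref, PlacementOffsets(slope, rot), f)
        # inverse in reverse order: undo rotation, then undo slope
        undo_rot = apply_offsets(fwd, PlacementOffsets(0.0, -rot), f,
                                 about=ref.t)
        back = apply_offsets(undo_rot, PlacementOffsets(-slope, 0.0), f,
                             about=ref.t)
        assert back.almost_equal(ref, tol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ParameterError):
            AnatomicalFrame(np.zeros(3), np.eye(3) * 1.1)
        with pytest.raises(ParameterError):
            AnatomicalFrame(np.zeros(3), np.diag([1.0, 1.0, -1.0]))


class TestLigamentSet:
    def test_implanted_bundle_inventory(self, default_model):
        bundles = default_model.bundles
        assert len(bundles) == 25
        counts = {}
        for b in bundles:
            counts[b.structure] = counts.get(b.structure, 0) + 1
        assert counts == {"PCL": 2, "MCL": 3, "LCL": 3, "opMCL": 1,
                          "dMCL": 2, "OPL": 2, "APL": 1, "pCAP": 2,
                          "LPFL": 3, "MPFL": 3, "PL": 3}

    def test_native_option_adds_only_acl(self):
        f = AnatomicalFrame.identity()
        cr = make_ligament_set(f, f)
        native = make_ligament_set(f, f, include_acl=True)
        assert len(native) == len(cr) + 2
        extra = {b.structure for b in native} - {b.structure for b in cr}
        assert extra == {"ACL"}

    def test_attachments_distinct_and_lengths_positive(self, default_model):
        from tkrsim.soft_tissue import bundle_length
        poses = default_model.body_poses(10.0, np.zeros(5))
        for b in default_model.bundles:
            assert bundle_length(b, poses) > 0
            assert b.reference_length > 0

    def test_missing_bundle_raises_configuration_error(self):
        from tkrsim.config import default_ligament_rules
        table = default_ligament_rules()
        table = table[table["bundle_id"] != "aPCL"]
        f = AnatomicalFrame.identity()
        with pytest.raises(ConfigurationError):
            make_ligament_set(f, f, table)

    def test_user_mesh_import(self, tmp_path, insert_mesh):
        from tkrsim.geometry import load_surface_mesh
        p = tmp_path / "insert.stl"
        insert_mesh.export(str(p))
        loaded = load_surface_mesh(str(p))
        assert loaded.distance_field is None
        assert loaded.area() == pytest.approx(insert_mesh.area(), rel=1e-6)
        assert set(np.unique(loaded.compartment)) == {-1, 1}

    def test_csv_round_trip(self, default_model):
        buf = io.StringIO()
        export_ligament_csv(default_model.bundles, buf)
        buf.seek(0)
        loaded = load_ligament_csv(buf)
        assert len(loaded) == len(default_model.bundles)
        for a, b in zip(default_model.bundles, loaded):
            assert a.name == b.name
            assert a.reference_length == pytest.approx(b.reference_length,
                                                       rel=1e-5)
            assert np.allclose(a.origin, b.origin, atol=1e-4)
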