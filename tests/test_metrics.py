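"""Joint coordinate decomposition and outcome metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tkrsim.errors import ComparisonError, ConfigurationError
from tkrsim.metrics import (FfcPair, JointState, compose_pose,
                            detect_paradoxical_anterior, detect_screw_home,
                            femoral_rollback, ffc_positions, grood_suntay,
                            rmse)
from tkrsim.pose import Pose


class TestGroodSuntay:
    def test_identity_pose_all_zero(self):
        st_ = grood_suntay(Pose.identity(), Pose.identity())
        assert np.allclose(st_.as_array(), 0.0, atol=1e-12)

    def test_pure_flexion_rotation(self):
        pose = Pose.from_axis_angle([0, 0, 1], -30.0)
        st_ = grood_suntay(Pose.identity(), pose)
        assert st_.flexion == pytest.approx(30.0, abs=1e-9)
        assert np.allclose([st_.adduction, st_.rotation,
                            st_.ap, st_.si, st_.ml], 0.0, atol=1e-9)

    def test_round_trip_seeded_states(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s = JointState(
                flexion=rng.uniform(-30, 140),
                adduction=rng.uniform(-30, 30),
                rotation=rng.uniform(-30, 30),
                ap=rng.uniform(-50, 50), si=rng.uniform(-50, 50),
                ml=rng.uniform(-50, 50))
            out = grood_suntay(Pose.identity(), compose_pose(s))
            assert np.allclose(out.as_array(), s.as_array(), atol=1e-9)

    @settings(max_examples=80, deadline=None)
    @given(flexion=st.floats(-30, 140), adduction=st.floats(-60, 60),
           rotation=st.floats(-45, 45), ap=st.floats(-80, 80),
           si=st.floats(-80, 80), ml=st.floats(-80, 80))
    def test_round_trip_property(self, flexion, adduction, rotation,
                                 ap, si, ml):
        s = JointState(flexion, adduction, rotation, ap, si, ml)
        out = grood_suntay(Pose.identity(), compose_pose(s))
        assert np.allclose(out.as_array(), s.as_array(), atol=1e-8)

    def test_pose_invariant_recompute(self):
        s = JointState(45.0, 5.0, -7.0, 3.0, -2.0, 1.0)
        pose = compose_pose(s)
        pose2 = compose_pose(grood_suntay(Pose.identity(), pose))
        assert pose.almost_equal(pose2, tol=1e-9)


def synthetic_trace(flexion, **columns):
    n = len(flexion)
    data = {"flexion_deg": np.asarray(flexion, dtype=float),
            "ap_mm": np.zeros(n), "si_mm": np.zeros(n), "ml_mm": np.zeros(n),
            "adduction_deg": np.zeros(n), "rotation_deg": np.zeros(n),
            "fem_ap_in_tibia_mm": np.zeros(n)}
    data.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    return pd.DataFrame(data)


class TestRollback:
    def test_static_sweep_all_zero(self):
        tr = synthetic_trace(np.arange(10, 50, 5.0))
        assert np.allclose(femoral_rollback(tr).to_numpy(), 0.0)

    def test_imposed_posterior_translation(self):
        flex = np.arange(10, 60, 10.0)
        ap = np.zeros(len(flex))
        ap[2] = -5.0
        rb = femoral_rollback(synthetic_trace(flex, fem_ap_in_tibia_mm=ap))
        assert rb.iloc[2] == pytest.approx(-5.0)

    def test_posterior_motion_gives_decreasing_values(self):
        flex = np.arange(10, 60, 10.0)
        ap = -0.2 * (flex - 10.0)
        rb = femoral_rollback(synthetic_trace(flex, fem_ap_in_tibia_mm=ap))
        assert np.all(np.diff(rb.to_numpy()) < 0)
        assert rb.iloc[0] == 0.0


class TestFfc:
    META = {"ffc_medial": np.array([-3.0, 25.0, -22.0]),
            "ffc_lateral": np.array([-3.0, 25.0, 22.0])}

    def test_symmetric_component_equal_ap_at_zero_rotation(self):
        tr = synthetic_trace(np.arange(10, 40, 10.0))
        ffc = ffc_positions(tr, self.META)
        assert np.allclose(ffc.medial_ap, ffc.lateral_ap, atol=1e-12)

    def test_internal_insert_rotation_antisymmetric_shift(self):
        # facet centres on the axial-rotation axis: shifts exactly mirror
        meta = {"ffc_medial": np.array([0.0, 25.0, -22.0]),
                "ffc_lateral": np.array([0.0, 25.0, 22.0])}
        tr = synthetic_trace([0.0])
        ref = ffc_positions(tr, meta)
        rot = Pose.from_axis_angle([0, 1, 0], 3.0)
        out = ffc_positions(tr, meta, pose_insert_t=rot)
        d_med = out.medial_ap[0] - ref.medial_ap[0]
        d_lat = out.lateral_ap[0] - ref.lateral_ap[0]
        assert d_lat < 0 < d_med            # lateral posterior, medial anterior
        assert d_med == pytest.approx(-d_lat, abs=1e-9)
        # off-axis centres keep the sign pattern
        tr10 = synthetic_trace([10.0])
        ref10 = ffc_positions(tr10, self.META)
        out10 = ffc_positions(tr10, self.META, pose_insert_t=rot)
        assert out10.lateral_ap[0] < ref10.lateral_ap[0]
        assert out10.medial_ap[0] > ref10.medial_ap[0]

    def test_missing_metadata_raises(self):
        with pytest.raises(ConfigurationError):
            ffc_positions(synthetic_trace([10.0]), {})

    def test_marked_angles_extractable(self):
        flex = np.arange(10, 121, 1.0)
        ffc = ffc_positions(synthetic_trace(flex), self.META)
        for a in (10, 30, 60, 90, 120):
            assert a in ffc.flexion


class TestScrewHome:
    def test_external_ramp_detected(self):
        flex = np.arange(60, -11, -1.0)
        # 3 deg external ramp developing entirely inside the terminal window
        rot = np.where(flex < 10, -3.0 * (10 - flex) / 20.0, 0.0)
        present, mag = detect_screw_home(synthetic_trace(flex,
                                                         rotation_deg=rot))
        assert present
        assert mag == pytest.approx(3.0, abs=1e-9)

    def test_constant_rotation_absent(self):
        flex = np.arange(60, -11, -1.0)
        present, mag = detect_screw_home(
            synthetic_trace(flex, rotation_deg=np.full(len(flex), 2.0)))
        assert present is False and mag == 0.0

    def test_internal_ramp_not_detected(self):
        flex = np.arange(60, -11, -1.0)
        rot = np.where(flex < 20, 3.0 * (20 - flex) / 30.0, 0.0)
        present, _ = detect_screw_home(synthetic_trace(flex,
                                                       rotation_deg=rot))
        assert present is False

    def test_trace_not_reaching_terminal_extension(self):
        flex = np.arange(60, 29, -1.0)
        present, mag = detect_screw_home(synthetic_trace(flex))
        assert present is None and np.isnan(mag)


class TestParadoxicalAnterior:
    def test_monotone_posterior_absent(self):
        flex = np.arange(10, 121, 5.0)
        ffc = FfcPair(flexion=flex,
                      medial=np.stack([-0.1 * flex, 0 * flex, 0 * flex], axis=1),
                      lateral=np.zeros((len(flex), 3)))
        present, _ = detect_paradoxical_anterior(ffc)
        assert present is False

    def test_anterior_then_posterior_with_bound(self):
        flex = np.arange(10, 121, 5.0)
        ap = np.where(flex <= 55, 0.1 * flex, 5.5 - 0.1 * (flex - 55))
        ffc = FfcPair(flexion=flex,
                      medial=np.stack([ap, 0 * flex, 0 * flex], axis=1),
                      lateral=np.zeros((len(flex), 3)))
        present, bound = detect_paradoxical_anterior(ffc)
        assert present and bound == pytest.approx(55.0)

    def test_noise_below_guard_ignored(self):
        flex = np.arange(10, 121, 5.0)
        rng = np.random.default_rng(0)
        ap = -0.1 * flex + rng.uniform(0, 1e-7, len(flex))
        ffc = FfcPair(flexion=flex,
                      medial=np.stack([ap, 0 * flex, 0 * flex], axis=1),
                      lateral=np.zeros((len(flex), 3)))
        present, _ = detect_paradoxical_anterior(ffc, guard=1e-6)
        assert present is False


class TestRmse:
    def test_identical_traces_zero(self):
        tr = synthetic_trace(np.arange(10, 50, 5.0),
                             contact_force_n=np.arange(8))
        assert rmse(tr, tr, "contact_force").rmse == 0.0

    def test_constant_offset(self):
        flex = np.arange(10, 50, 5.0)
        a = synthetic_trace(flex, contact_force_n=np.linspace(100, 200, 8))
        b = synthetic_trace(flex, contact_force_n=np.linspace(102, 202, 8))
        assert rmse(a, b, "contact_force").rmse == pytest.approx(2.0)

    def test_hand_evaluated_two_point_series(self):
        flex = [10.0, 20.0]
        a = synthetic_trace(flex, contact_force_n=[0.0, 0.0])
        b = synthetic_trace(flex, contact_force_n=[3.0, 4.0])
        assert rmse(a, b, "contact_force").rmse == pytest.approx(
            np.sqrt(12.5))

    def test_symmetry_in_arguments(self):
        flex = np.arange(10, 60, 5.0)
        rng = np.random.default_rng(3)
        a = synthetic_trace(flex, contact_force_n=rng.normal(200, 30, len(flex)))
        b = synthetic_trace(flex, contact_force_n=rng.normal(200, 30, len(flex)))
        assert rmse(a, b, "contact_force").rmse == pytest.approx(
            rmse(b, a, "contact_force").rmse)

    def test_uniform_offset_scales_linearly(self):
        flex = np.arange(10, 60, 5.0)
        base = np.linspace(100, 300, len(flex))
        a = synthetic_trace(flex, contact_force_n=base)
        r1 = rmse(a, synthetic_trace(flex, contact_force_n=base + 1.5),
                  "contact_force").rmse
        r3 = rmse(a, synthetic_trace(flex, contact_force_n=base + 4.5),
                  "contact_force").rmse
        assert r3 == pytest.approx(3 * r1)

    def test_resampling_onto_common_grid(self):
        a = synthetic_trace(np.arange(10, 61, 5.0),
                            contact_force_n=np.arange(10, 61, 5.0))
        b = synthetic_trace(np.arange(10, 61, 2.0),
                            contact_force_n=np.arange(10, 61, 2.0) + 1.0)
        assert rmse(a, b, "contact_force").rmse == pytest.approx(1.0)

    def test_disjoint_ranges_raise(self):
        a = synthetic_trace(np.arange(10, 30, 5.0), contact_force_n=np.ones(4))
        b = synthetic_trace(np.arange(60, 80, 5.0), contact_force_n=np.ones(4))
        with pytest.raises(ComparisonError):
            rmse(a, b, "contact_force")
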