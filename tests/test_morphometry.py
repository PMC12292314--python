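import logging

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import talofit as tf

LANDMARKS = {
    "shaft_distal": np.array([0.0, 0.0, 50.0]),
    "shaft_proximal": np.array([0.0, 0.0, 300.0]),
    "mt5_head": np.array([5.0, 90.0, -60.0]),
    "calcaneal_tuberosity": np.array([0.0, -60.0, -60.0]),
    "articular_center": np.array([0.0, 0.0, 0.0]),
}


class TestJointFrame:
    def test_prealigned_case_gets_identity_axes(self, mean_case):
        _, tibia, _, _ = mean_case
        frame = tf.build_joint_frame(tibia)
        assert np.allclose(frame.rotation, np.eye(3))
        lo, hi = tibia.bounds
        assert np.all(frame.origin >= lo) and np.all(frame.origin <= hi)

    def test_landmark_frame_is_orthonormal_and_anterior(self, mean_case):
        _, tibia, _, _ = mean_case
        frame = tf.build_joint_frame(tibia, LANDMARKS)
        assert np.allclose(frame.rotation.T @ frame.rotation, np.eye(3), atol=1e-12)
        assert frame.axis_z @ [0, 0, 1] == pytest.approx(1.0)
        assert frame.axis_y @ [0, 1, 0] > 0.99  # slight mt5 x-offset tolerated

    def test_rotated_landmarks_recover_rotated_axes(self, mean_case):
        _, tibia, _, _ = mean_case
        base = tf.build_joint_frame(tibia, LANDMARKS)
        R = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        rotated = {k: R @ v for k, v in LANDMARKS.items()}
        frame = tf.build_joint_frame(tibia.transformed(R), rotated)
        angle = np.degrees(np.arccos(np.clip(frame.axis_z @ (R @ base.axis_z), -1, 1)))
        assert angle < 0.1

    def test_collinear_landmarks_raise_alignment_error(self, mean_case):
        _, tibia, _, _ = mean_case
        bad = dict(LANDMARKS)
        bad["mt5_head"] = np.array([0.0, 0.0, -10.0])
        bad["calcaneal_tuberosity"] = np.array([0.0, 0.0, -90.0])
        with pytest.raises(tf.AlignmentError, match="collinear"):
            tf.build_joint_frame(tibia, bad)

    def test_left_handed_frame_rejected(self):
        with pytest.raises(tf.AlignmentError, match="right-handed"):
            tf.JointFrame(np.zeros(3), [1, 0, 0], [0, 0, 1], [0, 1, 0])


class TestMeasureJointSpace:
    def test_constant_gap_recovered(self):
        params = tf.SyntheticCaseParams(nodal_gaps=np.full(9, 5.0))
        tibia, talus, _ = tf.build_case_meshes(params)
        profile = tf.measure_joint_space(tibia, talus, case_id="const")
        assert np.allclose(profile.H, 5.0, atol=0.05)

    def test_reference_mean_case_recovered(self, mean_case):
        _, tibia, talus, truth = mean_case
        profile = tf.measure_joint_space(tibia, talus)
        assert np.abs(profile.H - truth.H).max() < 0.05

    def test_grid_line_missing_bone_names_the_node(self, mean_case):
        _, tibia, talus, _ = mean_case
        wide = tf.MeasurementGrid(spacing=40.0)  # beyond the articular footprint
        with pytest.raises(tf.MeasurementError, match="H1"):
            tf.measure_joint_space(tibia, talus, grid=wide)

    def test_interpenetration_warns_and_retains_value(self, mean_case, caplog):
        _, tibia, talus, _ = mean_case
        sunk = tibia.translated((0.0, 0.0, -10.0))
        with caplog.at_level(logging.WARNING, logger="talofit"):
            profile = tf.measure_joint_space(sunk, talus, case_id="sunk")
        assert np.all(profile.H < 0)
        assert any("negative" in r.message.lower() for r in caplog.records)

    def test_rigid_motion_invariance(self, mean_case):
        _, tibia, talus, _ = mean_case
        base = tf.measure_joint_space(tibia, talus)
        R = Rotation.from_euler("xyz", [14.0, -32.0, 57.0], degrees=True).as_matrix()
        t = np.array([12.0, -7.0, 30.0])
        frame = tf.JointFrame.identity().transformed(R, t)
        moved = tf.measure_joint_space(
            tibia.transformed(R, t), talus.transformed(R, t), frame=frame
        )
        assert np.allclose(moved.H, base.H, atol=1e-6)

    def test_left_side_mirrors_lateral_medial_columns(self, mean_case):
        _, tibia, talus, _ = mean_case
        right = tf.measure_joint_space(tibia, talus, side="right")
        left = tf.measure_joint_space(
            tibia.mirrored_x(), talus.mirrored_x(), side="left", case_id="L"
        )
        assert np.allclose(left.H, right.H, atol=1e-9)

    def test_recovery_error_shrinks_with_resolution(self):
        errs = []
        for res in (1.7, 0.9, 0.45):
            params = tf.SyntheticCaseParams(
                nodal_gaps=tf.REFERENCE_NODAL_MEANS.copy(), mesh_resolution=res
            )
            tibia, talus, truth = tf.build_case_meshes(params)
            profile = tf.measure_joint_space(tibia, talus)
            errs.append(np.abs(profile.H - truth.H).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05


class TestJointSpaceProfile:
    def test_requires_nine_finite_values(self):
        with pytest.raises(ValueError, match="nine"):
            tf.JointSpaceProfile(case_id="x", H=np.ones(8))
        with pytest.raises(ValueError, match="finite"):
            tf.JointSpaceProfile(case_id="x", H=np.r_[np.ones(8), np.inf])

    def test_label_indexing(self):
        profile = tf.JointSpaceProfile(case_id="x", H=np.arange(1.0, 10.0))
        assert profile[1] == 1.0 and profile[9] == 9.0
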