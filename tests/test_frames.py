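"""Joint coordinate decomposition: sign conventions, round trips, laxity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from kneesim.errors import SingularityError, ValidationError
from kneesim.frames import (
    DOF_COLUMNS,
    Frame,
    JointKinematics,
    RigidPose,
    grood_suntay,
    laxity,
    pose_from_kinematics,
    tibia_pose_from_relative,
)

I3 = np.eye(3)
FRAME = Frame.world_aligned()


def _gs(femur_rot=I3, femur_t=(0, 0, 0), tibia_rot=I3, tibia_t=(0, 0, 0)):
    return grood_suntay(
        RigidPose(femur_rot, femur_t), RigidPose(tibia_rot, tibia_t), FRAME, FRAME
    )


def _floating_axis_oracle(rf, rt):
    """Independent geometric floating-axis decomposition (right knee).

    e1 = femoral medial axis, e3 = tibial proximal axis, floating axis
    e2 = e1 x e3 normalized.  Flexion is the angle about e1 from the femoral
    anterior axis to the floating axis; ab/adduction opens the e1-e3 angle
    from 90 deg (valgus tips the tibial axis medially); tibial rotation is
    the angle about e3 from the floating axis to the tibial anterior axis,
    external positive.
    """
    e1 = rf[:, 1]
    e3 = rt[:, 2]
    e2 = np.cross(e1, e3)
    e2 = e2 / np.linalg.norm(e2)
    xf = rf[:, 0]
    fe = np.degrees(np.arctan2(np.dot(np.cross(xf, e2), e1), np.dot(xf, e2)))
    vv = 90.0 - np.degrees(np.arccos(np.clip(np.dot(e1, e3), -1, 1)))
    xt = rt[:, 0]
    ie = -np.degrees(np.arctan2(np.dot(np.cross(e2, xt), e3), np.dot(e2, xt)))
    return fe, vv, ie


class TestGroodSuntay:
    def test_identity_pose_reads_zero(self):
        jk = _gs()
        assert np.allclose(jk.as_array(), 0.0, atol=1e-12)

    def test_pure_flexion_30_degrees(self):
        # femur rotated -30 deg about its medio-lateral axis flexes the knee
        rf = Rotation.from_euler("y", -30, degrees=True).as_matrix()
        jk = _gs(femur_rot=rf)
        assert jk.FE == pytest.approx(30.0, abs=1e-9)
        assert np.allclose([jk.VV, jk.IE, jk.AP, jk.ML, jk.IS], 0.0, atol=1e-9)
        fe, vv, ie = _floating_axis_oracle(rf, I3)
        assert jk.FE == pytest.approx(fe, abs=1e-9)

    def test_medial_tibia_translation_positive_ml(self):
        jk = _gs(tibia_t=(0.0, 5.0, 0.0))
        assert jk.ML == pytest.approx(5.0, abs=1e-12)
        assert np.allclose([jk.FE, jk.VV, jk.IE, jk.AP, jk.IS], 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "rot, t, dof, expected",
        [
            (Rotation.from_euler("y", -10, degrees=True).as_matrix(), None, "FE", None),
            (Rotation.from_euler("x", -5, degrees=True).as_matrix(), None, "VV", 5.0),
            (Rotation.from_euler("z", -8, degrees=True).as_matrix(), None, "IE", 8.0),
            (I3, (4.0, 0, 0), "AP", 4.0),
            (I3, (0, 6.0, 0), "ML", 6.0),
            (I3, (0, 0, 3.0), "IS", 3.0),
        ],
    )
    def test_sign_convention_audit(self, rot, t, dof, expected):
        """Valgus / external rotation / anterior / medial / proximal all +."""
        if dof == "FE":
            jk = _gs(femur_rot=rot)
            assert jk.FE > 0
            return
        jk = _gs(tibia_rot=rot, tibia_t=t or (0, 0, 0))
        assert getattr(jk, dof) == pytest.approx(expected, abs=1e-9)

    def test_matches_floating_axis_oracle_on_random_poses(self, rng):
        for _ in range(50):
            rf = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            ang = rng.uniform(-40, 40, 3)
            rt = rf @ Rotation.from_euler("YXZ", ang, degrees=True).as_matrix()
            jk = grood_suntay(RigidPose(rf, np.zeros(3)), RigidPose(rt, np.zeros(3)), FRAME, FRAME)
            fe, vv, ie = _floating_axis_oracle(rf, rt)
            assert jk.FE == pytest.approx(fe, abs=1e-8)
            assert jk.VV == pytest.approx(vv, abs=1e-8)
            assert jk.IE == pytest.approx(ie, abs=1e-8)

    def test_invariant_under_common_rigid_transform(self, rng):
        rf = Rotation.from_euler("YXZ", [25, 4, -7], degrees=True).as_matrix()
        jk0 = _gs(femur_rot=rf, tibia_t=(1.0, -2.0, 3.0))
        common = RigidPose(
            Rotation.random(random_state=11).as_matrix(), np.array([10.0, -4.0, 2.0])
        )
        jk1 = grood_suntay(
            common.compose(RigidPose(rf, np.zeros(3))),
            common.compose(RigidPose(I3, (1.0, -2.0, 3.0))),
            FRAME,
            FRAME,
        )
        assert np.allclose(jk0.as_array(), jk1.as_array(), atol=1e-9)

    def test_singularity_raises(self):
        rt = Rotation.from_euler("x", -90, degrees=True).as_matrix()
        with pytest.raises(SingularityError):
            _gs(tibia_rot=rt)


class TestPoseFromKinematics:
    def test_zero_kinematics_identity(self):
        rel = pose_from_kinematics(JointKinematics.zeros())
        assert rel.almost_equal(RigidPose.identity(), tol=1e-12)

    def test_round_trip_random_nonsingular(self, rng):
        for _ in range(100):
            jk = JointKinematics(
                FE=float(rng.uniform(-120, 120)),
                VV=float(rng.uniform(-45, 45)),
                IE=float(rng.uniform(-40, 40)),
                AP=float(rng.uniform(-20, 20)),
                ML=float(rng.uniform(-20, 20)),
                IS=float(rng.uniform(-20, 20)),
            )
            rel = pose_from_kinematics(jk)
            femur = RigidPose.identity()
            tibia = tibia_pose_from_relative(rel, femur, FRAME, FRAME)
            back = grood_suntay(femur, tibia, FRAME, FRAME)
            assert np.max(np.abs(back.as_array() - jk.as_array())) < 1e-9

    def test_flexion_35_reproduced_by_axis_angle(self):
        rel = pose_from_kinematics(JointKinematics(35, 0, 0, 0, 0, 0))
        rotvec = Rotation.from_matrix(rel.rotation).as_rotvec(degrees=True)
        assert np.linalg.norm(rotvec) == pytest.approx(35.0, abs=1e-9)
        # rotation purely about the femoral medio-lateral axis
        assert abs(rotvec[0]) < 1e-9 and abs(rotvec[2]) < 1e-9

    def test_singular_input_raises(self):
        with pytest.raises(SingularityError):
            pose_from_kinematics(JointKinematics(0, 90, 0, 0, 0, 0))


class TestLaxity:
    def test_constant_series_zero(self):
        frame = pd.DataFrame({c: np.full(10, 1.25) for c in DOF_COLUMNS})
        assert (laxity(frame) == 0).all()

    def test_vv_range(self):
        frame = pd.DataFrame({c: np.zeros(3) for c in DOF_COLUMNS})
        frame["VV"] = [-2.00, 1.0, 3.15]
        assert laxity(frame)["VV"] == pytest.approx(5.15)

    def test_permutation_invariance(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 6)), columns=DOF_COLUMNS)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert np.allclose(laxity(frame), laxity(shuffled))

    def test_empty_series_raises(self):
        with pytest.raises(ValidationError):
            laxity(pd.DataFrame(columns=DOF_COLUMNS))


def test_rigid_pose_validates_rotation():
    with pytest.raises(ValidationError):
        RigidPose(np.eye(3) * 1.01, np.zeros(3))
    with pytest.raises(ValidationError):
        RigidPose(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
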