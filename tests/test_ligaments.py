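"""Nonlinear tensile law, reference-length algebra, actuator forces."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kneesim.errors import DegenerateGeometryError, ParameterError, ValidationError
from kneesim.frames import RigidPose
from kneesim.ligaments import (
    LigamentBundle,
    bundle_wrench,
    ligament_params_from_yaml,
    ligament_params_to_yaml,
    passive_quadriceps_force,
    strain,
    tensile_force,
    zero_load_length,
)


class TestStrainAndReferenceLength:
    @pytest.mark.parametrize(
        "L, L0, expected", [(50.0, 50.0, 0.0), (51.5, 50.0, 0.03), (45.0, 50.0, -0.10)]
    )
    def test_engineering_strain(self, L, L0, expected):
        assert strain(L, L0) == pytest.approx(expected, abs=1e-12)

    def test_invalid_zero_load_length_rejected(self):
        with pytest.raises(ValidationError):
            strain(50.0, 0.0)

    def test_zero_load_length_from_reference(self):
        # the default MCL reference strain of 0.04 maps 52 mm to 50 mm
        assert zero_load_length(52.0, 0.04) == pytest.approx(50.0, abs=1e-12)
        assert zero_load_length(77.7, 0.0) == pytest.approx(77.7)

    def test_reference_strain_below_minus_one_rejected(self):
        with pytest.raises(ValidationError):
            zero_load_length(50.0, -1.0)

    @given(
        Lr=st.floats(10.0, 300.0),
        eps_r=st.floats(-0.5, 0.5),
    )
    def test_closure_strain_at_reference_length_is_reference_strain(self, Lr, eps_r):
        assert strain(Lr, zero_load_length(Lr, eps_r)) == pytest.approx(eps_r, abs=1e-9)


class TestTensileForce:
    def test_slack_carries_no_force(self):
        assert tensile_force(-0.05, 400.0, 0.03) == 0.0

    def test_quadratic_toe_endpoint(self):
        # 0.25 * 400 * 0.06**2 / 0.03 at the toe/linear junction
        assert tensile_force(0.06, 400.0, 0.03) == pytest.approx(12.0, abs=1e-12)

    def test_linear_branch(self):
        assert tensile_force(0.10, 400.0, 0.03) == pytest.approx(28.0, abs=1e-12)

    @pytest.mark.parametrize("k", [50.0, 400.0, 6000.0, 25000.0])
    @pytest.mark.parametrize("eps_l", [0.01, 0.03, 0.08])
    def test_c0_and_c1_continuity_at_twice_linear_limit(self, k, eps_l):
        e = 2.0 * eps_l
        h = 1e-9
        below = tensile_force(e - h, k, eps_l)
        above = tensile_force(e + h, k, eps_l)
        assert abs(above - below) < 1e-4 * k  # C0
        d_below = (tensile_force(e - h, k, eps_l) - tensile_force(e - 3 * h, k, eps_l)) / (2 * h)
        d_above = (tensile_force(e + 3 * h, k, eps_l) - tensile_force(e + h, k, eps_l)) / (2 * h)
        assert d_below == pytest.approx(k, rel=1e-5)  # both slopes equal k
        assert d_above == pytest.approx(k, rel=1e-5)
        assert tensile_force(e, k, eps_l) == pytest.approx(k * eps_l, rel=1e-12)

    @given(
        eps=st.floats(-0.2, 0.5),
        deps=st.floats(1e-6, 0.1),
        k=st.floats(0.0, 1e4),
    )
    def test_monotone_nondecreasing_and_nonnegative(self, eps, deps, k):
        f0 = tensile_force(eps, k)
        f1 = tensile_force(eps + deps, k)
        assert f0 >= 0.0
        assert f1 >= f0

    def test_linear_in_stiffness_on_each_branch(self):
        for eps in (0.02, 0.10):
            assert tensile_force(eps, 800.0) == pytest.approx(2 * tensile_force(eps, 400.0))

    def test_invalid_linear_limit_rejected(self):
        with pytest.raises(ValidationError):
            tensile_force(0.05, 400.0, 0.0)


def _bundle(**kw):
    defaults = dict(
        name="test",
        ligament="MCL",
        origin_body="femur",
        insertion_body="tibia",
        origin_pt=(0.0, 0.0, 0.0),
        insertion_pt=(0.0, 0.0, -50.0),
        k=400.0,
        eps_r=0.04,
    )
    defaults.update(kw)
    return LigamentBundle(**defaults)


class TestBundleWrench:
    def test_slack_bundle_zero_pair(self):
        b = _bundle()
        b.set_reference_length(60.0)  # L0 ~ 57.7 > current 50
        fa, fb, info = bundle_wrench(b, RigidPose.identity(), RigidPose.identity())
        assert np.allclose(fa, 0) and np.allclose(fb, 0)
        assert info["strain"] < 0

    def test_taut_bundle_direction_convention(self):
        # insertion 56 mm above the origin along +z, L0 = 50 -> strain 0.12,
        # force 400*(0.12-0.03) = 36 N pulling the bodies together
        b = _bundle(insertion_pt=(0.0, 0.0, 56.0))
        b.L0 = 50.0
        fa, fb, info = bundle_wrench(b, RigidPose.identity(), RigidPose.identity())
        assert np.allclose(fa, [0, 0, 36.0], atol=1e-9)
        assert np.allclose(fb, [0, 0, -36.0], atol=1e-9)

    def test_action_reaction_over_random_configurations(self, rng):
        b = _bundle(insertion_pt=(5.0, -3.0, 45.0))
        b.set_reference_length(40.0)
        for _ in range(100):
            from scipy.spatial.transform import Rotation

            pa = RigidPose(
                Rotation.random(random_state=int(rng.integers(2**31))).as_matrix(),
                rng.uniform(-30, 30, 3),
            )
            pb = RigidPose(
                Rotation.random(random_state=int(rng.integers(2**31))).as_matrix(),
                rng.uniform(-30, 30, 3),
            )
            fa, fb, _ = bundle_wrench(b, pa, pb)
            assert np.allclose(fa + fb, 0.0, atol=1e-12)

    def test_coincident_attachments_degenerate(self):
        b = _bundle(insertion_pt=(0.0, 0.0, 0.0))
        b.L0 = 50.0
        with pytest.raises(DegenerateGeometryError):
            bundle_wrench(b, RigidPose.identity(), RigidPose.identity())

    def test_reference_length_fixes_zero_load_length(self):
        b = _bundle(eps_r=0.04)
        b.set_reference_length(52.0)
        assert b.L0 == pytest.approx(52.0 / 1.04, abs=1e-12)

    def test_invalid_parameters_name_the_bundle(self):
        with pytest.raises(ParameterError, match="test"):
            _bundle(k=-1.0)


class TestPassiveQuadriceps:
    def test_zero_elongation_returns_alpha(self):
        assert passive_quadriceps_force(0.0, 85.0, 0.05) == pytest.approx(85.0)

    def test_zero_alpha_is_zero(self):
        assert passive_quadriceps_force(123.0, 0.0, 0.05) == 0.0

    def test_monotone_increasing_for_positive_beta(self):
        grid = np.linspace(-20, 40, 50)
        vals = [passive_quadriceps_force(x, 85.0, 0.05) for x in grid]
        assert np.all(np.diff(vals) > 0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValidationError):
            passive_quadriceps_force(0.0, -1.0, 0.05)


def test_ligament_parameter_yaml_round_trip(tmp_path):
    bundles = [_bundle(name="a"), _bundle(name="b", k=650.0, eps_r=0.08, ligament="LCL")]
    path = tmp_path / "lig.yaml"
    ligament_params_to_yaml(bundles, path)
    back = ligament_params_from_yaml(path)
    assert [b.name for b in back] == ["a", "b"]
    assert back[1].k == 650.0 and back[1].eps_r == 0.08
    assert np.allclose(back[0].origin_pt, bundles[0].origin_pt)
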