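"""Settling, PID regulation, and the hip-driven squat cycle."""

import numpy as np
import pytest

from kneesim.errors import ValidationError
from kneesim.frames import laxity
from kneesim.simulator import (
    PidController,
    SquatProtocol,
    SquatTrace,
    equilibrium_settle,
    hip_height_for_flexion,
    pid_step,
    run_squat,
)


class TestPidController:
    def test_zero_error_zero_output(self):
        ctrl = PidController(kp=2.0, ki=1.0, kd=0.5, setpoint=90.0)
        assert pid_step(ctrl, 90.0, 0.1) == pytest.approx(0.0)

    def test_proportional_only_constant_error(self):
        ctrl = PidController(kp=3.0, setpoint=10.0)
        for _ in range(5):
            out = pid_step(ctrl, 8.0, 0.1)
            assert out == pytest.approx(3.0 * 2.0)

    def test_integral_antiwindup_respects_clamp(self):
        ctrl = PidController(ki=10.0, setpoint=100.0, output_min=-50.0, output_max=50.0)
        for _ in range(100):
            out = pid_step(ctrl, 0.0, 1.0)
        assert out == pytest.approx(50.0)
        assert ctrl.integral <= 50.0 / 10.0 + 1e-12

    def test_step_response_on_first_order_plant_reaches_setpoint(self):
        # plant: y' = (-y + 0.5 u) / tau, discretized; PI gains sized for it
        ctrl = PidController(kp=4.0, ki=8.0, setpoint=1.0, output_min=-100, output_max=100)
        y, dt, tau = 0.0, 0.01, 0.2
        for _ in range(600):
            u = pid_step(ctrl, y, dt)
            y += dt * (-y + 0.5 * u) / tau
        assert abs(y - 1.0) < 0.02

    def test_invalid_timestep(self):
        with pytest.raises(ValidationError):
            pid_step(PidController(), 0.0, 0.0)


class TestSettle:
    def test_settle_is_idempotent(self, settled_model):
        model = settled_model.copy()
        lr0 = {b.name: b.Lr for b in model.bundles}
        equilibrium_settle(model)
        assert max(abs(lr0[b.name] - b.Lr) for b in model.bundles) < 1e-9

    def test_strain_at_settled_pose_equals_reference_strain(self, settled_model):
        """Closure of the strain / zero-load-length relations at L = Lr."""
        for b in settled_model.bundles:
            eps = (b.Lr - b.L0) / b.L0
            assert eps == pytest.approx(b.eps_r, abs=1e-9)

    def test_net_vertical_force_on_femur_below_milli_newton(self, settled_model):
        from kneesim.simulator import _Configuration, _residual

        model = settled_model.copy()
        cfg = _Configuration(model)
        cfg.h = model.geometry["settle"]["hip_height"]
        cfg.theta = model.geometry["settle"]["femur_angle_rad"]
        r, _ = _residual(model, cfg, 0.0, {"hip_height": True}, skip_bodies=("patella",))
        assert abs(r[0]) < 1e-3

    def test_condyles_in_contact_after_settle(self, settled_model):
        assert settled_model.geometry["settle"]["contact_force"] > 0


class TestSquat:
    def test_requires_settled_model(self, default_model):
        with pytest.raises(ValidationError):
            run_squat(default_model.copy(), SquatProtocol(cycle_samples=5))

    def test_starts_at_start_flexion(self, short_trace):
        assert short_trace.data["FE"].iloc[0] == pytest.approx(35.0, abs=0.5)

    def test_flexion_reaches_depth_and_returns(self, short_trace):
        fe = short_trace.data["FE"]
        assert fe.max() == pytest.approx(90.0, abs=1.0)
        assert fe.iloc[-1] == pytest.approx(35.0, abs=0.5)

    def test_deterministic_bit_identical(self, settled_model, short_protocol):
        a = run_squat(settled_model.copy(), short_protocol)
        b = run_squat(settled_model.copy(), short_protocol)
        assert a.data.equals(b.data)

    def test_zero_drive_keeps_flexion_constant(self, settled_model):
        model = settled_model.copy()
        h35 = hip_height_for_flexion(model, 35.0)
        proto = SquatProtocol(cycle_samples=12, hip_profile=np.full(12, h35))
        trace = run_squat(model, proto)
        assert laxity(trace)["FE"] < 1.0

    def test_hip_tracking_rms_below_one_millimeter(self, settled_model, short_protocol, short_trace):
        h_ref = short_protocol.hip_heights(settled_model)
        disp_ref = h_ref - h_ref[0]
        err = short_trace.data["hip_disp"].to_numpy() - disp_ref
        assert np.sqrt(np.mean(err**2)) < 1.0

    def test_quadriceps_force_nonnegative(self, short_trace):
        assert (short_trace.data["F_quad"] >= 0).all()

    def test_rig_constraints_hold_by_construction(self, settled_model, rng):
        """The ankle eliminates AP and vertical displacement and the hip
        carriage eliminates lateral motion, for any free-DOF increment."""
        from kneesim.simulator import _Configuration

        cfg = _Configuration(settled_model)
        free = {"tibia": True, "patella": True, "femur_angle": True}
        for _ in range(20):
            cfg.apply(rng.normal(scale=0.01, size=11), free)
        poses = cfg.body_poses()
        ankle_world = poses["tibia"].transform_point([0.0, 0.0, 0.0])
        assert ankle_world[0] == 0.0  # anterior-posterior eliminated
        assert ankle_world[2] == 0.0  # vertical reaction point fixed
        hip_world = poses["carriage"].translation
        assert hip_world[0] == 0.0 and hip_world[1] == 0.0  # vertical slider

    def test_strains_finite_and_recorded_per_bundle(self, settled_model, short_trace):
        for b in settled_model.bundles:
            eps = short_trace.strain(b.name)
            assert np.all(np.isfinite(eps))
            assert len(eps) == short_trace.n_samples

    def test_solver_log_records_every_sample(self, settled_model, short_protocol):
        log = []
        run_squat(settled_model.copy(), short_protocol, log=log)
        assert len(log) == short_protocol.cycle_samples
        assert all("iterations" in entry and "residual" in entry for entry in log)

    def test_trace_csv_round_trip(self, short_trace, tmp_path):
        path = tmp_path / "trace.csv"
        short_trace.to_csv(path)
        back = SquatTrace.from_csv(path)
        assert list(back.data.columns) == list(short_trace.data.columns)
        assert np.allclose(back.data.to_numpy(), short_trace.data.to_numpy(), atol=1e-8)


class TestProtocol:
    def test_cyclic_flexion_targets(self):
        proto = SquatProtocol()
        targets = proto.flexion_targets()
        assert targets[0] == pytest.approx(proto.start_flexion)
        assert targets[-1] == pytest.approx(proto.start_flexion)
        assert targets.max() == pytest.approx(proto.max_flexion)

    def test_hip_heights_follow_two_link_closure(self, default_model):
        h0 = hip_height_for_flexion(default_model, 0.0)
        lf = default_model.geometry["femur_link_length"]
        lt = default_model.geometry["tibia_link_length"]
        assert h0 == pytest.approx(lf + lt)
        assert hip_height_for_flexion(default_model, 90.0) == pytest.approx(np.hypot(lf, lt))

    def test_validation(self):
        with pytest.raises(ValidationError):
            SquatProtocol(cycle_samples=1)
        with pytest.raises(ValidationError):
            SquatProtocol(start_flexion=90, max_flexion=35)
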