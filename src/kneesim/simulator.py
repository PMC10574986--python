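"""The virtual knee-joint simulator: hip-driven squat under quadriceps control.

The mechanism copies the physical rig: the femur hangs from a hip carriage
that can translate vertically and rotate in the sagittal plane; the tibia
is held at the ankle, which eliminates anterior-posterior (and vertical)
displacement while leaving medio-lateral translation and all rotations
free; the tibiofemoral and patellofemoral joints are governed purely by
compliant contact and the soft-tissue elements.  The vertical ankle
reaction is the "ankle load" the quadriceps PID regulates to its 90 N
setpoint while a PD loop tracks the prescribed hip-displacement profile.

The solver is quasi-static: at each discretized hip position the
unconstrained pose coordinates (femur sagittal angle; tibia rotations +
medio-lateral shift; full patellar pose - 11 DOF) are driven to static
equilibrium by a damped Newton iteration on the generalized force residual,
warm-started from the previous sample.  Contact damping is inactive along
this quasi-static path, which makes traces exactly reproducible.

Before any squat, :func:`equilibrium_settle` seats the femoral component in
the insert at full extension and fixes every bundle's reference length
(hence zero-load length) at that pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SettlingError, SimulationError, ValidationError
from .frames import DOF_COLUMNS, RigidPose, grood_suntay
from .ligaments import passive_quadriceps_force
from .model import CARRIAGE, KneeModel

_log = logging.getLogger(__name__)

_G_SCALE = 100.0  # mm; torque residuals are scaled to force units by this arm


@dataclass
class JointConstraints:
    """Descriptive record of the rig's joint constraints."""

    hip: str = "vertical translation + sagittal rotation"
    ankle: str = "3 rotations + medio-lateral translation free; AP and vertical eliminated"
    tibiofemoral: str = "unconstrained (contact + soft tissue)"
    patellofemoral: str = "unconstrained (contact + soft tissue)"


@dataclass
class PidController:
    """Discrete PID with clamped output and integral anti-windup."""

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0
    setpoint: float = 0.0
    output_min: float = -np.inf
    output_max: float = np.inf
    integral: float = 0.0
    prev_error: float | None = None

    def step(self, measured: float, dt: float) -> float:
        if dt <= 0:
            raise ValidationError("controller timestep must be positive")
        error = self.setpoint - measured
        derivative = 0.0 if self.prev_error is None else (error - self.prev_error) / dt
        self.prev_error = error
        self.integral += error * dt
        if self.ki > 0:  # anti-windup: keep the integral term inside the clamp
            bound = max(abs(self.output_min), abs(self.output_max))
            if np.isfinite(bound):
                self.integral = float(np.clip(self.integral, -bound / self.ki, bound / self.ki))
        out = self.kp * error + self.ki * self.integral + self.kd * derivative
        return float(np.clip(out, self.output_min, self.output_max))

    def reset(self) -> None:
        self.integral = 0.0
        self.prev_error = None


def pid_step(ctrl: PidController, measured: float, dt: float) -> float:
    """Advance ``ctrl`` one step against ``measured``; returns the output."""
    return ctrl.step(measured, dt)


@dataclass
class SquatProtocol:
    """One squat cycle: hip displacement profile and load setpoints.

    ``hip_profile`` (mm, absolute hip height per sample) is derived from the
    flexion trajectory ``start_flexion -> max_flexion -> start_flexion`` by
    two-link closure when not given explicitly.  The cycle is cyclic: it
    starts and ends at the start-flexion configuration.
    """

    start_flexion: float = 35.0
    max_flexion: float = 90.0
    ankle_load_setpoint: float = 90.0
    timestep: float = 0.1
    cycle_samples: int = 101
    hip_profile: np.ndarray | None = None
    quad_gains: tuple = (2.0, 18.0, 0.0)  # (kp, ki, kd) of the ankle-load PID
    hip_gain: float = 10.0  # 1/s, velocity-form PD tracking gain
    quad_force_max: float = 5000.0
    settle_substeps: int = 14  # continuation steps from full extension to start

    def __post_init__(self):
        if self.cycle_samples < 2:
            raise ValidationError("cycle_samples must be >= 2")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if not (0.0 < self.start_flexion < self.max_flexion <= 150.0):
            raise ValidationError("need 0 < start_flexion < max_flexion <= 150 deg")

    def flexion_targets(self) -> np.ndarray:
        s = np.linspace(0.0, 1.0, self.cycle_samples)
        return self.start_flexion + (self.max_flexion - self.start_flexion) * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * s)
        )

    def hip_heights(self, model: KneeModel) -> np.ndarray:
        if self.hip_profile is not None:
            return np.asarray(self.hip_profile, dtype=float)
        return np.array(
            [hip_height_for_flexion(model, phi) for phi in self.flexion_targets()]
        )


def hip_height_for_flexion(model: KneeModel, flexion_deg: float) -> float:
    """Two-link closure: hip height above the ankle at a given knee flexion."""
    lf = model.geometry["femur_link_length"]
    lt = model.geometry["tibia_link_length"]
    phi = np.deg2rad(flexion_deg)
    return float(np.sqrt(lf**2 + lt**2 + 2.0 * lf * lt * np.cos(phi)))


@dataclass
class SquatTrace:
    """Sampled squat cycle: kinematics, loads, per-bundle strains/forces."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def kinematics(self) -> pd.DataFrame:
        return self.data[DOF_COLUMNS]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def strain(self, bundle_name: str) -> np.ndarray:
        return self.data[f"eps_{bundle_name}"].to_numpy()

    def force(self, bundle_name: str) -> np.ndarray:
        return self.data[f"f_{bundle_name}"].to_numpy()

    def ligament_strain(self, model_or_names, ligament: str | None = None) -> np.ndarray:
        """Bundle-averaged strain series of one anatomical ligament."""
        if ligament is None:
            names = list(model_or_names)
        else:
            names = [b.name for b in model_or_names.bundles_of(ligament)]
        return np.mean([self.strain(n) for n in names], axis=0)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @staticmethod
    def from_csv(path, meta=None) -> "SquatTrace":
        return SquatTrace(pd.read_csv(path), meta or {})


# ---------------------------------------------------------------------------
# static mechanics


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        wx = _skew(w)
        return np.eye(3) + wx
    k = w / theta
    kx = _skew(k)
    return np.eye(3) + np.sin(theta) * kx + (1.0 - np.cos(theta)) * (kx @ kx)


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(R)
    return u @ vt


class _RawPose:
    """Validation-free rigid pose for the solver's hot path."""

    __slots__ = ("R", "t")

    def __init__(self, R, t):
        self.R = R
        self.t = t

    def transform_point(self, p):
        return self.R @ p + self.t

    def rotate_vector(self, v):
        return self.R @ v


def _cross(a, b):
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


class _Configuration:
    """Mutable mechanism configuration: femur angle/height, tibia, patella."""

    def __init__(self, model: KneeModel):
        g = model.geometry
        self.model = model
        self.hip_z0 = float(g["hip_z"])
        self.h = float(g["hip_z"])  # current hip height
        self.theta = 0.0  # femur sagittal angle, rad
        self.R_t = np.eye(3)
        self.y_ml = 0.0
        self.R_p = np.eye(3)
        self.t_p = np.asarray(g["patella_center0"], dtype=float).copy()

    def copy(self) -> "_Configuration":
        new = _Configuration.__new__(_Configuration)
        new.model = self.model
        new.hip_z0 = self.hip_z0
        new.h = self.h
        new.theta = self.theta
        new.R_t = self.R_t.copy()
        new.y_ml = self.y_ml
        new.R_p = self.R_p.copy()
        new.t_p = self.t_p.copy()
        return new

    # poses -----------------------------------------------------------------

    def hip_point(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.h])

    def femur_pose(self) -> RigidPose:
        c, s = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        hip0 = np.array([0.0, 0.0, self.hip_z0])
        return RigidPose(rot, self.hip_point() - rot @ hip0)

    def tibia_pose(self) -> RigidPose:
        return RigidPose(self.R_t, np.array([0.0, self.y_ml, 0.0]))

    def patella_pose(self) -> RigidPose:
        return RigidPose(self.R_p, self.t_p)

    def body_poses(self) -> dict:
        return {
            "femur": self.femur_pose(),
            "tibia": self.tibia_pose(),
            "patella": self.patella_pose(),
            CARRIAGE: RigidPose(np.eye(3), self.hip_point()),
        }

    def raw_poses(self, model) -> dict:
        """Validation-free world poses of bodies and implant components."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        rot_f = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        hip0 = np.array([0.0, 0.0, self.hip_z0])
        hip = self.hip_point()
        poses = {
            "femur": _RawPose(rot_f, hip - rot_f @ hip0),
            "tibia": _RawPose(self.R_t, np.array([0.0, self.y_ml, 0.0])),
            "patella": _RawPose(self.R_p, self.t_p),
            CARRIAGE: _RawPose(np.eye(3), hip),
        }
        for key, comp in model.implant.components().items():
            host = poses[comp.host]
            poses[key] = _RawPose(
                host.R @ comp.pose.rotation, host.R @ comp.pose.translation + host.t
            )
        return poses

    # DOF bookkeeping --------------------------------------------------------

    def apply(self, delta: np.ndarray, free: dict) -> None:
        i = 0
        if free.get("hip_height"):
            self.h += delta[i]
            i += 1
        if free.get("femur_angle"):
            self.theta += delta[i]
            i += 1
        if free.get("tibia"):
            self.R_t = _orthonormalize(_rodrigues(delta[i : i + 3]) @ self.R_t)
            self.y_ml += delta[i + 3]
            i += 4
        if free.get("patella"):
            self.t_p = self.t_p + delta[i : i + 3]
            self.R_p = _orthonormalize(_rodrigues(delta[i + 3 : i + 6]) @ self.R_p)
            i += 6


def _energy(model: KneeModel, cfg: _Configuration, quad_force: float, skip_bodies=()) -> float:
    """Total potential energy (N.mm) of the conservative static system.

    Bundle potentials integrate the piecewise tensile law; constant-tension
    actuators contribute force times length; contact stores the elastic
    penetration energy; gravity is weight times height.  The quadriceps
    tension is held fixed during a solve, so it too is conservative.
    """
    core = _get_core(model)
    out = core.evaluate(
        cfg, quad_force, skip_patella="patella" in skip_bodies, want_energy=True
    )
    return out["energy"]


_BODY_IDX = {"femur": 0, "tibia": 1, "patella": 2, CARRIAGE: 3}


class _ForceCore:
    """Vectorized force/energy evaluator built once per model state.

    Precomputes index arrays over every line element (passive bundles and
    actuator segments) so a residual evaluation is a handful of small numpy
    operations; invalidated (via ``token``) whenever bundle parameters,
    reference lengths, actuator constants or implant component poses change.
    """

    def __init__(self, model: KneeModel):
        self.model = model
        self.token = _core_token(model)
        bundles = model.bundles
        self.bundle_names = [b.name for b in bundles]
        self.nb = len(bundles)
        self.o_body = np.array([_BODY_IDX[b.origin_body] for b in bundles])
        self.i_body = np.array([_BODY_IDX[b.insertion_body] for b in bundles])
        self.o_pt = np.array([b.origin_pt for b in bundles]) if bundles else np.zeros((0, 3))
        self.i_pt = np.array([b.insertion_pt for b in bundles]) if bundles else np.zeros((0, 3))
        self.k = np.array([b.k for b in bundles])
        self.eps_l = np.array([b.eps_l for b in bundles])
        self.L0 = np.array([b.L0 if b.L0 is not None else np.nan for b in bundles])
        self.touches_patella = (self.o_body == 2) | (self.i_body == 2)

        segs = []
        for act in model.actuators:
            n = len(act.bundles)
            for body_a, pt_a, body_b, pt_b in act.bundles:
                segs.append(
                    (
                        _BODY_IDX[body_a],
                        np.asarray(pt_a, dtype=float),
                        _BODY_IDX[body_b],
                        np.asarray(pt_b, dtype=float),
                        act.kind == "quadriceps",
                        (1.0 / n) if act.kind == "quadriceps" else act.constant_force,
                    )
                )
        self.sa_body = np.array([s[0] for s in segs])
        self.sa_pt = np.array([s[1] for s in segs]) if segs else np.zeros((0, 3))
        self.sb_body = np.array([s[2] for s in segs])
        self.sb_pt = np.array([s[3] for s in segs]) if segs else np.zeros((0, 3))
        self.s_isquad = np.array([s[4] for s in segs])
        self.s_scale = np.array([s[5] for s in segs])
        self.s_touches_patella = (self.sa_body == 2) | (self.sb_body == 2)
        self.o_masks = [self.o_body == b for b in range(3)]
        self.i_masks = [self.i_body == b for b in range(3)]
        self.sa_masks = [self.sa_body == b for b in range(3)]
        self._mask_sets = {
            id(self.o_body): self.o_masks,
            id(self.i_body): self.i_masks,
            id(self.sa_body): self.sa_masks,
        }

        g = model.geometry
        self.masses = np.array([g["masses"]["femur"], g["masses"]["tibia"], g["masses"]["patella"]])
        self.coms = np.array(
            [g["coms"]["femur"], g["coms"]["tibia"], [0.0, 0.0, 0.0]]
        )
        self.gravity = g["gravity"]
        self.hip_z0 = float(g["hip_z"])
        comps = model.implant.components()
        self.comp_keys = list(comps)
        self.comp_host = [comps[k].host for k in self.comp_keys]
        self.comp_R = [comps[k].pose.rotation for k in self.comp_keys]
        self.comp_t = [comps[k].pose.translation for k in self.comp_keys]

    def frame_poses(self, cfg):
        c, s = np.cos(cfg.theta), np.sin(cfg.theta)
        rot_f = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        hip = np.array([0.0, 0.0, cfg.h])
        R = [rot_f, cfg.R_t, cfg.R_p, np.eye(3)]
        t = [
            hip - rot_f @ np.array([0.0, 0.0, self.hip_z0]),
            np.array([0.0, cfg.y_ml, 0.0]),
            cfg.t_p,
            hip,
        ]
        poses = {name: _RawPose(R[i], t[i]) for name, i in _BODY_IDX.items()}
        for key, host, cR, ct in zip(self.comp_keys, self.comp_host, self.comp_R, self.comp_t):
            hp = poses[host]
            poses[key] = _RawPose(hp.R @ cR, hp.R @ ct + hp.t)
        return R, t, poses

    def evaluate(self, cfg, quad_force, skip_patella=False, need_info=False, want_energy=False):
        """Net force/torque per body (+ optional info dict / potential energy)."""
        R, t, poses = self.frame_poses(cfg)
        Rb = np.stack(R)
        tb = np.stack(t)

        # world endpoints of passive bundles
        ow = np.einsum("nij,nj->ni", Rb[self.o_body], self.o_pt) + tb[self.o_body]
        iw = np.einsum("nij,nj->ni", Rb[self.i_body], self.i_pt) + tb[self.i_body]
        d = iw - ow
        L = np.sqrt((d * d).sum(axis=1))
        eps = (L - self.L0) / self.L0
        toe = 0.25 * self.k * eps * eps / self.eps_l
        lin = self.k * (eps - self.eps_l)
        f = np.where(eps <= 2.0 * self.eps_l, toe, lin)
        f = np.where(eps > 0.0, f, 0.0)
        f = np.where(np.isnan(self.L0), 0.0, f)
        active = np.ones(self.nb, dtype=bool)
        if skip_patella:
            active = ~self.touches_patella
        f_act = np.where(active, f, 0.0)
        fvec = (f_act / L)[:, None] * d  # force on origin body, toward insertion

        # actuator segments
        aw = np.einsum("nij,nj->ni", Rb[self.sa_body], self.sa_pt) + tb[self.sa_body]
        bw = np.einsum("nij,nj->ni", Rb[self.sb_body], self.sb_pt) + tb[self.sb_body]
        sd = bw - aw
        sL = np.sqrt((sd * sd).sum(axis=1))
        tension = np.where(self.s_isquad, self.s_scale * quad_force, self.s_scale)
        if skip_patella:
            tension = np.where(self.s_touches_patella, 0.0, tension)
        svec = (tension / sL)[:, None] * sd

        F = np.zeros((3, 3))
        T = np.zeros((3, 3))
        refs = np.array([[0.0, 0.0, cfg.h], [0.0, cfg.y_ml, 0.0], cfg.t_p])

        def add(body_idx_arr, pts, forces):
            masks = self._mask_sets[id(body_idx_arr)]
            for body in range(3):
                mask = masks[body]
                if not mask.any():
                    continue
                fb = forces[mask]
                F[body] += fb.sum(axis=0)
                arm = pts[mask] - refs[body]
                T[body, 0] += (arm[:, 1] * fb[:, 2] - arm[:, 2] * fb[:, 1]).sum()
                T[body, 1] += (arm[:, 2] * fb[:, 0] - arm[:, 0] * fb[:, 2]).sum()
                T[body, 2] += (arm[:, 0] * fb[:, 1] - arm[:, 1] * fb[:, 0]).sum()

        add(self.o_body, ow, fvec)
        add(self.i_body, iw, -fvec)
        add(self.sa_body, aw, svec)

        # contact
        model = self.model
        contacts = []
        energy_contact = 0.0
        for prim in model.contact_primitives:
            result = prim.evaluate(poses)
            if result is None:
                continue
            params = model.contact_params_for(prim.label)
            (body_a, body_b), depth, normal, point, _ = result
            mag = params.kc * depth**params.tau
            fa = mag * normal
            ia, ib = _BODY_IDX[body_a], _BODY_IDX[body_b]
            for body, force in ((ia, fa), (ib, -fa)):
                if body > 2:
                    continue
                F[body] += force
                arm = point - refs[body]
                T[body] += _cross(arm, force)
            contacts.append((prim.label, depth, mag))
            if want_energy:
                energy_contact += params.kc * depth ** (params.tau + 1.0) / (params.tau + 1.0)

        # gravity
        com_w = np.einsum("nij,nj->ni", Rb[:3], self.coms) + tb[:3]
        for body in range(3):
            w = np.array([0.0, 0.0, -self.masses[body] * self.gravity])
            F[body] += w
            T[body] += _cross(com_w[body] - refs[body], w)

        out = {"F": F, "T": T, "contacts": contacts}
        quad_mask = self.s_isquad
        out["quad_length"] = float(sL[quad_mask].mean()) if quad_mask.any() else 0.0
        if need_info:
            out["bundles"] = {
                name: (float(L[i]), float(eps[i]), float(f_act[i]))
                for i, name in enumerate(self.bundle_names)
            }
        if want_energy:
            E = 0.0
            epsc = np.clip(eps, 0.0, None)
            toe_e = self.k * self.L0 * epsc**3 / (12.0 * self.eps_l)
            lin_e = (2.0 / 3.0) * self.k * self.L0 * self.eps_l**2 + self.k * self.L0 * (
                0.5 * (epsc - self.eps_l) ** 2 - 0.5 * self.eps_l**2
            )
            eb = np.where(epsc <= 2.0 * self.eps_l, toe_e, lin_e)
            eb = np.where(np.isnan(self.L0) | ~active, 0.0, eb)
            E += float(eb.sum())
            E += float((tension * sL).sum())
            E += energy_contact
            E += float((self.masses * self.gravity * com_w[:, 2]).sum())
            out["energy"] = E
        return out


def _core_token(model: KneeModel) -> tuple:
    # cheap change-detection fingerprint: any mutation of bundle parameters,
    # reference lengths, actuator constants or component poses perturbs it
    sk = sl = 0.0
    for b in model.bundles:
        sk += b.k + 31.0 * b.eps_l
        sl += b.L0 if b.L0 is not None else -1.0
    sa = sum(a.constant_force + 7.0 * len(a.bundles) for a in model.actuators)
    sc = 0.0
    for comp in model.implant.components().values():
        sc += comp.pose.translation.sum() + comp.pose.rotation.trace() + comp.pose.rotation[0, 1]
    so = sum(p.kc + p.tau + p.Cc for p in getattr(model, "contact_overrides", {}).values())
    return (len(model.bundles), sk, sl, sa, sc, model.contact_params.kc, so)


def _get_core(model: KneeModel) -> _ForceCore:
    core = getattr(model, "_force_core", None)
    if core is None or core.token != _core_token(model):
        core = _ForceCore(model)
        model._force_core = core
    return core


def _unscale(free: dict, r: np.ndarray) -> np.ndarray:
    """Map the scaled residual back to generalized forces per solver unit."""
    factors = []
    for key in ("hip_height", "femur_angle", "tibia", "patella"):
        if free.get(key):
            if key == "hip_height":
                factors += [1.0]
            elif key == "femur_angle":
                factors += [_G_SCALE]
            elif key == "tibia":
                factors += [_G_SCALE] * 3 + [1.0]
            else:
                factors += [1.0] * 3 + [_G_SCALE] * 3
    return r * np.asarray(factors)


def _residual(
    model: KneeModel,
    cfg: _Configuration,
    quad_force: float,
    free: dict,
    skip_bodies=(),
    need_info: bool = False,
):
    core = _get_core(model)
    out = core.evaluate(
        cfg, quad_force, skip_patella="patella" in skip_bodies, need_info=need_info
    )
    F, T = out["F"], out["T"]
    r = []
    if free.get("hip_height"):
        r.append(F[0, 2])
    if free.get("femur_angle"):
        r.append(T[0, 1] / _G_SCALE)
    if free.get("tibia"):
        r.extend(T[1] / _G_SCALE)
        r.append(F[1, 1])
    if free.get("patella"):
        r.extend(F[2])
        r.extend(T[2] / _G_SCALE)
    info = {
        "contacts": out["contacts"],
        "quad_length": out["quad_length"],
        "ankle_load": -F[1, 2],
        "net_forces": {"femur": F[0], "tibia": F[1], "patella": F[2]},
    }
    if need_info:
        info["bundles"] = out["bundles"]
    return np.array(r), info


_STEP_SIZES = {
    "hip_height": 1e-6,
    "femur_angle": 1e-8,
    "tibia": [1e-8, 1e-8, 1e-8, 1e-6],
    "patella": [1e-6] * 3 + [1e-8] * 3,
}

_STEP_CAPS = {
    "hip_height": 1.5,
    "femur_angle": 0.05,
    "tibia": [0.05, 0.05, 0.05, 1.5],
    "patella": [3.0] * 3 + [0.15] * 3,
}


def _fd_steps(free: dict) -> np.ndarray:
    out = []
    for key in ("hip_height", "femur_angle", "tibia", "patella"):
        if free.get(key):
            v = _STEP_SIZES[key]
            out.extend(v if isinstance(v, list) else [v])
    return np.array(out)


def _step_caps(free: dict) -> np.ndarray:
    out = []
    for key in ("hip_height", "femur_angle", "tibia", "patella"):
        if free.get(key):
            v = _STEP_CAPS[key]
            out.extend(v if isinstance(v, list) else [v])
    return np.array(out)


def _adopt(cfg: _Configuration, other: _Configuration) -> None:
    cfg.h, cfg.theta = other.h, other.theta
    cfg.R_t, cfg.y_ml = other.R_t, other.y_ml
    cfg.R_p, cfg.t_p = other.R_p, other.t_p


def _descent_phase(
    model: KneeModel,
    cfg: _Configuration,
    quad_force: float,
    free: dict,
    caps: np.ndarray,
    rounds: int = 60,
    rel_tol: float = 1e-12,
    skip_bodies=(),
) -> bool:
    """Minimize the potential energy by recentered box-bounded L-BFGS-B.

    Gradients use the analytic generalized forces (exact at the box center,
    first-order in the exponential-map increment elsewhere); each round
    recenters the parametrization at the current best configuration.
    Returns True when the configuration moved.
    """
    from scipy.optimize import minimize as _minimize

    n = len(caps)
    e0 = _energy(model, cfg, quad_force, skip_bodies)
    moved = False
    for _ in range(rounds):
        center = cfg.copy()

        def fun(delta):
            trial = center.copy()
            trial.apply(delta, free)
            e = _energy(model, trial, quad_force, skip_bodies)
            r, _ = _residual(model, trial, quad_force, free, skip_bodies)
            return e, -_unscale(free, r)

        res = _minimize(
            fun,
            np.zeros(n),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-c, c) for c in caps],
            options={"maxiter": 40, "ftol": 1e-14, "gtol": 1e-9},
        )
        trial = center.copy()
        trial.apply(res.x, free)
        e1 = _energy(model, trial, quad_force, skip_bodies)
        if e1 < e0 - max(abs(e0) * rel_tol, 1e-10):
            _adopt(cfg, trial)
            moved = True
            if np.max(np.abs(res.x) / caps) < 0.5:
                break  # interior minimum: hand back to Newton
            e0 = e1
        else:
            break
    return moved


def solve_equilibrium(
    model: KneeModel,
    cfg: _Configuration,
    quad_force: float,
    free: dict,
    tol: float = 1e-6,
    max_iter: int = 200,
    skip_bodies=(),
    cold: bool = True,
    jac_cache: dict | None = None,
):
    """Drive the free pose coordinates of ``cfg`` to static equilibrium.

    Strategy: when far from equilibrium, first a block Gauss-Seidel sweep
    (patella subsystem, then the bone linkage) plus a descent on the exact
    potential energy (globally robust, crosses the flat valleys left by
    slack bundles); then a damped Levenberg-Marquardt polish on the
    generalized-force residual.  Convergence requires the scaled residual
    max-norm below ``tol`` (N, or N at a 100 mm arm for torques).
    Returns ``(info, iterations)``; raises :class:`SettlingError` otherwise.
    """
    steps = _fd_steps(free)
    caps = _step_caps(free)
    n = len(steps)
    r, info = _residual(model, cfg, quad_force, free, skip_bodies)
    norm_inf = np.max(np.abs(r)) if n else 0.0

    blocks = [k for k in ("hip_height", "femur_angle", "tibia") if free.get(k)]
    # the pre-passes are for cold starts; warm-started samples go straight to LM
    if cold and free.get("patella") and blocks and norm_inf > 25.0:
        bones_free = {k: True for k in blocks}
        for _ in range(8):
            sub_tol = float(np.clip(norm_inf * 0.02, tol, 1.0))
            for sub_free in ({"patella": True}, bones_free):
                try:
                    solve_equilibrium(
                        model, cfg, quad_force, sub_free,
                        tol=sub_tol, max_iter=80, skip_bodies=skip_bodies,
                    )
                except SettlingError:
                    pass
            r, info = _residual(model, cfg, quad_force, free, skip_bodies)
            norm_new = np.max(np.abs(r))
            if norm_new < 50 * tol or norm_new > 0.7 * norm_inf:
                norm_inf = norm_new
                break
            norm_inf = norm_new

    if cold and norm_inf > 25.0:
        if _descent_phase(model, cfg, quad_force, free, caps, skip_bodies=skip_bodies):
            r, info = _residual(model, cfg, quad_force, free, skip_bodies)
            norm_inf = np.max(np.abs(r))
    merit = float(r @ r)
    lam = 1e-8
    slow = 0
    J = None
    j_age = 0
    if jac_cache is not None and jac_cache.get("n") == n:
        J = jac_cache.get("J")
        j_age = 1  # borrowed from the previous sample; refresh on rejection
    for it in range(max_iter):
        if norm_inf < tol:
            _, info = _residual(model, cfg, quad_force, free, skip_bodies, need_info=True)
            info["iterations"] = it
            info["residual"] = float(norm_inf)
            if jac_cache is not None and J is not None:
                jac_cache["J"], jac_cache["n"] = J, n
            return info, it
        if J is None or j_age >= 4:
            J = np.empty((len(r), n))
            for k in range(n):
                dq = np.zeros(n)
                dq[k] = steps[k]
                plus = cfg.copy()
                plus.apply(dq, free)
                minus = cfg.copy()
                minus.apply(-dq, free)
                rp, _ = _residual(model, plus, quad_force, free, skip_bodies)
                rm, _ = _residual(model, minus, quad_force, free, skip_bodies)
                J[:, k] = (rp - rm) / (2.0 * steps[k])
            j_age = 0
        jtj = J.T @ J
        jtr = J.T @ r
        accepted = False
        for _ in range(18):
            A = jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-8))
            try:
                delta = np.linalg.solve(A, -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            delta = np.clip(delta, -caps, caps)
            trial = cfg.copy()
            trial.apply(delta, free)
            r_new, info_new = _residual(model, trial, quad_force, free, skip_bodies)
            merit_new = float(r_new @ r_new)
            if merit_new < merit:
                slow = slow + 1 if merit_new > 0.9 * merit else 0
                _adopt(cfg, trial)
                r, info = r_new, info_new
                merit, norm_inf = merit_new, np.max(np.abs(r_new))
                lam = max(lam * 0.1, 1e-10)
                accepted = True
                j_age += 1
                break
            if j_age > 0:
                j_age = 3  # stale Jacobian rejected a step: force a refresh
                break
            lam *= 10.0
        if accepted and j_age >= 3 and norm_inf > tol:
            continue
        if not accepted and j_age >= 3:
            J = None
            continue
        if accepted and slow >= 4 and norm_inf > 10 * tol:
            accepted = False  # crawling: hand over to the energy descent
            slow = 0
        if not accepted:
            # flat-valley rescue: descend the exact potential energy inside a
            # recentered trust box (handles a slack bundle about to engage)
            if _descent_phase(model, cfg, quad_force, free, caps, skip_bodies=skip_bodies):
                r, info = _residual(model, cfg, quad_force, free, skip_bodies)
                merit, norm_inf = float(r @ r), np.max(np.abs(r))
                lam = 1e-4
                accepted = True
        if not accepted:
            break
    if norm_inf < tol:
        _, info = _residual(model, cfg, quad_force, free, skip_bodies, need_info=True)
        info["iterations"] = max_iter
        info["residual"] = float(norm_inf)
        if jac_cache is not None and J is not None:
            jac_cache["J"], jac_cache["n"] = J, n
        return info, max_iter
    raise SettlingError("static equilibrium iteration did not converge", float(norm_inf))


# ---------------------------------------------------------------------------
# settling


def equilibrium_settle(
    model: KneeModel,
    tol: float = 1e-8,
    max_rounds: int = 40,
    lr_tol: float = 1e-11,
) -> dict:
    """Seat the femoral component at full extension and fix reference lengths.

    The tibia is held at its generated pose and the patella at its generated
    seat; the femur (hip height + sagittal angle) settles under gravity and
    contact.  Each bundle's reference length ``Lr`` is then the attachment
    distance at the settled pose and its zero-load length follows from the
    reference strain; because referencing changes the ligament loads, the
    settle/re-measure pair is iterated to a fixed point (|dLr| < 1 nm).

    Mutates ``model`` (bundle ``Lr``/``L0``, quadriceps reference length,
    ``geometry['settle']``) and returns a report with the settled pose.
    """
    free = {"hip_height": True, "femur_angle": True}
    cfg = _Configuration(model)
    cfg.h -= 0.1  # pre-load the contact so the touchdown Jacobian is non-degenerate
    last_info = None
    for round_ in range(max_rounds):
        info, _ = solve_equilibrium(
            model, cfg, quad_force=0.0, free=free, tol=tol, skip_bodies=("patella",)
        )
        poses = cfg.body_poses()
        max_change = 0.0
        for b in model.bundles:
            L = b.current_length(poses[b.origin_body], poses[b.insertion_body])
            if b.Lr is not None:
                max_change = max(max_change, abs(L - b.Lr))
            else:
                max_change = np.inf
            b.set_reference_length(L)
        last_info = info
        if max_change < lr_tol:
            break
    else:
        raise SettlingError("reference lengths did not reach a fixed point", max_change)

    # quadriceps reference (elongation zero at settle)
    quad = model.actuator("quadriceps")
    lengths = []
    for body_a, pt_a, body_b, pt_b in quad.bundles:
        a = poses[body_a].transform_point(pt_a)
        bb = poses[body_b].transform_point(pt_b)
        lengths.append(float(np.linalg.norm(bb - a)))
    quad.reference_length = float(np.mean(lengths))

    total_contact = sum(f for _, _, f in last_info["contacts"])
    if total_contact <= 0:
        raise SettlingError("femoral component not seated (no tibiofemoral contact)", 0.0)

    model.geometry["settle"] = {
        "hip_height": float(cfg.h),
        "femur_angle_rad": float(cfg.theta),
        "residual": last_info["residual"],
        "rounds": round_ + 1,
        "contact_force": float(total_contact),
    }
    return {
        "config": cfg,
        "info": last_info,
        "hip_height": float(cfg.h),
        "Lr": {b.name: b.Lr for b in model.bundles},
    }


def is_settled(model: KneeModel) -> bool:
    return all(b.Lr is not None for b in model.bundles) and "settle" in model.geometry


# ---------------------------------------------------------------------------
# squat


def _ik_predict(model: KneeModel, cfg: _Configuration, h_new: float) -> None:
    """Move the configuration to a two-link prediction at hip height ``h_new``.

    The tibia/femur increments follow planar closure (knee buckling
    anteriorly); the patella is carried along with the femur's rigid motion
    so it stays seated on the trochlea.
    """
    lf = model.geometry["femur_link_length"]
    lt = model.geometry["tibia_link_length"]

    def angles(h):
        cos_phi = np.clip((h * h - lf * lf - lt * lt) / (2.0 * lf * lt), -1.0, 1.0)
        phi = np.arccos(cos_phi)  # interior flexion
        psi = np.arcsin(np.clip(lf * np.sin(phi) / max(h, 1e-9), -1.0, 1.0))
        theta = -np.arcsin(np.clip(lt * np.sin(psi) / lf, -1.0, 1.0))
        return psi, theta

    psi_old, theta_old = angles(cfg.h)
    psi_new, theta_new = angles(h_new)

    # femur incremental motion (rotation about the hip + hip translation)
    d_theta = theta_new - theta_old
    c, s = np.cos(d_theta), np.sin(d_theta)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    hip_old = cfg.hip_point()
    hip_new = np.array([0.0, 0.0, h_new])

    # patella rides with the femur
    cfg.t_p = rot @ (cfg.t_p - hip_old) + hip_new
    cfg.R_p = _orthonormalize(rot @ cfg.R_p)

    cfg.h = h_new
    cfg.theta += d_theta
    d_psi = psi_new - psi_old
    c, s = np.cos(d_psi), np.sin(d_psi)
    cfg.R_t = _orthonormalize(np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]]) @ cfg.R_t)


def _replay_step(cfg: _Configuration, prev: _Configuration, prev2: _Configuration, h_new: float) -> None:
    """Warm-start predictor: replay the previous solved motion increment.

    The increment prev2 -> prev is scaled to the new hip-height step and
    reapplied, which captures the contact-compliant solution path to first
    order (the pure two-link prediction cannot); the hip height is then
    pinned to the prescribed value.
    """
    from scipy.spatial.transform import Rotation as _Rot

    dh_prev = prev.h - prev2.h
    s = (h_new - prev.h) / dh_prev if abs(dh_prev) > 1e-9 else 0.0
    s = float(np.clip(s, -2.5, 2.5))
    cfg.theta = prev.theta + s * (prev.theta - prev2.theta)
    w_t = _Rot.from_matrix(prev.R_t @ prev2.R_t.T).as_rotvec()
    cfg.R_t = _orthonormalize(_rodrigues(s * w_t) @ prev.R_t)
    cfg.y_ml = prev.y_ml + s * (prev.y_ml - prev2.y_ml)
    w_p = _Rot.from_matrix(prev.R_p @ prev2.R_p.T).as_rotvec()
    cfg.R_p = _orthonormalize(_rodrigues(s * w_p) @ prev.R_p)
    cfg.t_p = prev.t_p + s * (prev.t_p - prev2.t_p)
    cfg.h = h_new


def _goto_start(model, protocol, cfg, free, tol) -> None:
    """Continuation from the settled full-extension pose to start flexion."""
    h_start = protocol.hip_heights(model)[0]
    h0 = cfg.h
    quad = model.actuator("quadriceps")
    cache: dict = {}
    # seat the patella first: released from its generated hold, it slides up
    # the trochlea until the patellar ligament engages (a long flat valley
    # best crossed by the energy descent on the isolated subsystem)
    _, probe0 = _residual(model, cfg, 0.0, free)
    fq0 = passive_quadriceps_force(
        probe0["quad_length"] - quad.reference_length, quad.alpha, quad.beta
    ) + quad.preload
    solve_equilibrium(model, cfg, fq0, {"patella": True}, tol=tol)
    for k in range(1, protocol.settle_substeps + 1):
        frac = k / protocol.settle_substeps
        h_k = h0 + (h_start - h0) * (np.sin(0.5 * np.pi * frac)) ** 2 * 1.0
        _ik_predict(model, cfg, h_k)
        _, info_probe = _residual(model, cfg, 0.0, free)
        fq = passive_quadriceps_force(
            info_probe["quad_length"] - quad.reference_length, quad.alpha, quad.beta
        ) + quad.preload
        solve_equilibrium(model, cfg, fq, free, tol=tol, jac_cache=cache)


def run_squat(
    model: KneeModel,
    protocol: SquatProtocol | None = None,
    tol: float = 1e-5,
    log: list | None = None,
) -> SquatTrace:
    """Simulate one squat cycle; returns the sampled :class:`SquatTrace`.

    Requires a settled model (reference lengths fixed).  Deterministic:
    identical model + protocol give bit-identical traces.
    """
    if not is_settled(model):
        raise ValidationError("model must be settled (run equilibrium_settle first)")
    protocol = protocol or SquatProtocol()
    free = {"tibia": True, "patella": True, "femur_angle": True}

    cfg = _Configuration(model)
    cfg.h = model.geometry["settle"]["hip_height"]
    cfg.theta = model.geometry["settle"]["femur_angle_rad"]

    try:
        _goto_start(model, protocol, cfg, free, tol)
    except SettlingError as exc:
        if exc.residual >= 1e-2:
            raise SimulationError(f"continuation to start flexion failed: {exc}", -1) from exc
        _log.warning("continuation accepted at residual %.1e N", exc.residual)

    quad = model.actuator("quadriceps")
    kp, ki, kd = protocol.quad_gains
    pid = PidController(
        kp=kp,
        ki=ki,
        kd=kd,
        setpoint=protocol.ankle_load_setpoint,
        output_min=-protocol.quad_force_max,
        output_max=protocol.quad_force_max,
    )

    h_ref = protocol.hip_heights(model)
    if len(h_ref) != protocol.cycle_samples:
        raise ValidationError("hip_profile length must equal cycle_samples")
    dt = protocol.timestep
    femur_frame = model.bodies["femur"].anatomical_frame
    tibia_frame = model.bodies["tibia"].anatomical_frame

    jac_cache: dict = {}
    prev_cfg = None
    prev2_cfg = None
    # prime the loop with the ankle load at the start pose
    _, info = _residual(model, cfg, 0.0, free)
    measured = info["ankle_load"]
    h_sim = cfg.h
    e_prev = 0.0

    rows = []
    for k in range(protocol.cycle_samples):
        # hip PD tracking (velocity form)
        e = h_ref[k] - h_sim
        gain = min(protocol.hip_gain, 1.0 / dt)  # deadbeat at most
        h_prev = h_sim
        h_sim = h_sim + dt * gain * e
        e_prev = e

        # quadriceps force per the tendon-force law: passive + PID + preload
        _, probe = _residual(model, cfg, 0.0, free)
        passive = passive_quadriceps_force(
            probe["quad_length"] - quad.reference_length, quad.alpha, quad.beta
        )
        u = pid.step(measured, dt)
        fq = float(np.clip(passive + u + quad.preload, 0.0, protocol.quad_force_max))

        # bound the equilibrium-continuation step: coarse cycle grids are
        # split into hip-displacement substeps of at most ~4 mm
        n_sub = max(1, int(np.ceil(abs(h_sim - h_prev) / 4.0)))
        iters = 0
        info = None
        for s in range(1, n_sub + 1):
            h_s = h_prev + (h_sim - h_prev) * s / n_sub
            if prev_cfg is not None and prev2_cfg is not None:
                _replay_step(cfg, prev_cfg, prev2_cfg, h_s)
            else:
                _ik_predict(model, cfg, h_s)
            try:
                info, it_s = solve_equilibrium(
                    model, cfg, fq, free, tol=tol, cold=False, jac_cache=jac_cache
                )
            except SettlingError:
                try:  # one cold retry with the full pre-pass machinery
                    info, it_s = solve_equilibrium(model, cfg, fq, free, tol=tol, cold=True)
                except SettlingError as exc:
                    # a sub-centinewton residual is mechanically negligible at
                    # the trace's resolution: keep it, but record the sample
                    if exc.residual < 1e-2:
                        _log.warning("sample %d accepted at residual %.1e N", k, exc.residual)
                        _, info = _residual(model, cfg, fq, free, need_info=True)
                        info["residual"] = exc.residual
                        it_s = -1
                    else:
                        raise SimulationError(f"solver diverged: {exc}", k) from exc
            iters += it_s
        deepest = max((d for _, d, _ in info["contacts"]), default=0.0)
        if deepest > 5.0:
            raise SimulationError(f"contact penetration {deepest:.2f} mm exceeds 5 mm", k)
            prev2_cfg = prev_cfg
            prev_cfg = cfg.copy()
        measured = info["ankle_load"]

        jk = grood_suntay(cfg.femur_pose(), cfg.tibia_pose(), femur_frame, tibia_frame)
        row = {
            "t": k * dt,
            "FE": jk.FE,
            "VV": jk.VV,
            "IE": jk.IE,
            "AP": jk.AP,
            "ML": jk.ML,
            "IS": jk.IS,
            "F_ankle": measured,
            "F_quad": fq,
            "hip_disp": h_sim - h_ref[0],
        }
        for name, (L, eps, f) in info["bundles"].items():
            row[f"eps_{name}"] = eps
            row[f"f_{name}"] = f
        rows.append(row)
        if log is not None:
            log.append(
                {
                    "sample": k,
                    "iterations": iters,
                    "residual": info["residual"],
                    "ankle_load": measured,
                    "quad_force": fq,
                    "max_penetration": deepest,
                }
            )

    data = pd.DataFrame(rows)
    meta = {
        "setpoint": protocol.ankle_load_setpoint,
        "start_flexion": protocol.start_flexion,
        "max_flexion": protocol.max_flexion,
        "cycle_samples": protocol.cycle_samples,
        "timestep": protocol.timestep,
    }
    return SquatTrace(data, meta)
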