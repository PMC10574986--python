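"""Compliant normal contact between interfacing joint surfaces.

The normal force follows a penetration law ``F = kc * depth**tau + Cc *
depth_rate`` (stiffness 5000 N/mm, exponent 2.2, damping 10 N.s/mm by
default), applied as an equal-and-opposite pair along the contact normal.
Contact geometry is resolved analytically on the model's primitives:
condyle spheres seated in spherical insert dishes, a cam/post capsule
pair, and the patellar sphere riding on the trochlear cylinder.  No
friction is modeled; the law is purely normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError

#: depth over which the damping term is smoothly ramped in at touchdown, mm
DAMPING_RAMP_DEPTH = 0.01


@dataclass(frozen=True)
class ContactParams:
    """Penetration-law constants: stiffness (N/mm), exponent, damping (N.s/mm)."""

    kc: float = 5000.0
    tau: float = 2.2
    Cc: float = 10.0

    def __post_init__(self):
        if self.kc <= 0:
            raise ParameterError("kc", "contact stiffness must be positive")
        if self.tau < 1:
            raise ParameterError("tau", "contact exponent must be >= 1")
        if self.Cc < 0:
            raise ParameterError("Cc", "contact damping must be non-negative")


@dataclass(frozen=True)
class ContactPatch:
    """One interpenetrating primitive pair.

    ``depth`` is the maximum interpenetration (mm, >= 0), ``rate`` its time
    derivative (mm/s, positive = deepening), ``normal`` the unit direction
    along which the first body of ``pair`` is pushed, and ``point`` the
    world-frame location of the patch (mm).
    """

    pair: tuple
    depth: float
    rate: float
    normal: np.ndarray
    point: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.depth < 0:
            raise ValidationError("penetration depth must be non-negative")
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValidationError("contact normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))


# ---------------------------------------------------------------------------
# analytic primitives


@dataclass(frozen=True)
class SphereInDish:
    """Convex sphere seated in a concave spherical dish (dish radius larger).

    Penetration = |centers distance| + sphere radius - dish radius.
    """

    label: str
    sphere_frame: str
    sphere_body: str
    sphere_center: tuple
    sphere_radius: float
    dish_frame: str
    dish_body: str
    dish_center: tuple  # center of curvature, local frame
    dish_radius: float

    def evaluate(self, poses):
        cs = poses[self.sphere_frame].transform_point(self.sphere_center)
        cd = poses[self.dish_frame].transform_point(self.dish_center)
        d = cs - cd
        dist = float(np.linalg.norm(d))
        depth = dist + self.sphere_radius - self.dish_radius
        if depth <= 0 or dist < 1e-12:
            return None
        u = d / dist
        # force pushes the sphere back toward the dish curvature center
        point = cd + u * 0.5 * (dist + self.sphere_radius + self.dish_radius)
        return (self.sphere_body, self.dish_body), depth, -u, point, (cs, cd)


def _segment_closest_points(p0, p1, q0, q1):
    """Closest points between segments [p0,p1] and [q0,q1]."""
    u = p1 - p0
    v = q1 - q0
    w0 = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-project s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return p0 + s * u, q0 + t * v


@dataclass(frozen=True)
class CapsulePair:
    """External contact between two capsules (cam vs post)."""

    label: str
    frame_a: str
    body_a: str
    seg_a: tuple  # ((x,y,z), (x,y,z)) local endpoints
    radius_a: float
    frame_b: str
    body_b: str
    seg_b: tuple
    radius_b: float

    def evaluate(self, poses):
        pa = poses[self.frame_a]
        pb = poses[self.frame_b]
        a0 = pa.transform_point(self.seg_a[0])
        a1 = pa.transform_point(self.seg_a[1])
        b0 = pb.transform_point(self.seg_b[0])
        b1 = pb.transform_point(self.seg_b[1])
        ca, cb = _segment_closest_points(np.asarray(a0), np.asarray(a1), np.asarray(b0), np.asarray(b1))
        d = ca - cb
        dist = float(np.linalg.norm(d))
        depth = self.radius_a + self.radius_b - dist
        if depth <= 0 or dist < 1e-12:
            return None
        u = d / dist  # pushes body_a away from body_b
        point = cb + u * (self.radius_b - 0.5 * depth)
        return (self.body_a, self.body_b), depth, u, point, (ca, cb)


@dataclass(frozen=True)
class SphereOnCylinder:
    """Convex sphere riding on the outside of a cylinder (patella on trochlea)."""

    label: str
    sphere_frame: str
    sphere_body: str
    sphere_center: tuple
    sphere_radius: float
    cyl_frame: str
    cyl_body: str
    cyl_point: tuple  # a point on the axis, local
    cyl_axis: tuple  # unit axis direction, local
    cyl_radius: float

    def evaluate(self, poses):
        cs = poses[self.sphere_frame].transform_point(self.sphere_center)
        p = poses[self.cyl_frame].transform_point(self.cyl_point)
        axis = poses[self.cyl_frame].rotate_vector(self.cyl_axis)
        axis = axis / np.linalg.norm(axis)
        w = cs - p
        radial = w - (w @ axis) * axis
        dist = float(np.linalg.norm(radial))
        depth = self.cyl_radius + self.sphere_radius - dist
        if depth <= 0 or dist < 1e-12:
            return None
        u = radial / dist  # pushes the sphere radially outward
        foot = p + (w @ axis) * axis
        point = foot + u * (self.cyl_radius - 0.5 * depth)
        return (self.sphere_body, self.cyl_body), depth, u, point, (cs, foot)


# ---------------------------------------------------------------------------


def _point_velocity(frame, point, velocities):
    if velocities is None or frame not in velocities:
        return np.zeros(3)
    v, w, ref = velocities[frame]
    return np.asarray(v, dtype=float) + np.cross(np.asarray(w, dtype=float), point - ref)


def detect_contacts(primitives, poses, velocities=None):
    """Evaluate all primitive pairs; one :class:`ContactPatch` per overlap.

    ``poses`` maps frame keys to world :class:`RigidPose`; ``velocities``
    optionally maps frame keys to ``(v, omega, ref_point)`` for the overlap
    rate (zero when omitted, as in the quasi-static solver).
    """
    patches = []
    for prim in primitives:
        result = prim.evaluate(poses)
        if result is None:
            continue
        pair, depth, normal, point, witnesses = result
        rate = 0.0
        if velocities is not None:
            frame_a = getattr(prim, "sphere_frame", getattr(prim, "frame_a", None))
            frame_b = getattr(prim, "dish_frame", getattr(prim, "cyl_frame", getattr(prim, "frame_b", None)))
            va = _point_velocity(frame_a, point, velocities)
            vb = _point_velocity(frame_b, point, velocities)
            # deepening when the relative motion of body a opposes its push-out normal
            rate = float(-(va - vb) @ normal)
        patches.append(
            ContactPatch(pair=pair, depth=depth, rate=rate, normal=normal, point=point, label=prim.label)
        )
    return patches


def contact_force(patch: ContactPatch, params: ContactParams, damping_ramp: float = 0.0):
    """Force pair for one patch: ``(force_on_first, force_on_second)`` in N.

    The elastic term is ``kc * depth**tau``; the damping term ``Cc * rate``
    is optionally ramped in smoothly over ``damping_ramp`` mm of penetration
    to avoid a force discontinuity at touchdown.  The total magnitude is
    clamped at zero from below (no adhesion).
    """
    ramp = 1.0
    if damping_ramp > 0:
        ramp = min(1.0, patch.depth / damping_ramp)
    magnitude = params.kc * patch.depth**params.tau + ramp * params.Cc * patch.rate
    magnitude = max(0.0, float(magnitude))
    f = magnitude * patch.normal
    return f, -f
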