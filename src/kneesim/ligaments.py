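"""Nonlinear ligament bundles and tendon actuators.

Passive bundles follow the Blankevoort piecewise tensile law: zero force
when slack, a quadratic toe region up to twice the linear strain limit
``eps_l`` (default 0.03), then a linear region of stiffness ``k``.  Because
strain is dimensionless, ``k`` carries units of force (N).  The zero-load
length derives from a reference length ``Lr`` (measured at a settled
full-extension pose) and a reference strain ``eps_r``::

    L0 = Lr / (eps_r + 1)

so a bundle held at its reference length carries strain exactly ``eps_r``.

Muscle-tendon actuators are straight-line force elements: the quadriceps
passive component is ``alpha * exp(beta * Quadlength)`` with ``Quadlength``
the tendon elongation (mm) relative to its settled reference, and the
hamstrings are constant-force springs (50 N default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import DegenerateGeometryError, ParameterError, ValidationError

#: linear strain limit of the tensile law
DEFAULT_LINEAR_STRAIN_LIMIT = 0.03

#: default per-side hamstring constant force, N
DEFAULT_HAMSTRING_FORCE = 50.0

#: literature reference strains and stiffnesses (N) used to initialize the
#: default model; per multi-bundle ligament the stiffness is per bundle.
DEFAULT_LIGAMENT_PARAMS = {
    "MCL": {"eps_r": 0.04, "k": 400.0},
    "LCL": {"eps_r": 0.08, "k": 650.0},
    "MPFL": {"eps_r": 0.08, "k": 6000.0},
    "LPFL": {"eps_r": 0.06, "k": 3000.0},
    "PL": {"eps_r": -0.25, "k": 25000.0},
}


def strain(L: float, L0: float):
    """Engineering strain (L - L0) / L0; negative values mean slack."""
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 <= 0):
        raise ValidationError("zero-load length L0 must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValidationError("length L must be non-negative")
    out = (L - L0) / L0
    return float(out) if out.ndim == 0 else out


def zero_load_length(Lr: float, eps_r: float):
    """Zero-load length from reference length and reference strain."""
    eps_r = np.asarray(eps_r, dtype=float)
    if np.any(eps_r <= -1.0):
        raise ValidationError("reference strain must exceed -1")
    Lr = np.asarray(Lr, dtype=float)
    if np.any(Lr <= 0):
        raise ValidationError("reference length Lr must be positive")
    out = Lr / (eps_r + 1.0)
    return float(out) if out.ndim == 0 else out


def tensile_force(eps, k: float, eps_l: float = DEFAULT_LINEAR_STRAIN_LIMIT):
    """Piecewise tensile force: 0 slack / quadratic toe / linear, in N."""
    if eps_l <= 0:
        raise ValidationError("linear strain limit eps_l must be positive")
    if k < 0:
        raise ValidationError("stiffness k must be non-negative")
    eps = np.asarray(eps, dtype=float)
    toe = 0.25 * k * eps**2 / eps_l
    linear = k * (eps - eps_l)
    out = np.where(eps < 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, linear))
    return float(out) if out.ndim == 0 else out


@dataclass
class LigamentBundle:
    """One straight-line nonlinear bundle between two bodies.

    ``ligament`` groups bundles belonging to one anatomical ligament
    (e.g. the two MCL bundles); ``origin_pt`` / ``insertion_pt`` are in the
    host body frames (mm).  ``Lr`` is set by the settling step; setting it
    recomputes ``L0``.
    """

    name: str
    ligament: str
    origin_body: str
    insertion_body: str
    origin_pt: np.ndarray
    insertion_pt: np.ndarray
    k: float
    eps_r: float
    eps_l: float = DEFAULT_LINEAR_STRAIN_LIMIT
    Lr: float | None = None
    L0: float | None = None

    def __post_init__(self):
        self.origin_pt = np.asarray(self.origin_pt, dtype=float).reshape(3)
        self.insertion_pt = np.asarray(self.insertion_pt, dtype=float).reshape(3)
        if self.k < 0:
            raise ParameterError(self.name, "stiffness k must be non-negative")
        if self.eps_l <= 0:
            raise ParameterError(self.name, "linear strain limit eps_l must be positive")
        if self.eps_r <= -1.0:
            raise ParameterError(self.name, "reference strain eps_r must exceed -1")
        if self.Lr is not None:
            self.set_reference_length(self.Lr)
        elif self.L0 is not None and self.L0 <= 0:
            raise ParameterError(self.name, "zero-load length L0 must be positive")

    def set_reference_length(self, Lr: float) -> None:
        if Lr <= 0:
            raise ParameterError(self.name, "reference length Lr must be positive")
        self.Lr = float(Lr)
        self.L0 = zero_load_length(Lr, self.eps_r)

    def current_length(self, origin_pose, insertion_pose) -> float:
        a = origin_pose.transform_point(self.origin_pt)
        b = insertion_pose.transform_point(self.insertion_pt)
        return float(np.linalg.norm(b - a))

    def force_at_length(self, L: float) -> float:
        if self.L0 is None:
            raise ValidationError(f"bundle {self.name} has no reference length set")
        return float(tensile_force(strain(L, self.L0), self.k, self.eps_l))

    def copy(self) -> "LigamentBundle":
        return replace(
            self,
            origin_pt=self.origin_pt.copy(),
            insertion_pt=self.insertion_pt.copy(),
        )


def bundle_wrench(bundle: LigamentBundle, origin_pose, insertion_pose):
    """Equal-and-opposite force pair at the bundle attachments.

    Returns ``(force_on_origin_body, force_on_insertion_body, info)`` where
    forces are world-frame vectors (N) applied at the respective attachment
    points and ``info`` carries the current length, strain and tension.
    A taut bundle pulls its attachments toward each other.
    """
    a = origin_pose.transform_point(bundle.origin_pt)
    b = insertion_pose.transform_point(bundle.insertion_pt)
    d = b - a
    L = float(np.linalg.norm(d))
    if L < 1e-9:
        raise DegenerateGeometryError(
            f"bundle {bundle.name}: coincident attachment points"
        )
    u = d / L
    eps = strain(L, bundle.L0) if bundle.L0 is not None else 0.0
    f = float(tensile_force(eps, bundle.k, bundle.eps_l)) if bundle.L0 is not None else 0.0
    info = {"length": L, "strain": float(eps), "force": f, "points": (a, b)}
    return f * u, -f * u, info


@dataclass
class MuscleActuator:
    """Straight-line muscle-tendon actuator (quadriceps or hamstring).

    ``bundles`` is a list of (origin body name or "carriage", origin point,
    insertion body name, insertion point) attachment pairs; an applied total
    tension is split equally across bundles.  The quadriceps passive
    component is ``alpha * exp(beta * quad_elongation)``; hamstrings apply
    ``constant_force`` each.
    """

    name: str
    kind: str  # {"quadriceps", "hamstring"}
    bundles: list
    alpha: float = 0.0
    beta: float = 0.0
    preload: float = 0.0
    constant_force: float = DEFAULT_HAMSTRING_FORCE
    reference_length: float | None = None  # settled tendon length, mm

    def __post_init__(self):
        if self.kind not in ("quadriceps", "hamstring"):
            raise ParameterError(self.name, f"unknown actuator kind {self.kind!r}")
        if self.kind == "hamstring" and self.constant_force < 0:
            raise ParameterError(self.name, "hamstring force must be non-negative")
        if self.alpha < 0:
            raise ParameterError(self.name, "alpha must be non-negative")


def passive_quadriceps_force(quad_length: float, alpha: float, beta: float) -> float:
    """Passive quadriceps tension alpha * exp(beta * elongation) in N.

    ``quad_length`` is the tendon elongation in mm relative to the settled
    reference length.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    return float(alpha * np.exp(beta * quad_length))


# ---------------------------------------------------------------------------
# parameter file round trip


def ligament_params_to_yaml(bundles: list[LigamentBundle], path) -> None:
    """Write per-bundle parameters (k, eps_r, eps_l, attachments) to YAML."""
    doc = {}
    for b in bundles:
        doc[b.name] = {
            "ligament": b.ligament,
            "k": float(b.k),
            "eps_r": float(b.eps_r),
            "eps_l": float(b.eps_l),
            "origin_body": b.origin_body,
            "insertion_body": b.insertion_body,
            "origin_pt": [float(x) for x in b.origin_pt],
            "insertion_pt": [float(x) for x in b.insertion_pt],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def ligament_params_from_yaml(path) -> list[LigamentBundle]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    bundles = []
    for name in sorted(doc):
        entry = doc[name]
        bundles.append(
            LigamentBundle(
                name=name,
                ligament=entry["ligament"],
                origin_body=entry["origin_body"],
                insertion_body=entry["insertion_body"],
                origin_pt=np.array(entry["origin_pt"], dtype=float),
                insertion_pt=np.array(entry["insertion_pt"], dtype=float),
                k=float(entry["k"]),
                eps_r=float(entry["eps_r"]),
                eps_l=float(entry.get("eps_l", DEFAULT_LINEAR_STRAIN_LIMIT)),
            )
        )
    return bundles
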