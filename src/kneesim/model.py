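"""In-memory knee model: bodies, implant components, soft tissue, contact.

A :class:`KneeModel` bundles the three bones (femur, tibia, patella), the
posterior-stabilized implant components fixed to femur and tibia, the
passive ligament bundles, the muscle-tendon actuators, and the analytic
contact primitives that govern the tibiofemoral and patellofemoral
interfaces.  Poses of bodies are world rigid transforms; implant components
carry an additional fixed pose in their host bone frame, so rotating a
component (e.g. the tibial insert) never moves bone attachment sites.

Models serialize to a directory of STL meshes plus a ``model.json``
metadata file (frames, attachments, parameters, component poses).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .contact import CapsulePair, ContactParams, SphereInDish, SphereOnCylinder
from .errors import ValidationError
from .frames import Frame, RigidPose
from .ligaments import LigamentBundle, MuscleActuator

BODY_NAMES = ("femur", "tibia", "patella")

#: frame key for the hip-carriage (slider) that anchors quadriceps/hamstrings
CARRIAGE = "carriage"


@dataclass
class Body:
    """A rigid bone: watertight surface mesh, anatomical frame, named sites."""

    name: str
    mesh: trimesh.Trimesh
    anatomical_frame: Frame
    attachment_sites: dict = field(default_factory=dict)

    def site(self, name: str) -> np.ndarray:
        return self.attachment_sites[name]


@dataclass
class ImplantComponent:
    """An implant part fixed to a host bone via a rigid ``pose``."""

    name: str
    host: str
    mesh: trimesh.Trimesh
    pose: RigidPose = field(default_factory=RigidPose.identity)


@dataclass
class ImplantAssembly:
    femoral_component: ImplantComponent
    tibial_baseplate: ImplantComponent
    tibial_insert: ImplantComponent

    def components(self):
        return {
            "femoral_component": self.femoral_component,
            "tibial_baseplate": self.tibial_baseplate,
            "tibial_insert": self.tibial_insert,
        }


@dataclass
class KneeModel:
    """The simulated system; all lengths mm, forces N, masses kg."""

    bodies: dict
    implant: ImplantAssembly
    bundles: list
    actuators: list
    contact_params: ContactParams
    contact_primitives: list
    geometry: dict  # scalar layout: link lengths, anchors, masses, COMs
    params: object = None  # SyntheticKneeParams when generated
    contact_overrides: dict = field(default_factory=dict)  # primitive label -> ContactParams

    def contact_params_for(self, label: str) -> ContactParams:
        return self.contact_overrides.get(label, self.contact_params)

    # -- pose plumbing ------------------------------------------------------

    def generation_poses(self) -> dict:
        """World poses at the generated full-extension reference.

        Femur and tibia meshes are authored in world coordinates of that
        pose (identity); the patella mesh is authored about its own center.
        """
        poses = {name: RigidPose.identity() for name in self.bodies}
        if "patella_center0" in self.geometry:
            poses["patella"] = RigidPose(np.eye(3), np.asarray(self.geometry["patella_center0"], dtype=float))
        poses[CARRIAGE] = RigidPose(np.eye(3), np.array([0.0, 0.0, self.geometry["hip_z"]]))
        return poses

    def frame_poses(self, body_poses: dict) -> dict:
        """Extend body poses with world poses of the implant components."""
        poses = dict(body_poses)
        for key, comp in self.implant.components().items():
            poses[key] = body_poses[comp.host].compose(comp.pose)
        return poses

    def bundle_endpoint_poses(self, frame_poses: dict, bundle) -> tuple:
        return frame_poses[bundle.origin_body], frame_poses[bundle.insertion_body]

    def bundles_of(self, ligament: str) -> list:
        out = [b for b in self.bundles if b.ligament == ligament]
        if not out:
            raise ValidationError(f"model has no ligament named {ligament!r}")
        return out

    def actuator(self, name: str) -> MuscleActuator:
        for a in self.actuators:
            if a.name == name:
                return a
        raise ValidationError(f"model has no actuator named {name!r}")

    def copy(self) -> "KneeModel":
        """Deep copy of everything mutable (meshes are shared, geometry copied)."""
        bodies = {
            k: Body(b.name, b.mesh, b.anatomical_frame, {s: p.copy() for s, p in b.attachment_sites.items()})
            for k, b in self.bodies.items()
        }
        implant = ImplantAssembly(
            *[
                ImplantComponent(c.name, c.host, c.mesh, c.pose)
                for c in (
                    self.implant.femoral_component,
                    self.implant.tibial_baseplate,
                    self.implant.tibial_insert,
                )
            ]
        )
        actuators = [dataclasses.replace(a, bundles=[tuple(t) for t in a.bundles]) for a in self.actuators]
        return KneeModel(
            bodies=bodies,
            implant=implant,
            bundles=[b.copy() for b in self.bundles],
            actuators=actuators,
            contact_params=self.contact_params,
            contact_primitives=list(self.contact_primitives),
            geometry=json.loads(json.dumps(self.geometry)),
            params=self.params,
            contact_overrides=dict(self.contact_overrides),
        )


# ---------------------------------------------------------------------------
# serialization

_PRIMITIVE_TYPES = {
    "SphereInDish": SphereInDish,
    "CapsulePair": CapsulePair,
    "SphereOnCylinder": SphereOnCylinder,
}


def _pose_to_json(pose: RigidPose) -> dict:
    return {"quaternion": pose.as_quaternion().tolist(), "translation": pose.translation.tolist()}


def _pose_from_json(doc: dict) -> RigidPose:
    return RigidPose.from_quaternion(doc["quaternion"], doc["translation"])


def _frame_to_json(frame: Frame) -> dict:
    return {"origin": frame.origin.tolist(), "axes": frame.axes.tolist()}


def _primitive_to_json(prim) -> dict:
    doc = dataclasses.asdict(prim)
    doc["type"] = type(prim).__name__
    return doc


def _tolist(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_tolist(o) for o in obj]
    return obj


def save_model(model: KneeModel, directory) -> list:
    """Write meshes (binary STL) and metadata; returns the files written."""
    from .synthetic import SyntheticKneeParams, write_stl  # local: avoid cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    meshes = {f"{name}.stl": body.mesh for name, body in model.bodies.items()}
    for key, comp in model.implant.components().items():
        meshes[f"{key}.stl"] = comp.mesh
    for fname, mesh in meshes.items():
        write_stl(mesh, directory / fname)
        written.append(fname)

    doc = {
        "units": {"length": "mm", "force": "N", "angle": "deg", "mass": "kg"},
        "bodies": {
            name: {
                "mesh": f"{name}.stl",
                "anatomical_frame": _frame_to_json(b.anatomical_frame),
                "attachment_sites": {k: v.tolist() for k, v in b.attachment_sites.items()},
            }
            for name, b in model.bodies.items()
        },
        "implant": {
            key: {"host": c.host, "mesh": f"{key}.stl", "pose": _pose_to_json(c.pose)}
            for key, c in model.implant.components().items()
        },
        "bundles": [
            {
                "name": b.name,
                "ligament": b.ligament,
                "origin_body": b.origin_body,
                "insertion_body": b.insertion_body,
                "origin_pt": b.origin_pt.tolist(),
                "insertion_pt": b.insertion_pt.tolist(),
                "k": b.k,
                "eps_r": b.eps_r,
                "eps_l": b.eps_l,
                "Lr": b.Lr,
            }
            for b in model.bundles
        ],
        "actuators": [
            {
                "name": a.name,
                "kind": a.kind,
                "bundles": _tolist(a.bundles),
                "alpha": a.alpha,
                "beta": a.beta,
                "preload": a.preload,
                "constant_force": a.constant_force,
                "reference_length": a.reference_length,
            }
            for a in model.actuators
        ],
        "contact_params": dataclasses.asdict(model.contact_params),
        "contact_overrides": {
            label: dataclasses.asdict(p) for label, p in model.contact_overrides.items()
        },
        "contact_primitives": [_primitive_to_json(p) for p in model.contact_primitives],
        "geometry": model.geometry,
        "params": dataclasses.asdict(model.params) if model.params is not None else None,
    }
    with open(directory / "model.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    written.append("model.json")
    return written


def load_model(directory) -> KneeModel:
    from .synthetic import SyntheticKneeParams, read_stl  # local: avoid cycle

    directory = Path(directory)
    with open(directory / "model.json") as fh:
        doc = json.load(fh)

    bodies = {}
    for name, entry in doc["bodies"].items():
        bodies[name] = Body(
            name=name,
            mesh=read_stl(directory / entry["mesh"]),
            anatomical_frame=Frame(
                np.array(entry["anatomical_frame"]["origin"]),
                np.array(entry["anatomical_frame"]["axes"]),
            ),
            attachment_sites={k: np.array(v) for k, v in entry["attachment_sites"].items()},
        )
    comps = {}
    for key, entry in doc["implant"].items():
        comps[key] = ImplantComponent(
            name=key,
            host=entry["host"],
            mesh=read_stl(directory / entry["mesh"]),
            pose=_pose_from_json(entry["pose"]),
        )
    implant = ImplantAssembly(
        femoral_component=comps["femoral_component"],
        tibial_baseplate=comps["tibial_baseplate"],
        tibial_insert=comps["tibial_insert"],
    )
    bundles = []
    for b in doc["bundles"]:
        bundle = LigamentBundle(
            name=b["name"],
            ligament=b["ligament"],
            origin_body=b["origin_body"],
            insertion_body=b["insertion_body"],
            origin_pt=np.array(b["origin_pt"]),
            insertion_pt=np.array(b["insertion_pt"]),
            k=b["k"],
            eps_r=b["eps_r"],
            eps_l=b["eps_l"],
        )
        if b["Lr"] is not None:
            bundle.set_reference_length(b["Lr"])
        bundles.append(bundle)
    actuators = [
        MuscleActuator(
            name=a["name"],
            kind=a["kind"],
            bundles=[
                (p[0], np.array(p[1]), p[2], np.array(p[3])) for p in a["bundles"]
            ],
            alpha=a["alpha"],
            beta=a["beta"],
            preload=a["preload"],
            constant_force=a["constant_force"],
            reference_length=a["reference_length"],
        )
        for a in doc["actuators"]
    ]
    primitives = []
    for p in doc["contact_primitives"]:
        cls = _PRIMITIVE_TYPES[p.pop("type")]
        for key in ("sphere_center", "dish_center", "cyl_point", "cyl_axis"):
            if key in p:
                p[key] = tuple(p[key])
        for key in ("seg_a", "seg_b"):
            if key in p:
                p[key] = tuple(tuple(q) for q in p[key])
        primitives.append(cls(**p))
    params = None
    if doc.get("params") is not None:
        params = SyntheticKneeParams(**doc["params"])
    return KneeModel(
        bodies=bodies,
        implant=implant,
        bundles=bundles,
        actuators=actuators,
        contact_params=ContactParams(**doc["contact_params"]),
        contact_primitives=primitives,
        geometry=doc["geometry"],
        params=params,
        contact_overrides={
            label: ContactParams(**p)
            for label, p in doc.get("contact_overrides", {}).items()
        },
    )
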