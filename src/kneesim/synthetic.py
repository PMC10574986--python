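"""Seeded parametric post-TKA knee generator.

Builds an analytic-primitive knee standing in for CT/STL specimen data: a
femur and tibia with a posterior-stabilized implant (two spherical femoral
condyles plus a cam, a polyethylene insert with two spherical dishes plus a
post, a tibial baseplate), a patellar body riding a trochlear cylinder, and
the full soft-tissue set (MCL anterior/posterior, LCL, MPFL, LPFL, three
patellar-ligament bundles, three quadriceps bundles, medial and lateral
hamstrings).  All primitives are tessellated into watertight meshes; the
contact module works on the analytic primitives directly.

Conventions: right knee; world axes X anterior, Y medial, Z proximal; ankle
at the origin at the generated full-extension pose; units mm / N / kg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .contact import CapsulePair, ContactParams, SphereInDish, SphereOnCylinder
from .errors import ParameterError, StlFormatError
from .frames import Frame, RigidPose
from .ligaments import (
    DEFAULT_LIGAMENT_PARAMS,
    DEFAULT_LINEAR_STRAIN_LIMIT,
    LigamentBundle,
    MuscleActuator,
)
from .model import CARRIAGE, Body, ImplantAssembly, ImplantComponent, KneeModel


@dataclass
class SyntheticKneeParams:
    """Parameters of the generated knee; defaults give the package's default model.

    Radii/lengths in mm, masses in kg.  ``condyle_radii`` and
    ``insert_dish_radii`` are (medial, lateral); each dish radius must be at
    least its paired condyle radius (conforming, non-penetrating at rest).
    The generator is deterministic: identical parameters (including
    ``seed``) give bit-identical output; ``seed`` drives the optional
    attachment jitter emulating specimen variability.
    """

    condyle_radii: tuple = (22.0, 22.0)
    condyle_spacing: float = 52.0
    insert_dish_radii: tuple = (30.0, 30.0)
    dish_depth: float = 6.0
    insert_thickness: float = 10.0
    baseplate_thickness: float = 3.0
    insert_half_ap: float = 27.0
    insert_half_ml: float = 37.0
    post_cam_dims: dict = field(
        default_factory=lambda: {
            "post_radius": 5.0,
            "post_height": 9.0,
            "post_x": -12.0,
            "cam_radius": 6.0,
            "cam_ring_radius": 25.9,
            "cam_angle_deg": 112.6,
            "cam_half_length": 12.0,
        }
    )
    bone_segment_lengths: dict = field(default_factory=lambda: {"femur": 320.0, "tibia": 280.0})
    femur_shaft_radius: float = 16.0
    tibia_shaft_radius: float = 16.0
    trochlea_radius: float = 26.0
    patella_radius: float = 12.0
    patella_angle_deg: float = 25.0
    mesh_resolution: dict = field(
        default_factory=lambda: {"sphere_subdivisions": 3, "cylinder_sections": 48, "grid": 48}
    )
    attachment_offsets: dict = field(default_factory=dict)
    attachment_jitter_mm: float = 0.0
    seed: int = 7
    masses: dict = field(default_factory=lambda: {"femur": 4.0, "tibia": 3.0, "patella": 0.2})
    quad_alpha: float = 85.0
    quad_beta: float = 0.05
    quad_preload: float = 0.0
    hamstring_force: float = 50.0
    ligament_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.condyle_radii = tuple(float(r) for r in self.condyle_radii)
        self.insert_dish_radii = tuple(float(r) for r in self.insert_dish_radii)
        lengths = {
            "condyle_spacing": self.condyle_spacing,
            "dish_depth": self.dish_depth,
            "insert_thickness": self.insert_thickness,
            "baseplate_thickness": self.baseplate_thickness,
            "femur_shaft_radius": self.femur_shaft_radius,
            "tibia_shaft_radius": self.tibia_shaft_radius,
            "trochlea_radius": self.trochlea_radius,
            "patella_radius": self.patella_radius,
            "bone_segment_lengths.femur": self.bone_segment_lengths["femur"],
            "bone_segment_lengths.tibia": self.bone_segment_lengths["tibia"],
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ParameterError(name, f"must be strictly positive, got {value}")
        for i, r in enumerate(self.condyle_radii):
            if r <= 0:
                raise ParameterError("condyle_radii", f"must be strictly positive, got {r}")
        for i, (rd, rc) in enumerate(zip(self.insert_dish_radii, self.condyle_radii)):
            if rd <= 0:
                raise ParameterError("insert_dish_radii", f"must be strictly positive, got {rd}")
            if rd < rc:
                raise ParameterError(
                    "insert_dish_radii",
                    f"dish radius {rd} must be >= paired condyle radius {rc}",
                )
        if self.attachment_jitter_mm < 0:
            raise ParameterError("attachment_jitter_mm", "must be non-negative")
        if int(self.seed) != self.seed:
            raise ParameterError("seed", "must be an integer")
        self.seed = int(self.seed)


def default_params(**overrides) -> SyntheticKneeParams:
    return SyntheticKneeParams(**overrides)


# ---------------------------------------------------------------------------
# meshing helpers


def _tf(translation, rotation=None) -> np.ndarray:
    m = np.eye(4)
    if rotation is not None:
        m[:3, :3] = rotation
    m[:3, 3] = translation
    return m


def _sphere(radius, center, subdivisions) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(center)
    return mesh


def _ellipsoid(semi_axes, center, subdivisions) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(semi_axes)
    mesh.apply_translation(center)
    return mesh


def _cylinder_z(radius, z0, z1, xy, sections) -> trimesh.Trimesh:
    mesh = trimesh.creation.cylinder(radius=radius, height=z1 - z0, sections=sections)
    mesh.apply_translation([xy[0], xy[1], 0.5 * (z0 + z1)])
    return mesh


def _cylinder_y(radius, center, half_length, sections) -> trimesh.Trimesh:
    mesh = trimesh.creation.cylinder(radius=radius, height=2 * half_length, sections=sections)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
    mesh.apply_transform(_tf([0, 0, 0], rot))
    mesh.apply_translation(center)
    return mesh


def _box(xmin, xmax, ymin, ymax, zmin, zmax) -> trimesh.Trimesh:
    extents = [xmax - xmin, ymax - ymin, zmax - zmin]
    center = [0.5 * (xmin + xmax), 0.5 * (ymin + ymax), 0.5 * (zmin + zmax)]
    return trimesh.creation.box(extents=extents, transform=_tf(center))


def _heightfield_solid(xs, ys, z_top_fn, z_bottom) -> trimesh.Trimesh:
    """Watertight solid between a flat bottom and a heightfield top surface."""
    nx, ny = len(xs), len(ys)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    z_top = z_top_fn(gx, gy)
    top = np.column_stack([gx.ravel(), gy.ravel(), z_top.ravel()])
    bottom = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z_bottom)])
    vertices = np.vstack([top, bottom])

    def vid(i, j, layer):
        return layer * nx * ny + i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j + 1, 0), vid(i, j + 1, 0)
            faces += [[a, b, c], [a, c, d]]  # top, +z out
            a, b, c, d = vid(i, j, 1), vid(i + 1, j, 1), vid(i + 1, j + 1, 1), vid(i, j + 1, 1)
            faces += [[a, c, b], [a, d, c]]  # bottom, -z out
    for i in range(nx - 1):  # walls along x at ymin / ymax
        faces += [[vid(i, 0, 0), vid(i, 0, 1), vid(i + 1, 0, 1)], [vid(i, 0, 0), vid(i + 1, 0, 1), vid(i + 1, 0, 0)]]
        j = ny - 1
        faces += [[vid(i, j, 0), vid(i + 1, j, 1), vid(i, j, 1)], [vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j, 1)]]
    for j in range(ny - 1):  # walls along y at xmin / xmax
        faces += [[vid(0, j, 0), vid(0, j + 1, 1), vid(0, j, 1)], [vid(0, j, 0), vid(0, j + 1, 0), vid(0, j + 1, 1)]]
        i = nx - 1
        faces += [[vid(i, j, 0), vid(i, j, 1), vid(i, j + 1, 1)], [vid(i, j, 0), vid(i, j + 1, 1), vid(i, j + 1, 0)]]
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    mesh.fix_normals()
    return mesh


def _sector_prism(radii, angles_deg, y_half, center_xz, n_arc=24) -> trimesh.Trimesh:
    """Extruded annular-sector (trochlear flange) along the Y axis."""
    a0, a1 = np.deg2rad(angles_deg[0]), np.deg2rad(angles_deg[1])
    angs = np.linspace(a0, a1, n_arc)
    outer = np.column_stack([np.cos(angs), np.sin(angs)]) * radii[1]
    inner = np.column_stack([np.cos(angs[::-1]), np.sin(angs[::-1])]) * radii[0]
    poly = np.vstack([outer, inner])  # closed CCW polygon in xz
    n = len(poly)
    centroid = poly.mean(axis=0)
    ring0 = np.column_stack([poly[:, 0], np.full(n, -y_half), poly[:, 1]])
    ring1 = np.column_stack([poly[:, 0], np.full(n, y_half), poly[:, 1]])
    c0 = np.array([[centroid[0], -y_half, centroid[1]]])
    c1 = np.array([[centroid[0], y_half, centroid[1]]])
    vertices = np.vstack([ring0, ring1, c0, c1])
    i_c0, i_c1 = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces += [[i, j, n + j], [i, n + j, n + i]]  # side wall
        faces += [[i_c0, j, i]]  # -y cap (fan)
        faces += [[i_c1, n + i, n + j]]  # +y cap
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    mesh.apply_translation([center_xz[0], 0.0, center_xz[1]])
    mesh.fix_normals()
    return mesh


# ---------------------------------------------------------------------------
# STL round trip


def write_stl(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    """Write a mesh as binary (default) or ASCII STL."""
    path = Path(path)
    if ascii:
        data = trimesh.exchange.stl.export_stl_ascii(mesh)
        path.write_text(data)
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))


def read_stl(path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL; malformed input raises :class:`StlFormatError`.

    Vertices are kept as the triangle soup stored in the file (no merging),
    so a write/read round trip preserves the triangle count exactly and
    coordinates to single-float precision.
    """
    path = Path(path)
    try:
        size = path.stat().st_size
    except OSError as exc:
        raise StlFormatError(f"cannot stat {path}: {exc}", 0)
    if size == 0:
        raise StlFormatError(f"empty STL file {path}", 0)
    data = path.read_bytes()
    is_ascii = data.lstrip()[:5] == b"solid" and b"facet" in data[:500]
    if not is_ascii:
        if size < 84:
            raise StlFormatError(f"binary STL truncated before triangle count in {path}", size)
        n = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        expected = 84 + 50 * n
        if size < expected:
            raise StlFormatError(
                f"binary STL {path} declares {n} triangles but is truncated", size
            )
    try:
        with open(path, "rb") as fh:
            loaded = trimesh.exchange.stl.load_stl(fh)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise StlFormatError(f"malformed STL {path}: {exc}", 0) from exc
    return trimesh.Trimesh(**loaded, process=False)


# ---------------------------------------------------------------------------
# attachment layout


def _attachment_layout(p: SyntheticKneeParams, knee_z: float, tibia_len: float, patella_center):
    """Built-in anatomical-atlas-style attachment sites, body frames (mm)."""
    femur = {
        "MCL_ant_origin": (10.0, 40.0, knee_z),
        "MCL_post_origin": (2.0, 40.0, knee_z),
        "LCL_origin": (-6.0, -40.0, knee_z),
        "MPFL_origin": (0.0, 40.0, knee_z + 2.0),
        "LPFL_origin": (0.0, -40.0, knee_z + 2.0),
    }
    tibia = {
        "MCL_ant_insertion": (8.0, 16.0, tibia_len - 70.0),
        "MCL_post_insertion": (0.0, 16.0, tibia_len - 75.0),
        "LCL_insertion": (-10.0, -33.0, tibia_len - 28.0),
        "PL_med_insertion": (30.0, 8.0, tibia_len - 9.0),
        "PL_ctr_insertion": (30.0, 0.0, tibia_len - 9.0),
        "PL_lat_insertion": (30.0, -8.0, tibia_len - 9.0),
        "ham_med_attach": (-25.0, 28.0, tibia_len - 15.0),
        "ham_lat_attach": (-25.0, -28.0, tibia_len - 15.0),
    }
    patella = {
        "quad_med": (2.0, 8.0, 10.0),
        "quad_ctr": (2.0, 0.0, 11.0),
        "quad_lat": (2.0, -8.0, 10.0),
        "PL_med": (2.0, 8.0, -10.0),
        "PL_ctr": (2.0, 0.0, -11.0),
        "PL_lat": (2.0, -8.0, -10.0),
        "MPFL_insertion": (0.0, 11.0, 2.0),
        "LPFL_insertion": (0.0, -11.0, 2.0),
    }
    return {"femur": femur, "tibia": tibia, "patella": patella}


def _apply_offsets_and_jitter(layout: dict, p: SyntheticKneeParams) -> dict:
    rng = np.random.default_rng(p.seed)
    out = {}
    for body, sites in layout.items():
        out[body] = {}
        for name, pos in sites.items():
            pos = np.asarray(pos, dtype=float)
            if name in p.attachment_offsets:
                pos = pos + np.asarray(p.attachment_offsets[name], dtype=float)
            if p.attachment_jitter_mm > 0:
                pos = pos + rng.uniform(-p.attachment_jitter_mm, p.attachment_jitter_mm, 3)
            out[body][name] = pos
    return out


# ---------------------------------------------------------------------------


def generate_synthetic_knee(params: SyntheticKneeParams | None = None) -> KneeModel:
    """Build the synthetic post-TKA knee model at its full-extension pose.

    The generated pose is the reference configuration: both femoral condyles
    rest in their insert dishes with exactly zero interpenetration, the
    patella touches the trochlea, and all anatomical frames coincide at the
    knee center so the joint coordinates read zero.
    """
    p = params if params is not None else SyntheticKneeParams()
    res = p.mesh_resolution
    sub = int(res["sphere_subdivisions"])
    sections = int(res["cylinder_sections"])
    grid = int(res["grid"])

    tibia_len = float(p.bone_segment_lengths["tibia"])
    femur_len = float(p.bone_segment_lengths["femur"])
    rc_med, rc_lat = p.condyle_radii
    rd_med, rd_lat = p.insert_dish_radii
    half_spacing = 0.5 * p.condyle_spacing
    insert_top = tibia_len + p.baseplate_thickness + p.insert_thickness
    # seated condyle centers define the femoral flexion axis height
    knee_z = insert_top - p.dish_depth + rc_med
    if abs(rc_med - rc_lat) > 1e-9:
        # seat both condyles exactly: lateral dish curvature center shifts
        knee_z = insert_top - p.dish_depth + rc_med
    hip_z = knee_z + femur_len
    dish_center_med = np.array([0.0, half_spacing, insert_top - p.dish_depth + rd_med])
    dish_center_lat = np.array(
        [0.0, -half_spacing, knee_z + (rd_lat - rc_lat)]
    )
    condyle_center_med = np.array([0.0, half_spacing, knee_z])
    condyle_center_lat = np.array([0.0, -half_spacing, knee_z])

    pc = p.post_cam_dims
    cam_angle = np.deg2rad(pc["cam_angle_deg"])
    cam_center = np.array(
        [
            pc["cam_ring_radius"] * np.cos(cam_angle),
            0.0,
            knee_z + pc["cam_ring_radius"] * np.sin(cam_angle),
        ]
    )
    post_base = insert_top - 3.0
    post_top = post_base + pc["post_height"]

    pat_angle = np.deg2rad(p.patella_angle_deg)
    pat_dist = p.trochlea_radius + p.patella_radius
    patella_center = np.array(
        [pat_dist * np.cos(pat_angle), 0.0, knee_z + pat_dist * np.sin(pat_angle)]
    )

    # ---- meshes -----------------------------------------------------------
    femur_mesh = trimesh.util.concatenate(
        [
            _cylinder_z(p.femur_shaft_radius, knee_z + 32.0, hip_z, (0.0, 0.0), sections),
            _ellipsoid([32.0, 42.0, 22.0], [0.0, 0.0, knee_z + 6.0], sub),
        ]
    )
    tibia_mesh = trimesh.util.concatenate(
        [
            _box(-25.0, 30.0, -35.0, 35.0, tibia_len - 30.0, tibia_len),
            _cylinder_z(p.tibia_shaft_radius, 0.0, tibia_len - 25.0, (0.0, 0.0), sections),
        ]
    )
    patella_mesh = _sphere(p.patella_radius, [0.0, 0.0, 0.0], sub)

    femoral_component_mesh = trimesh.util.concatenate(
        [
            _sphere(rc_med, condyle_center_med, sub),
            _sphere(rc_lat, condyle_center_lat, sub),
            _cylinder_y(pc["cam_radius"], cam_center, pc["cam_half_length"], sections),
            _sector_prism(
                (p.trochlea_radius - 8.0, p.trochlea_radius),
                (15.0, 95.0),
                14.0,
                (0.0, knee_z),
            ),
        ]
    )
    baseplate_mesh = _box(
        -p.insert_half_ap,
        p.insert_half_ap,
        -p.insert_half_ml,
        p.insert_half_ml,
        tibia_len,
        tibia_len + p.baseplate_thickness,
    )

    def insert_top_fn(gx, gy):
        z = np.full(gx.shape, insert_top)
        for center, radius in ((dish_center_med, rd_med), (dish_center_lat, rd_lat)):
            rho2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2
            inside = rho2 < radius**2
            dish_z = np.where(inside, center[2] - np.sqrt(np.maximum(radius**2 - rho2, 0.0)), np.inf)
            z = np.minimum(z, dish_z)
        return z

    xs = np.linspace(-p.insert_half_ap, p.insert_half_ap, grid + 1)
    ys = np.linspace(-p.insert_half_ml, p.insert_half_ml, int(grid * 1.3) + 1)
    insert_mesh = trimesh.util.concatenate(
        [
            _heightfield_solid(xs, ys, insert_top_fn, tibia_len + p.baseplate_thickness),
            _cylinder_z(pc["post_radius"], post_base, post_top, (pc["post_x"], 0.0), sections),
        ]
    )

    # ---- frames, attachments ---------------------------------------------
    knee_center = np.array([0.0, 0.0, knee_z])
    frames = {
        "femur": Frame(knee_center, np.eye(3)),
        "tibia": Frame(knee_center, np.eye(3)),
        "patella": Frame(np.zeros(3), np.eye(3)),
    }
    layout = _apply_offsets_and_jitter(
        _attachment_layout(p, knee_z, tibia_len, patella_center), p
    )

    bodies = {
        "femur": Body("femur", femur_mesh, frames["femur"], layout["femur"]),
        "tibia": Body("tibia", tibia_mesh, frames["tibia"], layout["tibia"]),
        "patella": Body("patella", patella_mesh, frames["patella"], layout["patella"]),
    }

    implant = ImplantAssembly(
        femoral_component=ImplantComponent("femoral_component", "femur", femoral_component_mesh),
        tibial_baseplate=ImplantComponent("tibial_baseplate", "tibia", baseplate_mesh),
        tibial_insert=ImplantComponent("tibial_insert", "tibia", insert_mesh),
    )

    # ---- soft tissue ------------------------------------------------------
    lig_params = {**DEFAULT_LIGAMENT_PARAMS}
    for name, entry in p.ligament_params.items():
        lig_params[name] = {**lig_params.get(name, {}), **entry}

    def bundle(name, ligament, origin_site, insertion_site, origin_body="femur", insertion_body="tibia"):
        lp = lig_params[ligament]
        return LigamentBundle(
            name=name,
            ligament=ligament,
            origin_body=origin_body,
            insertion_body=insertion_body,
            origin_pt=layout[origin_body][origin_site],
            insertion_pt=layout[insertion_body][insertion_site],
            k=float(lp["k"]),
            eps_r=float(lp["eps_r"]),
            eps_l=float(lp.get("eps_l", DEFAULT_LINEAR_STRAIN_LIMIT)),
        )

    bundles = [
        bundle("MCL_ant", "MCL", "MCL_ant_origin", "MCL_ant_insertion"),
        bundle("MCL_post", "MCL", "MCL_post_origin", "MCL_post_insertion"),
        bundle("LCL", "LCL", "LCL_origin", "LCL_insertion"),
        bundle("MPFL", "MPFL", "MPFL_origin", "MPFL_insertion", "femur", "patella"),
        bundle("LPFL", "LPFL", "LPFL_origin", "LPFL_insertion", "femur", "patella"),
        bundle("PL_med", "PL", "PL_med", "PL_med_insertion", "patella", "tibia"),
        bundle("PL_ctr", "PL", "PL_ctr", "PL_ctr_insertion", "patella", "tibia"),
        bundle("PL_lat", "PL", "PL_lat", "PL_lat_insertion", "patella", "tibia"),
    ]

    quad_anchor = {"med": (35.0, 10.0, 0.0), "ctr": (35.0, 0.0, 0.0), "lat": (35.0, -10.0, 0.0)}
    actuators = [
        MuscleActuator(
            name="quadriceps",
            kind="quadriceps",
            bundles=[
                ("patella", layout["patella"]["quad_med"], CARRIAGE, np.array(quad_anchor["med"])),
                ("patella", layout["patella"]["quad_ctr"], CARRIAGE, np.array(quad_anchor["ctr"])),
                ("patella", layout["patella"]["quad_lat"], CARRIAGE, np.array(quad_anchor["lat"])),
            ],
            alpha=p.quad_alpha,
            beta=p.quad_beta,
            preload=p.quad_preload,
        ),
        MuscleActuator(
            name="ham_med",
            kind="hamstring",
            bundles=[("tibia", layout["tibia"]["ham_med_attach"], CARRIAGE, np.array([-35.0, 20.0, 0.0]))],
            constant_force=p.hamstring_force,
        ),
        MuscleActuator(
            name="ham_lat",
            kind="hamstring",
            bundles=[("tibia", layout["tibia"]["ham_lat_attach"], CARRIAGE, np.array([-35.0, -20.0, 0.0]))],
            constant_force=p.hamstring_force,
        ),
    ]

    primitives = [
        SphereInDish(
            "condyle_med",
            "femoral_component",
            "femur",
            tuple(condyle_center_med),
            rc_med,
            "tibial_insert",
            "tibia",
            tuple(dish_center_med),
            rd_med,
        ),
        SphereInDish(
            "condyle_lat",
            "femoral_component",
            "femur",
            tuple(condyle_center_lat),
            rc_lat,
            "tibial_insert",
            "tibia",
            tuple(dish_center_lat),
            rd_lat,
        ),
        CapsulePair(
            "cam_post",
            "femoral_component",
            "femur",
            (
                tuple(cam_center - np.array([0.0, pc["cam_half_length"], 0.0])),
                tuple(cam_center + np.array([0.0, pc["cam_half_length"], 0.0])),
            ),
            pc["cam_radius"],
            "tibial_insert",
            "tibia",
            ((pc["post_x"], 0.0, post_base), (pc["post_x"], 0.0, post_top)),
            pc["post_radius"],
        ),
        SphereOnCylinder(
            "patellofemoral",
            "patella",
            "patella",
            (0.0, 0.0, 0.0),
            p.patella_radius,
            "femoral_component",
            "femur",
            (0.0, 0.0, knee_z),
            (0.0, 1.0, 0.0),
            p.trochlea_radius,
        ),
    ]

    geometry = {
        "knee_z": float(knee_z),
        "hip_z": float(hip_z),
        "insert_top": float(insert_top),
        "femur_link_length": float(femur_len),
        "tibia_link_length": float(knee_z),  # ankle (origin) to flexion axis
        "ankle_point": [0.0, 0.0, 0.0],
        "hip_point": [0.0, 0.0, float(hip_z)],
        "baseplate_center": [0.0, 0.0, float(tibia_len + 0.5 * p.baseplate_thickness)],
        "patella_center0": [float(x) for x in patella_center],
        "masses": {k: float(v) for k, v in p.masses.items()},
        "coms": {
            "femur": [0.0, 0.0, float(knee_z + 0.55 * femur_len)],
            "tibia": [0.0, 0.0, float(0.5 * tibia_len)],
            "patella": [float(x) for x in patella_center],
        },
        "gravity": 9.81,
    }

    model = KneeModel(
        bodies=bodies,
        implant=implant,
        bundles=bundles,
        actuators=actuators,
        contact_params=ContactParams(),
        contact_primitives=primitives,
        geometry=geometry,
        params=p,
    )
    _validate_attachments(model)
    return model


def point_mesh_distance(mesh: trimesh.Trimesh, points) -> np.ndarray:
    """Unsigned distance from points to a triangle surface (brute force)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (n, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    normal = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", normal, normal)

    def seg_dist(p, s0, s1):
        d = s1 - s0
        dd = np.einsum("ij,ij->i", d, d)
        t = np.clip(np.einsum("ij,ij->i", p - s0, d) / np.where(dd > 0, dd, 1.0), 0.0, 1.0)
        diff = p - (s0 + t[:, None] * d)
        return np.einsum("ij,ij->i", diff, diff)

    out = np.empty(len(points))
    for i, p in enumerate(points):
        # squared distance to the three edges (covers all boundary regions)
        d2 = np.minimum(seg_dist(p, a, b), np.minimum(seg_dist(p, b, c), seg_dist(p, c, a)))
        # interior projection where the foot point has all-positive barycentrics
        ap = p - a
        t = np.einsum("ij,ij->i", ap, normal) / np.where(nn > 0, nn, 1.0)
        foot = p - t[:, None] * normal
        v0, v1, v2 = c - a, b - a, foot - a
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d02 = np.einsum("ij,ij->i", v0, v2)
        d12 = np.einsum("ij,ij->i", v1, v2)
        denom = d00 * d11 - d01 * d01
        denom = np.where(np.abs(denom) > 1e-30, denom, 1.0)
        u = (d11 * d02 - d01 * d12) / denom
        v = (d00 * d12 - d01 * d02) / denom
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        plane_d2 = np.einsum("ij,ij->i", p - foot, p - foot)
        d2 = np.where(inside, np.minimum(d2, plane_d2), d2)
        out[i] = np.sqrt(d2.min())
    return out


def _validate_attachments(model: KneeModel, tol_mm: float = 5.0) -> None:
    """Every attachment site must lie within ``tol_mm`` of its host surface."""
    for name, body in model.bodies.items():
        if not body.attachment_sites:
            continue
        pts = np.array(list(body.attachment_sites.values()))
        dist = point_mesh_distance(body.mesh, pts)
        for site, d in zip(body.attachment_sites, dist):
            if d > tol_mm:
                raise ParameterError(
                    f"{name}.{site}", f"attachment lies {d:.1f} mm from host surface (> {tol_mm})"
                )


# ---------------------------------------------------------------------------
# implant perturbation


def apply_implant_ie_rotation(model: KneeModel, angle_deg: float) -> KneeModel:
    """Rotate baseplate + insert about the tibial long axis (new model).

    The rotation axis is the tibial anatomical long axis through the
    baseplate center; positive angles follow the right-hand rule about the
    proximal (+Z) axis.  Bones and every ligament attachment are untouched.
    """
    if abs(angle_deg) > 15.0:
        raise ParameterError("angle_deg", f"|angle| must be <= 15 deg, got {angle_deg}")
    out = model.copy()
    if angle_deg == 0.0:
        return out
    c = np.asarray(model.geometry["baseplate_center"], dtype=float)
    a = np.deg2rad(angle_deg)
    rz = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    spin = RigidPose(rz, c - rz @ c)
    for comp in (out.implant.tibial_baseplate, out.implant.tibial_insert):
        comp.pose = spin.compose(comp.pose)
    return out


# ---------------------------------------------------------------------------
# parameter files


def params_to_yaml(params: SyntheticKneeParams, path) -> None:
    doc = dataclasses.asdict(params)
    doc["condyle_radii"] = list(doc["condyle_radii"])
    doc["insert_dish_radii"] = list(doc["insert_dish_radii"])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_from_yaml(path) -> SyntheticKneeParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticKneeParams(**doc)
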