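"""End-to-end study driver: generate, settle, calibrate, sensitivity, report.

``run_study_protocol`` executes the full chain on the synthetic knee: it
generates the model, settles it at full extension, simulates a reference
squat, perturbs the MCL stiffness and calibrates it back against that
self-generated reference, runs the two-arm sensitivity study, and writes
every artifact plus a provenance manifest (config hash, seed, package
version, per-stage status and the list of produced files).  Outputs carry
no timestamps, so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationSpec, calibrate
from .errors import KneesimError, ValidationError
from .model import save_model
from .sensitivity import run_sensitivity_study
from .simulator import SquatProtocol, equilibrium_settle, run_squat
from .synthetic import SyntheticKneeParams, generate_synthetic_knee

_log = logging.getLogger(__name__)


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("kneesim")
    except Exception:  # noqa: BLE001
        return "unknown"


@dataclass
class RunConfig:
    """Configuration of one full protocol run."""

    seed: int = 7
    out_dir: str = "kneesim_run"
    params: dict = field(default_factory=dict)  # SyntheticKneeParams overrides
    protocol: dict = field(default_factory=dict)  # SquatProtocol overrides
    calibration: dict | None = field(default_factory=dict)  # None skips the stage
    study: dict | None = field(default_factory=dict)  # None skips the stage
    perturb_k_factor: float = 1.6  # MCL detuning before self-calibration
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return RunConfig(**doc)

    def digest(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_study_protocol(cfg: RunConfig) -> dict:
    """Execute the chained study; returns the manifest dictionary.

    Stage failures abort the run with the failing stage recorded in the
    manifest; every artifact produced before the failure is kept on disk.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "version": _package_version(),
        "stages": {},
        "files": [],
    }

    def finish(stage, status, files=()):
        manifest["stages"][stage] = status
        manifest["files"].extend(files)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    solver_log: list = []
    try:
        # -- generate ------------------------------------------------------
        params = SyntheticKneeParams(seed=cfg.seed, **cfg.params)
        model = generate_synthetic_knee(params)
        model_files = save_model(model, out / "model")
        finish("generate", "completed", [f"model/{f}" for f in model_files])

        # -- settle --------------------------------------------------------
        equilibrium_settle(model)
        settle_doc = {k: v for k, v in model.geometry["settle"].items()}
        settle_doc["Lr"] = {b.name: b.Lr for b in model.bundles}
        with open(out / "settle.json", "w") as fh:
            json.dump(settle_doc, fh, indent=1, sort_keys=True)
        finish("settle", "completed", ["settle.json"])

        # -- reference squat + calibration --------------------------------
        protocol = SquatProtocol(**cfg.protocol)
        if cfg.calibration is None:
            finish("calibrate", "skipped")
        else:
            reference = run_squat(model, protocol, log=solver_log)
            reference.to_csv(out / "reference_trace.csv")
            true_k = float(model.bundles_of("MCL")[0].k)
            for b in model.bundles_of("MCL"):
                b.k = true_k * cfg.perturb_k_factor
            spec = CalibrationSpec(
                free_parameters=[("MCL", "k", true_k / 4.0, true_k * 4.0)],
                seed=cfg.seed,
                **cfg.calibration,
            )
            result = calibrate(model, reference, spec, protocol)
            result.to_json(out / "calibration.json")
            result.report_table().to_csv(out / "calibration_channels.csv", index=False)
            finish(
                "calibrate",
                "completed",
                ["reference_trace.csv", "calibration.json", "calibration_channels.csv"],
            )

        # -- sensitivity ---------------------------------------------------
        if cfg.study is None:
            finish("study", "skipped")
        else:
            report = run_sensitivity_study(model, protocol, **cfg.study)
            report.to_json(out / "sensitivity.json")
            report.differences_table().to_csv(out / "sensitivity_differences.csv", index=False)
            finish(
                "study", "completed", ["sensitivity.json", "sensitivity_differences.csv"]
            )

        # -- final trace + solver log --------------------------------------
        trace = run_squat(model, protocol, log=solver_log)
        trace.to_csv(out / "final_trace.csv")
        with open(out / "solver_log.json", "w") as fh:
            json.dump(solver_log, fh, indent=1)
        finish("report", "completed", ["final_trace.csv", "solver_log.json"])
    except KneesimError as exc:
        failing = _next_stage(manifest["stages"])
        finish(failing, f"failed: {exc}")
        raise
    return manifest


_STAGE_ORDER = ("generate", "settle", "calibrate", "study", "report")


def _next_stage(stages: dict) -> str:
    for name in _STAGE_ORDER:
        if name not in stages:
            return name
    return "report"


def verify_manifest(out_dir) -> bool:
    """Every manifest-listed file exists and vice versa (ignoring the manifest)."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    listed = set(manifest["files"])
    on_disk = {
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    }
    if listed != on_disk:
        raise ValidationError(
            f"manifest mismatch: only-listed={sorted(listed - on_disk)}, "
            f"only-on-disk={sorted(on_disk - listed)}"
        )
    return True
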