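"""Ligament fine-tuning against a reference squat trace.

Mirrors the model-personalization step: ligament stiffnesses (optionally
reference strains) are tuned to minimize the discrepancy between simulated
and reference kinematics and loads while maximizing their correlation.
The multi-criteria goal is scalarized per channel as::

    sum_c  w_c * [ RMSE_c / range_c  +  (1 - rho_c) / 2 ]

with ``range_c`` the reference channel range (a constant simulated channel
scores the worst-case correlation term of 1).  The search is
derivative-free - cyclic coordinate descent with a golden-section line
search per parameter in log space - because the simulator response is only
piecewise-smooth (contact and ligament slack transitions).  Only
improvements are accepted, so the objective history is non-increasing; no
claim of global optimality is made.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

_log = logging.getLogger(__name__)

from .errors import CalibrationError, SimulationError, ValidationError
from .frames import DOF_COLUMNS
from .metrics import compare_channels, pearson, rmse
from .model import KneeModel
from .simulator import SquatProtocol, SquatTrace, run_squat

#: channels entering the objective: six joint DOFs plus the two loads
OBJECTIVE_CHANNELS = tuple(DOF_COLUMNS) + ("F_ankle", "F_quad")

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class CalibrationSpec:
    """What to tune and how hard to try.

    ``free_parameters`` is a list of ``(ligament, field, lower, upper)``
    with field ``"k"`` (stiffness, N) or ``"eps_r"`` (reference strain);
    bounds must be finite with lower < upper.  ``weights`` maps channel
    names to non-negative weights (missing channels default to 1).
    """

    free_parameters: list
    weights: dict = field(default_factory=dict)
    max_iterations: int = 3  # full coordinate-descent cycles
    tolerance: float = 0.02  # relative parameter-change convergence threshold
    line_search_evals: int = 12
    seed: int = 0

    def __post_init__(self):
        if not self.free_parameters:
            raise ValidationError("calibration needs at least one free parameter")
        for entry in self.free_parameters:
            ligament, fieldname, lo, hi = entry
            if fieldname not in ("k", "eps_r"):
                raise ValidationError(f"unknown free parameter field {fieldname!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValidationError(f"bad bounds for {ligament}.{fieldname}: ({lo}, {hi})")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be non-negative")
        if self.weights and all(w == 0 for w in self.weights.values()):
            raise ValidationError("at least one weight must be positive")


@dataclass
class CalibrationResult:
    parameters: dict  # (ligament, field) -> fitted value
    objective: float
    history: list  # best objective after each accepted improvement
    converged: bool
    channel_report: list  # per-channel dicts (RMSE, rho, category)
    evaluations: int

    def report_table(self):
        import pandas as pd

        return pd.DataFrame(self.channel_report)

    def to_json(self, path=None) -> str:
        doc = {
            "parameters": {f"{l}.{f}": v for (l, f), v in self.parameters.items()},
            "objective": self.objective,
            "history": self.history,
            "converged": self.converged,
            "channel_report": self.channel_report,
            "evaluations": self.evaluations,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def objective(
    simulated: SquatTrace,
    reference: SquatTrace,
    weights: dict | None = None,
    channels=OBJECTIVE_CHANNELS,
) -> float:
    """Range-normalized RMSE plus correlation penalty, weight-summed."""
    if simulated.n_samples != reference.n_samples:
        raise ValidationError("simulated and reference traces on different grids")
    weights = weights or {}
    total = 0.0
    for c in channels:
        w = weights.get(c, 1.0)
        if w == 0.0:
            continue
        sim_c = simulated.data[c].to_numpy()
        ref_c = reference.data[c].to_numpy()
        scale = float(np.ptp(ref_c))
        err = rmse(sim_c, ref_c)
        term = err / scale if scale > 0 else err
        try:
            rho = pearson(sim_c, ref_c)
        except ValidationError:
            if np.array_equal(sim_c, ref_c):
                rho = 1.0  # identical constant channels: perfect agreement
            else:
                _log.warning("channel %s constant: correlation set to worst case", c)
                rho = -1.0
        total += w * (term + (1.0 - rho) / 2.0)
    return float(total)


def _get_param(model: KneeModel, ligament: str, fieldname: str) -> float:
    return float(getattr(model.bundles_of(ligament)[0], fieldname))


def _set_param(model: KneeModel, ligament: str, fieldname: str, value: float) -> None:
    for b in model.bundles_of(ligament):
        setattr(b, fieldname, float(value))


def calibrate(
    model: KneeModel,
    reference_trace: SquatTrace,
    spec: CalibrationSpec,
    protocol: SquatProtocol | None = None,
) -> CalibrationResult:
    """Fit the free parameters of a settled model to a reference trace.

    Works on a copy of the model's soft-tissue parameters and writes the
    best-found values back into ``model``.  A trial point whose simulation
    fails scores +inf and the search continues; if every point fails a
    :class:`CalibrationError` is raised.
    """
    protocol = protocol or SquatProtocol()
    evaluations = {"n": 0, "ok": 0}

    def evaluate(params: dict) -> float:
        for (lig, f), v in params.items():
            _set_param(model, lig, f, v)
        evaluations["n"] += 1
        try:
            trace = run_squat(model, protocol)
        except SimulationError:
            return float("inf")
        evaluations["ok"] += 1
        return objective(trace, reference_trace, spec.weights)

    params = {
        (lig, f): _get_param(model, lig, f)
        for (lig, f, _, _) in spec.free_parameters
    }
    bounds = {(lig, f): (lo, hi) for (lig, f, lo, hi) in spec.free_parameters}

    best = evaluate(params)
    history = [best] if np.isfinite(best) else []
    converged = False

    for _cycle in range(spec.max_iterations):
        start_params = dict(params)
        for key in list(params.keys()):
            lo, hi = bounds[key]
            # golden-section in log space for k (multiplicative scale),
            # linear for reference strains
            logspace = key[1] == "k" and lo > 0
            to_x = (lambda v: math.log(v)) if logspace else (lambda v: v)
            from_x = (lambda x: math.exp(x)) if logspace else (lambda x: x)
            a, b = to_x(lo), to_x(hi)
            c = b - _GOLDEN * (b - a)
            d = a + _GOLDEN * (b - a)

            def f_at(x):
                trial = dict(params)
                trial[key] = from_x(x)
                return evaluate(trial), trial

            fc, pc = f_at(c)
            fd, pd_ = f_at(d)
            best_local, best_params = (fc, pc) if fc <= fd else (fd, pd_)
            for _ in range(max(0, spec.line_search_evals - 2)):
                if fc <= fd:
                    b, d, fd = d, c, fc
                    c = b - _GOLDEN * (b - a)
                    fc, pc = f_at(c)
                    if fc < best_local:
                        best_local, best_params = fc, pc
                else:
                    a, c, fc = c, d, fd
                    d = a + _GOLDEN * (b - a)
                    fd, pd_ = f_at(d)
                    if fd < best_local:
                        best_local, best_params = fd, pd_
            if best_local < best:
                best = best_local
                params = best_params
                history.append(best)
        rel_change = max(
            (
                abs(params[k] - start_params[k])
                / max(abs(start_params[k]), 1e-12)
                for k in params
            ),
            default=0.0,
        )
        if rel_change < spec.tolerance:
            converged = True
            break

    if evaluations["ok"] == 0:
        raise CalibrationError("every calibration trial point failed to simulate")

    # leave the model at the best-found parameters and report the fit
    for (lig, f), v in params.items():
        _set_param(model, lig, f, v)
    final_trace = run_squat(model, protocol)
    report = [
        c.as_dict()
        for c in compare_channels(final_trace.data, reference_trace.data, OBJECTIVE_CHANNELS)
    ]
    if not history:
        history = [best]
    return CalibrationResult(
        parameters=params,
        objective=best,
        history=history,
        converged=converged and spec.max_iterations > 0,
        channel_report=report,
        evaluations=evaluations["n"],
    )
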