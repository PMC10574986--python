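"""Strain-difference summaries, stiffness matching, kinematic differences."""

import numpy as np
import pandas as pd
import pytest

from kneesim.errors import ValidationError
from kneesim.sensitivity import (
    INACTIVE,
    SensitivityReport,
    StrainErrorTarget,
    kinematic_difference,
    ligament_activity,
    stiffness_for_strain_error,
    strain_difference,
)
from kneesim.simulator import SquatProtocol, SquatTrace, equilibrium_settle, run_squat
from kneesim.synthetic import SyntheticKneeParams, generate_synthetic_knee


def _toy_pair(n=12, offset=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = {
        "t": np.arange(n) * 0.1,
        "FE": np.linspace(35, 90, n),
        "eps_MCL_ant": 0.04 + 0.02 * np.sin(np.linspace(0, 3, n)),
        "eps_MCL_post": 0.03 + 0.01 * np.cos(np.linspace(0, 3, n)),
        "f_MCL_ant": rng.uniform(0, 30, n),
        "f_MCL_post": rng.uniform(0, 30, n),
    }
    a = SquatTrace(pd.DataFrame(base))
    b_data = dict(base)
    b_data["eps_MCL_ant"] = base["eps_MCL_ant"] + offset
    b_data["eps_MCL_post"] = base["eps_MCL_post"] + offset
    return a, SquatTrace(pd.DataFrame(b_data))


class TestStrainDifference:
    def test_identical_traces_zero(self):
        a, _ = _toy_pair()
        assert strain_difference(a, a, "MCL") == 0.0

    def test_uniform_offset_recovered(self):
        a, b = _toy_pair(offset=0.0027)
        assert strain_difference(a, b, "MCL") == pytest.approx(0.0027, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_max_summary_dominates_mean(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _toy_pair(seed=seed)
        b.data["eps_MCL_ant"] += rng.normal(0, 0.002, len(b.data))
        assert strain_difference(a, b, "MCL", "max") >= strain_difference(a, b, "MCL", "mean")

    def test_unknown_ligament_raises(self):
        a, b = _toy_pair()
        with pytest.raises(ValidationError):
            strain_difference(a, b, "ACL")

    def test_grid_mismatch_raises(self):
        a, _ = _toy_pair(n=10)
        _, b = _toy_pair(n=12)
        with pytest.raises(ValidationError):
            strain_difference(a, b, "MCL")


class TestKinematicDifference:
    def _trace(self, values):
        n = len(next(iter(values.values())))
        data = {c: np.zeros(n) for c in ["t", "FE", "VV", "IE", "AP", "ML", "IS"]}
        data.update(values)
        return SquatTrace(pd.DataFrame(data))

    def test_identical_traces_zero(self):
        t = self._trace({"IE": np.arange(5.0)})
        d = kinematic_difference(t, t)
        for dof in d:
            assert d[dof] == {"mean": 0.0, "sd": 0.0}

    def test_constant_ie_offset_signed_optimal_minus_perturbed(self):
        opt = self._trace({"IE": np.arange(5.0)})
        pert = self._trace({"IE": np.arange(5.0) - 1.0})
        d = kinematic_difference(opt, pert)
        assert d["IE"] == {"mean": 1.0, "sd": 0.0}

    def test_matches_hand_computed_five_sample_oracle(self):
        opt = self._trace({"VV": np.array([1.0, 2.0, 0.0, -1.0, 3.0])})
        pert = self._trace({"VV": np.array([0.0, 1.0, 1.0, 1.0, 1.0])})
        diff = np.array([1.0, 1.0, -1.0, -2.0, 2.0])
        d = kinematic_difference(opt, pert)["VV"]
        assert d["mean"] == pytest.approx(diff.mean())
        assert d["sd"] == pytest.approx(diff.std())

    def test_flexion_excluded(self):
        t = self._trace({"IE": np.arange(4.0)})
        assert "FE" not in kinematic_difference(t, t)


@pytest.fixture(scope="module")
def protocol():
    return SquatProtocol(cycle_samples=21)


@pytest.fixture(scope="module")
def lax_lcl_model():
    """A knee whose LCL stays below its zero-load length all cycle,
    emulating a poorly balanced, lax lateral compartment."""
    params = SyntheticKneeParams(ligament_params={"LCL": {"eps_r": -0.05}})
    model = generate_synthetic_knee(params)
    equilibrium_settle(model)
    return model


class TestStiffnessMatching:

    def test_inactive_ligament_yields_sentinel(self, lax_lcl_model, protocol):
        trace = run_squat(lax_lcl_model.copy(), protocol)
        assert not ligament_activity(trace, "LCL").active
        low, high = stiffness_for_strain_error(
            lax_lcl_model.copy(), "LCL", StrainErrorTarget("LCL", 0.0057), protocol
        )
        assert low.k == INACTIVE and high.k == INACTIVE

    def test_perturbing_inactive_ligament_has_no_mechanical_effect(
        self, lax_lcl_model, protocol
    ):
        """A never-taut ligament transmits no force, so its stiffness cannot
        alter the motion: its recorded force stays identically zero and the
        traces agree to solver precision (the iterative solver's trial
        evaluations may transiently tension the slack bundle, which perturbs
        the floating-point path but not the equilibria)."""
        nominal = run_squat(lax_lcl_model.copy(), protocol)
        perturbed_model = lax_lcl_model.copy()
        for b in perturbed_model.bundles_of("LCL"):
            b.k = 5 * b.k
        perturbed = run_squat(perturbed_model, protocol)
        assert (nominal.data["f_LCL"] == 0).all()
        assert (perturbed.data["f_LCL"] == 0).all()
        assert np.allclose(nominal.data.to_numpy(), perturbed.data.to_numpy(), atol=1e-6)

    def test_small_target_stays_near_nominal_stiffness(self, settled_model, protocol):
        """Continuity at vanishing perturbation: a tiny strain-error target
        must return stiffnesses close to the nominal value."""
        model = settled_model.copy()
        nominal = run_squat(model.copy(), protocol)
        low, high = stiffness_for_strain_error(
            model,
            "MCL",
            StrainErrorTarget("MCL", 2e-5),
            protocol,
            nominal_trace=nominal,
        )
        k_nom = 400.0
        assert abs(high.k - k_nom) / k_nom < 0.10
        assert abs(low.k - k_nom) / k_nom < 0.10


class TestReportSerialization:
    def test_json_round_trip_lossless(self, tmp_path):
        report = SensitivityReport(
            stiffness_windows={"MCL": {"k_nominal": 400.0, "k_low": 200.0, "k_high": 900.0}},
            scenarios={
                "MCL_k_up": {
                    "kind": "stiffness",
                    "k": 900.0,
                    "differences": {"IE": {"mean": -0.5, "sd": 0.1}},
                }
            },
            us_vs_imp={"MCL_k_up__vs__implant_ie_+3.2": {"IE": {"mean": 1.0, "sd": 0.2}}},
            curves={"MCL_k_up": {"FE": [35.0, 90.0], "dVV": [0.0, 0.1], "dIE": [0.0, -0.4]}},
            meta={"targets": {"MCL": 0.0027}},
        )
        path = tmp_path / "report.json"
        report.to_json(path)
        back = SensitivityReport.from_json(path)
        assert back.stiffness_windows == report.stiffness_windows
        assert back.scenarios == report.scenarios
        assert back.us_vs_imp == report.us_vs_imp
        assert back.curves == report.curves
        assert back.window("MCL") == (200.0, 900.0)

    def test_target_validation(self):
        with pytest.raises(ValidationError):
            StrainErrorTarget("MCL", 0.0)
        with pytest.raises(ValidationError):
            StrainErrorTarget("MCL", 0.001, "sideways")
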