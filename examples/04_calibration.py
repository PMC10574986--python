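"""Recover a known MCL stiffness from a self-generated reference squat.

The reference trace is simulated with the true stiffness (400 N); the model
is then detuned to 650 N and the coordinate-descent calibration minimizes
the per-channel RMSE + correlation objective to recover the truth.  A
coarse cycle grid keeps the demo quick.
"""

from kneesim import generate_synthetic_knee
from kneesim.calibration import CalibrationSpec, calibrate
from kneesim.simulator import SquatProtocol, equilibrium_settle, run_squat

model = generate_synthetic_knee()
equilibrium_settle(model)
protocol = SquatProtocol(cycle_samples=21)

reference = run_squat(model.copy(), protocol)  # truth: k_MCL = 400 N
for b in model.bundles_of("MCL"):
    b.k = 650.0  # detuned starting point

spec = CalibrationSpec(
    free_parameters=[("MCL", "k", 100.0, 1600.0)],
    max_iterations=2,
    line_search_evals=12,
)
result = calibrate(model, reference, spec, protocol)

fitted = result.parameters[("MCL", "k")]
print(f"fitted k_MCL = {fitted:.1f} N (truth 400 N, started at 650 N)")
print(f"objective {result.objective:.6f} after {result.evaluations} simulations")
print("per-channel agreement with the reference trace:")
print(result.report_table().round(4).to_string(index=False))
print("An objective near zero and excellent correlations mean the detuned "
      "model was pulled back onto the reference kinematics and loads.")
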