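"""Recover a perturbed death-rate constant by calibration.

Starts the p38-death rate at four times its reference value and lets the
coordinate search pull it back toward the value consistent with ~25% death
by 30 h in the untreated arm, mirroring the fit-compare-modify loop used
to parameterise the model in the first place.  Small ensembles keep the
demonstration quick; the objective uses common random numbers so it is a
deterministic function of the parameters.
"""

from polyqsim import CalibrationTarget, fit_parameters
from polyqsim.network import DEFAULT_PARAMETERS

reference = DEFAULT_PARAMETERS["k_p38death"]
targets = (CalibrationTarget("percent_dead_at", 30.0, 25.0, tolerance=5.0),)

fitted, report = fit_parameters(
    ["k_p38death"],
    targets,
    initial={"k_p38death": 4.0 * reference},
    n_runs=60,
    final_n_runs=120,
    base_seed=5,
    max_cycles=4,
)

print(f"reference k_p38death : {reference:.3e} /h per active kinase")
print(f"perturbed start      : {4 * reference:.3e}")
print(f"recovered value      : {fitted['k_p38death']:.3e}")
print(f"objective            : {report.initial_objective:.2f} -> {report.final_objective:.2f}")
print(f"full-scale check     : {report.final_check}")
print(
    "\nThe recovered rate lands within a factor ~2 of the reference — the death\n"
    "percentage constrains the rate only through a noisy 30 h ensemble summary,\n"
    "which is exactly the precision manual fit-and-check calibration achieves."
)
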