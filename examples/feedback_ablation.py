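"""Interrogate the p38MAPK -> ROS positive-feedback loop.

Removes the single reaction in which active p38 generates ROS, reruns the
untreated and p38-inhibitor ensembles with matched seeds, and prints the
two signatures that make the loop necessary: death falls everywhere, and
the p38 inhibitor loses its effect on inclusion formation.
"""

from polyqsim import (
    ScenarioConfig,
    ablate_feedback,
    build_polyq_model,
    percent_dead,
    percent_with_inclusions,
    run_ensemble,
)

N, SEED = 100, 11

for arm in ("untreated", "SKF"):
    scen = ScenarioConfig(treatment=arm, n_runs=N, base_seed=SEED)
    intact = run_ensemble(scen)
    ablated = run_ensemble(scen, model=ablate_feedback(build_polyq_model(scen)))
    d_fb = percent_dead(intact, 30.0).values[0]
    d_ab = percent_dead(ablated, 30.0).values[0]
    i_fb = percent_with_inclusions(intact).at(36.0)
    i_ab = percent_with_inclusions(ablated).at(36.0)
    print(
        f"{arm:>10}: dead@30h {d_fb:5.1f}% -> {d_ab:5.1f}% ablated;  "
        f"incl@36h {i_fb:5.1f}% -> {i_ab:5.1f}% ablated"
    )

print(
    "\nWith the loop cut, untreated and p38-inhibited cells become nearly\n"
    "indistinguishable in inclusion formation — the model's way of saying that\n"
    "p38MAPK matters for aggregation only through the ROS it generates."
)
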