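"""Compare the four treatment arms at ensemble level.

Runs modest ensembles (60 cells each; the headline figures use 300) of the
untreated, proteasome-inhibitor (PI, from 24 h), glutathione-depletion
(BSO, from 24 h) and p38-inhibitor (SKF86002, from time 0) scenarios and
prints the three readouts: % dead by 30 h, % of cells with an inclusion
body, and the mean mRFPu reporter level.
"""

from polyqsim import (
    ScenarioConfig,
    mean_mrfpu,
    percent_dead,
    percent_with_inclusions,
    run_ensemble,
)

N, SEED = 60, 11

print(f"{'arm':>10} {'dead@30h':>10} {'incl@30h':>9} {'incl@36h':>9} "
      f"{'incl@48h':>9} {'mRFPu@36h':>10}")
for arm in ("untreated", "PI", "BSO", "SKF"):
    ens = run_ensemble(ScenarioConfig(treatment=arm, n_runs=N, base_seed=SEED))
    dead = percent_dead(ens, 30.0)
    incl = percent_with_inclusions(ens)
    rep = mean_mrfpu(ens)
    print(
        f"{arm:>10} {dead.values[0]:8.1f}%  {incl.at(30.0):7.1f}%  {incl.at(36.0):7.1f}%  "
        f"{incl.at(48.0):7.1f}%  {rep.at(36.0):9.0f}"
    )

print(
    "\nExpected pattern: the proteasome inhibitor accelerates inclusion formation\n"
    "and sends the degron reporter soaring, while its effect on death only 6 h\n"
    "after dosing is small; the p38 inhibitor lowers death, inclusions and\n"
    "reporter levels together; glutathione depletion raises ROS and hence both\n"
    "aggregation and reporter load after 24 h."
)
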