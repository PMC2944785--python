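"""Simulate one untreated cell and narrate its fate.

Builds the untreated polyQ model, runs a single exact stochastic
realisation to 48 h, and prints the milestones a live-cell imaging
experiment would see: reporter accumulation, inclusion-body onset, and
(possibly) death with its cause.
"""

import numpy as np

from polyqsim import ScenarioConfig, build_polyq_model, simulate

scenario = ScenarioConfig(treatment="untreated", base_seed=4)
model = build_polyq_model(scenario)
grid = np.arange(1, 97) * 0.5  # sample every 30 min to 48 h
traj = simulate(model, horizon=48.0, grid=grid, seed=4)

onset = next((t for t in grid if traj.value_at("SeqAggP", t) >= 1), None)
print("hour  PolyQ  oligomers  boundProt  ROS  p38_P  mRFPu  inclusion")
for t in (12.0, 24.0, 30.0, 36.0, 42.0, 48.0):
    olig = sum(traj.value_at(f"AggPolyQ{i}", t) for i in range(1, 6))
    print(
        f"{t:4.0f}  {traj.value_at('PolyQ', t):5d}  {olig:9d}  "
        f"{traj.value_at('AggP_Proteasome', t):9d}  {traj.value_at('ROS', t):3d}  "
        f"{traj.value_at('p38_P', t):5d}  {traj.value_at('mRFPu', t):5d}  "
        f"{traj.value_at('SeqAggP', t):9d}"
    )

print()
if onset is not None:
    print(f"inclusion body first seen at {onset:.1f} h (SeqAggP counts sequestered monomer units)")
else:
    print("no inclusion body formed within 48 h")
if traj.alive:
    print("the cell is alive at 48 h")
else:
    print(f"the cell died at {traj.death_time:.1f} h via the {traj.death_cause} pathway")
print(
    "\nRising mRFPu reports declining proteasome capacity; ROS above its basal ~10\n"
    "molecules accelerates aggregation and activates p38MAPK, whose active form\n"
    "both feeds back into ROS production and drives one of the two death hazards."
)
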