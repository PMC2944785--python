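# Model and methods

## The model

`polyqsim` simulates a single cultured cell expressing an expanded
polyglutamine (polyQ) protein — an HttQ103-like huntingtin exon-1 fragment —
as a network of ~50 discrete-molecule reactions advanced with the exact
Gillespie direct method. The state is a vector of integer copy numbers;
time is in hours and every rate constant is per hour. Copy numbers are
small enough (tens to low thousands) that cell-to-cell stochasticity
dominates outcomes, which is the phenomenon of interest: nominally
identical cells form inclusions and die at widely different times.

The network couples six processes:

1. **polyQ turnover.** Continuous synthesis from transfection at t=0;
   degradation is a catalytic collision with a free proteasome
   (`PolyQ + Proteasome -> Proteasome`), so the effective first-order rate
   scales with the free fraction of the proteasome pool. Synthesis and
   degradation constants are tied so the half-life is 20 h when the
   proteasome is uninhibited, with a steady pool of ~3000 monomers.
2. **Nucleated aggregation.** Two monomers form a dimer (`AggPolyQ1`,
   rate `k_nucPolyQ`); oligomers grow reversibly one monomer at a time
   (`k_aggPolyQ`/`k_disaggPolyQ`) up to the hexamer. Six monomers is the
   seed: the addition step from `AggPolyQ5` converts the material
   irreversibly into an inclusion body (`SeqAggP` counts sequestered
   monomer units; `Inclusion` counts bodies). The ladder is subcritical —
   most dimers dissolve — so seeding is a rare first-passage event with the
   long, broadly distributed lag times characteristic of amyloid formation.
3. **Inclusion growth and sequestration.** Each inclusion body sequesters
   monomers, oligomers, misfolded protein and proteasome-bound material at
   a surface-limited rate (proportional to the number of bodies, not their
   mass); proteasome-bound aggregates are taken up faster
   (`k_seqAggPProt`), which is the mechanism by which inclusions relieve
   both ROS production and the bound-proteasome death drive. Sequestered
   proteasomes stay inside the inclusion (`SeqAggP_Proteasome`).
4. **Proteasome inhibition.** Oligomers of four or more monomers bind free
   proteasomes into inactive `AggP_Proteasome` complexes. A degron
   reporter (`mRFPu`, 30 min uninhibited half-life, steady pool ~100)
   reads out remaining capacity, exactly as the fluorescent reporter does
   in the imaging experiments the model mirrors.
5. **ROS and p38MAPK.** ROS has basal generation and first-order removal
   (half-life 1 h, stationary mean ~10 molecules). Small aggregates — free
   or proteasome-bound — generate additional ROS; inclusions do so at a
   15-fold lower per-unit rate. ROS above basal (i) multiplies the
   aggregation and misfolding rates by the linear factor
   `1 + alpha*(ROS-basal)/basal` and (ii) activates p38MAPK
   (`p38 -> p38_P`, propensity proportional to the excess over basal).
   Active p38_P generates further ROS (`k_genROSp38`) — the positive
   feedback loop the package exists to interrogate.
6. **Cell death.** Two hazards, realised as reactions whose product is a
   cause flag; an event then zeroes the gating parameter `k_alive`, which
   multiplies every propensity, so a dead cell is absorbing and its counts
   freeze. The p38 hazard is linear in `p38_P` (any single active kinase
   can, rarely, kill). The proteasome hazard is a steep power law in the
   aggregate-bound fraction, normalised at the ~50% threshold:
   `k_PIdeath * ((bound/total)/0.5)^4`, a small leak at low occupancy
   rising sharply toward the threshold.

A generic native/misfolded protein pool (`NatP`/`MisP`, with ROS-modulated
misfolding) supplies background proteasome load; its occupancy is what
separates the reporter levels of high-ROS and low-ROS arms.

## Treatments

- **PI** (proteasome inhibitor): at 24 h an event multiplies all
  proteasome-mediated degradation rates by 0 (the drug concentration is
  treated as saturating).
- **BSO** (glutathione depletion): at 24 h ROS removal is slowed 5-fold.
- **SKF86002** (p38 inhibitor, applied before transfection): the p38
  activation rate is zero from t=0.
- **Feedback ablation**: removal of exactly the `p38_P -> ROS` reaction.
- **No-feedback refit**: the ablated model with `k_aggPolyQ` x2,
  `k_p38death` x8 and `k_PIdeath` x2, the analogue of refitting the
  loop-less model to the untreated data.

## Parameters

Constants pinned by the biology: polyQ half-life 20 h (uninhibited),
mRFPu half-life 30 min, ROS half-life 1 h and basal mean 10 molecules,
seed size six, proteasome-death threshold 50%, treatment times (24 h for
PI/BSO, 0 for SKF), ensemble size 300, horizon 48 h. Initial pools:
500 proteasomes (conserved across free/bound/sequestered forms), 100 p38
(conserved across phospho-forms), 2500 NatP, 10 ROS.

Everything else is this package's calibration, fitted with the
`calibration` module's coordinate search plus manual iteration against the
untreated anchors (~25% death by 30 h; inclusion fraction in the 20–60%
band at 36 h and still rising at 48 h) and then checked against the
treatment orderings. The shipped values live in
`polyqsim.network.DEFAULT_PARAMETERS`; the headline ones are the
nucleation/growth pair (`k_nucPolyQ` 4.25e-5, `k_aggPolyQ` 5.6e-5 with
dissociation 0.4/h), the ROS gain `alpha` = 0.266, the feedback strength
`k_genROSp38` = 1.2, and the two death coefficients (`k_p38death` 6.4e-4
per active kinase; `k_PIdeath` 2.2/h at the 50% threshold).

## Design choices in the open

- **Nucleation vs growth constants.** With one shared aggregation constant
  the synthesis flux caps aggregate production identically in every arm
  (monomer-pool depletion cancels the ROS factor) and no treatment
  ordering can emerge; the slow-nucleation/fast-exchange split is also the
  standard nucleated-polymerization picture for amyloids.
- **Monomer budget.** The polyQ pool is set high enough (~3000) that
  synthesis/degradation dominate the monomer budget. If aggregation
  consumed a large share, pool depletion would again equalise the arms.
- **Which oligomers inhibit.** Only tetramers and larger bind proteasomes.
  Binding from every rung would tie the bound pool to the nucleation flux
  (arm-independent, see above); binding from the upper rungs scales
  steeply (~f^3–f^5) with the ROS factor and preserves the arm separation.
- **Inclusion growth law.** Growth proportional to the number of bodies
  (surface-limited) rather than to sequestered mass. Mass-proportional
  growth is exponential and swallows the monomer pool within hours of
  seeding, which contradicts the observed stationarity of the oligomer
  pool in inclusion-bearing cells.
- **ROS-modulated misfolding.** Oxidative damage to the generic protein
  pool is the only mechanism in the network that lets high-ROS arms load
  the proteasome with extra substrate; without it the BSO reporter rise
  and the untreated-vs-SKF reporter separation cannot occur.
- **Hazard shapes.** Linear for p38 (simplest form positive at one
  molecule); threshold-normalised power law with exponent 4 for the
  proteasome channel (hazard at 50% bound is 625x the hazard at 10%).
- **Dead cells in summaries.** Dead cells contribute their frozen state to
  inclusion percentages and reporter means. Freezing preserves per-run
  monotonicity of inclusion formation and avoids survivorship jumps; it is
  also what makes the no-feedback refit fail in the observed direction
  (dying untreated cells freeze before seeding, so the p38-inhibited arm
  overtakes them in inclusion count).
- **Event semantics.** Events fire once; a time trigger inside a drawn
  waiting interval advances the clock only to the trigger and discards the
  drawn reaction (propensities are stale after a parameter jump);
  simultaneous events apply in declaration order. The paper-level events
  (treatment at 24 h, death flags) never co-occur by construction.

## Numerical choices

- Direct SSA, no approximations: copy numbers are small and the death
  hazards live in distribution tails where leaping would bias.
- One independent RNG stream per replicate cell, derived by mixing the
  replicate index into the ensemble base seed (`numpy` `SeedSequence`);
  ensembles are bit-reproducible and order-independent.
- Trajectories are recorded on a 0.5 h grid (right-continuous step
  interpolation); reporting grids (6 h cadence from 24 h for inclusion
  percentages) are downsampled from it. Half-life protocols use finer
  grids (0.02 h) to keep quantization below the tolerance.
- Half-life measurement: median over replicates of the first grid time the
  pool falls to half its value at the shut-off; runs that never halve are
  censored to +inf, and the median is infinite only if most runs censor.
- The half-life protocol variant disables nucleation, aggregate binding
  and generic misfolding so the proteasome pool is exactly free — the
  measured value is then the turnover constant the protocol defines, not a
  partially-inhibited mixture.
- Calibration uses common random numbers (fixed seed block per objective
  evaluation), making the objective deterministic in the parameters;
  cyclic coordinate descent on log-scaled parameters with step halving,
  ensemble size 100 during search and 300 for the final check.

## Problem sizes

Ensemble summaries and the ordering checks use the full 300 replicates to
48 h (one ensemble simulates in ~10–20 s). Engine-validation fixtures use
100–200 replicates; calibration demonstrations use 40–120 replicates.
The half-life targets use 100 replicates, and the stationary-ROS target
50 replicates averaged over a 50 h window.

## What the simulations do and do not show

All data here are synthetic: the generator *is* the model, so passing
checks demonstrate internal consistency — that the implemented network
reproduces the anchor outcomes and orderings it was built around — not
that the network is a validated description of polyQ biology. Real
readouts (fluorescence intensities, flow-cytometry death calls) involve
measurement noise, thresholding and population heterogeneity that the
molecule-count summaries ignore; the mRFPu scale in particular is
arbitrary (molecule counts, not fluorescence units).

## Known limitations

- The proteasome-inhibitor arm reproduces the qualitative predictions
  (earlier and more numerous inclusions, soaring reporter, late excess of
  inclusions without the feedback loop) but its predicted *reduction* of
  death at 30 h is small here (~0–4 percentage points, sign-correct on
  most seeds) — only 6 h separate treatment from readout, and the drug
  simultaneously raises the monomer pool (more oligomer production) and
  relieves binding (inclusion uptake, substrate competition), effects that
  nearly cancel in the bound-proteasome trajectory.
- The untreated and p38-inhibited inclusion curves run parallel over
  36–48 h in most realisations, but the comparison is noisy at n=300 and
  an unlucky ensemble can concentrate the untreated rise early in the
  window.
- BSO is modelled only as slowed ROS removal; glutathione itself is not a
  species.
- No explicit pro-apoptotic protein (e.g. p53): the proteasome death
  channel lumps that pathway into a hazard on the bound fraction.
- Autophagy, spatial structure, cell division and the non-pathogenic
  HttQ25 control are out of scope.
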