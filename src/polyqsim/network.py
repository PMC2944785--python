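"""The polyglutamine / proteasome / p38MAPK cytotoxicity network.

One simulated "cell" carries an expanded-polyQ protein (an HttQ103-like
huntingtin exon-1 fragment) that is continuously synthesised and degraded by
the proteasome, nucleates into small reversible oligomers (AggPolyQ1..5,
holding 2..6 monomers), and past the seed size of six monomers collapses
irreversibly into an inclusion-body pool (SeqAggP, counted in sequestered
monomer units; Inclusion counts bodies).  Small aggregates generate
reactive oxygen species (ROS), and the larger ones (tetramers and up) bind
and inhibit proteasomes; inclusions generate ROS at a much lower per-unit
rate.  ROS above its basal level both accelerates aggregation and
activates the stress kinase p38MAPK (p38 -> p38_P); active p38_P feeds back
into ROS production — the "vicious cycle" — and drives one death hazard,
while the fraction of aggregate-bound proteasome drives a second, steeply
threshold-like hazard.  A degron reporter (mRFPu) with a 30-minute
uninhibited half-life reads out proteasome capacity, and a generic
native/misfolded protein pool (NatP/MisP) supplies background proteasome
load and inclusion growth material.

Printed constraints pin several constants: polyQ half-life 20 h with an
uninhibited proteasome, mRFPu half-life 30 min, ROS half-life 1 h with a
basal mean of ~10 molecules, seed size six, proteasome-death threshold ~50%.
Every remaining rate is a calibration product of this package (see
docs/methods.md); the untreated scenario is calibrated to ~25% cell death
by 30 h over 300 replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .core import (
    ALIVE_PARAM,
    PI_EXPONENT_PARAM,
    PI_THRESHOLD_PARAM,
    PROT_TOTAL_PARAM,
    ROS_ALPHA_PARAM,
    ROS_BASAL_PARAM,
    EventDef,
    ModelDef,
    ReactionDef,
    SpeciesDef,
)

__all__ = [
    "ScenarioConfig",
    "TREATMENTS",
    "DEFAULT_PARAMETERS",
    "INITIAL_COUNTS",
    "FEEDBACK_REACTION_ID",
    "build_polyq_model",
    "build_ros_submodel",
    "build_halflife_model",
    "p38_death_hazard",
    "proteasome_death_hazard",
    "has_inclusion",
    "oligomer_species",
]

TREATMENTS = ("untreated", "PI", "BSO", "SKF")

#: reaction id of the p38_P -> ROS positive-feedback channel
FEEDBACK_REACTION_ID = "genROSp38"

LN2 = math.log(2.0)

#: total proteasome copies per cell; conserved across free, aggregate-bound,
#: misfolded-substrate-bound and inclusion-sequestered pools
N_PROTEASOME = 500

#: initial copy numbers (transfection at t=0: no polyQ protein yet)
INITIAL_COUNTS: Dict[str, int] = {
    "PolyQ": 0,
    "AggPolyQ1": 0,
    "AggPolyQ2": 0,
    "AggPolyQ3": 0,
    "AggPolyQ4": 0,
    "AggPolyQ5": 0,
    "SeqAggP": 0,
    "Inclusion": 0,
    "Proteasome": N_PROTEASOME,
    "AggP_Proteasome": 0,
    "MisP_Proteasome": 0,
    "SeqAggP_Proteasome": 0,
    "mRFPu": 0,
    "ROS": 10,
    "p38": 100,
    "p38_P": 0,
    "NatP": 2500,
    "MisP": 0,
    "p38_death_flag": 0,
    "proteasome_death_flag": 0,
}

_ROLES = {
    "PolyQ": "protein",
    "SeqAggP": "aggregate",
    "Inclusion": "aggregate",
    "Proteasome": "protein",
    "AggP_Proteasome": "complex",
    "MisP_Proteasome": "complex",
    "SeqAggP_Proteasome": "complex",
    "mRFPu": "reporter",
    "ROS": "signal",
    "p38": "signal",
    "p38_P": "signal",
    "NatP": "protein",
    "MisP": "protein",
    "p38_death_flag": "flag",
    "proteasome_death_flag": "flag",
}

# Rate constants are per hour.  Constants pinned by printed values are
# expressed through them (half-lives, basal ROS); the rest are the package's
# calibration against the untreated death/inclusion outcomes.
DEFAULT_PARAMETERS: Dict[str, float] = {
    ALIVE_PARAM: 1.0,
    ROS_BASAL_PARAM: 10.0,
    ROS_ALPHA_PARAM: 0.266,
    PROT_TOTAL_PARAM: float(N_PROTEASOME),
    PI_EXPONENT_PARAM: 4.0,
    PI_THRESHOLD_PARAM: 0.5,
    # polyQ turnover: steady pool ~3000 monomers, half-life 20 h uninhibited
    "k_synPolyQ": 3000 * LN2 / 20.0,
    "k_degPolyQ": LN2 / 20.0 / N_PROTEASOME,
    # aggregation ladder (calibrated): slow nucleation, reversible growth
    "k_nucPolyQ": 4.25e-5,
    "k_aggPolyQ": 5.6e-5,
    "k_disaggPolyQ": 0.4,
    "k_seqAggP": 7.98e-2,
    "k_seqAggPProt": 1.25,
    "k_inhprot": 2.926e-3,
    # reporter: steady pool ~100, half-life 30 min uninhibited
    "k_synmRFPu": 100 * LN2 / 0.5,
    "k_degmRFPu": LN2 / 0.5 / N_PROTEASOME,
    # ROS: half-life 1 h, basal stationary mean 10
    "k_genROS": 10.0 * LN2,
    "k_remROS": LN2,
    "k_genROSAggP": 0.03,
    "k_genROSSeqAggP": 0.002,
    # p38MAPK module (calibrated)
    "k_actp38": 5.32e-3,
    "k_inactp38": 0.6,
    "k_genROSp38": 1.2,
    # death hazards (calibrated)
    "k_p38death": 6.4e-4,
    "k_PIdeath": 2.2,
    # generic native/misfolded pool
    "k_misfold": 3.2e-3,
    "k_refold": 6.25e-2,
    "k_binMisPProt": 1.6e-3,
    "k_degMisP": 0.128,
}

#: treatment magnitudes (scenario wiring, not kinetic constants)
PI_INHIBITION_FACTOR = 0.0  # pharmacological PI treated as saturating
BSO_REMROS_FACTOR = 0.2  # glutathione depletion slows ROS clearance 5-fold
TREATMENT_TIME_H = 24.0  # PI and BSO applied 24 h post-transfection


@dataclass
class ScenarioConfig:
    """One computer experiment: treatment arm, feedback wiring, ensemble size."""

    treatment: str = "untreated"
    feedback_on: bool = True
    horizon: float = 48.0
    n_runs: int = 300
    base_seed: int = 1
    overrides: Dict[str, float] = field(default_factory=dict)
    record_dt: float = 0.5

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.horizon <= 0 or self.n_runs <= 0:
            raise ValueError("horizon and n_runs must be positive")


def p38_death_hazard(p38P: float, k_p38death: float) -> float:
    """Death hazard of the p38 pathway: linear in active kinase.

    Zero with no active p38; any single p38_P molecule gives a positive
    hazard, so even low activation occasionally kills a cell.
    """
    if p38P < 0:
        raise ValueError("p38_P count must be non-negative")
    return k_p38death * p38P

def proteasome_death_hazard(
    bound: float,
    total: float,
    k_PIdeath: float,
    exponent: float = 6.0,
    threshold: float = 0.5,
) -> float:
    """Death hazard of the proteasome-inhibition pathway.

    A power law in the aggregate-bound fraction normalised at the ~50%
    threshold, ``k * ((bound/total)/threshold)**h``, so ``k_PIdeath`` is the
    hazard (per hour) of a cell sitting exactly at the threshold.  The form
    gives a small leak at low occupancy and a steep rise towards the
    threshold; with h=6 the hazard at 50% bound is 15625x the hazard at 10%.
    """
    if total <= 0:
        raise ValueError("total proteasome count must be positive")
    if bound < 0 or bound > total:
        raise ValueError("bound count must lie in [0, total]")
    return k_PIdeath * ((bound / total) / threshold) ** exponent


def oligomer_species() -> List[str]:
    return [f"AggPolyQ{i}" for i in range(1, 6)]


def has_inclusion(counts_or_traj, t: Optional[float] = None) -> bool:
    """True iff the inclusion pool SeqAggP holds at least one unit.

    Accepts a counts mapping, a CellState, or a Trajectory (with ``t``).
    SeqAggP has no consuming reaction, so once true this stays true.
    """
    if t is not None:
        return counts_or_traj.value_at("SeqAggP", t) >= 1
    counts = getattr(counts_or_traj, "counts", counts_or_traj)
    return counts["SeqAggP"] >= 1


def _species_list(params_init: Dict[str, int]) -> List[SpeciesDef]:
    out = []
    for name, n0 in params_init.items():
        role = _ROLES.get(name, "aggregate" if name.startswith("AggPolyQ") else "protein")
        out.append(SpeciesDef(name, n0, role))
    return out


def _reactions(feedback_on: bool) -> List[ReactionDef]:
    R = ReactionDef
    rx: List[ReactionDef] = [
        # polyQ turnover; degradation is catalytic in free proteasome so the
        # effective rate scales with the uninhibited fraction
        R("synPolyQ", (), (("PolyQ", 1),), "k_synPolyQ"),
        R("degPolyQ", (("PolyQ", 1), ("Proteasome", 1)), (("Proteasome", 1),), "k_degPolyQ"),
        # nucleation: two monomers collide; ROS above basal accelerates
        R(
            "aggPolyQ1",
            (("PolyQ", 2),),
            (("AggPolyQ1", 1),),
            "k_nucPolyQ",
            "ros_modulated_mass_action",
            ("ROS",),
        ),
    ]
    # reversible ladder growth AggPolyQ_i + PolyQ <-> AggPolyQ_{i+1}
    for i in range(1, 5):
        rx.append(
            R(
                f"aggPolyQ{i + 1}",
                ((f"AggPolyQ{i}", 1), ("PolyQ", 1)),
                ((f"AggPolyQ{i + 1}", 1),),
                "k_aggPolyQ",
                "ros_modulated_mass_action",
                ("ROS",),
            )
        )
    rx.append(R("disaggPolyQ1", (("AggPolyQ1", 1),), (("PolyQ", 2),), "k_disaggPolyQ"))
    for i in range(2, 6):
        rx.append(
            R(
                f"disaggPolyQ{i}",
                ((f"AggPolyQ{i}", 1),),
                ((f"AggPolyQ{i - 1}", 1), ("PolyQ", 1)),
                "k_disaggPolyQ",
            )
        )
    # seeding: the sixth monomer converts the largest oligomer into an
    # inclusion body of six sequestered units; irreversible.  SeqAggP
    # tallies sequestered monomer units, Inclusion counts bodies.
    rx.append(
        R(
            "seedSeqAggP",
            (("AggPolyQ5", 1), ("PolyQ", 1)),
            (("SeqAggP", 6), ("Inclusion", 1)),
            "k_aggPolyQ",
            "ros_modulated_mass_action",
            ("ROS",),
        )
    )
    # inclusion growth: each body sequesters monomers, misfolded protein,
    # oligomers and proteasome-bound material at a surface-limited rate
    # (per body, not per sequestered unit); proteasomes stay inside the
    # inclusion (SeqAggP_Proteasome tally) and are never released
    rx.append(
        R(
            "seqPolyQ",
            (("Inclusion", 1), ("PolyQ", 1)),
            (("Inclusion", 1), ("SeqAggP", 1)),
            "k_seqAggP",
        )
    )
    rx.append(
        R(
            "seqMisP",
            (("Inclusion", 1), ("MisP", 1)),
            (("Inclusion", 1), ("SeqAggP", 1)),
            "k_seqAggP",
        )
    )
    for i in range(1, 6):
        rx.append(
            R(
                f"seqAggPolyQ{i}",
                (("Inclusion", 1), (f"AggPolyQ{i}", 1)),
                (("Inclusion", 1), ("SeqAggP", i + 1)),
                "k_seqAggP",
            )
        )
    rx.append(
        R(
            "seqAggPProteasome",
            (("Inclusion", 1), ("AggP_Proteasome", 1)),
            (("Inclusion", 1), ("SeqAggP", 2), ("SeqAggP_Proteasome", 1)),
            "k_seqAggPProt",
        )
    )
    rx.append(
        R(
            "seqMisPProteasome",
            (("Inclusion", 1), ("MisP_Proteasome", 1)),
            (("Inclusion", 1), ("SeqAggP", 1), ("SeqAggP_Proteasome", 1)),
            "k_seqAggPProt",
        )
    )
    # proteasome inhibition by small aggregates: only oligomers of four or
    # more monomers are bulky enough to jam the degradation machinery
    for i in range(3, 6):
        rx.append(
            R(
                f"inhProt{i}",
                ((f"AggPolyQ{i}", 1), ("Proteasome", 1)),
                (("AggP_Proteasome", 1),),
                "k_inhprot",
            )
        )
    # degron reporter
    rx.append(R("synmRFPu", (), (("mRFPu", 1),), "k_synmRFPu"))
    rx.append(
        R("degmRFPu", (("mRFPu", 1), ("Proteasome", 1)), (("Proteasome", 1),), "k_degmRFPu")
    )
    # ROS: basal turnover plus generation by small aggregates (free and
    # proteasome-bound) and, much more weakly, by inclusions
    rx.append(R("genROS", (), (("ROS", 1),), "k_genROS"))
    rx.append(R("remROS", (("ROS", 1),), (), "k_remROS"))
    for sp in oligomer_species() + ["AggP_Proteasome"]:
        rx.append(
            R(f"genROS_{sp}", ((sp, 1),), ((sp, 1), ("ROS", 1)), "k_genROSAggP")
        )
    rx.append(
        R(
            "genROS_SeqAggP",
            (("SeqAggP", 1),),
            (("SeqAggP", 1), ("ROS", 1)),
            "k_genROSSeqAggP",
        )
    )
    # p38MAPK activation by ROS above basal, deactivation, and (optionally)
    # the positive feedback of active kinase on ROS production
    rx.append(
        R(
            "actp38",
            (("p38", 1),),
            (("p38_P", 1),),
            "k_actp38",
            "ros_excess_mass_action",
            ("ROS",),
        )
    )
    rx.append(R("inactp38", (("p38_P", 1),), (("p38", 1),), "k_inactp38"))
    if feedback_on:
        rx.append(
            R(
                FEEDBACK_REACTION_ID,
                (("p38_P", 1),),
                (("p38_P", 1), ("ROS", 1)),
                "k_genROSp38",
            )
        )
    # death hazards set a cause flag; the k_alive event then freezes the cell
    rx.append(
        R(
            "p38death",
            (),
            (("p38_death_flag", 1),),
            "k_p38death",
            "p38_death_hazard",
            ("p38_P",),
        )
    )
    rx.append(
        R(
            "PIdeath",
            (),
            (("proteasome_death_flag", 1),),
            "k_PIdeath",
            "proteasome_death_hazard",
            ("AggP_Proteasome",),
        )
    )
    # generic protein pool: misfolding (accelerated by oxidative damage
    # when ROS is above basal), refolding, proteasomal clearance
    rx.append(
        R(
            "misfold",
            (("NatP", 1),),
            (("MisP", 1),),
            "k_misfold",
            "ros_modulated_mass_action",
            ("ROS",),
        )
    )
    rx.append(R("refold", (("MisP", 1),), (("NatP", 1),), "k_refold"))
    rx.append(
        R(
            "binMisPProt",
            (("MisP", 1), ("Proteasome", 1)),
            (("MisP_Proteasome", 1),),
            "k_binMisPProt",
        )
    )
    rx.append(R("degMisP", (("MisP_Proteasome", 1),), (("Proteasome", 1),), "k_degMisP"))
    return rx


def _death_events() -> List[EventDef]:
    return [
        EventDef("p38_death", ("species_ge", "p38_death_flag", 1), ((ALIVE_PARAM, 0.0),)),
        EventDef(
            "proteasome_death",
            ("species_ge", "proteasome_death_flag", 1),
            ((ALIVE_PARAM, 0.0),),
        ),
    ]


def build_polyq_model(scenario: ScenarioConfig) -> ModelDef:
    """Assemble the ModelDef for one treatment arm.

    Treatment wiring: PI blocks all proteasome-mediated degradation from
    24 h (saturating inhibitor); BSO slows ROS removal 5-fold from 24 h;
    SKF86002 (p38 inhibitor, applied before transfection) zeroes the p38
    activation rate from time 0.  ``feedback_on=False`` drops exactly the
    p38_P -> ROS generation reaction.
    """
    params = dict(DEFAULT_PARAMETERS)
    params.update(scenario.overrides)
    events = _death_events()
    if scenario.treatment == "PI":
        factor = PI_INHIBITION_FACTOR
        events.append(
            EventDef(
                "PI_treatment",
                ("time", TREATMENT_TIME_H),
                (
                    ("k_degPolyQ", factor * params["k_degPolyQ"]),
                    ("k_degmRFPu", factor * params["k_degmRFPu"]),
                    ("k_degMisP", factor * params["k_degMisP"]),
                ),
            )
        )
    elif scenario.treatment == "BSO":
        events.append(
            EventDef(
                "BSO_treatment",
                ("time", TREATMENT_TIME_H),
                (("k_remROS", BSO_REMROS_FACTOR * params["k_remROS"]),),
            )
        )
    elif scenario.treatment == "SKF":
        params["k_actp38"] = 0.0

    model = ModelDef(
        species=_species_list(INITIAL_COUNTS),
        reactions=_reactions(scenario.feedback_on),
        parameters=params,
        events=events,
        name=f"polyq_{scenario.treatment}" + ("" if scenario.feedback_on else "_nofb"),
    )
    return model


def build_ros_submodel(
    overrides: Optional[Dict[str, float]] = None, initial_ros: int = 10
) -> ModelDef:
    """Basal ROS generation/removal in isolation (no aggregates, no p38)."""
    params = {
        ALIVE_PARAM: 1.0,
        "k_genROS": DEFAULT_PARAMETERS["k_genROS"],
        "k_remROS": DEFAULT_PARAMETERS["k_remROS"],
    }
    if overrides:
        params.update(overrides)
    return ModelDef(
        species=[SpeciesDef("ROS", initial_ros, "signal")],
        reactions=[
            ReactionDef("genROS", (), (("ROS", 1),), "k_genROS"),
            ReactionDef("remROS", (("ROS", 1),), (), "k_remROS"),
        ],
        parameters=params,
        name="ros_submodel",
    )


def build_halflife_model(
    species: str, shutoff_time: float, overrides: Optional[Dict[str, float]] = None
) -> ModelDef:
    """Turnover-measurement variant of the polyQ model.

    Aggregation, aggregate-proteasome binding and the generic misfolded-
    protein load are switched off so the proteasome pool stays entirely
    free, and an event zeroes the synthesis rate of ``species`` ('PolyQ' or
    'mRFPu') at ``shutoff_time`` hours.  The subsequent decay of the pool
    measures the uninhibited half-life set by the turnover constants alone.
    """
    if species not in ("PolyQ", "mRFPu"):
        raise ValueError("half-life protocol applies to PolyQ or mRFPu")
    scen = ScenarioConfig(treatment="untreated", overrides=dict(overrides or {}))
    model = build_polyq_model(scen)
    model.parameters["k_nucPolyQ"] = 0.0
    model.parameters["k_aggPolyQ"] = 0.0
    model.parameters["k_inhprot"] = 0.0
    model.parameters["k_misfold"] = 0.0
    syn = {"PolyQ": "k_synPolyQ", "mRFPu": "k_synmRFPu"}[species]
    model.events = list(model.events) + [
        EventDef("synthesis_shutoff", ("time", shutoff_time), ((syn, 0.0),))
    ]
    model.name = f"polyq_halflife_{species}"
    return model
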