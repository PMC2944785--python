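"""Discrete-molecule reaction networks: species, reactions, parameters, events.

This layer is deliberately model-agnostic.  It knows about mass-action
kinetics for at most two colliding molecules (the Gillespie collision
assumption), about rate laws that are modulated by a reactive-oxygen-species
(ROS) count through a multiplicative factor, and about cell-death hazard
laws whose concrete shapes live in :mod:`polyqsim.network`.  The concrete
polyglutamine network is built on top of these primitives.

Counts are integer molecule numbers; time is measured in hours and every
rate constant is per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "EventDef",
    "ModelDef",
    "ParameterSet",
    "ROLES",
    "LAW_KINDS",
    "validate_model",
    "propensity",
    "ros_factor",
]

#: allowed species role tags
ROLES = frozenset({"protein", "aggregate", "complex", "reporter", "signal", "flag"})

#: allowed kinetic-law kinds
LAW_KINDS = frozenset(
    {
        "mass_action",
        "ros_modulated_mass_action",
        "ros_excess_mass_action",
        "p38_death_hazard",
        "proteasome_death_hazard",
    }
)

#: parameter-name conventions used by the ROS-dependent and hazard laws
ROS_BASAL_PARAM = "ROS_basal"
ROS_ALPHA_PARAM = "ros_alpha"
PROT_TOTAL_PARAM = "Proteasome_total"
PI_EXPONENT_PARAM = "pi_death_exponent"
PI_THRESHOLD_PARAM = "pi_death_threshold"
ALIVE_PARAM = "k_alive"

ParameterSet = Dict[str, float]


@dataclass(frozen=True)
class SpeciesDef:
    """A molecular species with an integer initial copy number."""

    name: str
    initial_count: int = 0
    role: str = "protein"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r}")
        if self.initial_count < 0 or int(self.initial_count) != self.initial_count:
            raise ValueError(f"initial_count of {self.name} must be a non-negative integer")


@dataclass(frozen=True)
class ReactionDef:
    """A reaction channel.

    ``reactants``/``products`` are ``(species, stoichiometry)`` pairs;
    ``modifiers`` affect the propensity but are neither consumed nor
    produced (the ROS pseudo-second-order trick, and hazard drivers).
    """

    id: str
    reactants: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...]
    rate_param: str
    law_kind: str = "mass_action"
    modifiers: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        if self.law_kind not in LAW_KINDS:
            raise ValueError(f"unknown law_kind {self.law_kind!r} in reaction {self.id}")

    @property
    def reactant_order(self) -> int:
        return sum(n for _, n in self.reactants)


@dataclass(frozen=True)
class EventDef:
    """A one-shot event.

    ``trigger`` is either ``("time", T)`` — fires when simulated time first
    reaches ``T`` hours — or ``("species_ge", name, value)`` — fires at the
    first instant the named species count is >= value.  ``assignments`` are
    ``(target, new_value)`` pairs where the target is a parameter or species
    name; they are applied atomically and the event is then consumed.
    """

    id: str
    trigger: Tuple
    assignments: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", tuple(self.assignments))
        kind = self.trigger[0]
        if kind == "time":
            if len(self.trigger) != 2 or self.trigger[1] < 0:
                raise ValueError(f"bad time trigger in event {self.id}")
        elif kind == "species_ge":
            if len(self.trigger) != 3:
                raise ValueError(f"bad species trigger in event {self.id}")
        else:
            raise ValueError(f"unknown trigger kind {kind!r} in event {self.id}")


@dataclass
class ModelDef:
    """A complete reaction network: species, reactions, parameters, events."""

    species: List[SpeciesDef] = field(default_factory=list)
    reactions: List[ReactionDef] = field(default_factory=list)
    parameters: ParameterSet = field(default_factory=dict)
    events: List[EventDef] = field(default_factory=list)
    name: str = "model"

    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    def species_index(self) -> Dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_counts(self) -> Dict[str, int]:
        return {s.name: s.initial_count for s in self.species}

    def get_reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "ModelDef":
        return ModelDef(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=dict(self.parameters),
            events=list(self.events),
            name=self.name,
        )


def validate_model(model: ModelDef) -> List[str]:
    """Collect structural violations; an empty list means well-formed.

    Checks: duplicate names, undeclared species in reactions/events,
    unresolved rate parameters, non-positive or non-integer stoichiometry,
    reactant order above the two-molecule collision limit, negative rates,
    and the presence/validity of ``k_alive``.
    """
    errors: List[str] = []
    names = [s.name for s in model.species]
    declared = set(names)
    if len(declared) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        errors.append(f"duplicate species names: {', '.join(dupes)}")
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):
        dupes = sorted({i for i in rids if rids.count(i) > 1})
        errors.append(f"duplicate reaction ids: {', '.join(dupes)}")

    for r in model.reactions:
        for s, n in list(r.reactants) + list(r.products):
            if s not in declared:
                errors.append(f"reaction {r.id}: undeclared species {s!r}")
            if n <= 0 or int(n) != n:
                errors.append(f"reaction {r.id}: non-positive-integer stoichiometry for {s}")
        for s in r.modifiers:
            if s not in declared:
                errors.append(f"reaction {r.id}: undeclared modifier {s!r}")
        if r.rate_param not in model.parameters:
            errors.append(f"reaction {r.id}: missing parameter {r.rate_param!r}")
        if r.law_kind in ("mass_action", "ros_modulated_mass_action", "ros_excess_mass_action"):
            if r.reactant_order > 2:
                errors.append(
                    f"reaction {r.id}: reactant order {r.reactant_order} exceeds the "
                    "two-molecule collision limit"
                )
        if r.law_kind.startswith("ros_") and not r.modifiers:
            errors.append(f"reaction {r.id}: ROS-modulated law requires ROS as a modifier")
        if r.law_kind in ("p38_death_hazard", "proteasome_death_hazard") and not r.modifiers:
            errors.append(f"reaction {r.id}: hazard law requires a driving modifier species")

    for ev in model.events:
        if ev.trigger[0] == "species_ge" and ev.trigger[1] not in declared:
            errors.append(f"event {ev.id}: undeclared trigger species {ev.trigger[1]!r}")
        for target, _ in ev.assignments:
            if target not in declared and target not in model.parameters:
                errors.append(f"event {ev.id}: assignment target {target!r} is undeclared")

    for k, v in model.parameters.items():
        if v < 0:
            errors.append(f"parameter {k} is negative")
    if ALIVE_PARAM in model.parameters and model.parameters[ALIVE_PARAM] not in (0.0, 1.0):
        errors.append("k_alive must be 0 or 1")
    return errors


def ros_factor(ros: float, basal: float, alpha: float) -> float:
    """Multiplicative enhancement of aggregation kinetics by ROS.

    Equals 1 at or below basal ROS and grows linearly with the excess above
    basal: ``1 + alpha * (ros - basal) / basal``.  The functional form is a
    modelling choice (the biology only pins down "no effect at basal, more
    effect above"); ``alpha`` is a calibrated dimensionless gain.
    """
    if basal <= 0:
        raise ValueError("basal ROS level must be positive")
    if ros <= basal:
        return 1.0
    return 1.0 + alpha * (ros - basal) / basal


def _mass_action_core(reaction: ReactionDef, counts: Mapping[str, int], k: float) -> float:
    a = k
    for s, n in reaction.reactants:
        x = counts[s]
        if x < 0:
            raise ValueError(f"negative count for {s}")
        if n == 1:
            a *= x
        elif n == 2:
            a *= x * (x - 1) / 2.0
        else:  # pragma: no cover - rejected by validate_model
            raise ValueError("stoichiometry beyond the two-molecule limit")
    return a


def propensity(reaction: ReactionDef, counts: Mapping[str, int], params: ParameterSet) -> float:
    """Instantaneous firing rate (events/hour) of one reaction channel.

    All laws are gated by ``k_alive`` so a dead cell is absorbing.  This is
    the reference (pure-Python) evaluation; the simulation engine uses a
    compiled equivalent and the two are cross-checked in the test suite.
    """
    k = params[reaction.rate_param] * params.get(ALIVE_PARAM, 1.0)
    kind = reaction.law_kind
    if kind == "mass_action":
        return _mass_action_core(reaction, counts, k)
    if kind == "ros_modulated_mass_action":
        ros = counts[reaction.modifiers[0]]
        f = ros_factor(ros, params[ROS_BASAL_PARAM], params[ROS_ALPHA_PARAM])
        return _mass_action_core(reaction, counts, k) * f
    if kind == "ros_excess_mass_action":
        ros = counts[reaction.modifiers[0]]
        excess = max(ros - params[ROS_BASAL_PARAM], 0.0)
        return _mass_action_core(reaction, counts, k) * excess
    # hazard shapes are owned by the polyQ network layer
    from . import network

    if kind == "p38_death_hazard":
        return network.p38_death_hazard(counts[reaction.modifiers[0]], k)
    if kind == "proteasome_death_hazard":
        return network.proteasome_death_hazard(
            counts[reaction.modifiers[0]],
            params[PROT_TOTAL_PARAM],
            k,
            exponent=params.get(PI_EXPONENT_PARAM, 6.0),
            threshold=params.get(PI_THRESHOLD_PARAM, 0.5),
        )
    raise ValueError(f"unknown law kind {kind!r}")  # pragma: no cover
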