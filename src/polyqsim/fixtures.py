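"""Tiny analytically solvable networks used to validate the SSA engine.

Each fixture is a ModelDef built from core primitives together with its
closed-form expectations, computed from the rates at call time (never stored
constants).  They carry no biology: their sole purpose is to catch engine
faults (biased selection, broken waiting times, bad bookkeeping) with
classical results — Poisson stationarity of the immigration-death process,
the ln2/k half-life of first-order decay, and thermodynamic-limit agreement
of dimerization with its ODE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .core import ModelDef, ReactionDef, SpeciesDef

__all__ = ["FixtureSpec", "make_fixture"]

KINDS = ("immigration_death", "pure_decay", "dimerization")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    rates: Dict[str, float]
    initial: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if any(v <= 0 for v in self.rates.values()):
            raise ValueError("fixture rates must be positive")


def make_fixture(spec: FixtureSpec):
    """Build the fixture model and its analytic expectations.

    Returns ``(model, expected)`` where ``expected`` holds closed-form
    quantities:

    - immigration_death (rates ``lam``, ``mu``): stationary count is
      Poisson(lam/mu), so mean = variance = lam/mu.
    - pure_decay (rate ``k``): half-life ln2/k hours.
    - dimerization (rate ``k``, 2A -> B): deterministic-limit monomer count
      a(t) = a0 / (1 + a0*k*t/... ) given by ``expected["ode"](t)``; with
      propensity k*A*(A-1)/2 the large-count ODE is da/dt = -k*a^2.
    """
    if spec.kind == "immigration_death":
        lam, mu = spec.rates["lam"], spec.rates["mu"]
        model = ModelDef(
            species=[SpeciesDef("X", spec.initial, "protein")],
            reactions=[
                ReactionDef("birth", (), (("X", 1),), "lam"),
                ReactionDef("death", (("X", 1),), (), "mu"),
            ],
            parameters={"lam": lam, "mu": mu},
            name="immigration_death",
        )
        m = lam / mu
        return model, {"mean": m, "variance": m}
    if spec.kind == "pure_decay":
        k = spec.rates["k"]
        model = ModelDef(
            species=[SpeciesDef("X", spec.initial, "protein")],
            reactions=[ReactionDef("decay", (("X", 1),), (), "k")],
            parameters={"k": k},
            name="pure_decay",
        )
        return model, {"half_life": np.log(2.0) / k}
    # dimerization: 2A -> B
    k = spec.rates["k"]
    a0 = spec.initial
    model = ModelDef(
        species=[SpeciesDef("A", a0, "protein"), SpeciesDef("B", 0, "complex")],
        reactions=[ReactionDef("dimerize", (("A", 2),), (("B", 1),), "k")],
        parameters={"k": k},
        name="dimerization",
    )

    def ode(t: float) -> float:
        # da/dt = -k a^2  (propensity k*a*(a-1)/2 consumes 2 monomers/event)
        return a0 / (1.0 + a0 * k * t)

    return model, {"ode": ode}
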