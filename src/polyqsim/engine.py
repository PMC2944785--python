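"""Exact stochastic simulation (Gillespie direct method) with events.

The engine compiles a :class:`~polyqsim.core.ModelDef` into flat arrays and
runs the direct method in a numba-jitted kernel: draw an exponential waiting
time at total propensity ``a0``, pick a channel proportionally to its
propensity, apply the stoichiometry.  One-shot events interrupt the clock:
if a pending time trigger falls inside the waiting interval the state is
advanced only to the trigger, the assignments are applied, and the drawn
reaction is discarded (propensities are then stale and must be redrawn).
Species-threshold events are checked after every state change.

Death is not special-cased: a hazard reaction produces a flag species, a
threshold event zeroes ``k_alive``, and because every propensity carries a
``k_alive`` factor the dead cell is absorbing and its counts freeze.

Trajectories are recorded on a fixed grid with right-continuous step
interpolation (the sample at grid time T is the state after all jumps <= T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .core import (
    ALIVE_PARAM,
    PI_EXPONENT_PARAM,
    PI_THRESHOLD_PARAM,
    PROT_TOTAL_PARAM,
    ROS_ALPHA_PARAM,
    ROS_BASAL_PARAM,
    EventDef,
    ModelDef,
    validate_model,
)

__all__ = ["CellState", "Trajectory", "simulate", "CompiledModel", "compile_model", "apply_event"]

_LAW_CODE = {
    "mass_action": 0,
    "ros_modulated_mass_action": 1,
    "ros_excess_mass_action": 2,
    "p38_death_hazard": 3,
    "proteasome_death_hazard": 4,
}

DEATH_CAUSE_NONE = "none"


@dataclass
class CellState:
    """Integer copy-number state of one simulated cell."""

    counts: Dict[str, int]
    time: float = 0.0
    alive: bool = True
    death_cause: str = DEATH_CAUSE_NONE
    death_time: Optional[float] = None


@dataclass
class Trajectory:
    """Grid-sampled time course of one cell plus its final fate."""

    grid: np.ndarray  # (G,) hours, strictly increasing
    samples: np.ndarray  # (G, S) integer counts
    species: List[str]
    alive: bool
    death_cause: str
    death_time: Optional[float]
    seed: int = 0

    def series(self, name: str) -> np.ndarray:
        return self.samples[:, self.species.index(name)]

    def value_at(self, name: str, t: float) -> int:
        """Count of `name` at the latest grid point <= t."""
        i = int(np.searchsorted(self.grid, t, side="right")) - 1
        if i < 0:
            raise ValueError(f"t={t} precedes the sampling grid")
        return int(self.samples[i, self.species.index(name)])


@dataclass
class CompiledModel:
    """Flat-array form of a ModelDef consumed by the jitted kernel."""

    model: ModelDef
    species: List[str]
    sidx: Dict[str, int]
    x0: np.ndarray
    param_names: List[str]
    pidx: Dict[str, int]
    p0: np.ndarray
    rx_react_idx: np.ndarray  # (R, 2) species index, -1 padding
    rx_react_st: np.ndarray  # (R, 2)
    rx_net: np.ndarray  # (R, S)
    rx_law: np.ndarray  # (R,)
    rx_param: np.ndarray  # (R,)
    rx_driver: np.ndarray  # (R,) modifier species index or -1
    ev_kind: np.ndarray  # (E,) 0 time, 1 species_ge
    ev_time: np.ndarray
    ev_species: np.ndarray
    ev_thresh: np.ndarray
    ev_assign_ofs: np.ndarray  # (E+1,)
    as_is_param: np.ndarray
    as_idx: np.ndarray
    as_value: np.ndarray
    special: Tuple[int, int, int, int, int, int]  # param idx: k_alive, ROS basal, ROS alpha, proteasome total, hazard exponent, hazard threshold


def compile_model(model: ModelDef) -> CompiledModel:
    errors = validate_model(model)
    if errors:
        raise ValueError("invalid model: " + "; ".join(errors))
    species = model.species_names()
    sidx = model.species_index()
    x0 = np.array([s.initial_count for s in model.species], dtype=np.int64)

    param_names = list(model.parameters)
    for required in (ALIVE_PARAM,):
        if required not in param_names:
            param_names.append(required)
    pidx = {n: i for i, n in enumerate(param_names)}
    p0 = np.array([model.parameters.get(n, 1.0) for n in param_names], dtype=np.float64)

    R, S = len(model.reactions), len(species)
    rx_react_idx = np.full((R, 2), -1, dtype=np.int64)
    rx_react_st = np.zeros((R, 2), dtype=np.int64)
    rx_net = np.zeros((R, S), dtype=np.int64)
    rx_law = np.zeros(R, dtype=np.int64)
    rx_param = np.zeros(R, dtype=np.int64)
    rx_driver = np.full(R, -1, dtype=np.int64)
    for i, r in enumerate(model.reactions):
        for j, (s, n) in enumerate(r.reactants):
            rx_react_idx[i, j] = sidx[s]
            rx_react_st[i, j] = n
            rx_net[i, sidx[s]] -= n
        for s, n in r.products:
            rx_net[i, sidx[s]] += n
        rx_law[i] = _LAW_CODE[r.law_kind]
        rx_param[i] = pidx[r.rate_param]
        if r.modifiers:
            rx_driver[i] = sidx[r.modifiers[0]]

    E = len(model.events)
    ev_kind = np.zeros(E, dtype=np.int64)
    ev_time = np.full(E, np.inf)
    ev_species = np.full(E, -1, dtype=np.int64)
    ev_thresh = np.zeros(E)
    ofs = [0]
    as_is_param: List[int] = []
    as_idx: List[int] = []
    as_value: List[float] = []
    for i, ev in enumerate(model.events):
        if ev.trigger[0] == "time":
            ev_time[i] = float(ev.trigger[1])
        else:
            ev_kind[i] = 1
            ev_species[i] = sidx[ev.trigger[1]]
            ev_thresh[i] = float(ev.trigger[2])
        for target, value in ev.assignments:
            if target in pidx:
                as_is_param.append(1)
                as_idx.append(pidx[target])
            else:
                as_is_param.append(0)
                as_idx.append(sidx[target])
            as_value.append(float(value))
        ofs.append(len(as_idx))

    def pi(name: str, default: float) -> int:
        if name in pidx:
            return pidx[name]
        return -1

    special = (
        pidx[ALIVE_PARAM],
        pi(ROS_BASAL_PARAM, 1.0),
        pi(ROS_ALPHA_PARAM, 0.0),
        pi(PROT_TOTAL_PARAM, 1.0),
        pi(PI_EXPONENT_PARAM, 6.0),
        pi(PI_THRESHOLD_PARAM, 0.5),
    )
    return CompiledModel(
        model=model,
        species=species,
        sidx=sidx,
        x0=x0,
        param_names=param_names,
        pidx=pidx,
        p0=p0,
        rx_react_idx=rx_react_idx,
        rx_react_st=rx_react_st,
        rx_net=rx_net,
        rx_law=rx_law,
        rx_param=rx_param,
        rx_driver=rx_driver,
        ev_kind=ev_kind,
        ev_time=ev_time,
        ev_species=ev_species,
        ev_thresh=ev_thresh,
        ev_assign_ofs=np.array(ofs, dtype=np.int64),
        as_is_param=np.array(as_is_param, dtype=np.int64),
        as_idx=np.array(as_idx, dtype=np.int64),
        as_value=np.array(as_value, dtype=np.float64),
        special=special,
    )


@njit(cache=False)
def _propensities(
    x, p, rx_react_idx, rx_react_st, rx_law, rx_param, rx_driver,
    ip_alive, ip_basal, ip_alpha, ip_total, ip_h, ip_tau, a
):
    alive = p[ip_alive]
    basal = p[ip_basal] if ip_basal >= 0 else 1.0
    alpha = p[ip_alpha] if ip_alpha >= 0 else 0.0
    total = p[ip_total] if ip_total >= 0 else 1.0
    hexp = p[ip_h] if ip_h >= 0 else 6.0
    tau = p[ip_tau] if ip_tau >= 0 else 0.5
    for i in range(rx_law.shape[0]):
        k = p[rx_param[i]] * alive
        law = rx_law[i]
        if law <= 2:
            v = k
            for j in range(2):
                si = rx_react_idx[i, j]
                if si >= 0:
                    n = rx_react_st[i, j]
                    if n == 1:
                        v *= x[si]
                    else:
                        v *= x[si] * (x[si] - 1) / 2.0
            if law == 1:
                ros = x[rx_driver[i]]
                if ros > basal:
                    v *= 1.0 + alpha * (ros - basal) / basal
            elif law == 2:
                ros = x[rx_driver[i]]
                excess = ros - basal
                v *= excess if excess > 0.0 else 0.0
            a[i] = v
        elif law == 3:
            a[i] = k * x[rx_driver[i]]
        else:
            frac = x[rx_driver[i]] / total
            a[i] = k * (frac / tau) ** hexp
    return a


@njit(cache=False)
def _run_kernel(
    x,
    p,
    rx_react_idx,
    rx_react_st,
    rx_net,
    rx_law,
    rx_param,
    rx_driver,
    ev_kind,
    ev_time,
    ev_species,
    ev_thresh,
    ev_assign_ofs,
    as_is_param,
    as_idx,
    as_value,
    ip_alive,
    ip_basal,
    ip_alpha,
    ip_total,
    ip_h,
    ip_tau,
    grid,
    horizon,
    seed,
):
    np.random.seed(seed)
    R = rx_law.shape[0]
    E = ev_kind.shape[0]
    G = grid.shape[0]
    samples = np.zeros((G, x.shape[0]), dtype=np.int64)
    ev_fired = np.zeros(E, dtype=np.int64)
    a = np.zeros(R)
    t = 0.0
    gptr = 0
    death_time = np.nan

    # events whose trigger already holds at t=0 fire immediately
    for e in range(E):
        if ev_fired[e] == 0 and (
            (ev_kind[e] == 0 and ev_time[e] <= 0.0)
            or (ev_kind[e] == 1 and x[ev_species[e]] >= ev_thresh[e])
        ):
            was_alive = p[ip_alive]
            for j in range(ev_assign_ofs[e], ev_assign_ofs[e + 1]):
                if as_is_param[j] == 1:
                    p[as_idx[j]] = as_value[j]
                else:
                    x[as_idx[j]] = np.int64(as_value[j])
            ev_fired[e] = 1
            if was_alive > 0.0 and p[ip_alive] == 0.0:
                death_time = t

    while t < horizon:
        _propensities(
            x, p, rx_react_idx, rx_react_st, rx_law, rx_param, rx_driver,
            ip_alive, ip_basal, ip_alpha, ip_total, ip_h, ip_tau, a,
        )
        a0 = 0.0
        for i in range(R):
            a0 += a[i]

        # earliest pending time event
        t_ev = np.inf
        e_next = -1
        for e in range(E):
            if ev_kind[e] == 0 and ev_fired[e] == 0 and ev_time[e] < t_ev:
                t_ev = ev_time[e]
                e_next = e

        if a0 <= 0.0:
            t_new = t_ev if t_ev < horizon else horizon
            fire_reaction = False
        else:
            tau = -np.log(1.0 - np.random.random()) / a0
            t_new = t + tau
            if t_new >= t_ev:
                # event interrupts: discard the drawn reaction
                t_new = t_ev
                fire_reaction = False
            else:
                fire_reaction = t_new <= horizon

        if t_new > horizon:
            t_new = t_new if t_new < horizon else horizon
        # record grid points passed before the state changes at t_new
        while gptr < G and grid[gptr] < t_new:
            for s in range(x.shape[0]):
                samples[gptr, s] = x[s]
            gptr += 1

        if t_new >= horizon and not (fire_reaction and t_new <= horizon):
            t = horizon
            break
        t = t_new

        if fire_reaction:
            # select channel proportionally to propensity
            u = np.random.random() * a0
            c = 0.0
            r_sel = R - 1
            for i in range(R):
                c += a[i]
                if u < c:
                    r_sel = i
                    break
            for s in range(x.shape[0]):
                x[s] += rx_net[r_sel, s]
                if x[s] < 0:
                    # engine invariant breach; surface as a poisoned sample
                    raise ValueError("species count went negative")
        elif e_next >= 0 and t == ev_time[e_next]:
            was_alive = p[ip_alive]
            for j in range(ev_assign_ofs[e_next], ev_assign_ofs[e_next + 1]):
                if as_is_param[j] == 1:
                    p[as_idx[j]] = as_value[j]
                else:
                    x[as_idx[j]] = np.int64(as_value[j])
            ev_fired[e_next] = 1
            if was_alive > 0.0 and p[ip_alive] == 0.0:
                death_time = t

        # species-threshold events (checked after every state change)
        for e in range(E):
            if ev_kind[e] == 1 and ev_fired[e] == 0 and x[ev_species[e]] >= ev_thresh[e]:
                was_alive = p[ip_alive]
                for j in range(ev_assign_ofs[e], ev_assign_ofs[e + 1]):
                    if as_is_param[j] == 1:
                        p[as_idx[j]] = as_value[j]
                    else:
                        x[as_idx[j]] = np.int64(as_value[j])
                ev_fired[e] = 1
                if was_alive > 0.0 and p[ip_alive] == 0.0:
                    death_time = t

    while gptr < G:
        for s in range(x.shape[0]):
            samples[gptr, s] = x[s]
        gptr += 1
    return samples, ev_fired, death_time


def apply_event(state: CellState, event: EventDef, params: Dict[str, float]) -> CellState:
    """Apply one event's assignments to a state/parameter pair (pure-Python path).

    Mirrors the kernel semantics for unit-level reasoning; raises on
    assignment to an undeclared target.
    """
    for target, value in event.assignments:
        if target in state.counts:
            state.counts[target] = int(value)
        elif target in params:
            params[target] = float(value)
        else:
            raise KeyError(f"event {event.id}: assignment target {target!r} is undeclared")
    if params.get(ALIVE_PARAM, 1.0) == 0.0 and state.alive:
        state.alive = False
        state.death_time = state.time
    return state


def _death_cause(compiled: CompiledModel, final_counts: np.ndarray) -> str:
    for name, cause in (("p38_death_flag", "p38_death"), ("proteasome_death_flag", "proteasome_death")):
        if name in compiled.sidx and final_counts[compiled.sidx[name]] > 0:
            return cause
    return DEATH_CAUSE_NONE


def simulate(
    model: ModelDef | CompiledModel,
    horizon: float,
    grid: Sequence[float] | np.ndarray,
    seed: int,
) -> Trajectory:
    """Run one exact SSA realisation and sample it on `grid`.

    Identical ``(model, seed)`` give identical trajectories.  ``horizon``
    must cover the grid.  The returned trajectory carries the final fate
    (alive flag, death cause from the flag species, death time).
    """
    compiled = model if isinstance(model, CompiledModel) else compile_model(model)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if horizon < grid[-1]:
        raise ValueError("horizon must cover the sampling grid")
    x = compiled.x0.copy()
    p = compiled.p0.copy()
    ip_alive, ip_basal, ip_alpha, ip_total, ip_h, ip_tau = compiled.special
    samples, _ev_fired, death_time = _run_kernel(
        x,
        p,
        compiled.rx_react_idx,
        compiled.rx_react_st,
        compiled.rx_net,
        compiled.rx_law,
        compiled.rx_param,
        compiled.rx_driver,
        compiled.ev_kind,
        compiled.ev_time,
        compiled.ev_species,
        compiled.ev_thresh,
        compiled.ev_assign_ofs,
        compiled.as_is_param,
        compiled.as_idx,
        compiled.as_value,
        ip_alive,
        ip_basal,
        ip_alpha,
        ip_total,
        ip_h,
        ip_tau,
        grid,
        float(horizon),
        int(seed) % 2**31,
    )
    dead = not np.isnan(death_time)
    return Trajectory(
        grid=grid,
        samples=samples,
        species=list(compiled.species),
        alive=not dead,
        death_cause=_death_cause(compiled, x) if dead else DEATH_CAUSE_NONE,
        death_time=float(death_time) if dead else None,
        seed=int(seed),
    )
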