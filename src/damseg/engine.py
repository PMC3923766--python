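"""Discrete-time stochastic simulation of the homeostatic cell population.

The elementary step: a cell is selected uniformly at random and dies with
probability equal to its damage level; otherwise nothing changes. On death
the vacancy is filled immediately by the division of another cell — any
other cell in the well-mixed topology, one of the two ring neighbours in
the 1D topology — so the population size stays exactly N. The dividing
cell's daughters inherit its damage, plus new damage with probability p
(split per the segregation mode), and occupy the vacancy and the divider's
slot in random order. One time unit is N elementary steps, so each cell is
selected once per unit on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import _kernel
from .params import ModelParams, Mode, Topology, daughter_damages


@dataclass
class Population:
    """Simulator state: per-cell damage, increment counts, elapsed steps.

    ``increments[i]`` counts the mutational increments accumulated along the
    lineage history of the cell in slot i; it indexes the damage lattice
    ``epsilon + increments * s`` (s = delta/2 symmetric, delta asymmetric)
    before clamping at 1. Unmutated inheritance copies the parental damage
    value bit-for-bit, so testing ``damage == epsilon`` identifies the
    initial-level class without floating-point drift.
    """

    damages: np.ndarray
    increments: np.ndarray
    t_steps: int
    params: ModelParams

    def copy(self) -> "Population":
        return Population(
            self.damages.copy(), self.increments.copy(), self.t_steps, self.params
        )

    @property
    def t(self) -> float:
        """Elapsed time in time units (N elementary steps each)."""
        return self.t_steps / self.params.n


@dataclass(frozen=True)
class SummaryStats:
    """Snapshot statistics: mean damage, initial-level fraction, histogram."""

    t: float
    mean_damage: float
    f0: float
    histogram: Dict[int, float]


@dataclass
class Trajectory:
    """Per-time-unit summary statistics of one run, plus optional kymograph.

    ``collapsed`` flags early termination in the absorbing all-damage-one
    state; ``collapse_time`` is then the time unit at which it was entered.
    The kymograph rows are damage snapshots, one per recorded time point.
    """

    stats: List[SummaryStats] = field(default_factory=list)
    kymograph: Optional[np.ndarray] = None
    collapsed: bool = False
    collapse_time: Optional[float] = None
    params: Optional[ModelParams] = None
    final_population: Optional[Population] = None

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.stats])

    @property
    def mean_damage(self) -> np.ndarray:
        return np.array([s.mean_damage for s in self.stats])

    @property
    def f0(self) -> np.ndarray:
        return np.array([s.f0 for s in self.stats])


def init_population(params: ModelParams) -> Population:
    """All N cells at damage ``epsilon`` with zero increments, t = 0."""
    damages = np.full(params.n, params.epsilon, dtype=np.float64)
    increments = np.zeros(params.n, dtype=np.int64)
    return Population(damages, increments, 0, params)


def summarize(pop: Population) -> SummaryStats:
    """Exact mean damage, initial-level fraction f0, increment histogram.

    f0 uses exact equality to ``epsilon``: unmutated lineages copy the
    parental value, so no arithmetic ever perturbs it.
    """
    n = pop.params.n
    mean = float(pop.damages.mean())
    f0 = float(np.count_nonzero(pop.damages == pop.params.epsilon) / n)
    counts = np.bincount(pop.increments)
    hist = {k: counts[k] / n for k in np.nonzero(counts)[0]}
    return SummaryStats(t=pop.t, mean_damage=mean, f0=f0, histogram=hist)


def step(pop: Population, rng: np.random.Generator) -> Population:
    """One elementary step, in place; returns the same Population.

    Draw order (fixed, shared with the compiled kernel): selected cell,
    death uniform, divider, mutation, daughter placement. The last three
    draws are consumed only when the selected cell actually dies.
    """
    p = pop.params
    n = p.n
    damages = pop.damages
    i = int(rng.integers(0, n))
    if rng.random() < damages[i]:
        if p.topology is Topology.RING_1D:
            j = (i - 1) % n if rng.random() < 0.5 else (i + 1) % n
        else:
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
        mutated = rng.random() < p.p
        pair = daughter_damages(damages[j], mutated, p.mode, p.delta)
        cj = int(pop.increments[j])
        if mutated:
            if p.mode is Mode.SYMMETRIC:
                c_hi = c_lo = cj + 1
            else:
                c_hi, c_lo = cj + 1, cj
        else:
            c_hi = c_lo = cj
        if rng.random() < 0.5:
            slot_hi, slot_lo = i, j
        else:
            slot_hi, slot_lo = j, i
        damages[slot_hi] = pair.d_high
        pop.increments[slot_hi] = c_hi
        damages[slot_lo] = pair.d_low
        pop.increments[slot_lo] = c_lo
    pop.t_steps += 1
    return pop


def is_collapsed(pop: Population) -> bool:
    """True when every cell has damage exactly 1 (the absorbing state)."""
    return bool(np.all(pop.damages == 1.0))


def run(
    params: ModelParams,
    max_time_units: float,
    record_kymograph: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate for up to ``max_time_units`` time units, recording per unit.

    Deterministic given ``params.seed`` (or an explicitly supplied ``rng``)
    and ``max_time_units``. Stops early, with ``collapsed=True``, if the
    absorbing all-damage-one state is reached.
    """
    if max_time_units <= 0:
        raise ValueError("max_time_units must be > 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = init_population(params)
    n_units = int(max_time_units)
    traj = Trajectory(params=params)
    kymo_rows: List[np.ndarray] = []

    def record() -> None:
        traj.stats.append(summarize(pop))
        if record_kymograph:
            kymo_rows.append(pop.damages.copy())

    record()
    if is_collapsed(pop):  # epsilon == 1: born collapsed
        traj.collapsed = True
        traj.collapse_time = 0.0
    else:
        symmetric = params.mode is Mode.SYMMETRIC
        ring = params.topology is Topology.RING_1D
        for _ in range(n_units):
            offset = pop.t_steps
            steps_done, _, t_all1 = _kernel.advance_units(
                pop.damages,
                pop.increments,
                rng,
                1,
                params.p,
                params.delta,
                symmetric,
                ring,
                params.epsilon,
                _kernel.STOP_NONE,
            )
            pop.t_steps += int(steps_done)
            record()
            if t_all1 >= 0:
                traj.collapsed = True
                traj.collapse_time = (offset + int(t_all1)) / params.n
                break
    if record_kymograph:
        traj.kymograph = np.array(kymo_rows)
    traj.final_population = pop
    return traj


def first_passage(
    params: ModelParams,
    criterion: str,
    max_time_units: float,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, bool]:
    """First time unit at which a collapse criterion holds, or censor.

    ``criterion`` is ``"f0_zero"`` (no cell left at the initial damage
    level) or ``"all_damage_one"``. Both events are absorbing and are
    detected at elementary-step resolution, so ``tau`` is the exact first
    passage in time units (steps / N). Returns ``(tau, censored)``; a
    censored result has ``tau == max_time_units``. Runs entirely inside
    the compiled kernel, so large ``max_time_units`` are cheap.
    """
    if criterion not in ("f0_zero", "all_damage_one"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = init_population(params)
    max_units = int(max_time_units)
    if is_collapsed(pop):
        return 0.0, False
    stop = _kernel.STOP_F0_ZERO if criterion == "f0_zero" else _kernel.STOP_NONE
    _steps_done, step_f0, step_all1 = _kernel.advance_units(
        pop.damages,
        pop.increments,
        rng,
        max_units,
        params.p,
        params.delta,
        params.mode is Mode.SYMMETRIC,
        params.topology is Topology.RING_1D,
        params.epsilon,
        stop,
    )
    hit = step_f0 if criterion == "f0_zero" else step_all1
    if hit >= 0:
        return float(hit) / params.n, False
    return float(max_units), True
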