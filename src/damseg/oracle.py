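"""Exact Markov-chain analysis of tiny instances of the model.

For small N and coarse damage lattices the population is a finite Markov
chain over multisets (well-mixed; the dynamics are exchangeable) or over
ring configurations modulo rotation/reflection. Enumerating the reachable
states and assembling the exact one-elementary-step transition matrix
gives expected absorption/first-passage times by the fundamental-matrix
linear solve — an independent yardstick for the stochastic engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import ModelParams, Mode, Topology

State = Tuple[int, ...]


class StateSpaceError(RuntimeError):
    """The reachable state space exceeds the configured bound."""


def damage_lattice(params: ModelParams) -> np.ndarray:
    """Reachable damage values, produced by the same clamped fold as the
    engine (d -> min(d + s, 1)), so the floats match the simulator's
    bit-for-bit."""
    s = params.increment_step
    levels = [params.epsilon]
    while levels[-1] < 1.0:
        levels.append(min(levels[-1] + s, 1.0))
    return np.array(levels)


def _canonical_ring(state: State) -> State:
    """Lexicographic minimum over rotations and reflections."""
    n = len(state)
    best = state
    rev = state[::-1]
    for base in (state, rev):
        for r in range(n):
            cand = base[r:] + base[:r]
            if cand < best:
                best = cand
    return best


@dataclass
class StateSpace:
    """Reachable states of a tiny instance, with index maps.

    Well-mixed states are sorted tuples of lattice-level indices; ring
    states are tuples canonicalized modulo rotation/reflection.
    """

    states: List[State]
    index: Dict[State, int]
    levels: np.ndarray
    params: ModelParams

    @property
    def n_states(self) -> int:
        return len(self.states)

    def canonicalize(self, raw: Iterable[int]) -> State:
        t = tuple(raw)
        if self.params.topology is Topology.RING_1D:
            return _canonical_ring(t)
        return tuple(sorted(t))

    def state_of_damages(self, damages: np.ndarray) -> State:
        """Map a simulator damage vector onto a canonical state."""
        lookup = {v: i for i, v in enumerate(self.levels)}
        return self.canonicalize(lookup[d] for d in damages)

    def initial_state(self) -> State:
        return self.canonicalize((0,) * self.params.n)

    def absorbing_indices(self) -> List[int]:
        """States where every cell sits at damage 1 (lattice top)."""
        top = len(self.levels) - 1
        return [
            i for i, s in enumerate(self.states) if all(l == top for l in s)
        ]

    def f0_zero_indices(self) -> List[int]:
        """States with no cell left at the initial damage level."""
        return [i for i, s in enumerate(self.states) if 0 not in s]


def _step_transitions(
    state: State, params: ModelParams, levels: np.ndarray, canon
) -> Dict[State, float]:
    """Exact one-elementary-step distribution from ``state``.

    Mirrors the engine's law: select a slot uniformly; it dies with
    probability equal to its damage; the divider is any other cell
    (well-mixed) or one of the two ring neighbours; the division mutates
    with probability p; daughters fill the vacancy and the divider's slot
    (placement order is irrelevant for multisets and is enumerated with
    probability 1/2 each on the ring).
    """
    n = params.n
    p = params.p
    top = len(levels) - 1
    out: Dict[State, float] = {}

    def add(next_state: State, prob: float) -> None:
        if prob > 0.0:
            out[next_state] = out.get(next_state, 0.0) + prob

    survive = 0.0
    ring = params.topology is Topology.RING_1D
    for i in range(n):
        d_i = levels[state[i]]
        survive += (1.0 - d_i) / n
        if d_i == 0.0:
            continue
        death = d_i / n
        if ring:
            dividers = [((i - 1) % n, 0.5), ((i + 1) % n, 0.5)]
        else:
            dividers = [(j, 1.0 / (n - 1)) for j in range(n) if j != i]
        for j, w in dividers:
            b = state[j]
            up = min(b + 1, top)
            base = death * w
            for hi_at_i, w_place in (((True), 0.5), ((False), 0.5)):
                lst = list(state)
                if params.mode is Mode.SYMMETRIC:
                    hi = lo = up
                else:
                    hi, lo = up, b
                # mutated branch
                if hi_at_i:
                    lst[i], lst[j] = hi, lo
                else:
                    lst[i], lst[j] = lo, hi
                add(canon(lst), base * p * w_place)
                # unmutated branch: both daughters copy the divider
                lst[i] = lst[j] = b
                add(canon(lst), base * (1.0 - p) * w_place)
    add(canon(list(state)), survive)
    return out


def enumerate_states(params: ModelParams, max_states: int = 20_000) -> StateSpace:
    """Breadth-first closure of the reachable set from the all-epsilon state."""
    levels = damage_lattice(params)
    space = StateSpace([], {}, levels, params)
    canon = space.canonicalize
    start = space.initial_state()
    space.states.append(start)
    space.index[start] = 0
    frontier = [start]
    while frontier:
        nxt: List[State] = []
        for s in frontier:
            for t in _step_transitions(s, params, levels, canon):
                if t not in space.index:
                    if len(space.states) >= max_states:
                        raise StateSpaceError(
                            f"more than {max_states} reachable states; use a "
                            "smaller N or a larger delta"
                        )
                    space.index[t] = len(space.states)
                    space.states.append(t)
                    nxt.append(t)
        frontier = nxt
    return space


def transition_matrix(space: StateSpace, params: ModelParams) -> sp.csr_matrix:
    """Row-stochastic one-elementary-step matrix over ``space.states``."""
    rows, cols, vals = [], [], []
    for i, s in enumerate(space.states):
        for t, pr in _step_transitions(s, params, space.levels, space.canonicalize).items():
            rows.append(i)
            cols.append(space.index[t])
            vals.append(pr)
    m = sp.csr_matrix(
        (vals, (rows, cols)), shape=(space.n_states, space.n_states)
    )
    assert np.allclose(np.asarray(m.sum(axis=1)).ravel(), 1.0, atol=1e-12)
    return m


def _target_reachable_everywhere(matrix: sp.csr_matrix, target: List[int]) -> bool:
    """True iff every state has a path into ``target`` (finite hitting time)."""
    n = matrix.shape[0]
    rev = (matrix > 0).T.tocsr()
    seen = np.zeros(n, dtype=bool)
    stack = list(target)
    seen[target] = True
    while stack:
        v = stack.pop()
        for w in rev.indices[rev.indptr[v]:rev.indptr[v + 1]]:
            if not seen[w]:
                seen[w] = True
                stack.append(int(w))
    return bool(seen.all())


def expected_absorption_time(
    space: StateSpace,
    matrix: sp.csr_matrix,
    params: ModelParams,
    criterion: str = "all_damage_one",
) -> float:
    """Exact expected hitting time, in time units, from the all-epsilon state.

    ``all_damage_one`` targets the absorbing all-ones set; ``f0_zero``
    targets the (also absorbing) set with no initial-level cell left. If
    the target is not almost-surely reached (p = 0 or epsilon = 0) the
    result is ``inf`` rather than an error. The linear solve is the
    fundamental-matrix system (I - Q) t = 1 over non-target states,
    converted from elementary steps to time units.
    """
    if criterion == "all_damage_one":
        target = space.absorbing_indices()
    elif criterion == "f0_zero":
        target = space.f0_zero_indices()
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    start = space.index[space.initial_state()]
    if start in target:
        return 0.0
    if not target or not _target_reachable_everywhere(matrix, target):
        return math.inf
    transient = np.array([i for i in range(space.n_states) if i not in set(target)])
    q = matrix[transient][:, transient]
    eye = sp.identity(len(transient), format="csc")
    t_steps = spla.spsolve(eye - q.tocsc(), np.ones(len(transient)))
    pos = int(np.searchsorted(transient, start))
    return float(t_steps[pos]) / params.n
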