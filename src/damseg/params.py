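"""Model parameters and the pure division/apoptosis rules.

The model describes a homeostatic tissue of ``N`` somatic cells. Each cell
carries a scalar damage level ``d`` in [0, 1] (here interpreted as the load
of mitochondrial DNA mutations). Damage is irreversible: at division every
daughter inherits at least the parent's damage. The three biological
parameters are the initial damage level ``epsilon``, the probability ``p``
of acquiring additional mutations between divisions, and the additional
damage ``delta`` (the "fragility") acquired in a mutated division cycle.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Any, Mapping


class Mode(str, enum.Enum):
    """How newly acquired damage is partitioned between daughters."""

    SYMMETRIC = "symmetric"
    ASYMMETRIC = "asymmetric"


class Topology(str, enum.Enum):
    """Who may divide to replace an apoptotic cell."""

    WELL_MIXED = "well_mixed"
    RING_1D = "ring_1d"


#: Exact field names accepted in flat JSON configs and CLI flags.
PARAM_FIELDS = ("n", "epsilon", "p", "delta", "mode", "topology", "seed")


class ParameterError(ValueError):
    """A model parameter violates its contract."""


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter set of the damage-segregation model.

    Attributes
    ----------
    n : int
        Number of cells; constant over time (homeostasis). Must be >= 2 so
        an apoptotic cell always has another cell available to divide.
    epsilon : float
        Damage level of every cell at t = 0, in [0, 1]. Doubles as the
        initial per-selection apoptosis probability.
    p : float
        Probability that the dividing cell has acquired additional damage
        since its last division, in [0, 1].
    delta : float
        Fragility: total additional damage created by a mutated division
        cycle; must be > 0.
    mode : Mode
        Symmetric (each daughter gets ``delta/2``) or asymmetric (one
        daughter gets all of ``delta``).
    topology : Topology
        Well-mixed (any other cell may divide) or a 1D ring with periodic
        boundaries (only the two neighbours of the dead cell may divide).
    seed : int
        Non-negative seed of the single RNG stream used by a run.
    """

    n: int
    epsilon: float
    p: float
    delta: float
    mode: Mode = Mode.SYMMETRIC
    topology: Topology = Topology.WELL_MIXED
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ParameterError("n must be an integer >= 2")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ParameterError("epsilon out of range [0, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError("p out of range [0, 1]")
        if not self.delta > 0.0:
            raise ParameterError("delta must be > 0")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "seed", int(self.seed))
        object.__setattr__(self, "epsilon", float(self.epsilon))
        object.__setattr__(self, "p", float(self.p))
        object.__setattr__(self, "delta", float(self.delta))
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "topology", Topology(self.topology))
        if self.epsilon == 0.0:
            warnings.warn(
                "epsilon = 0: apoptosis can never occur; dynamics are frozen",
                stacklevel=3,
            )
        elif self.epsilon == 1.0:
            warnings.warn(
                "epsilon = 1: the population starts in the absorbing "
                "all-damage-one state",
                stacklevel=3,
            )

    @property
    def increment_step(self) -> float:
        """Per-daughter damage increment of a mutated division.

        ``delta/2`` in symmetric mode, ``delta`` in asymmetric mode; this is
        the spacing of the reachable damage lattice ``epsilon + m * step``.
        """
        return self.delta / 2.0 if self.mode is Mode.SYMMETRIC else self.delta

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        fields = {f: getattr(self, f) for f in PARAM_FIELDS}
        fields.update(changes)
        return ModelParams(**fields)


@dataclass(frozen=True)
class DamagePair:
    """Damage levels of the two daughters of one division, high first."""

    d_high: float
    d_low: float

    def __post_init__(self) -> None:
        if self.d_high < self.d_low:
            raise ValueError("d_high must be >= d_low")


def validate_params(raw: Mapping[str, Any]) -> ModelParams:
    """Build an immutable :class:`ModelParams` from a flat mapping.

    ``raw`` must contain exactly the keys ``n, epsilon, p, delta, mode,
    topology, seed`` (the last three may be omitted and default to
    ``symmetric``, ``well_mixed`` and 0). Out-of-range values raise
    :class:`ParameterError` naming the offending field; ``epsilon`` of 0 or
    1 is allowed but triggers a warning.
    """
    unknown = set(raw) - set(PARAM_FIELDS)
    if unknown:
        raise ParameterError(f"unknown key(s): {sorted(unknown)}")
    missing = {"n", "epsilon", "p", "delta"} - set(raw)
    if missing:
        raise ParameterError(f"missing required key(s): {sorted(missing)}")
    fields = dict(raw)
    fields.setdefault("mode", Mode.SYMMETRIC)
    fields.setdefault("topology", Topology.WELL_MIXED)
    fields.setdefault("seed", 0)
    try:
        fields["mode"] = Mode(fields["mode"])
    except ValueError:
        raise ParameterError(
            f"mode must be one of {[m.value for m in Mode]}"
        ) from None
    try:
        fields["topology"] = Topology(fields["topology"])
    except ValueError:
        raise ParameterError(
            f"topology must be one of {[t.value for t in Topology]}"
        ) from None
    return ModelParams(**fields)


def apoptosis_prob(d: float) -> float:
    """Per-selection apoptosis probability of a cell with damage ``d``.

    The model takes the probability proportional to the damage level with
    unit constant, so the probability simply equals ``d``. Damage is
    already confined to [0, 1], and the unit constant makes ``epsilon``
    directly interpretable as the initial per-selection death probability.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("damage level outside [0, 1]")
    return d


def daughter_damages(
    d_parent: float, mutated: bool, mode: Mode, delta: float
) -> DamagePair:
    """Damage levels of the two daughters of a dividing cell.

    Without mutation both daughters inherit ``d_parent`` exactly (damage is
    duplicated, never diluted). A mutated division creates ``delta`` of new
    damage in total: in symmetric mode each daughter receives ``delta/2``;
    in asymmetric mode one daughter receives all of ``delta`` and the other
    only the parental level. Each daughter is clamped at 1 after the
    increment.
    """
    if not 0.0 <= d_parent <= 1.0:
        raise ValueError("parent damage outside [0, 1]")
    if not delta > 0.0:
        raise ValueError("delta must be > 0")
    if not mutated:
        return DamagePair(d_parent, d_parent)
    mode = Mode(mode)
    if mode is Mode.SYMMETRIC:
        d = min(d_parent + delta / 2.0, 1.0)
        return DamagePair(d, d)
    return DamagePair(min(d_parent + delta, 1.0), d_parent)
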