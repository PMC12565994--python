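"""Boltzmann populations of a conformer ensemble from electronic energies.

Total electronic energies (Hartree, implicit-solvent DFT) are used directly
as the state energies E_r — no zero-point or thermal free-energy corrections.
The population of state r at temperature T is

    p_r = exp(-(E_r - E_min) / kT) / Z,   Z = sum_t exp(-(E_t - E_min) / kT)

with the minimum energy subtracted for numerical stability (the populations
are invariant under any constant energy shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

from .types import Ensemble, ValidationError

__all__ = [
    "HARTREE_TO_KCAL_PER_MOL",
    "BOLTZMANN_HARTREE_PER_K",
    "STANDARD_TEMPERATURE_K",
    "hartree_to_kcal",
    "boltzmann_populations",
    "group_ratio",
    "PopulationResult",
]

#: CODATA conversion, kcal mol^-1 per Hartree.
HARTREE_TO_KCAL_PER_MOL = 627.5094740631

#: Boltzmann constant in Hartree per Kelvin (CODATA-derived).
BOLTZMANN_HARTREE_PER_K = 3.166811563e-6

#: Room temperature used throughout the study.
STANDARD_TEMPERATURE_K = 298.15


def hartree_to_kcal(delta: float) -> float:
    """Convert an energy difference from Hartree to kcal/mol."""
    if not math.isfinite(delta):
        raise ValidationError(f"energy difference must be finite, got {delta}")
    return delta * HARTREE_TO_KCAL_PER_MOL


@dataclass(frozen=True)
class PopulationResult:
    """Boltzmann populations of an ensemble at one temperature.

    ``partition_function`` is relative to the minimum-energy state (the
    weight of that state is exactly 1).  ``relative_energies`` are in
    kcal/mol above the minimum-energy conformer.
    """

    temperature: float
    probabilities: dict[Hashable, float]
    partition_function: float
    relative_energies: dict[Hashable, float]

    def group_population(self, ids: Iterable[Hashable]) -> float:
        """Summed probability of a set of conformer ids."""
        ids = set(ids)
        missing = ids - set(self.probabilities)
        if missing:
            raise ValidationError(f"unknown conformer ids: {sorted(map(str, missing))}")
        return sum(self.probabilities[i] for i in ids)


def boltzmann_populations(
    ensemble: Ensemble | Mapping[Hashable, float],
    temperature: float = STANDARD_TEMPERATURE_K,
) -> PopulationResult:
    """Boltzmann populations from total electronic energies in Hartree.

    Accepts an :class:`~confspect.types.Ensemble` or a plain mapping
    ``conformer id -> energy (Ha)``.  Exact energy ties (degenerate minima)
    need no special casing: the weights split evenly by the formula itself.
    """
    if temperature <= 0 or not math.isfinite(temperature):
        raise ValidationError(f"temperature must be positive, got {temperature}")
    energies = (
        ensemble.energies if isinstance(ensemble, Ensemble) else dict(ensemble)
    )
    if not energies:
        raise ValidationError("need at least one conformer energy")
    if not all(math.isfinite(e) for e in energies.values()):
        raise ValidationError("all energies must be finite")

    e_min = min(energies.values())
    kt = BOLTZMANN_HARTREE_PER_K * temperature
    weights = {cid: math.exp(-(e - e_min) / kt) for cid, e in energies.items()}
    z = sum(weights.values())
    return PopulationResult(
        temperature=float(temperature),
        probabilities={cid: w / z for cid, w in weights.items()},
        partition_function=z,
        relative_energies={
            cid: hartree_to_kcal(e - e_min) for cid, e in energies.items()
        },
    )


def group_ratio(
    populations: PopulationResult,
    group_a: Iterable[Hashable],
    group_b: Iterable[Hashable],
) -> float:
    """Population ratio (sum over group A) / (sum over group B).

    Groups must be disjoint and non-empty; a zero denominator is an error.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if a & b:
        raise ValidationError(f"groups overlap: {sorted(map(str, a & b))}")
    pa = populations.group_population(a)
    pb = populations.group_population(b)
    if pb == 0:
        raise ValidationError("group B has zero total population")
    return pa / pb
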