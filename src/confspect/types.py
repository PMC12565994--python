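"""Domain containers for conformer-ensemble spectroscopy.

The objects here mirror what a quantum-chemistry post-processing run produces
for a small conformer ensemble in implicit solvent: per-conformer total
electronic energies, GIAO magnetic shielding tensors, electronic transition
lists, plus the experimental side (peak lists and sampled spectra).
All are plain dataclasses validated on construction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AtomSite",
    "ShieldingTensor",
    "Transition",
    "ConformerRecord",
    "Ensemble",
    "ExperimentalPeak",
    "Spectrum",
    "ValidationError",
    "parse_atom_label",
]

#: hc in eV·nm, used for the transition energy/wavelength consistency check.
HC_EV_NM = 1239.84198

#: Largest tolerated mismatch (nm) between a stored wavelength and the one
#: derived from the stored energy.
WAVELENGTH_CONSISTENCY_NM = 0.01

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Fe", "Zn", "Se",
}

_LABEL_RE = re.compile(r"^([A-Z][a-z]?)(\d+)$")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def parse_atom_label(label: str) -> tuple[str, int]:
    """Split an atom label like ``"C5"`` or ``"H11"`` into (element, index)."""
    m = _LABEL_RE.match(str(label))
    if m is None:
        raise ValidationError(f"not a valid atom label: {label!r}")
    element, index = m.group(1), int(m.group(2))
    if element not in _ELEMENTS:
        raise ValidationError(f"unknown element {element!r} in label {label!r}")
    return element, index


@dataclass(frozen=True)
class AtomSite:
    """One atom of a conformer geometry.

    ``index`` is the 1-based label used throughout the tables and figures
    (so ``AtomSite(5, "C")`` is the atom written C5).  ``position`` is a
    Cartesian triple in Å and may be absent for table-only records.
    """

    index: int
    element: str
    position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if int(self.index) < 1:
            raise ValidationError(f"atom index must be >= 1, got {self.index}")
        if self.element not in _ELEMENTS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.position is not None:
            pos = tuple(float(x) for x in self.position)
            if len(pos) != 3 or not all(math.isfinite(x) for x in pos):
                raise ValidationError(
                    f"atom {self.label}: position must be a finite 3-vector"
                )
            object.__setattr__(self, "position", pos)

    @property
    def label(self) -> str:
        """Label in table notation, e.g. ``"C5"``."""
        return f"{self.element}{self.index}"


@dataclass(frozen=True)
class ShieldingTensor:
    """A 3x3 magnetic shielding tensor (ppm) attached to one atom.

    Only the diagonal enters the isotropic value; off-diagonal components
    are carried for completeness.
    """

    atom_index: int
    components: np.ndarray

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        if comp.shape != (3, 3):
            raise ValidationError(
                f"shielding tensor for atom {self.atom_index}: expected 3x3, "
                f"got shape {comp.shape}"
            )
        if not np.all(np.isfinite(comp)):
            raise ValidationError(
                f"shielding tensor for atom {self.atom_index}: non-finite entries"
            )
        object.__setattr__(self, "components", comp)

    @property
    def isotropic(self) -> float:
        """Mean of the three diagonal components, ppm."""
        return float(np.trace(self.components) / 3.0)


@dataclass(frozen=True)
class Transition:
    """One vertical singlet-singlet electronic transition."""

    state_index: int
    energy_ev: float
    oscillator_strength: float
    wavelength_nm: float | None = None
    contributions: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if int(self.state_index) < 1:
            raise ValidationError("transition state index must be positive")
        if not (self.energy_ev > 0 and math.isfinite(self.energy_ev)):
            raise ValidationError(
                f"state {self.state_index}: energy must be positive, "
                f"got {self.energy_ev}"
            )
        if self.oscillator_strength < 0:
            raise ValidationError(
                f"state {self.state_index}: oscillator strength must be >= 0"
            )
        if self.wavelength_nm is not None:
            derived = HC_EV_NM / self.energy_ev
            if abs(derived - self.wavelength_nm) > WAVELENGTH_CONSISTENCY_NM + 5e-3:
                raise ValidationError(
                    f"state {self.state_index}: wavelength {self.wavelength_nm} nm "
                    f"inconsistent with energy {self.energy_ev} eV "
                    f"(expected {derived:.2f} nm)"
                )
        object.__setattr__(
            self,
            "contributions",
            tuple((str(k), float(v)) for k, v in self.contributions),
        )

    @property
    def wavelength(self) -> float:
        """Wavelength in nm, derived from the energy when not stored."""
        if self.wavelength_nm is not None:
            return self.wavelength_nm
        return HC_EV_NM / self.energy_ev


@dataclass
class ConformerRecord:
    """Everything computed for a single conformer in a given solvent."""

    id: int | str
    solvent: str
    total_energy_ha: float
    geometry: tuple[AtomSite, ...] = ()
    shieldings: tuple[ShieldingTensor, ...] = ()
    transitions: tuple[Transition, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.total_energy_ha):
            raise ValidationError(
                f"conformer {self.id}: total energy must be finite"
            )
        if self.total_energy_ha >= 0:
            raise ValidationError(
                f"conformer {self.id}: total electronic energy of a real "
                f"molecule must be negative, got {self.total_energy_ha}"
            )
        self.geometry = tuple(self.geometry)
        indices = [a.index for a in self.geometry]
        if len(set(indices)) != len(indices):
            raise ValidationError(
                f"conformer {self.id}: duplicate atom indices in geometry"
            )
        self.shieldings = tuple(self.shieldings)
        self.transitions = tuple(self.transitions)

    def atom(self, label: str | int) -> AtomSite:
        """Look up an atom by index or table label (``"C5"``)."""
        if isinstance(label, str):
            element, index = parse_atom_label(label)
        else:
            element, index = None, int(label)
        for site in self.geometry:
            if site.index == index:
                if element is not None and site.element != element:
                    raise ValidationError(
                        f"label {label!r} names {element} but atom {index} "
                        f"is {site.element}"
                    )
                return site
        raise KeyError(f"no atom with index {index} in conformer {self.id}")


@dataclass
class Ensemble:
    """A set of conformers of one molecule in one solvent.

    ``references`` maps a nucleus ("13C", "1H") to the isotropic shielding of
    the TMS reference in ppm, required to turn shieldings into chemical shifts.
    """

    molecule_name: str
    conformers: tuple[ConformerRecord, ...]
    references: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conformers = tuple(self.conformers)
        if not self.conformers:
            raise ValidationError("ensemble must contain at least one conformer")
        ids = [c.id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate conformer ids: {ids}")
        solvents = {c.solvent for c in self.conformers}
        if len(solvents) != 1:
            raise ValidationError(
                f"all conformers must share one solvent, got {sorted(solvents)}"
            )
        for nucleus, shielding in self.references.items():
            if not shielding > 0:
                raise ValidationError(
                    f"reference shielding for {nucleus} must be positive"
                )

    @property
    def solvent(self) -> str:
        return self.conformers[0].solvent

    @property
    def ids(self) -> tuple[int | str, ...]:
        return tuple(c.id for c in self.conformers)

    def conformer(self, cid: int | str) -> ConformerRecord:
        for c in self.conformers:
            if c.id == cid:
                return c
        raise KeyError(f"no conformer with id {cid!r}")

    @property
    def energies(self) -> dict[int | str, float]:
        """Mapping conformer id -> total electronic energy in Hartree."""
        return {c.id: c.total_energy_ha for c in self.conformers}


@dataclass(frozen=True)
class ExperimentalPeak:
    """One experimental NMR peak (or a printed multiplet range).

    When a range is given the ``shift`` is its midpoint; ``area`` is the
    integrated intensity in arbitrary units and may be absent (the printed
    tables do not report areas).
    """

    nucleus: str
    shift: float
    shift_range: tuple[float, float] | None = None
    area: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.nucleus not in ("1H", "13C"):
            raise ValidationError(f"unknown nucleus {self.nucleus!r}")
        if not math.isfinite(self.shift):
            raise ValidationError("peak shift must be finite")
        if self.shift_range is not None:
            lo, hi = (float(x) for x in self.shift_range)
            if lo > hi:
                lo, hi = hi, lo
            if not (lo - 1e-9 <= self.shift <= hi + 1e-9):
                raise ValidationError(
                    f"shift {self.shift} outside its range ({lo}, {hi})"
                )
            object.__setattr__(self, "shift_range", (lo, hi))
        if self.area is not None and self.area < 0:
            raise ValidationError("peak area must be >= 0")


@dataclass
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength or energy grid."""

    axis_kind: str
    grid: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis_kind not in ("wavelength_nm", "energy_eV"):
            raise ValidationError(f"unknown axis kind {self.axis_kind!r}")
        grid = np.asarray(self.grid, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if grid.ndim != 1 or grid.shape != intensity.shape:
            raise ValidationError(
                f"grid and intensity must be 1-D and equal length, got "
                f"{grid.shape} vs {intensity.shape}"
            )
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValidationError("spectrum grid must be strictly increasing")
        if not np.all(np.isfinite(intensity)):
            raise ValidationError("spectrum intensities must be finite")
        self.grid = grid
        self.intensity = intensity

    def __len__(self) -> int:
        return int(self.grid.size)

    def with_intensity(self, intensity: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new intensities and updated metadata."""
        return Spectrum(
            axis_kind=self.axis_kind,
            grid=self.grid.copy(),
            intensity=np.asarray(intensity, dtype=float),
            metadata={**self.metadata, **meta},
        )


def same_grid(a: Spectrum, b: Spectrum, atol: float = 1e-9) -> bool:
    """True when two spectra share axis kind and (numerically) the same grid."""
    return (
        a.axis_kind == b.axis_kind
        and len(a) == len(b)
        and bool(np.allclose(a.grid, b.grid, atol=atol, rtol=0.0))
    )
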