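"""Synthetic conformer ensembles with known ground truth.

Every stage of the analysis pipeline can be exercised without any external
data: the generator emits ensembles whose energies realize prescribed
Boltzmann populations, shielding tensors whose isotropic values encode known
chemical shifts, peak lists whose areas are proportional to conformer-group
populations, and broadened UV-Vis spectra from a transition template.

All generators are pure functions of the configuration (seed included):
identical configs give identical output.  Defaults mirror the coumarin–
cytisine study conditions: four conformers with sub-kcal/mol energy gaps
(0.04 / 0 / 0.69 / 0.43 kcal/mol), TMS reference shieldings 184.32 ppm
(13C) and 31.96 ppm (1H), a 0.25 eV FWHM broadening on a 200–500 nm / 2 nm
grid, and the five printed transitions of the most stable conformer as the
UV template.

The geometry scaffold is a deliberately minimal abstract dicarbonyl chain
O=C-C(=O)-C=O with two padding hydrogens — not a cytisine model (synthetic
by construction).  Conformer classification needs only the two marker
dihedrals, which the scaffold realizes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Mapping, Sequence

import numpy as np

from .nmr import DEFAULT_RESOLUTION_PPM, cluster_shifts
from .types import (
    AtomSite,
    ConformerRecord,
    Ensemble,
    ExperimentalPeak,
    ShieldingTensor,
    Spectrum,
    Transition,
    ValidationError,
    parse_atom_label,
)
from .thermo import HARTREE_TO_KCAL_PER_MOL, boltzmann_populations
from .uvvis import BroadeningConfig, broaden_transitions, ensemble_spectrum

__all__ = [
    "GeneratorConfig",
    "generate_ensemble",
    "generate_shieldings",
    "generate_peak_list",
    "generate_uvvis",
    "scaffold_geometry",
    "FAMILY_DIHEDRALS",
]

#: Marker dihedral pairs (theta1, theta2) in degrees realized per family.
FAMILY_DIHEDRALS = {
    1: (-12.0, 97.0),
    2: (132.0, -97.0),
    3: (-12.0, -97.0),
    4: (132.0, 97.0),
}

#: Transitions of the most stable conformer (energy eV, oscillator strength).
_DEFAULT_TEMPLATE = (
    (3.9181, 0.2191),
    (4.2610, 0.1676),
    (4.5374, 0.1814),
    (5.6977, 0.0816),
    (6.0862, 0.4132),
)

_TMS_REFERENCES = {"13C": 184.32, "1H": 31.96}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    ``energy_gaps_kcal`` are per-conformer energies above the global minimum
    (kcal/mol), one per conformer; the defaults are the study's relative
    energies in DMSO.  ``true_scaling`` holds the (a, b) affine parameters
    per nucleus that relate unscaled to scaled shifts.  Noise parameters
    default to zero so that the noiseless pipelines are exact.
    """

    seed: int = 0
    n_conformers: int = 4
    energy_gaps_kcal: tuple[float, ...] = (0.04, 0.0, 0.69, 0.43)
    true_scaling: dict = field(
        default_factory=lambda: {"13C": (1.05, -2.0), "1H": (1.02, -0.08)}
    )
    shift_noise_sd: float = 0.0
    area_noise_cv: float = 0.0
    transition_template: tuple[tuple[float, float], ...] = _DEFAULT_TEMPLATE
    geometry_template: str | None = "carbonyl_chain"
    base_energy_ha: float = -1221.0
    references: dict = field(default_factory=lambda: dict(_TMS_REFERENCES))
    anisotropy_sd: float = 5.0
    offdiagonal_sd: float = 2.0
    transition_jitter_sd: float = 0.0
    baseline: float = 0.0
    spectrum_noise_sd: float = 0.0
    broadening: BroadeningConfig = field(default_factory=BroadeningConfig)

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValidationError("need at least one conformer")
        if len(self.energy_gaps_kcal) != self.n_conformers:
            raise ValidationError(
                f"energy_gaps_kcal has {len(self.energy_gaps_kcal)} entries "
                f"for {self.n_conformers} conformers"
            )
        for name in (
            "shift_noise_sd",
            "area_noise_cv",
            "anisotropy_sd",
            "offdiagonal_sd",
            "transition_jitter_sd",
            "spectrum_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one operation, pure in (seed, stream)."""
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# Geometry scaffold
# ---------------------------------------------------------------------------

def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Internal-coordinate placement: position of atom d bonded to c with
    angle b-c-d and signed dihedral d-c-b-a equal to ``dihedral_deg``."""
    angle = math.radians(angle_deg)
    torsion = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def scaffold_geometry(theta1: float, theta2: float) -> tuple[AtomSite, ...]:
    """Abstract O=C-C(=O)-C=O scaffold realizing the two marker dihedrals.

    Atom indices follow the study's labels for the atoms that matter:
    O1, C19 (first carbonyl), O4, C45 (central carbonyl), O8, C31 (last
    carbonyl), plus padding hydrogens H90/H91.  Built so that
    ``dihedral(O1, C19, C45, O4) == theta1`` and
    ``dihedral(O4, C45, C31, O8) == theta2`` exactly.
    """
    c19 = np.array([0.0, 0.0, 0.0])
    c45 = np.array([1.52, 0.0, 0.0])
    # O4 on the central carbon, 120 deg from the C19 arm, in the xy-plane
    o4 = c45 + 1.22 * np.array(
        [math.cos(math.radians(60.0)), -math.sin(math.radians(60.0)), 0.0]
    )
    o1 = _place_atom(o4, c45, c19, 1.22, 120.0, theta1)
    # planar sp2 centre: C31 anti to C19 across the C45-O4 plane
    c31 = _place_atom(c19, o4, c45, 1.52, 120.0, 180.0)
    o8 = _place_atom(o4, c45, c31, 1.22, 120.0, theta2)
    h90 = _place_atom(o1, c45, c19, 1.09, 120.0, 180.0)
    h91 = _place_atom(o8, c45, c31, 1.09, 120.0, 180.0)
    return (
        AtomSite(1, "O", tuple(o1)),
        AtomSite(4, "O", tuple(o4)),
        AtomSite(8, "O", tuple(o8)),
        AtomSite(19, "C", tuple(c19)),
        AtomSite(31, "C", tuple(c31)),
        AtomSite(45, "C", tuple(c45)),
        AtomSite(90, "H", tuple(h90)),
        AtomSite(91, "H", tuple(h91)),
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_ensemble(config: GeneratorConfig | None = None) -> Ensemble:
    """Synthetic ensemble with prescribed energy gaps and marker dihedrals.

    Total energies are ``base_energy_ha + gap / 627.509...`` so that
    Boltzmann populations reproduce the gaps exactly.  Conformer r gets the
    marker dihedrals of family ``((r-1) mod 4) + 1``, so classification by
    geometry recovers the intended family.
    """
    config = config or GeneratorConfig()
    conformers = []
    for r in range(1, config.n_conformers + 1):
        family = (r - 1) % 4 + 1
        theta1, theta2 = FAMILY_DIHEDRALS[family]
        geometry = (
            scaffold_geometry(theta1, theta2)
            if config.geometry_template is not None
            else ()
        )
        energy = (
            config.base_energy_ha
            + config.energy_gaps_kcal[r - 1] / HARTREE_TO_KCAL_PER_MOL
        )
        conformers.append(
            ConformerRecord(
                id=r,
                solvent="synthetic",
                total_energy_ha=energy,
                geometry=geometry,
            )
        )
    return Ensemble(
        molecule_name="synthetic dicarbonyl scaffold",
        conformers=tuple(conformers),
        references=dict(config.references),
    )


def generate_shieldings(
    config: GeneratorConfig,
    true_shifts: Mapping[tuple[str, Hashable], float],
) -> dict[Hashable, tuple[ShieldingTensor, ...]]:
    """Shielding tensors whose isotropic values encode known shifts.

    For each (atom label, conformer id) -> shift entry, builds a 3x3 tensor
    with diagonal mean exactly ``reference - shift`` (plus Gaussian noise of
    sd ``shift_noise_sd`` on the mean when requested).  Anisotropic diagonal
    spread and off-diagonal noise never move the mean, so the noiseless
    round trip through isotropic shielding + referencing is exact.
    """
    rng = config.rng(1)
    out: dict[Hashable, list[ShieldingTensor]] = {}
    for (atom, cid), shift in sorted(
        true_shifts.items(), key=lambda kv: (str(kv[0][1]), kv[0][0])
    ):
        element, index = parse_atom_label(atom)
        nucleus = "13C" if element == "C" else "1H"
        reference = config.references[nucleus]
        iso = reference - float(shift)
        if config.shift_noise_sd > 0:
            iso += rng.normal(0.0, config.shift_noise_sd)
        spread = rng.normal(0.0, config.anisotropy_sd, size=2)
        diagonal = iso + np.array([spread[0], spread[1], -spread.sum()])
        tensor = np.diag(diagonal)
        off = rng.normal(0.0, config.offdiagonal_sd, size=(3, 3))
        tensor += off - np.diag(np.diag(off))
        out.setdefault(cid, []).append(ShieldingTensor(index, tensor))
    return {cid: tuple(tensors) for cid, tensors in out.items()}


def generate_peak_list(
    config: GeneratorConfig,
    true_shifts: Mapping[tuple[str, Hashable], float],
    populations: Mapping[Hashable, float],
    proton_counts: Mapping[str, int] | None = None,
) -> list[ExperimentalPeak]:
    """Peak list with areas proportional to population x proton count.

    Per atom, conformer shifts are merged at the nucleus' resolution: a
    merged cluster emits one peak whose area sums the member populations;
    conformers split beyond the resolution emit separate peaks.  Areas pick
    up multiplicative log-normal noise of coefficient of variation
    ``area_noise_cv`` (mean preserved).
    """
    rng = config.rng(2)
    proton_counts = proton_counts or {}
    sigma = (
        math.sqrt(math.log(1.0 + config.area_noise_cv**2))
        if config.area_noise_cv > 0
        else 0.0
    )
    per_atom: dict[str, dict[Hashable, float]] = {}
    for (atom, cid), shift in true_shifts.items():
        per_atom.setdefault(str(atom), {})[cid] = float(shift)

    peaks: list[ExperimentalPeak] = []
    for atom in sorted(per_atom):
        element, _ = parse_atom_label(atom)
        nucleus = "13C" if element == "C" else "1H"
        count = int(proton_counts.get(atom, 1))
        for cluster in cluster_shifts(
            per_atom[atom], DEFAULT_RESOLUTION_PPM[nucleus], atom=atom
        ):
            weight = sum(populations[c] for c in cluster.conformers)
            if weight == 0:
                continue
            shift = sum(
                populations[c] * cluster.shifts[c] for c in cluster.conformers
            ) / weight
            area = weight * count
            if sigma > 0:
                area *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            peaks.append(
                ExperimentalPeak(
                    nucleus=nucleus, shift=shift, area=area, label=atom
                )
            )
    return peaks


def generate_uvvis(
    config: GeneratorConfig | None = None,
) -> tuple[Spectrum, dict]:
    """Broadened ensemble spectrum plus the ground-truth record.

    Each conformer's transitions start from ``transition_template``; with
    ``transition_jitter_sd > 0`` the energies get per-conformer Gaussian
    offsets.  The ensemble spectrum is Boltzmann-weighted from the energy
    gaps, then an additive baseline and Gaussian noise are applied.  With
    all noise at zero the output equals the plain broadened template.
    """
    config = config or GeneratorConfig()
    rng = config.rng(3)
    energies = {
        r + 1: config.base_energy_ha
        + config.energy_gaps_kcal[r] / HARTREE_TO_KCAL_PER_MOL
        for r in range(config.n_conformers)
    }
    weights = boltzmann_populations(energies)
    per_conformer: dict[Hashable, Spectrum] = {}
    transitions_truth: dict[Hashable, tuple[Transition, ...]] = {}
    for cid in sorted(energies):
        transitions = []
        for k, (energy, strength) in enumerate(config.transition_template, start=1):
            jitter = (
                rng.normal(0.0, config.transition_jitter_sd)
                if config.transition_jitter_sd > 0
                else 0.0
            )
            transitions.append(
                Transition(
                    state_index=k,
                    energy_ev=energy + jitter,
                    oscillator_strength=strength,
                )
            )
        transitions_truth[cid] = tuple(transitions)
        per_conformer[cid] = broaden_transitions(transitions, config.broadening)
    spectrum = ensemble_spectrum(per_conformer, weights)
    intensity = spectrum.intensity + config.baseline
    if config.spectrum_noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, config.spectrum_noise_sd, size=intensity.shape
        )
    truth = {
        "weights": dict(weights.probabilities),
        "transitions": transitions_truth,
        "baseline": config.baseline,
    }
    return spectrum.with_intensity(intensity, synthetic=True), truth
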