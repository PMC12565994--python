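"""UV-Vis absorption: broadened transition spectra, ensemble weighting, and
processing of measured spectra.

Simulated spectra follow the usual convention for plotting TD-DFT results:
every vertical transition contributes a Gaussian band on the *energy* axis
with a fixed full width at half maximum (default 0.25 eV) and a peak height
proportional to its oscillator strength.  The energy-axis profile is then
sampled on the instrument's wavelength grid (default 200–500 nm, 2 nm step).
An ensemble spectrum is the population-weighted pointwise sum of the
per-conformer spectra.

Experimental processing covers transmission → absorbance (A = log10(1/T)),
normalization to the band maximum in a window, solvent background
subtraction, and a derivative-based report of band maxima and shoulders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .thermo import PopulationResult
from .types import Spectrum, Transition, ValidationError, same_grid

__all__ = [
    "HC_EV_NM",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "BroadeningConfig",
    "broaden_transitions",
    "ensemble_spectrum",
    "simulate_ensemble_spectrum",
    "transmission_to_absorbance",
    "normalize_spectrum",
    "subtract_background",
    "report_extrema",
    "SpectralFeature",
]

logger = logging.getLogger("confspect")

#: hc in eV·nm: E [eV] * lambda [nm] = 1239.84198.
HC_EV_NM = 1239.84198


def energy_to_wavelength(energy_ev):
    """Convert photon energy in eV to wavelength in nm (elementwise)."""
    arr = np.asarray(energy_ev, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("photon energy must be positive")
    out = HC_EV_NM / arr
    return float(out) if arr.ndim == 0 else out


def wavelength_to_energy(wavelength_nm):
    """Convert wavelength in nm to photon energy in eV (elementwise)."""
    arr = np.asarray(wavelength_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("wavelength must be positive")
    out = HC_EV_NM / arr
    return float(out) if arr.ndim == 0 else out


@dataclass(frozen=True)
class BroadeningConfig:
    """Lineshape and sampling grid for simulated absorption spectra."""

    fwhm_ev: float = 0.25
    lineshape: str = "gaussian"
    grid_min_nm: float = 200.0
    grid_max_nm: float = 500.0
    grid_step_nm: float = 2.0
    intensity_convention: str = "height_proportional_to_f"

    def __post_init__(self) -> None:
        if not self.fwhm_ev > 0:
            raise ValidationError("FWHM must be positive")
        if self.lineshape != "gaussian":
            raise ValidationError(f"unsupported lineshape {self.lineshape!r}")
        if not self.grid_min_nm < self.grid_max_nm:
            raise ValidationError("grid_min must be below grid_max")
        if not self.grid_step_nm > 0:
            raise ValidationError("grid step must be positive")

    @property
    def sigma_ev(self) -> float:
        """Gaussian sigma in eV: FWHM / (2 sqrt(2 ln 2))."""
        return self.fwhm_ev / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.grid_max_nm - self.grid_min_nm) / self.grid_step_nm))
        return self.grid_min_nm + self.grid_step_nm * np.arange(n + 1)


def broaden_transitions(
    transitions: Sequence[Transition],
    config: BroadeningConfig | None = None,
) -> Spectrum:
    """Sum of Gaussian bands, one per transition, sampled on the nm grid.

    On the energy axis ``I(E) = sum_i f_i exp(-(E - E_i)^2 / (2 sigma^2))``,
    so each band's height equals its oscillator strength.  Linear in the
    transition list: concatenating two lists sums their spectra.  An empty
    list yields a zero spectrum.
    """
    config = config or BroadeningConfig()
    grid = config.wavelength_grid()
    energies = HC_EV_NM / grid
    intensity = np.zeros_like(grid)
    sigma = config.sigma_ev
    for t in transitions:
        intensity += t.oscillator_strength * np.exp(
            -((energies - t.energy_ev) ** 2) / (2.0 * sigma**2)
        )
    return Spectrum(
        axis_kind="wavelength_nm",
        grid=grid,
        intensity=intensity,
        metadata={
            "fwhm_ev": config.fwhm_ev,
            "lineshape": config.lineshape,
            "intensity_convention": config.intensity_convention,
            "n_transitions": len(transitions),
        },
    )


def ensemble_spectrum(
    per_conformer: Mapping[Hashable, Spectrum],
    weights: PopulationResult | Mapping[Hashable, float],
) -> Spectrum:
    """Pointwise population-weighted sum of per-conformer spectra.

    All spectra must share one grid; ``weights`` must cover every conformer
    id.  With normalized weights the result is a convex combination and is
    bounded by the pointwise min/max of the inputs.
    """
    if not per_conformer:
        raise ValidationError("need at least one per-conformer spectrum")
    probs = (
        weights.probabilities if isinstance(weights, PopulationResult) else weights
    )
    missing = set(per_conformer) - set(probs)
    if missing:
        raise ValidationError(
            f"weights missing for conformers: {sorted(map(str, missing))}"
        )
    spectra = list(per_conformer.items())
    first = spectra[0][1]
    for cid, spec in spectra[1:]:
        if not same_grid(first, spec):
            raise ValidationError(f"grid mismatch for conformer {cid}")
    total = np.zeros_like(first.intensity)
    used = {}
    for cid, spec in spectra:
        total += probs[cid] * spec.intensity
        used[cid] = float(probs[cid])
    return first.with_intensity(total, weights=used)


def simulate_ensemble_spectrum(
    ensemble,
    config: BroadeningConfig | None = None,
    weights: PopulationResult | Mapping[Hashable, float] | None = None,
    temperature: float | None = None,
) -> Spectrum:
    """Broaden every conformer's transitions and Boltzmann-weight the sum.

    ``weights`` overrides the Boltzmann populations computed from the
    ensemble energies (at ``temperature``, default 298.15 K).
    """
    from .thermo import STANDARD_TEMPERATURE_K, boltzmann_populations

    config = config or BroadeningConfig()
    if weights is None:
        weights = boltzmann_populations(
            ensemble, temperature or STANDARD_TEMPERATURE_K
        )
    per_conformer = {
        c.id: broaden_transitions(c.transitions, config)
        for c in ensemble.conformers
    }
    return ensemble_spectrum(per_conformer, weights)


def transmission_to_absorbance(transmission, clip: bool = True):
    """Absorbance A = log10(1/T) from a transmission coefficient in (0, 1].

    T > 1 (calibration overshoot) logs a warning and is clipped to 1 when
    ``clip`` is set, else raises.  T <= 0 is always an error.
    """
    arr = np.asarray(transmission, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("transmission must be positive")
    if np.any(arr > 1):
        if not clip:
            raise ValidationError("transmission above 1")
        logger.warning("transmission above 1 clipped to 1")
        arr = np.minimum(arr, 1.0)
    out = np.log10(1.0 / arr)
    return float(out) if np.ndim(transmission) == 0 else out


def normalize_spectrum(
    spectrum: Spectrum, window: tuple[float, float] | None = None
) -> Spectrum:
    """Divide intensities by the maximum inside ``window`` (grid units).

    After normalization the maximum within the window equals 1 exactly.
    """
    if window is None:
        mask = np.ones_like(spectrum.grid, dtype=bool)
    else:
        lo, hi = sorted(window)
        mask = (spectrum.grid >= lo) & (spectrum.grid <= hi)
        if not mask.any():
            raise ValidationError(
                f"window {window} does not overlap the grid "
                f"[{spectrum.grid[0]}, {spectrum.grid[-1]}]"
            )
    peak = float(spectrum.intensity[mask].max())
    if peak <= 0:
        raise ValidationError("maximum in the normalization window is not positive")
    return spectrum.with_intensity(
        spectrum.intensity / peak, normalized=True, normalization_window=window
    )


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise sample minus background, floored at zero.

    The number of floored points is recorded in the metadata — flooring is
    visible, never silent.
    """
    if not same_grid(sample, background):
        raise ValidationError("sample and background grids differ")
    diff = sample.intensity - background.intensity
    floored = int(np.sum(diff < 0))
    if floored:
        logger.warning("background exceeded sample at %d points; floored", floored)
    return sample.with_intensity(
        np.maximum(diff, 0.0), background_subtracted=True, floored_points=floored
    )


@dataclass(frozen=True)
class SpectralFeature:
    """A band maximum or shoulder found in a sampled spectrum."""

    position: float
    intensity: float
    kind: str  # "maximum" | "shoulder"


def report_extrema(spectrum: Spectrum) -> list[SpectralFeature]:
    """Find band maxima and shoulders on the sampled grid.

    Maxima are strict local maxima of the intensity.  A shoulder is a
    partially resolved band: a strict local minimum of |dI/dx| on a flank
    where the slope keeps its sign — the curve flattens (inflection
    plateau) without turning over.
    """
    if len(spectrum) < 5:
        raise ValidationError("need at least 5 grid points")
    grid, intensity = spectrum.grid, spectrum.intensity
    d1 = np.gradient(intensity, grid)
    # guard against float noise on exactly linear stretches
    slope_eps = 1e-9 * float(np.max(np.abs(d1))) if np.any(d1) else 0.0
    features: list[SpectralFeature] = []
    for i in range(1, len(grid) - 1):
        if intensity[i] > intensity[i - 1] and intensity[i] > intensity[i + 1]:
            features.append(SpectralFeature(grid[i], intensity[i], "maximum"))
            continue
        prev_s, here_s, next_s = (
            np.sign(d1[i - 1]),
            np.sign(d1[i]),
            np.sign(d1[i + 1]),
        )
        if (
            abs(d1[i]) < abs(d1[i - 1]) - slope_eps
            and abs(d1[i]) < abs(d1[i + 1]) - slope_eps
            and prev_s == here_s == next_s != 0
        ):
            features.append(SpectralFeature(grid[i], intensity[i], "shoulder"))
    return features
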