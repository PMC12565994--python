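"""Energy/wavelength conversion, band broadening, and spectrum processing."""

import math

import numpy as np
import pytest

import confspect as cs
from confspect.uvvis import HC_EV_NM


class TestEnergyWavelength:
    @pytest.mark.parametrize(
        "energy_ev, wavelength_nm",
        [(3.9181, 316.44), (6.0708, 204.23), (4.0278, 307.82)],
    )
    def test_printed_pairs(self, energy_ev, wavelength_nm):
        assert round(cs.energy_to_wavelength(energy_ev), 2) == pytest.approx(
            wavelength_nm, abs=0.01
        )

    def test_one_ev_definition(self):
        assert cs.energy_to_wavelength(1.0) == pytest.approx(1239.84198)
        assert cs.wavelength_to_energy(1239.84198) == pytest.approx(1.0)

    def test_round_trip(self, rng):
        energies = rng.uniform(0.5, 10.0, size=50)
        back = cs.wavelength_to_energy(cs.energy_to_wavelength(energies))
        np.testing.assert_allclose(back, energies, atol=1e-10)

    def test_non_positive_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.energy_to_wavelength(0.0)
        with pytest.raises(cs.ValidationError):
            cs.wavelength_to_energy(-300.0)

    def test_all_printed_transition_rows_consistent(self):
        """Every printed (energy, wavelength) pair satisfies the hc
        conversion to the printed 2-decimal precision."""
        df = cs.load_transitions()
        for _, row in df.iterrows():
            derived = round(HC_EV_NM / row["energy_ev"], 2)
            assert abs(derived - row["wavelength_nm"]) <= 0.01 + 1e-9


class TestBroadenTransitions:
    def test_single_transition_height_and_fwhm(self):
        config = cs.BroadeningConfig(
            grid_min_nm=250, grid_max_nm=400, grid_step_nm=0.05
        )
        transition = cs.Transition(1, 4.0, 0.5)
        spectrum = cs.broaden_transitions([transition], config)
        peak_index = int(np.argmax(spectrum.intensity))
        assert spectrum.intensity[peak_index] == pytest.approx(0.5, abs=1e-4)
        peak_energy = HC_EV_NM / spectrum.grid[peak_index]
        assert peak_energy == pytest.approx(4.0, abs=0.005)
        # half maximum sits FWHM/2 away on the energy axis
        energies = HC_EV_NM / spectrum.grid
        half = 0.5 / 2
        for target in (4.0 - 0.125, 4.0 + 0.125):
            nearest = np.argmin(np.abs(energies - target))
            assert spectrum.intensity[nearest] == pytest.approx(half, abs=2e-3)

    def test_linear_in_transition_list(self):
        transition = cs.Transition(1, 4.5, 0.3)
        single = cs.broaden_transitions([transition])
        double = cs.broaden_transitions([transition, transition])
        np.testing.assert_allclose(double.intensity, 2.0 * single.intensity)

    def test_empty_list_gives_zero_spectrum(self):
        spectrum = cs.broaden_transitions([])
        assert len(spectrum) == 151
        assert np.all(spectrum.intensity == 0.0)

    def test_strongest_band_position_against_dense_grid_oracle(
        self, ethanol_ensemble
    ):
        """On a dense grid, the global maximum of conformer 1's broadened
        spectrum falls at the strongest (203.71 nm) transition's position."""
        transitions = ethanol_ensemble.conformer(1).transitions
        config = cs.BroadeningConfig(
            grid_min_nm=200, grid_max_nm=500, grid_step_nm=0.02
        )
        spectrum = cs.broaden_transitions(transitions, config)
        # independent dense evaluation on the energy axis
        energies = np.arange(2.0, 6.5, 0.001)
        sigma = 0.25 / (2 * math.sqrt(2 * math.log(2)))
        dense = np.zeros_like(energies)
        for t in transitions:
            dense += t.oscillator_strength * np.exp(
                -((energies - t.energy_ev) ** 2) / (2 * sigma**2)
            )
        oracle_nm = HC_EV_NM / energies[np.argmax(dense)]
        found_nm = spectrum.grid[np.argmax(spectrum.intensity)]
        assert abs(found_nm - oracle_nm) <= 0.02 + 1e-9
        assert abs(found_nm - 203.71) < 0.5

    def test_band_area_conserves_total_oscillator_strength(
        self, ethanol_ensemble
    ):
        """Integrated intensity on a fine energy grid equals
        sum(f) * sigma * sqrt(2 pi) within 0.1%."""
        transitions = ethanol_ensemble.conformer(4).transitions
        sigma = 0.25 / (2 * math.sqrt(2 * math.log(2)))
        energies = np.arange(1.0, 12.0, 0.001)
        profile = np.zeros_like(energies)
        for t in transitions:
            profile += t.oscillator_strength * np.exp(
                -((energies - t.energy_ev) ** 2) / (2 * sigma**2)
            )
        area = np.trapezoid(profile, energies)
        expected = sum(t.oscillator_strength for t in transitions) * sigma * math.sqrt(
            2 * math.pi
        )
        assert abs(area - expected) / expected < 1e-3


class TestEnsembleSpectrum:
    @staticmethod
    def spectra_pair():
        grid = np.arange(200.0, 300.0, 2.0)
        a = cs.Spectrum("wavelength_nm", grid, np.ones_like(grid))
        b = cs.Spectrum("wavelength_nm", grid, 2.0 * np.ones_like(grid))
        return a, b

    def test_delta_weights_pass_through(self):
        a, b = self.spectra_pair()
        out = cs.ensemble_spectrum({1: a, 2: b}, {1: 1.0, 2: 0.0})
        np.testing.assert_allclose(out.intensity, a.intensity)

    def test_identical_inputs_any_weights(self):
        a, _ = self.spectra_pair()
        out = cs.ensemble_spectrum({1: a, 2: a}, {1: 0.3, 2: 0.7})
        np.testing.assert_allclose(out.intensity, a.intensity)

    def test_against_pointwise_sum_oracle(self, rng):
        grid = np.arange(200.0, 300.0, 2.0)
        spectra = {
            i: cs.Spectrum("wavelength_nm", grid, rng.random(grid.size))
            for i in range(4)
        }
        weights = {i: w for i, w in enumerate(rng.random(4))}
        out = cs.ensemble_spectrum(spectra, weights)
        expected = sum(weights[i] * spectra[i].intensity for i in range(4))
        np.testing.assert_allclose(out.intensity, expected, atol=1e-12)

    def test_convex_combination_bounds(self, rng):
        grid = np.arange(200.0, 300.0, 2.0)
        spectra = {
            i: cs.Spectrum("wavelength_nm", grid, rng.random(grid.size))
            for i in range(3)
        }
        raw = rng.random(3)
        weights = dict(enumerate(raw / raw.sum()))
        out = cs.ensemble_spectrum(spectra, weights)
        low = np.min([s.intensity for s in spectra.values()], axis=0)
        high = np.max([s.intensity for s in spectra.values()], axis=0)
        assert np.all(out.intensity >= low - 1e-12)
        assert np.all(out.intensity <= high + 1e-12)

    def test_grid_mismatch_rejected(self):
        a, _ = self.spectra_pair()
        other = cs.Spectrum(
            "wavelength_nm", np.arange(210.0, 310.0, 2.0), np.ones(50)
        )
        with pytest.raises(cs.ValidationError, match="grid"):
            cs.ensemble_spectrum({1: a, 2: other}, {1: 0.5, 2: 0.5})

    def test_full_pipeline_deterministic(self, ethanol_ensemble):
        first = cs.simulate_ensemble_spectrum(ethanol_ensemble)
        second = cs.simulate_ensemble_spectrum(ethanol_ensemble)
        assert np.array_equal(first.intensity, second.intensity)


class TestTransmissionToAbsorbance:
    @pytest.mark.parametrize("t, a", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decades(self, t, a):
        assert cs.transmission_to_absorbance(t) == pytest.approx(a)

    def test_non_positive_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.transmission_to_absorbance(0.0)

    def test_above_one_clipped_or_rejected(self):
        assert cs.transmission_to_absorbance(1.02) == 0.0
        with pytest.raises(cs.ValidationError):
            cs.transmission_to_absorbance(1.02, clip=False)


class TestNormalizeSpectrum:
    def test_constant_spectrum(self):
        grid = np.arange(200.0, 300.0, 2.0)
        spec = cs.Spectrum("wavelength_nm", grid, 5.0 * np.ones_like(grid))
        out = cs.normalize_spectrum(spec)
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_idempotent(self, rng):
        grid = np.arange(200.0, 300.0, 2.0)
        spec = cs.Spectrum("wavelength_nm", grid, rng.random(grid.size) + 0.1)
        once = cs.normalize_spectrum(spec, window=(260, 290))
        twice = cs.normalize_spectrum(once, window=(260, 290))
        np.testing.assert_allclose(twice.intensity, once.intensity)
        inside = (grid >= 260) & (grid <= 290)
        assert once.intensity[inside].max() == 1.0

    def test_all_zero_window_rejected(self):
        grid = np.arange(200.0, 300.0, 2.0)
        intensity = np.where(grid < 250, 1.0, 0.0)
        spec = cs.Spectrum("wavelength_nm", grid, intensity)
        with pytest.raises(cs.ValidationError):
            cs.normalize_spectrum(spec, window=(260, 290))


class TestSubtractBackground:
    def test_background_equals_sample(self, rng):
        grid = np.arange(200.0, 300.0, 2.0)
        spec = cs.Spectrum("wavelength_nm", grid, rng.random(grid.size))
        out = cs.subtract_background(spec, spec)
        assert np.all(out.intensity == 0.0)

    def test_zero_background_is_identity(self, rng):
        grid = np.arange(200.0, 300.0, 2.0)
        spec = cs.Spectrum("wavelength_nm", grid, rng.random(grid.size))
        zero = cs.Spectrum("wavelength_nm", grid, np.zeros_like(grid))
        out = cs.subtract_background(spec, zero)
        np.testing.assert_array_equal(out.intensity, spec.intensity)
        assert out.metadata["floored_points"] == 0

    def test_flooring_is_counted(self):
        grid = np.arange(200.0, 210.0, 2.0)
        sample = cs.Spectrum("wavelength_nm", grid, np.array([1, 0, 2, 0, 1.0]))
        background = cs.Spectrum(
            "wavelength_nm", grid, np.array([0, 1, 1, 1, 0.0])
        )
        out = cs.subtract_background(sample, background)
        np.testing.assert_array_equal(out.intensity, [1, 0, 1, 0, 1.0])
        assert out.metadata["floored_points"] == 2


class TestReportExtrema:
    @staticmethod
    def gaussian_sum(amplitudes, centers_nm, fwhm_ev=0.25):
        grid = np.arange(200.0, 500.1, 2.0)
        energies = HC_EV_NM / grid
        sigma = fwhm_ev / (2 * math.sqrt(2 * math.log(2)))
        intensity = np.zeros_like(grid)
        for amp, center in zip(amplitudes, centers_nm):
            e0 = HC_EV_NM / center
            intensity += amp * np.exp(-((energies - e0) ** 2) / (2 * sigma**2))
        return cs.Spectrum("wavelength_nm", grid, intensity)

    def test_single_band_single_maximum(self):
        spec = self.gaussian_sum([1.0], [292.0])
        features = cs.report_extrema(spec)
        maxima = [f for f in features if f.kind == "maximum"]
        assert len(maxima) == 1
        assert abs(maxima[0].position - 292.0) <= 2.0
        assert not [f for f in features if f.kind == "shoulder"]

    def test_resolved_pair_at_default_width(self):
        """At 0.25 eV FWHM the 292/319 nm pair (4:1) is separated by about
        3.4 sigma and resolves into two maxima (dense-grid derivative
        analysis confirms no shoulder)."""
        spec = self.gaussian_sum([0.4, 0.1], [292.0, 319.0])
        features = cs.report_extrema(spec)
        positions = sorted(f.position for f in features if f.kind == "maximum")
        assert len(positions) == 2
        assert abs(positions[0] - 292.0) <= 4.0
        assert abs(positions[1] - 319.0) <= 4.0

    def test_shoulder_on_broader_bands(self):
        """With 0.35 eV FWHM the weak 319 nm band no longer turns over and
        appears as a flank shoulder near its position."""
        spec = self.gaussian_sum([0.4, 0.1], [292.0, 319.0], fwhm_ev=0.35)
        features = cs.report_extrema(spec)
        maxima = [f for f in features if f.kind == "maximum"]
        shoulders = [f for f in features if f.kind == "shoulder"]
        assert len(maxima) == 1 and abs(maxima[0].position - 292.0) <= 4.0
        assert len(shoulders) == 1 and abs(shoulders[0].position - 319.0) <= 4.0

    def test_monotone_spectrum_reports_nothing(self):
        grid = np.arange(200.0, 300.0, 2.0)
        spec = cs.Spectrum("wavelength_nm", grid, np.linspace(0, 1, grid.size))
        assert cs.report_extrema(spec) == []

    def test_too_few_points_rejected(self):
        spec = cs.Spectrum(
            "wavelength_nm", np.array([1.0, 2, 3, 4]), np.zeros(4)
        )
        with pytest.raises(cs.ValidationError):
            cs.report_extrema(spec)
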