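import numpy as np
import pytest

import confspect as cs


@pytest.fixture(scope="session")
def dmso_ensemble():
    return cs.reference_ensemble("DMSO")


@pytest.fixture(scope="session")
def ethanol_ensemble():
    return cs.reference_ensemble("ethanol")


@pytest.fixture(scope="session")
def carbon_shift_map():
    return cs.theoretical_shift_map("13C")


@pytest.fixture(scope="session")
def carbon_peaks():
    return cs.experimental_peaks("13C")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ensemble():
    """Two-conformer ensemble with geometry, shieldings and transitions."""
    atoms = (
        cs.AtomSite(1, "C", (0.0, 0.0, 0.0)),
        cs.AtomSite(2, "O", (1.2, 0.0, 0.0)),
        cs.AtomSite(3, "H", (-0.6, 0.9, 0.0)),
    )
    shieldings = (
        cs.ShieldingTensor(1, np.array([[130.0, 1.0, 0.0],
                                        [0.5, 135.0, -0.3],
                                        [0.0, 0.2, 140.0]])),
    )
    transitions = (
        cs.Transition(state_index=1, energy_ev=4.0, oscillator_strength=0.3),
    )
    conformers = tuple(
        cs.ConformerRecord(
            id=i,
            solvent="DMSO",
            total_energy_ha=-100.0 + 0.001 * i,
            geometry=atoms,
            shieldings=shieldings,
            transitions=transitions,
        )
        for i in (1, 2)
    )
    return cs.Ensemble(
        molecule_name="toy",
        conformers=conformers,
        references={"13C": 184.32, "1H": 31.96},
    )
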