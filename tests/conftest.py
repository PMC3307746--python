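import pytest

from repquant.registry import default_registry
from repquant.simulate import (
    ImageSimConfig,
    SpectraSimConfig,
    simulate_fields,
    simulate_spectra,
)
from repquant.spectra import process_peak_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_spectra():
    """Compact simulated cohort: 2 GF + 2 colonised animals x 3 tissues."""
    return simulate_spectra(SpectraSimConfig(seed=7, n_animals_per_status=2))


@pytest.fixture(scope="session")
def small_matrix(small_spectra):
    return process_peak_table(
        small_spectra.peaks, small_spectra.registry, small_spectra.metadata
    )


@pytest.fixture(scope="session")
def small_images():
    """Compact image cohort: 2 animals/status x 2 fields, 128 px square."""
    return simulate_fields(
        ImageSimConfig(
            seed=7, n_fields_per_animal=2, n_animals_per_status=2, shape=(128, 128)
        )
    )
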