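import numpy as np
import pytest

from somvnir.datatypes import SoilDataset, SpectraSet


@pytest.fixture
def toy_spectra():
    """6 bands x 5 samples of positive reflectance, seeded."""
    rng = np.random.default_rng(42)
    wl = np.array([500.0, 600.0, 700.0, 800.0, 900.0, 1000.0])
    refl = rng.uniform(0.1, 0.9, size=(5, 6))
    return SpectraSet(wavelengths=wl, reflectance=refl)


@pytest.fixture
def toy_dataset(toy_spectra):
    rng = np.random.default_rng(7)
    som = rng.uniform(1.0, 40.0, size=toy_spectra.n_samples)
    return SoilDataset(som=som, spectra=toy_spectra)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic survey (168 samples, 1 nm grid), reused."""
    from somvnir.synthetic import generate_dataset

    return generate_dataset(seed=11)


@pytest.fixture(scope="session")
def preprocessed_default(default_dataset):
    """The default survey after the standard trim/downsample/smooth chain."""
    from somvnir.preprocess import preprocess_pipeline

    return preprocess_pipeline(default_dataset.spectra)
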