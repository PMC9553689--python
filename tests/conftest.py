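import numpy as np
import pandas as pd
import pytest

from nutspec import synthetic as syn


@pytest.fixture(scope="session")
def noise_free_dataset():
    """40 synthetic samples with exactly linear (noise-free) spectra."""
    spec = syn.SyntheticDatasetSpec(
        n_samples=40, composition_ranges=syn.STUDY_COMPOSITION_RANGES, seed=101
    )
    comps = syn.generate_compositions(spec)
    spectra = syn.generate_nir_spectra(comps, noise=syn.NOISE_FREE)
    return comps, spectra


@pytest.fixture(scope="session")
def small_full_rank_problem():
    """A small n > p regression problem where OLS is the exact answer."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 5))
    beta = np.array([1.5, -2.0, 0.3, 0.0, 4.0])
    y = X @ beta + 3.0 + rng.normal(0, 0.1, 20)
    return X, y


@pytest.fixture
def toy_spectra():
    from nutspec.containers import SpectraSet

    wl = np.arange(900.0, 1000.0, 10.0)
    rng = np.random.default_rng(0)
    return SpectraSet(wl, rng.normal(size=(4, wl.size)), ["a", "a", "b", "c"])
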