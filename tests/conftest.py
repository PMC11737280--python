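"""Shared fixtures: synthetic panels, processed spectra, reference databases."""

from __future__ import annotations

import numpy as np
import pytest

from maldicci.preprocess import PreprocessConfig, ProcessedSpectrum, preprocess_dataset
from maldicci.refdb import build_database
from maldicci.synthetic import GeneratorConfig, generate_panels


@pytest.fixture(scope="session")
def small_gen_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_species=3,
        specimens_per_species=2,
        spots_per_specimen=3,
        test_specimens_per_species=1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panels(small_gen_config):
    return generate_panels(small_gen_config)


@pytest.fixture(scope="session")
def preprocess_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def processed_panels(small_panels, preprocess_config):
    ref, ref_meta, test, test_meta = small_panels
    return (
        preprocess_dataset(ref, preprocess_config),
        ref_meta,
        preprocess_dataset(test, preprocess_config),
        test_meta,
    )


@pytest.fixture(scope="session")
def small_db(processed_panels):
    pref, ref_meta, _, _ = processed_panels
    return build_database(pref, ref_meta)


def make_processed(intensity: np.ndarray, spectrum_id: str = "s",
                   grid_min: float = 2000.0, step: float = 1.0) -> ProcessedSpectrum:
    """Wrap a bare intensity trace as a ProcessedSpectrum on a uniform grid."""
    grid = grid_min + step * np.arange(intensity.size)
    return ProcessedSpectrum(grid_mz=grid, intensity=intensity, spectrum_id=spectrum_id)


@pytest.fixture(scope="session")
def random_processed_pair_factory():
    """Factory for random positive spectra on the full default grid."""

    def factory(seed: int, n: int = 18001):
        rng = np.random.default_rng(seed)
        a = rng.random(n) + 0.01
        b = rng.random(n) + 0.01
        return make_processed(a / a.sum(), f"a{seed}"), make_processed(b / b.sum(), f"b{seed}")

    return factory
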