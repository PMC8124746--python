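import numpy as np
import pytest

from shrubspec import (SpectralLibrary, Spectrum, TransectConfig, WavelengthGrid,
                       generate_scene)


@pytest.fixture(scope="session")
def default_grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def tiny_grid():
    return WavelengthGrid(350.0, 359.0, 1.0)  # 10 points


def make_spectrum(grid, reflectance, quadrat="Q0", season="spring",
                  replicate=1, sample_id=None, mask=None):
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.ndim == 0:
        reflectance = np.full(len(grid), float(reflectance))
    return Spectrum(
        grid=grid, reflectance=reflectance, valid_mask=mask,
        sample_id=sample_id or f"{quadrat}_{season}_r{replicate}",
        quadrat_id=quadrat, season=season, replicate=replicate)


@pytest.fixture
def spectrum_factory(tiny_grid):
    def _make(reflectance, **kw):
        return make_spectrum(kw.pop("grid", tiny_grid), reflectance, **kw)
    return _make


@pytest.fixture(scope="session")
def default_scene():
    """One full-size transect scene at the study-condition defaults."""
    return generate_scene(TransectConfig(seed=42))


@pytest.fixture(scope="session")
def small_scene():
    """A short transect (32 quadrats) for fast pipeline-level tests."""
    return generate_scene(TransectConfig(length_m=93.0, seed=7))


@pytest.fixture
def blob_matrix():
    """Well-separated spherical blobs of 'spectra' for clustering tests.

    Separation is 20x the within-blob SD, so cluster recovery is
    unambiguous.
    """
    def _make(n_blobs, n_per_blob=20, n_features=25, sep=20.0, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_blobs, n_features))
        centers = centers / np.linalg.norm(centers, axis=1, keepdims=True)
        centers = centers * sep * sd * np.arange(1, n_blobs + 1)[:, None]
        X = np.concatenate([
            c + rng.normal(scale=sd, size=(n_per_blob, n_features))
            for c in centers])
        labels = np.repeat(np.arange(n_blobs), n_per_blob)
        return X, labels
    return _make
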