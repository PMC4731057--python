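"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import maldimix as mm

warnings.filterwarnings("ignore", message="Objective did not converge")


def fractions_to_designs(fractions, total=1_000_000):
    return tuple(
        (total - round(f / 100.0 * total), round(f / 100.0 * total))
        for f in fractions
    )


SMALL_FRACTIONS = (0.0, 1, 2, 5, 10, 20, 40, 60, 80, 100.0)


@pytest.fixture(scope="session")
def linear_dataset():
    """Noiseless, exactly linear two-component dataset (10 designs x 2
    technical replicates, total 1e6 cells)."""
    gen = mm.GeneratorConfig(
        designs=fractions_to_designs(SMALL_FRACTIONS), replicates=2, seed=1
    ).linear()
    spectra, manifest, truth = mm.generate_spectra(gen)
    return gen, spectra, manifest, truth


@pytest.fixture(scope="session")
def linear_selected(linear_dataset):
    """Linear dataset preprocessed and reduced to a 10-peak panel."""
    _, spectra, manifest, _ = linear_dataset
    cfg = mm.PipelineConfig(seed=1, panel_size=10)
    prep = mm.preprocess_dataset(spectra, manifest, cfg)
    y = manifest.y_contaminant
    panel, sel = mm.select_panel(prep.matrix, y, cfg)
    return sel, y, panel, prep


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small default-noise dataset (11 designs x 3 replicates)."""
    fracs = (0.0, 1, 2, 5, 10, 20, 35, 50, 70, 90, 100.0)
    gen = mm.GeneratorConfig(
        designs=fractions_to_designs(fracs), replicates=3, seed=2
    )
    spectra, manifest, truth = mm.generate_spectra(gen)
    return gen, spectra, manifest, truth


@pytest.fixture(scope="session")
def noisy_selected(noisy_dataset):
    _, spectra, manifest, _ = noisy_dataset
    cfg = mm.PipelineConfig(seed=2, panel_size=10)
    prep = mm.preprocess_dataset(spectra, manifest, cfg)
    y = manifest.y_contaminant
    panel, sel = mm.select_panel(prep.matrix, y, cfg)
    return sel, y, panel, prep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
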