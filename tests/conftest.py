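import numpy as np
import pytest

from mgba import genosim, phenosim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """200 samples x 20 SNPs with moderate LD."""
    return genosim.generate_region(200, 20, 0.6, seed=42)


@pytest.fixture(scope="session")
def big_panel():
    """2000 samples x 60 SNPs, strong LD (the study's region geometry)."""
    return genosim.generate_region(2000, 60, 0.9, seed=7)


@pytest.fixture(scope="session")
def factor_model_mid():
    """Unit-variance exchangeable factor model with r = 0.57."""
    return phenosim.FactorModel.from_correlation(0.57)


def panel_from_dosages(dosages, positions=None):
    """Build a GenotypePanel from a literal dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    if positions is None:
        positions = np.arange(1, dosages.shape[1] + 1) * 100
    return genosim.GenotypePanel.from_dosages(dosages, positions)
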