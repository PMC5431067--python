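"""Shared fixtures: the default synthetic dataset and derived objects.

Session-scoped because generation and the EOS fit are reused by many
tests; everything is seeded, so sharing does not couple test outcomes.
"""

import numpy as np
import pytest
from hypothesis import settings

import glassdyn as gd

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return gd.default_tdz_config()


@pytest.fixture(scope="session")
def dataset(truth):
    """Default ternidazole-like dataset: 4 isobars + 4 isotherms, seeded."""
    return gd.generate_dataset(truth, include_spectra=False)


@pytest.fixture(scope="session")
def dataset_with_spectra(truth):
    return gd.generate_dataset(truth, include_spectra=True)


@pytest.fixture(scope="session")
def relax_map(dataset):
    return dataset.relaxation_map


@pytest.fixture(scope="session")
def tait_fit(dataset):
    """Tait EOS fitted to the dataset's own PVT table."""
    return gd.fit_tait(dataset.pvt)


@pytest.fixture(scope="session")
def isobar_vft_fits(relax_map):
    """Per-isobar VFT fits of the supercooled-liquid α relaxation times."""
    alpha = relax_map[(relax_map.process == "alpha")
                      & (relax_map.tau_s <= gd.TAU_GLASS)]
    fits = []
    for P, g in alpha.groupby("P_MPa"):
        if g.T_K.nunique() >= 5:
            fits.append((float(P), gd.fit_vft(g.T_K, g.tau_s)))
    return fits


@pytest.fixture(scope="session")
def noiseless_map():
    """Same grid and ground truth as the default dataset, zero noise."""
    cfg = gd.default_tdz_config(tau_log_noise=0.0, spectrum_noise=0.0)
    return gd.generate_dataset(cfg, include_spectra=False).relaxation_map


def make_spectrum(model, f_lo=1e-2, f_hi=1e9, n=89, noise=0.0, seed=0,
                  T=np.nan, P=np.nan):
    """Evaluate a SpectrumModel on a log grid, optionally with 2%-style
    multiplicative log-normal noise."""
    f = np.geomspace(f_lo, f_hi, n)
    _, eps2 = gd.eval_spectrum(model, f)
    if noise > 0:
        rng = np.random.default_rng(seed)
        eps2 = eps2 * np.exp(noise * rng.standard_normal(eps2.shape))
    return gd.SpectrumRecord(T=T, P=P, f=f, eps2=eps2)
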