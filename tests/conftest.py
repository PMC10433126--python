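"""Shared fixtures: analytic Gaussian profile tables and fitted models.

Session-scoped because fitting a collimator model is the most expensive
setup step and the models are immutable.
"""

import numpy as np
import pytest

from bed3d.profiles import DoseProfileTable, build_radial_profile
from bed3d.synth import default_profile_spec, gen_profile_tables

SIGMA = 3.0  # mm; FWHM = 2*sigma*sqrt(2 ln 2) = 7.0644 mm
GAUSS_FWHM = 2.0 * SIGMA * np.sqrt(2.0 * np.log(2.0))


def gaussian_table(axis: str, sigma: float = SIGMA, label: int = 4,
                   spacing: float = 0.25, noise_sd: float = 0.0,
                   seed: int = 0) -> DoseProfileTable:
    """Pure-Gaussian falloff table exp(-t^2 / (2 sigma^2))."""
    ext = 4.2 * sigma
    m = int(np.ceil(ext / spacing))
    t = spacing * np.arange(-m, m + 1)
    y = np.exp(-(t**2) / (2.0 * sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, 1.05)
        y[m] = 1.0
    return DoseProfileTable(collimator_label=label, axis=axis,
                            offsets_mm=t, rel_dose=y)


def gaussian_table_fwhm(axis: str, fwhm: float, **kw) -> DoseProfileTable:
    return gaussian_table(axis, sigma=fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))), **kw)


@pytest.fixture(scope="session")
def isotropic_model():
    """Collimator model fitted to three identical sigma=3 Gaussian axes."""
    tables = {a: gaussian_table(a) for a in "xyz"}
    return build_radial_profile(tables)


@pytest.fixture(scope="session")
def aniso_model():
    """Collimator model with Gaussian axes of FWHM (6, 6, 5) mm."""
    tables = {a: gaussian_table_fwhm(a, f)
              for a, f in zip("xyz", (6.0, 6.0, 5.0))}
    return build_radial_profile(tables)


@pytest.fixture(scope="session")
def broad_model():
    """Smooth, wide Gaussian model (sigma = 8 mm) for refinement checks."""
    tables = {a: gaussian_table(a, sigma=8.0, label=18) for a in "xyz"}
    return build_radial_profile(tables)


@pytest.fixture(scope="session")
def model_4mm():
    """Fitted model for the synthetic (flat-shouldered) 4 mm collimator."""
    spec = default_profile_spec(4, seed=11)
    return build_radial_profile(gen_profile_tables(spec))


@pytest.fixture(scope="session")
def all_models():
    """Fitted models for all four collimators (noiseless fixtures)."""
    models = {}
    for k, label in enumerate((4, 8, 14, 18)):
        spec = default_profile_spec(label, seed=20 + k)
        models[label] = build_radial_profile(gen_profile_tables(spec))
    return models
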