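"""Shared fixtures: small synthetic studies on a coarse wavenumber grid.

Tests run on a 16 cm^-1 grid (226 points) rather than the production
2 cm^-1 grid; every operator under test is resolution-agnostic.
"""

import numpy as np
import pytest

from voctrace import gcms, prep, synthetic

COARSE = synthetic.default_grid(16.0)


@pytest.fixture(scope="session")
def default_cfg():
    return synthetic.SyntheticConfig(n_per_class=20, wavenumber_grid=COARSE, seed=0)


@pytest.fixture(scope="session")
def voc_table(default_cfg):
    return synthetic.make_voc_table(default_cfg)


@pytest.fixture(scope="session")
def conc_table(default_cfg, voc_table):
    istd = gcms.InternalStandard(
        v_s=default_cfg.istd_volume_ul,
        c_s=default_cfg.istd_conc_ug_ml,
        mass_g=default_cfg.sample_mass_g,
        i_s=default_cfg.istd_area,
    )
    return gcms.quantify(voc_table, istd)


@pytest.fixture(scope="session")
def spectra(default_cfg, voc_table):
    return synthetic.make_spectra(default_cfg, voc_table)


@pytest.fixture(scope="session")
def separated_spectra():
    """Well-separated three-class spectra for classifier checks."""
    cfg = synthetic.well_separated_config(seed=0, n_per_class=20, wavenumber_grid=COARSE)
    voc = synthetic.make_voc_table(cfg)
    return synthetic.make_spectra(cfg, voc)


@pytest.fixture(scope="session")
def deriv_features(separated_spectra):
    """First-derivative feature matrix + labels of the separated cohort."""
    pp = prep.preprocess(prep.average_replicates(separated_spectra), "1stDer")
    return pp.absorbance, pp.sample_labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
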