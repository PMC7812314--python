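import numpy as np
import pytest

from maldimatch.synthdata import SimConfig, generate_ims_dataset, generate_lcms_table


def small_config(**overrides) -> SimConfig:
    """A desk-sized two-region scenario used across the unit tests."""
    base = dict(
        n_proteins=150,
        grid_shape=(16, 16),
        n_regions=2,
        n_ims_peptides=40,
        n_decoys_per_ims_peptide=2,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    table, truth = generate_lcms_table(cfg)
    ds = generate_ims_dataset(cfg, truth)
    return cfg, table, truth, ds


@pytest.fixture(scope="session")
def noise_free_sim():
    cfg = small_config(
        mass_error_sd=0.0,
        ims_mult_sigma=0.0,
        ims_gain_sigma=0.0,
        ims_texture_sigma=0.0,
        noise_peaks_per_pixel=0,
        missing_quantile=0.0,
        seed=11,
    )
    table, truth = generate_lcms_table(cfg)
    ds = generate_ims_dataset(cfg, truth)
    return cfg, table, truth, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
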