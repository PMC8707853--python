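import numpy as np
import pytest
from hypothesis import settings

import nircalib as nc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    """The study layout: 89 samples x 6 replicates, 900-1698 nm at 6 nm."""
    return nc.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """(refs, replicate spectra, per-sample averaged spectra) at the default seed."""
    rng = np.random.default_rng(default_config.seed)
    refs = nc.generate_reference(default_config, rng)
    spectra = nc.generate_spectra(default_config, refs, rng)
    avg = nc.average_replicates(spectra)
    return refs, spectra, avg


@pytest.fixture(scope="session")
def noiseless_config():
    return nc.SyntheticConfig(seed=3, baseline_offset_sd=0.0, baseline_slope_sd=0.0,
                              scatter_slope_sd=0.0, replicate_noise_sd=0.0,
                              channel_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    rng = np.random.default_rng(noiseless_config.seed)
    refs = nc.generate_reference(noiseless_config, rng)
    spectra = nc.generate_spectra(noiseless_config, refs, rng)
    return refs, spectra, nc.average_replicates(spectra)


def subset(avg: "nc.SpectraSet", ids):
    """Row-subset of an averaged SpectraSet by sample id."""
    idx = [avg.sample_ids.index(i) for i in ids]
    return nc.SpectraSet(
        avg.wavelengths, avg.values[idx], [avg.sample_ids[i] for i in idx],
        mode=avg.mode,
        cultivars=None if avg.cultivars is None else [avg.cultivars[i] for i in idx])
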