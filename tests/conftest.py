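import warnings

import numpy as np
import pytest

import eigenphase as ep


@pytest.fixture(autouse=True)
def _quiet_contrast_warnings():
    # random test matrices legitimately trip the empirical-contrast check
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="sample-eigenvector contrast")
        yield


@pytest.fixture(scope="session")
def truth():
    """Default synthetic study: three omics, planted lags (0, -0.05, +0.22) h."""
    return ep.generate_truth(seed=11)


@pytest.fixture(scope="session")
def noiseless_truth():
    t = ep.generate_truth(seed=11)
    for spec in t.omics.values():
        spec.sigma = 0.0
    return t


@pytest.fixture(scope="session")
def transcriptome(truth):
    return ep.simulate_omics(truth, "transcriptome")


@pytest.fixture(scope="session")
def transcriptome_dec(transcriptome):
    return ep.stratify(transcriptome)


def small_matrix(seed=0, m=10, n=5):
    rng = np.random.default_rng(seed)
    return ep.OmicsMatrix(
        values=rng.normal(5.0, 1.0, (m, n)),
        molecule_ids=[f"g{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(n)],
        sample_times=np.arange(n, dtype=float),
        omics_label="test",
    )
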