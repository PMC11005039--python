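import numpy as np
import pytest

from aldock.oracle import SyntheticOracleSpec, make_synthetic_library


@pytest.fixture(scope="session")
def noiseless_library():
    """Small well-specified instance: linear ground truth, no noise."""
    spec = SyntheticOracleSpec(n_ligands=5000, n_bits=64, seed=11)
    return make_synthetic_library(spec)


@pytest.fixture(scope="session")
def noisy_library():
    """Same scale with noise variance equal to signal variance."""
    spec = SyntheticOracleSpec(n_ligands=5000, n_bits=64, noise_to_signal=1.0, seed=11)
    return make_synthetic_library(spec)


@pytest.fixture()
def score_table(tmp_path):
    path = tmp_path / "scores.csv"
    path.write_text(
        "id,smiles,score\n"
        "mol-a,CCO,-42.1\n"
        "mol-b,CCN,-7.0\n"
        "mol-c,CCC,-55.3\n"
    )
    return path


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
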