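import numpy as np
import pandas as pd
import pytest

from mixpurify import ReferenceProfile, generate_pure_profiles
from mixpurify.simulate import counts_to_tpm_unit_length


@pytest.fixture(scope="session")
def pure_profiles():
    """Synthetic 500-gene, 3-cell-type pure count profiles (4 samples each)."""
    counts, assignment = generate_pure_profiles(seed=11)
    return counts, assignment


@pytest.fixture(scope="session")
def pure_tpm(pure_profiles):
    counts, assignment = pure_profiles
    tpm = {
        s: counts_to_tpm_unit_length(counts.values[s])
        for s in counts.sample_ids
    }
    return tpm, assignment


@pytest.fixture(scope="session")
def reference_pair(pure_tpm):
    """One tumor and one TAM reference profile sharing a gene universe."""
    tpm, _ = pure_tpm
    return (
        ReferenceProfile("tumor", tpm["tumor_1"]),
        ReferenceProfile("tam", tpm["tam_1"]),
    )


def make_tpm_series(values, genes=None):
    """Build a TPM vector summing to 1e6 from arbitrary non-negative weights."""
    arr = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(len(arr))]
    s = pd.Series(arr, index=genes)
    return s / s.sum() * 1e6
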