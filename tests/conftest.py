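import numpy as np
import pandas as pd
import pytest

from herdstat.genio import GenotypeMatrix, HaplotypePanel


def make_gm(calls, populations=None, chroms=None, positions=None):
    """Build a small GenotypeMatrix from a genotype array (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pops = populations or ["p1"] * n
    samples = pd.DataFrame({
        "id": [f"a{i}" for i in range(n)], "population": pops,
    })
    snps = pd.DataFrame({
        "chrom": chroms or ["1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m, "alt": ["C"] * m,
    })
    return GenotypeMatrix(samples, snps, calls)


def make_panel(hap_calls, populations=None, chroms=None, positions=None):
    """Build a HaplotypePanel from a (2n, m) 0/1 array."""
    hap_calls = np.asarray(hap_calls, dtype=np.int8)
    n2, m = hap_calls.shape
    assert n2 % 2 == 0
    n = n2 // 2
    pops = populations or ["p1"] * n
    samples = pd.DataFrame({
        "id": [f"a{i}" for i in range(n)], "population": pops,
    })
    snps = pd.DataFrame({
        "chrom": chroms or ["1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m, "alt": ["C"] * m,
    })
    return HaplotypePanel(samples, snps, hap_calls)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
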