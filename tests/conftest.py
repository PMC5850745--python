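import numpy as np
import pytest

from coalabc.variant_io import GenotypeMatrix


def make_gm(
    calls,
    pops=None,
    pos=None,
    chrom=None,
    gq=None,
    dp=None,
    multiallelic=None,
):
    """Build a GenotypeMatrix from a plain dosage array (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_indiv = calls.shape
    if pops is None:
        half = n_indiv // 2
        pops = ["A"] * half + ["B"] * (n_indiv - half)
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if chrom is None:
        chrom = np.array(["chr1"] * n_sites, dtype=object)
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        calls=calls,
        sample_ids=[f"S{i}" for i in range(n_indiv)],
        pop_labels=list(pops),
        gq=None if gq is None else np.asarray(gq),
        dp=None if dp is None else np.asarray(dp),
        multiallelic=multiallelic,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_gm(rng, n_sites=30, n_indiv=10, miss_frac=0.0, pops=None):
    calls = rng.integers(0, 3, size=(n_sites, n_indiv)).astype(np.int8)
    if miss_frac > 0:
        mask = rng.random((n_sites, n_indiv)) < miss_frac
        calls[mask] = -1
    return make_gm(calls, pops=pops)
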