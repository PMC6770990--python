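"""Shared fixtures and independent oracles for the test suite."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genoprof.util import revcomp

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_kmer_hist(seqs, k):
    """Dictionary-of-strings canonical k-mer depth histogram; the
    independent oracle for the packed-integer counter."""
    counts = Counter()
    valid = set("ACGT")
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= valid:
                counts[min(w, revcomp(w))] += 1
    return dict(Counter(counts.values()))


def brute_force_nx(lengths, x):
    """Prefix-scan Nx oracle."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    cum = 0
    for v in ls:
        cum += v
        if cum >= x / 100.0 * total:
            return v
    return ls[-1]


def brute_force_l50(lengths):
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    cum = 0
    for i, v in enumerate(ls, 1):
        cum += v
        if cum >= total / 2:
            return i
    return len(ls)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_gene_set():
    """Synthetic contig + 20 annotated gene models with known defects."""
    from genoprof import synthesize_gene_set

    genome_seq, models, truth = synthesize_gene_set(seed=7)
    return genome_seq, models, truth
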