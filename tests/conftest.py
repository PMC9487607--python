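"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ampbench import seqdata, synthetic
from ampbench.seqdata import SequenceRecord


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(n_positive=150, n_background=6000,
                                     seed=42)


@pytest.fixture(scope="session")
def small_positives(small_cfg):
    return synthetic.generate_positives(small_cfg)


@pytest.fixture(scope="session")
def small_background(small_cfg):
    return synthetic.generate_background(small_cfg)


@pytest.fixture(scope="session")
def small_split(small_positives):
    reduced = seqdata.reduce_redundancy_positive(small_positives, 0.9)
    return seqdata.split_positive(reduced, 0.8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_peptides(rng, n, lo=8, hi=40):
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(list(seqdata.AMINO_ACIDS), size=L)))
    return out


@pytest.fixture
def toy_records():
    return [
        SequenceRecord("a", "KKLLKKWW", {"antimicrobial", "secreted"},
                       {"cytoplasm"}),
        SequenceRecord("b", "AAAAGGGGSSSS", {"transmembrane"}, set()),
        SequenceRecord("c", "DDEEKKRR", set(), {"secreted"}),
        SequenceRecord("d", "CCCCCCCC", {"toxin"}, {"mitochondria"}),
        SequenceRecord("e", "LLVVIIFFWW", set(), {"cytoplasm", "golgi"}),
    ]
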