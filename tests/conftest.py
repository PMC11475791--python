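import numpy as np
import pytest

from bovcdr3 import FilterConfig, default_motif_set
from bovcdr3.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def igm_motifs():
    return default_motif_set("IgM")


@pytest.fixture(scope="session")
def igg_motifs():
    return default_motif_set("IgG")


@pytest.fixture(scope="session")
def filter_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def clean_igg_batch():
    """300 error-free IgG reads with 50% orientation flips, plus truth."""
    cfg = SimConfig(
        n_reads=300, seed=20240917, isotype="IgG",
        substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
    )
    reads, manifest = generate(cfg)
    return cfg, reads, manifest


def brute_force_hits(seq: str, pattern: str, max_subs: int):
    """Independent oracle: Hamming distance at every offset."""
    m = len(pattern)
    hits = []
    for start in range(len(seq) - m + 1):
        window = seq[start:start + m]
        d = sum(1 for a, b in zip(window, pattern) if a != b)
        if d <= max_subs:
            hits.append((start, start + m, d))
    return hits


@pytest.fixture(scope="session")
def oracle():
    return brute_force_hits
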