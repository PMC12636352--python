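import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kprob.pan_io import PromoterRecord, PromoterSet
from kprob.simulate import simulate_expression, simulate_pangenome


@pytest.fixture
def tiny_promoters():
    return PromoterSet([
        PromoterRecord("pan001", "B73", "Zm001", "ACGTACGTAACC"),
        PromoterRecord("pan001", "Mo17", "Zm002", "ACGTACGTAACG"),
        PromoterRecord("pan002", "B73", "Zm003", "TTTTGGGGCCCC"),
    ])


@pytest.fixture(scope="session")
def small_fixture():
    """Small planted-motif pan-genome shared by several test modules."""
    promoters, truth = simulate_pangenome(
        n_pangenes=40, n_accessions=10, promoter_len=250,
        n_planted=2, motif_len=11, pangenes_per_motif=12, seed=101)
    expression = simulate_expression(promoters, truth, seed=102)
    return promoters, expression, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
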