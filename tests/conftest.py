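import numpy as np
import pytest

from recurdrift.synthetic_cohort import random_signature_matrix
from recurdrift.variant_filters import VariantRecord


@pytest.fixture(scope="session")
def sig3():
    """Small well-separated synthetic signature matrix (K=3)."""
    return random_signature_matrix(3, seed=11)


@pytest.fixture(scope="session")
def sig4():
    return random_signature_matrix(4, seed=7)


@pytest.fixture
def make_variant():
    """Factory for variant records with sensible defaults."""

    def _make(**kwargs):
        defaults = dict(
            chrom="chrA",
            pos=1000,
            ref="C",
            alt="T",
            alt_support_tumor=8,
            depth_tumor=30,
            context5="A",
            context3="G",
            impact="MODERATE",
            consequence="missense_variant",
        )
        defaults.update(kwargs)
        return VariantRecord(**defaults)

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
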