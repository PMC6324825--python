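"""Shared fixtures: small synthetic proteins, alignments and contexts.

Everything is generated programmatically at session start with fixed
seeds; no fixture files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from cdpred.coevolution import msa_couplings
from cdpred.features import ProteinFeatureContext
from cdpred.msa import Msa, compute_meff
from cdpred.synthetic import make_toy_protein, sample_coupled_msa


@pytest.fixture(scope="session")
def toy30():
    return make_toy_protein(L=30, seed=2)


@pytest.fixture(scope="session")
def msa30(toy30):
    return sample_coupled_msa(toy30, M=300, seed=3)


@pytest.fixture(scope="session")
def couplings30(msa30):
    return msa_couplings(msa30, tol=1e-3)


@pytest.fixture(scope="session")
def ctx30(toy30, msa30, couplings30):
    stats = compute_meff(msa30)
    return ProteinFeatureContext.build(
        msa30, stats, couplings30, toy30.ss, toy30.acc
    )


@pytest.fixture()
def tiny_msa():
    """4-row, hand-checkable alignment."""
    return Msa(
        query_id="q",
        rows=["ACDE", "ACDE", "AGDE", "TTTT"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
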