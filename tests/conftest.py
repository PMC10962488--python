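"""Shared fixtures.

The pretrained generator is expensive (~2 minutes on one CPU) and is shared
at session scope by the learning smoke test and the transfer-shift test.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import RDLogger

from moldesign.corpus import build_alphabet
from moldesign.fixtures import generate_smiles_corpus
from moldesign.generator import ConditionalSmilesVAE

RDLogger.DisableLog("rdApp.*")

#: architecture/schedule of the desk-scale ("smoke") generator profile
SMOKE_PROFILE = dict(
    embedding_dim=32,
    encoder_rnn_dim=64,
    encoder_rnn_layers=1,
    latent_dim=16,
    fpc_hidden_dims=(16, 16),
    decoder_rnn_dim=64,
    decoder_rnn_layers=1,
    fpc_rescale=True,
    kl_weight=0.02,
    base_lr=1e-3,
    batch_size=64,
    max_epochs=300,
    seed=3,
)


@pytest.fixture(scope="session")
def fixture_corpus() -> list[str]:
    """500 grammar-generated SMILES, ~10% carrying the sulfur marker."""
    return generate_smiles_corpus(500, seed=11)


@pytest.fixture(scope="session")
def marker_domain() -> list[str]:
    """80 molecules that all carry the sulfur marker fragment."""
    return generate_smiles_corpus(80, seed=12, marker_fraction=1.0)


@pytest.fixture(scope="session")
def smoke_model(fixture_corpus, marker_domain) -> ConditionalSmilesVAE:
    """Generator pretrained on the fixture corpus with the smoke profile.

    The alphabet covers the marker domain too, so transfer runs can reuse it.
    """
    alphabet = build_alphabet([fixture_corpus, marker_domain])
    model = ConditionalSmilesVAE(**SMOKE_PROFILE)
    model.fit(fixture_corpus, alphabet=alphabet)
    return model


@pytest.fixture(scope="session")
def tiny_model() -> ConditionalSmilesVAE:
    """A very small fitted model for shape/determinism contracts (seconds)."""
    corpus = generate_smiles_corpus(40, seed=7)
    model = ConditionalSmilesVAE(
        embedding_dim=8,
        encoder_rnn_dim=12,
        encoder_rnn_layers=1,
        latent_dim=6,
        fpc_hidden_dims=(8, 8),
        decoder_rnn_dim=12,
        decoder_rnn_layers=1,
        batch_size=20,
        max_epochs=2,
        seed=0,
    )
    model.fit(corpus)
    return model


class SetActivityModel:
    """Deterministic stand-in activity predictor: active iff in a fixed set."""

    def __init__(self, active: set[str]):
        self.active = set(active)

    def predict(self, smiles):
        return np.array([1 if s in self.active else 0 for s in smiles])


@pytest.fixture
def set_activity_model():
    return SetActivityModel
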