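"""Shared fixtures: synthetic corpora and small trained models.

Training is done once per session; the CLM fixtures deliberately use the
same corpus/seed conditions as the batch-generation tests so results are
reproducible end to end.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from agentmol.clm import tiny_clm_config, train_clm
from agentmol.data_io import AffinityDataset, LigandProteinPair, split_dataset
from agentmol.dti_rcnn import RcnnConfig, build_rcnn, encode_dataset, train_rcnn
from agentmol.fixtures import FixtureSpec, make_paired_corpus
from agentmol.tokenization import BpeTokenizerSpec, build_char_vocab, train_bpe

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def corpus_lines(ds: AffinityDataset) -> list[str]:
    return [f"{p.protein_seq} {p.smiles}" for p in ds]


@pytest.fixture(scope="session")
def fixture_corpus():
    """200 noise-free synthetic pairs (seed 7): the standard CLM test corpus."""
    return make_paired_corpus(FixtureSpec(n_pairs=200, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def bpe_tokenizer(fixture_corpus):
    return train_bpe(corpus_lines(fixture_corpus), BpeTokenizerSpec())


@pytest.fixture(scope="session")
def tiny_clm(fixture_corpus, bpe_tokenizer):
    """Tiny (2-layer, width-64) language model trained 10 epochs on the corpus."""
    train, val = split_dataset(fixture_corpus, 0.7, seed=7)
    model, log = train_clm(train, val, bpe_tokenizer, tiny_clm_config(seed=7))
    return model, log


@pytest.fixture(scope="session")
def memorized_clm():
    """A model trained on one repeated pair until it memorizes it."""
    pair = LigandProteinPair(
        smiles="C1CCCCC1C(N)CCO", protein_seq="MKTAYIAKQRQISFVK", pki=5.0
    )
    ds = AffinityDataset([pair] * 32)
    tok = train_bpe([f"{pair.protein_seq} {pair.smiles}"] * 3, BpeTokenizerSpec())
    cfg = tiny_clm_config(seed=3, epochs=40, batch_size=8, warmup_steps=5)
    model, log = train_clm(ds, ds, tok, cfg)
    return model, tok, pair, log


@pytest.fixture(scope="session")
def small_rcnn(fixture_corpus):
    """A briefly-trained regressor + vocabulary for plumbing/smoke tests."""
    vocab = build_char_vocab(fixture_corpus)
    train, val = split_dataset(fixture_corpus, 0.7, seed=5)
    cfg = RcnnConfig(epochs=3, batch_size=16, seed=5)
    model = build_rcnn(cfg, vocab.size)
    model, history = train_rcnn(
        model, encode_dataset(train, vocab), encode_dataset(val, vocab)
    )
    return model, vocab, history
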