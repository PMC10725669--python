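"""Shared fixtures: tiny hand-written corpora and small embedding tables."""

import numpy as np
import pytest

import pharlstm as ph

# One sentence, two drug mentions, one interacting pair.
MINI_XML = """<?xml version="1.0" encoding="UTF-8"?>
<corpus>
 <document id="d1">
  <sentence id="d1.s0" text="aspirin strongly boosts harmful warfarin">
   <entity id="d1.s0.e0" charOffset="0-6" type="drug" text="aspirin"/>
   <entity id="d1.s0.e1" charOffset="32-39" type="drug" text="warfarin"/>
   <pair id="d1.s0.p0" e1="d1.s0.e0" e2="d1.s0.e1" ddi="true"/>
  </sentence>
 </document>
</corpus>
"""

# Four drug mentions, no pair annotations.
FOUR_DRUG_XML = """<?xml version="1.0" encoding="UTF-8"?>
<corpus>
 <document id="d2">
  <sentence id="d2.s0" text="alpha beta with gamma and delta given">
   <entity id="d2.s0.e0" charOffset="0-4" type="drug" text="alpha"/>
   <entity id="d2.s0.e1" charOffset="6-9" type="drug" text="beta"/>
   <entity id="d2.s0.e2" charOffset="16-20" type="drug" text="gamma"/>
   <entity id="d2.s0.e3" charOffset="26-30" type="drug" text="delta"/>
  </sentence>
 </document>
</corpus>
"""


@pytest.fixture
def mini_corpus():
    return ph.parse_ddi_corpus_string(MINI_XML, "binary")


@pytest.fixture
def four_drug_sentence():
    corpus = ph.parse_ddi_corpus_string(FOUR_DRUG_XML, "binary")
    return corpus.documents[0].sentences[0]


@pytest.fixture
def small_table():
    vocab = ["aspirin", "warfarin", "strongly", "boosts", "harmful",
             "alpha", "beta", "gamma", "delta", "with", "and", "given"]
    return ph.init_embedding_table(vocab, d=8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
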