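import pytest

from notesift.baselines import GbtClassifier
from notesift.nn import AttentionDnnClassifier
from notesift.simulate import filtered_spec, generate_corpus, unfiltered_spec

# Desk-scale network hyperparameters shared across tests: small enough to
# train in seconds, large enough to separate planted cues from filler.
DNN_TEST_PARAMS = dict(
    embed_dim=32, n_filters=32, hidden_size=32, attn_size=32,
    max_len=96, epochs=5, batch_size=32,
)


@pytest.fixture(scope="session")
def train_corpus():
    """Keyword-filtered training corpus (separable: cues only in positives)."""
    return generate_corpus(filtered_spec(600, 0.294, seed=11))


@pytest.fixture(scope="session")
def eval_corpus():
    """Unfiltered low-prevalence evaluation corpus."""
    return generate_corpus(unfiltered_spec(400, 0.035, seed=12))


@pytest.fixture(scope="session")
def gbt_model(train_corpus):
    return GbtClassifier(seed=0).fit(train_corpus)


@pytest.fixture(scope="session")
def dnn_model(train_corpus):
    return AttentionDnnClassifier(seed=0, **DNN_TEST_PARAMS).fit(train_corpus)
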