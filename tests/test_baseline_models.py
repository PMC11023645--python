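"""Local classifiers: boosted trees and the numpy attention network."""

import numpy as np
import pytest

from notesift.baselines import GbtClassifier, ModelScore, chance_level_f1
from notesift.corpus import Corpus, NoteSection
from notesift.evaluation import confusion, metrics
from notesift.nn import AttentionDnnClassifier
from notesift.simulate import generate_corpus, unfiltered_spec
from notesift.tokenize import tokenize

from conftest import DNN_TEST_PARAMS


# ----------------------------------------------------------- boosted trees


def test_gbt_training_f1_is_perfect_on_separable_corpus(gbt_model, train_corpus):
    preds = [s.label for s in gbt_model.predict(train_corpus)]
    assert metrics(confusion(preds, train_corpus.labels)).f1 == 1.0


def test_gbt_probabilities_lie_in_unit_interval(gbt_model, eval_corpus):
    probs = gbt_model.predict_proba(eval_corpus)
    assert np.all((probs >= 0) & (probs <= 1))


def test_gbt_heldout_f1_beats_prevalence_matched_chance(gbt_model):
    held = generate_corpus(unfiltered_spec(1000, 0.035, seed=13))
    preds = [s.label for s in gbt_model.predict(held)]
    f1 = metrics(confusion(preds, held.labels)).f1
    assert f1 > chance_level_f1(held.realized_prevalence)


def test_single_class_training_set_rejected():
    sections = [NoteSection(f"s{i}", "memory loss noted", 1) for i in range(10)]
    corpus = Corpus(sections)
    with pytest.raises(ValueError):
        GbtClassifier().fit(corpus)
    with pytest.raises(ValueError):
        AttentionDnnClassifier().fit(corpus)


def test_gbt_refit_with_same_seed_is_deterministic(train_corpus, eval_corpus, gbt_model):
    again = GbtClassifier(seed=0).fit(train_corpus)
    assert np.array_equal(gbt_model.predict_proba(eval_corpus),
                          again.predict_proba(eval_corpus))


def test_gbt_gains_are_nonnegative_and_within_vocabulary(gbt_model):
    gains = gbt_model.feature_gains()
    assert gains, "fitted model should expose split gains"
    assert all(g >= 0 for g in gains.values())
    assert set(gains) <= set(gbt_model.vocabulary)


# --------------------------------------------------------- cutoff semantics


@pytest.mark.parametrize("prob, label", [(0.5, 1), (0.49, 0), (0.0, 0), (1.0, 1)])
def test_cutoff_boundary_counts_as_positive(prob, label):
    assert ModelScore("x", prob).label == label


def test_labels_equal_thresholding_oracle(gbt_model, eval_corpus):
    scores = gbt_model.predict(eval_corpus)
    probs = gbt_model.predict_proba(eval_corpus)
    assert [s.label for s in scores] == [int(p >= 0.5) for p in probs]


# -------------------------------------------------------- attention network


def test_attention_weights_sum_to_one_per_section(dnn_model, eval_corpus):
    maps = dnn_model.attention_maps(eval_corpus.subset(eval_corpus.ids[:60]))
    for m in maps:
        assert len(m.tokens) == len(m.weights)
        if m.tokens:
            assert abs(float(np.sum(m.weights)) - 1.0) < 1e-9
        assert np.all(np.asarray(m.weights) >= 0)


def test_mean_attention_on_cue_tokens_exceeds_filler(dnn_model, train_corpus):
    positives = Corpus([s for s in train_corpus if s.label == 1][:80])
    maps = dnn_model.attention_maps(positives)
    cue_weights, filler_weights = [], []
    for sec, amap in zip(positives, maps):
        cue_tokens = set()
        for cue in sec.meta["cues"]:
            cue_tokens.update(tokenize(cue))
        for tok, w in zip(amap.tokens, amap.weights):
            (cue_weights if tok in cue_tokens else filler_weights).append(float(w))
    assert np.mean(cue_weights) > np.mean(filler_weights)


def test_training_loss_decreases_over_first_three_epochs(dnn_model):
    losses = dnn_model.loss_history_
    assert len(losses) >= 3
    assert losses[0] > losses[1] > losses[2]


def test_refit_with_same_seed_reproduces_probabilities(train_corpus):
    small = Corpus(train_corpus.sections[:120])
    params = dict(DNN_TEST_PARAMS, epochs=2)
    a = AttentionDnnClassifier(seed=7, **params).fit(small)
    b = AttentionDnnClassifier(seed=7, **params).fit(small)
    assert np.array_equal(a.predict_proba(small), b.predict_proba(small))


def test_empty_vocabulary_rejected():
    sections = [NoteSection(f"s{i}", "!!! ??? ...", i % 2) for i in range(10)]
    with pytest.raises(ValueError):
        AttentionDnnClassifier().fit(Corpus(sections))


def test_backprop_gradients_match_finite_differences():
    model = AttentionDnnClassifier(
        embed_dim=3, n_filters=4, kernel_size=3, hidden_size=2,
        attn_size=3, dropout=0.0, max_len=8, seed=0,
    )
    model.vocab = {w: i + 2 for i, w in enumerate("a b c d e".split())}
    model.params = model._init_params(np.random.default_rng(1))
    ids = np.array([[2, 3, 4, 0, 0], [5, 6, 2, 3, 4]])
    mask = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 1, 1.0]])
    y = np.array([1.0, 0.0])
    _, grads = model.loss_and_grads(ids, mask, y)
    eps = 1e-6
    for name, p in model.params.items():
        flat = p.reshape(-1)
        rng = np.random.default_rng(sum(map(ord, name)))
        for idx in rng.choice(flat.size, size=min(flat.size, 12), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = model.loss_and_grads(ids, mask, y)
            flat[idx] = orig - eps
            lm, _ = model.loss_and_grads(ids, mask, y)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert abs(numeric - analytic) <= 1e-6 + 1e-4 * (abs(numeric) + abs(analytic)), (
                f"gradient mismatch in {name}[{idx}]: {numeric} vs {analytic}"
            )


def test_model_save_load_roundtrip(tmp_path, gbt_model, dnn_model, eval_corpus):
    gbt_model.save(tmp_path / "g")
    dnn_model.save(tmp_path / "d")
    g2 = GbtClassifier.load(tmp_path / "g")
    d2 = AttentionDnnClassifier.load(tmp_path / "d")
    assert np.allclose(gbt_model.predict_proba(eval_corpus), g2.predict_proba(eval_corpus))
    assert np.allclose(dnn_model.predict_proba(eval_corpus), d2.predict_proba(eval_corpus))
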