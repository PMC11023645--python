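"""Mean + 2*SD keyword selection for LLM output, attention and tree gain."""

import statistics

import numpy as np
import pytest

from notesift.interpretation import (
    KeywordReport,
    attention_keyword_report,
    flag_attention_tokens,
    gain_keyword_report,
    llm_keyword_report,
    merged_report,
    merged_report_markdown,
    normalize_keyword,
)
from notesift.nn import AttentionMap
from notesift.prompting import EFFECTIVE_PARSEABLE, NOT_EFFECTIVE, LLMReply


def _reply(keywords):
    return LLMReply("", EFFECTIVE_PARSEABLE, 1, keywords)


# ------------------------------------------------------------- LLM keywords


def test_dominant_keyword_alone_is_selected():
    replies = [_reply(["memory loss"]) for _ in range(50)]
    replies += [_reply([f"kw{i}"]) for i in range(9)]
    report = llm_keyword_report(replies)
    assert report.selected == ["memory loss"]


def test_equal_frequencies_select_nothing():
    replies = [_reply([f"kw{i}"]) for i in range(8)]
    report = llm_keyword_report(replies)
    assert report.selected == []
    assert report.threshold == pytest.approx(1.0)  # SD = 0, strict inequality


def test_llm_selection_matches_independent_recomputation():
    rng = np.random.default_rng(17)
    vocab = [f"kw{i}" for i in range(12)]
    replies = []
    for _ in range(120):
        k = int(rng.integers(1, 4))
        kws = rng.choice(vocab, size=k, replace=False).tolist()
        # heavy skew for one keyword
        if rng.random() < 0.7:
            kws.append("dementia")
        replies.append(_reply(kws))
    report = llm_keyword_report(replies)
    counts = {}
    for r in replies:
        for kw in {normalize_keyword(k) for k in r.keywords}:
            counts[kw] = counts.get(kw, 0) + 1
    vals = list(counts.values())
    cut = statistics.fmean(vals) + 2 * statistics.pstdev(vals)
    assert set(report.selected) == {k for k, v in counts.items() if v > cut}
    assert report.threshold == pytest.approx(cut)


def test_llm_selection_invariant_under_count_scaling():
    replies = [_reply(["memory loss"]) for _ in range(40)] + [
        _reply([f"kw{i}"]) for i in range(9)
    ]
    base = llm_keyword_report(replies).selected
    scaled = llm_keyword_report(replies * 3).selected
    assert base == scaled


def test_replies_without_keywords_are_rejected():
    with pytest.raises(ValueError):
        llm_keyword_report([LLMReply("", NOT_EFFECTIVE)])


# -------------------------------------------------------- attention keywords


def test_uniform_attention_flags_nothing():
    amap = AttentionMap("s1", ["a"] * 10, np.full(10, 0.1))
    assert flag_attention_tokens(amap) == []


def test_dominant_token_among_near_zero_tokens_is_flagged():
    weights = np.full(21, 0.01)
    weights[7] = 1.0 - 0.20
    tokens = [f"t{i}" for i in range(21)]
    amap = AttentionMap("s1", tokens, weights)
    assert flag_attention_tokens(amap) == ["t7"]


def test_flagged_tokens_match_per_section_bruteforce():
    rng = np.random.default_rng(23)
    maps = []
    for i in range(25):
        n = int(rng.integers(2, 30))
        w = rng.dirichlet(np.ones(n) * 0.2)
        maps.append(AttentionMap(f"s{i}", [f"t{j}" for j in range(n)], w))
    report = attention_keyword_report(maps)
    expected = {}
    for m in maps:
        cut = m.weights.mean() + 2 * m.weights.std()
        for tok, w in zip(m.tokens, m.weights):
            if w > cut:
                expected[tok] = expected.get(tok, 0) + 1
    assert report.stats == {k: float(v) for k, v in expected.items()}
    assert set(report.selected) == set(expected)


def test_attention_report_rejects_degenerate_input():
    with pytest.raises(ValueError):
        attention_keyword_report([])
    with pytest.raises(ValueError):
        flag_attention_tokens(AttentionMap("s", ["a", "b"], np.array([1.0])))


# ------------------------------------------------------------ gain keywords


class _FakeGainModel:
    def __init__(self, gains):
        self._gains = gains

    def feature_gains(self):
        return self._gains


def test_dominant_gain_feature_selected_over_vocabulary_population():
    gains = {"dementia": 50.0}
    gains.update({f"f{i}": 0.0 for i in range(9)})
    report = gain_keyword_report(_FakeGainModel(gains), include_zero_gain=True)
    assert report.selected == ["dementia"]


def test_equal_gains_select_nothing():
    report = gain_keyword_report(_FakeGainModel({"a": 2.0, "b": 2.0, "c": 2.0}))
    assert report.selected == []


def test_gain_selection_matches_recomputation_from_exported_table(gbt_model):
    report = gain_keyword_report(gbt_model)
    gains = {k: v for k, v in gbt_model.feature_gains().items() if v > 0}
    vals = np.array(list(gains.values()))
    cut = vals.mean() + 2 * vals.std()
    assert set(report.selected) == {k for k, v in gains.items() if v > cut}


def test_model_without_gains_rejected():
    with pytest.raises(ValueError):
        gain_keyword_report(_FakeGainModel({}))


# ------------------------------------------------------------ merged report


def test_merged_report_with_no_model_reports_contains_only_expert_column():
    table = merged_report([], ["Memory", "recall"])
    assert set(table["keyword"]) == {"memory", "recall"}
    assert table["expert"].all()
    assert not table[["llm_output", "attention", "gain"]].to_numpy().any()
    assert (table["unique_to"] == "expert").all()


def test_keyword_present_in_every_source_is_one_shared_row():
    reports = [
        KeywordReport("llm_output", {"memory": 10.0}, 5.0, ["memory"]),
        KeywordReport("attention", {"memory": 3.0}, 0.0, ["memory"]),
        KeywordReport("gain", {"memory": 9.0}, 5.0, ["memory"]),
    ]
    table = merged_report(reports, ["memory"])
    assert len(table) == 1
    row = table.iloc[0]
    assert row[["llm_output", "attention", "gain", "expert"]].all()
    assert row["unique_to"] == ""
    assert "memory" in merged_report_markdown(table)


def test_membership_flags_match_set_oracle():
    rng = np.random.default_rng(29)
    vocab = [f"kw{i}" for i in range(15)]
    selections = {
        src: sorted(rng.choice(vocab, size=int(rng.integers(1, 10)), replace=False))
        for src in ("llm_output", "attention", "gain")
    }
    reports = [
        KeywordReport(src, {k: 1.0 for k in sel}, 0.0, list(sel))
        for src, sel in selections.items()
    ]
    expert = sorted(rng.choice(vocab, size=5, replace=False))
    table = merged_report(reports, expert)
    for _, row in table.iterrows():
        assert row["expert"] == (row["keyword"] in expert)
        for src in ("llm_output", "attention", "gain"):
            assert row[src] == (row["keyword"] in selections[src])


def test_keyword_report_invariant_enforced():
    with pytest.raises(ValueError):
        KeywordReport("llm_output", {"a": 1.0, "b": 5.0}, 2.0, ["a"])
    with pytest.raises(ValueError):
        KeywordReport("bogus_source", {"a": 1.0}, 0.0, [])
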