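"""Prompt rendering, reply triage, example selection, mock backend."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from notesift.corpus import Corpus, NoteSection
from notesift.prompting import (
    EFFECTIVE_PARSEABLE,
    EFFECTIVE_UNPARSEABLE,
    NOT_EFFECTIVE,
    BackendConfig,
    HashingEmbedder,
    LLMReply,
    MockBackend,
    PromptTemplate,
    TemplateTuningLog,
    build_error_instructions,
    default_template,
    effective_rate,
    render_prompt,
    select_dynamic,
    select_kmeans,
    select_random,
    select_targeted,
    triage_reply,
)
from notesift.simulate import filtered_spec, generate_corpus


def _mini_pool(n=12, seed=0):
    return generate_corpus(filtered_spec(n, 0.4, seed=seed))


QUERY = NoteSection("q1", "Patient reports forgetfulness.", 1)


# ---------------------------------------------------------------- rendering


def test_description_only_prompt_orders_description_before_query():
    tpl = PromptTemplate("Decide whether cognitive decline is documented.")
    text = render_prompt(tpl, QUERY)
    assert text.index(tpl.task_description) < text.index(QUERY.text)
    assert text.count(QUERY.text) == 1
    assert "JSON" in text  # response-format directive always present


def test_five_examples_appear_in_order_before_query():
    examples = [(f"example text {i}", i % 2) for i in range(5)]
    tpl = PromptTemplate("desc", augmentation_examples=examples)
    text = render_prompt(tpl, QUERY)
    positions = [text.index(t) for t, _ in examples]
    assert positions == sorted(positions)
    assert positions[-1] < text.index(QUERY.text)


def test_rendering_is_deterministic():
    tpl = default_template()
    assert render_prompt(tpl, QUERY) == render_prompt(tpl, QUERY)


def test_template_requires_task_description():
    with pytest.raises(ValueError):
        PromptTemplate("   ")


def test_template_yaml_roundtrip(tmp_path):
    tpl = PromptTemplate("desc", "guide", [("ex", 1)], "avoid negation errors", "t7")
    tpl.to_yaml(tmp_path / "t.yaml")
    back = PromptTemplate.from_yaml(tmp_path / "t.yaml")
    assert back == tpl


# ------------------------------------------------------------------- triage


@pytest.mark.parametrize("raw, category, verdict", [
    ('{"cognitive_decline": true, "keywords": ["memory loss"]}', EFFECTIVE_PARSEABLE, 1),
    ('{"cognitive_decline": "no", "keywords": []}', EFFECTIVE_PARSEABLE, 0),
    ('Sure! Here you go: {"cognitive_decline": false, "keywords": ["sleep"]} Done.',
     EFFECTIVE_PARSEABLE, 0),
    ("Yes — evidence found. Keywords: memory loss, MoCA.", EFFECTIVE_UNPARSEABLE, 1),
    ("No evidence of cognitive decline. Keywords: none.", EFFECTIVE_UNPARSEABLE, 0),
    ("I cannot determine that.", NOT_EFFECTIVE, None),
    ("Yes, definitely.", NOT_EFFECTIVE, None),  # verdict without keywords
    ("", NOT_EFFECTIVE, None),
])
def test_triage_examples(raw, category, verdict):
    reply = triage_reply(raw)
    assert reply.category == category
    assert reply.verdict == verdict
    if category == EFFECTIVE_PARSEABLE:
        assert reply.keywords is not None


@settings(derandomize=True, max_examples=200)
@given(st.text(max_size=300))
def test_triage_is_total_over_arbitrary_strings(raw):
    reply = triage_reply(raw)
    assert reply.category in (EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE, NOT_EFFECTIVE)
    if reply.category == NOT_EFFECTIVE:
        assert reply.verdict is None


def test_not_effective_replies_cannot_carry_a_verdict():
    with pytest.raises(ValueError):
        LLMReply("x", NOT_EFFECTIVE, verdict=1)


# ----------------------------------------------------------- effective rate


def test_effective_rate_eight_of_ten():
    replies = [LLMReply("", EFFECTIVE_PARSEABLE, 1, ["m"]) for _ in range(5)]
    replies += [LLMReply("", EFFECTIVE_UNPARSEABLE, 0, ["m"]) for _ in range(3)]
    replies += [LLMReply("", NOT_EFFECTIVE) for _ in range(2)]
    assert effective_rate(replies) == 0.8
    assert effective_rate(replies, include_unparseable=False) == 0.5


def test_effective_rate_all_parseable_is_one_and_empty_errors():
    replies = [LLMReply("", EFFECTIVE_PARSEABLE, 1, ["m"])] * 4
    assert effective_rate(replies) == 1.0
    with pytest.raises(ValueError):
        effective_rate([])


def test_effective_rate_equals_count_oracle_on_random_mixtures():
    rng = np.random.default_rng(3)
    cats = [EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE, NOT_EFFECTIVE]
    for _ in range(30):
        picks = [cats[i] for i in rng.integers(0, 3, size=int(rng.integers(1, 40)))]
        replies = [
            LLMReply("", c, None if c == NOT_EFFECTIVE else 1,
                     None if c == NOT_EFFECTIVE else ["k"])
            for c in picks
        ]
        expected = sum(c != NOT_EFFECTIVE for c in picks) / len(picks)
        assert effective_rate(replies) == expected


# -------------------------------------------------------- example selection


def test_random_selection_of_whole_pool_and_determinism():
    pool = _mini_pool(5)
    assert {s.section_id for s in select_random(pool, 5, seed=1)} == set(pool.ids)
    a = select_random(_mini_pool(12), 5, seed=9)
    b = select_random(_mini_pool(12), 5, seed=9)
    assert [s.section_id for s in a] == [s.section_id for s in b]
    with pytest.raises(ValueError):
        select_random(_mini_pool(4), 5)


def test_random_selection_is_uniform_per_item_chi_square():
    pool = _mini_pool(10)
    counts = {sid: 0 for sid in pool.ids}
    for seed in range(1000):
        for s in select_random(pool, 5, seed=seed):
            counts[s.section_id] += 1
    observed = np.array(list(counts.values()))
    _, p = stats.chisquare(observed)
    assert p > 1e-3


def test_targeted_selection_returns_exactly_the_prior_errors():
    pool = _mini_pool(12)
    error_ids = set(pool.ids[:5])
    picked = select_targeted(pool, error_ids, k=5)
    assert {s.section_id for s in picked} == error_ids
    with pytest.raises(ValueError):
        select_targeted(pool, set(), k=5)


def test_targeted_selection_stays_inside_prior_errors():
    pool = _mini_pool(30, seed=5)
    rng = np.random.default_rng(1)
    for trial in range(20):
        n_err = int(rng.integers(5, 20))
        error_ids = set(rng.choice(pool.ids, size=n_err, replace=False))
        picked = select_targeted(pool, error_ids, k=5, seed=trial)
        assert {s.section_id for s in picked} <= error_ids
        assert len(picked) == 5


class ToyEmbedder:
    """Deterministic lookup embedder for hand-built geometry."""

    def __init__(self, table):
        self.table = table
        self.dim = len(next(iter(table.values())))

    def embed(self, text):
        return np.asarray(self.table[text], dtype=float)


def _blob_pool():
    centers = [(0, 0), (10, 0), (0, 10), (10, 10), (5, 20)]
    table, sections = {}, []
    for b, (cx, cy) in enumerate(centers):
        for j, (dx, dy) in enumerate([(0, 0), (1, 0), (0, 1)]):
            text = f"blob {b} member {j}"
            table[text] = (cx + dx, cy + dy)
            sections.append(NoteSection(f"b{b}m{j}", text, 0))
    return Corpus(sections), ToyEmbedder(table)


def test_kmeans_medoids_pick_one_member_per_separated_blob():
    pool, emb = _blob_pool()
    medoids = select_kmeans(pool, emb, k=5, seed=0)
    blobs = sorted(m.section_id[1] for m in medoids)
    assert blobs == ["0", "1", "2", "3", "4"]
    assert all(m.section_id in set(pool.ids) for m in medoids)


def test_kmeans_singleton_pool_returns_every_point():
    pool, emb = _blob_pool()
    five = Corpus([pool.by_id(f"b{i}m0") for i in range(5)])
    medoids = select_kmeans(five, emb, k=5, seed=3)
    assert {m.section_id for m in medoids} == set(five.ids)


def test_kmeans_fixed_seed_reproducible_and_small_pool_errors():
    pool, emb = _blob_pool()
    a = select_kmeans(pool, emb, 5, seed=2)
    b = select_kmeans(pool, emb, 5, seed=2)
    assert [s.section_id for s in a] == [s.section_id for s in b]
    with pytest.raises(ValueError):
        select_kmeans(Corpus(pool.sections[:3]), emb, k=5)


def test_dynamic_selection_ranks_identical_member_first():
    pool = _mini_pool(10)
    emb = HashingEmbedder(64)
    member = pool.sections[4]
    query = NoteSection("query", member.text, member.label)
    picked = select_dynamic(query, pool, emb, k=5)
    assert picked[0].section_id == member.section_id


def test_dynamic_selection_matches_bruteforce_on_toy_vectors():
    vecs = {
        f"t{i}": v
        for i, v in enumerate(
            [(1, 0), (0.9, 0.1), (0.5, 0.5), (0, 1), (-1, 0), (0.8, 0.6),
             (0.99, 0.01), (0.2, 0.9)]
        )
    }
    sections = [NoteSection(f"p{i}", f"t{i}", 0) for i in range(8)]
    pool = Corpus(sections)
    emb = ToyEmbedder(vecs)
    query = NoteSection("q", "t0", 0)
    vecs["t0"] = (1, 0)
    picked = select_dynamic(query, pool, emb, k=5)

    def cos(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    expected = sorted(sections, key=lambda s: (-cos(vecs["t0"], vecs[s.text]), s.section_id))
    assert [s.section_id for s in picked] == [s.section_id for s in expected[:5]]


def test_dynamic_selection_with_k_equal_pool_returns_sorted_pool():
    pool = _mini_pool(7)
    emb = HashingEmbedder(64)
    picked = select_dynamic(QUERY, pool, emb, k=7)
    assert {s.section_id for s in picked} == set(pool.ids)
    with pytest.raises(ValueError):
        select_dynamic(QUERY, pool, emb, k=8)


# ------------------------------------------------------- error instructions


def test_error_instructions_empty_input_yields_empty_text():
    assert build_error_instructions([]) == ""


def test_error_instructions_orders_categories_by_frequency():
    errs = [("a", "transient-cause")] + [("b", "misread-negation")] * 3
    text = build_error_instructions(errs)
    assert text.index("negated") < text.index("transient")
    assert "(3 cases)" in text and "(1 case)" in text
    assert build_error_instructions(errs) == text  # deterministic


def test_error_instructions_reject_unknown_tags():
    with pytest.raises(ValueError):
        build_error_instructions([("x", "made-up-category")])


# ----------------------------------------------------------------- embedder


def test_hashing_embedder_contract():
    emb = HashingEmbedder(128)
    for text in ["memory loss", "x", "!!!", "MoCA score of 22"]:
        v = emb.embed(text)
        assert v.shape == (128,)
        assert np.linalg.norm(v) > 0
    assert np.array_equal(emb.embed("memory loss"), emb.embed("memory loss"))


# ------------------------------------------------------------- mock backend


def test_mock_error_rate_zero_reproduces_gold_labels():
    corpus = generate_corpus(filtered_spec(200, 0.3, seed=41))
    backend = MockBackend(BackendConfig(seed=1, mock_error_rate=0.0))
    for s in corpus:
        reply = backend.classify(s)
        assert reply.category == EFFECTIVE_PARSEABLE
        assert reply.verdict == s.label


def test_mock_flip_fraction_within_three_se_of_configured_rate():
    corpus = generate_corpus(filtered_spec(2000, 0.3, seed=42))
    backend = MockBackend(BackendConfig(seed=2, mock_error_rate=0.2))
    flips = sum(backend.classify(s).verdict != s.label for s in corpus)
    se = math.sqrt(0.2 * 0.8 / 2000)
    assert abs(flips / 2000 - 0.2) <= 3 * se


def test_mock_fixed_seed_gives_identical_reply_sequence():
    corpus = generate_corpus(filtered_spec(60, 0.3, seed=43))
    a = MockBackend(BackendConfig(seed=9, mock_error_rate=0.3, mock_unparseable_rate=0.2))
    b = MockBackend(BackendConfig(seed=9, mock_error_rate=0.3, mock_unparseable_rate=0.2))
    ra = [a.classify(s).raw for s in corpus]
    rb = [b.classify(s).raw for s in corpus]
    assert ra == rb


def test_mock_emits_configured_reply_format_mixture():
    corpus = generate_corpus(filtered_spec(300, 0.3, seed=44))
    backend = MockBackend(
        BackendConfig(seed=3, mock_unparseable_rate=0.3, mock_ineffective_rate=0.2)
    )
    cats = [backend.classify(s).category for s in corpus]
    assert {EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE, NOT_EFFECTIVE} <= set(cats)


# ------------------------------------------------------------ tuning ledger


def test_tuning_log_stops_after_three_attempts_without_improvement():
    log = TemplateTuningLog()
    for name, rate in [("t1", 0.6), ("t2", 0.8), ("t3", 0.7), ("t4", 0.8)]:
        log.record(name, rate)
        assert not log.should_stop
    log.record("t5", 0.75)
    assert log.should_stop
    assert log.best.template_name == "t2"


def test_tuning_log_stops_at_perfect_rate():
    log = TemplateTuningLog()
    log.record("t1", 1.0)
    assert log.should_stop
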