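"""Prompt construction, reply triage, few-shot example selection and a
deterministic mock backend.

Prompts are sectioned: a required task description plus optional task
guidance, error-analysis-based instructions and few-shot augmentation
examples, rendered in a fixed order ahead of the query section. Replies
are triaged into three effectiveness categories: *effective and parseable*
(a well-formed JSON object answering both questions — verdict and
supporting keywords), *effective but not parseable* (both answers
recoverable from free text via a documented fallback scan), and *not
effective* (at least one answer missing).

Four five-shot example-selection strategies are provided: random (hard),
targeted at prior errors (hard), k-means cluster medoids (hard), and
dynamic per-query nearest neighbors (soft). Text embeddings go through a
pluggable embedder contract; the shipped default is a deterministic
feature-hashing embedder so the whole subsystem runs offline.

The mock backend answers from the gold label, flipping it independently
with a configured error probability — it stands in for a remote model so
the surrounding machinery (prompt rendering, triage, ensembling, error
analysis) can be exercised and tested at any scale.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import yaml
from sklearn.cluster import KMeans

from .corpus import Corpus, NoteSection
from .screen import KeywordPattern, expert_patterns, matching_keywords
from .tokenize import tokenize

EFFECTIVE_PARSEABLE = "effective_parseable"
EFFECTIVE_UNPARSEABLE = "effective_unparseable"
NOT_EFFECTIVE = "not_effective"

VERDICT_KEY = "cognitive_decline"
KEYWORDS_KEY = "keywords"

DEFAULT_TASK_DESCRIPTION = (
    "You are reviewing one section of a clinical note. Decide whether the "
    "section contains evidence of cognitive decline (signs, symptoms, "
    "diagnostic evaluations, cognitive assessments, or treatment). "
    "Transient causes, such as memory loss due to medication, do not count."
)

DEFAULT_TASK_GUIDANCE = (
    "Cognitive decline spans subjective cognitive decline, mild cognitive "
    "impairment, and dementia. Base the judgment only on the text provided."
)

RESPONSE_DIRECTIVE = (
    'Respond with a JSON object containing two keys: "cognitive_decline" '
    '(true or false) and "keywords" (the list of words or phrases from the '
    "section that informed the decision)."
)


# --------------------------------------------------------------- templates


@dataclass
class PromptTemplate:
    """Sectioned prompt: required task description, optional extras."""

    task_description: str
    task_guidance: str | None = None
    augmentation_examples: list[tuple[str, int]] = field(default_factory=list)
    error_instructions: str | None = None
    name: str = "template"

    def __post_init__(self) -> None:
        if not self.task_description or not self.task_description.strip():
            raise ValueError("task_description must be non-empty")
        for ex in self.augmentation_examples:
            if len(ex) != 2 or ex[1] not in (0, 1):
                raise ValueError("each example must be (text, binary gold label)")

    def with_examples(self, examples: Sequence[NoteSection]) -> "PromptTemplate":
        return PromptTemplate(
            self.task_description,
            self.task_guidance,
            [(s.text, s.label) for s in examples],
            self.error_instructions,
            self.name,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "task_description": self.task_description,
            "task_guidance": self.task_guidance,
            "augmentation_examples": [
                {"text": t, "label": int(l)} for t, l in self.augmentation_examples
            ],
            "error_instructions": self.error_instructions,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PromptTemplate":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            task_description=doc["task_description"],
            task_guidance=doc.get("task_guidance"),
            augmentation_examples=[
                (ex["text"], int(ex["label"]))
                for ex in doc.get("augmentation_examples") or []
            ],
            error_instructions=doc.get("error_instructions"),
            name=doc.get("name", "template"),
        )


def default_template() -> PromptTemplate:
    return PromptTemplate(DEFAULT_TASK_DESCRIPTION, DEFAULT_TASK_GUIDANCE)


def render_prompt(template: PromptTemplate, query_section: NoteSection) -> str:
    """Deterministic prompt text: description, guidance, error instructions,
    examples (in order), the response-format directive, then the query
    section verbatim, exactly once."""
    parts = [template.task_description.strip()]
    if template.task_guidance:
        parts.append(template.task_guidance.strip())
    if template.error_instructions:
        parts.append(template.error_instructions.strip())
    if template.augmentation_examples:
        ex_lines = [f"Here are {len(template.augmentation_examples)} labeled examples:"]
        for i, (text, label) in enumerate(template.augmentation_examples, 1):
            word = "positive" if label else "negative"
            ex_lines.append(f"Example {i}:\n{text}\nLabel: {word}")
        parts.append("\n\n".join(ex_lines))
    parts.append(RESPONSE_DIRECTIVE)
    parts.append(f"Note section:\n{query_section.text}")
    return "\n\n".join(parts)


# ------------------------------------------------------------------ triage


@dataclass
class LLMReply:
    """A raw backend response plus its triage outcome."""

    raw: str
    category: str
    verdict: int | None = None
    keywords: list[str] | None = None

    def __post_init__(self) -> None:
        if self.category == NOT_EFFECTIVE and self.verdict is not None:
            raise ValueError("not_effective replies carry no verdict")
        if self.category == EFFECTIVE_PARSEABLE and (
            self.verdict is None or self.keywords is None
        ):
            raise ValueError("effective_parseable replies carry verdict and keywords")

    @property
    def effective(self) -> bool:
        return self.category in (EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE)


def _coerce_verdict(value) -> int | None:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, float)) and value in (0, 1):
        return int(value)
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("yes", "true", "positive", "1"):
            return 1
        if low in ("no", "false", "negative", "0"):
            return 0
    return None


def _coerce_keywords(value) -> list[str] | None:
    if isinstance(value, list) and all(isinstance(x, str) for x in value):
        return [x.strip() for x in value]
    if isinstance(value, str):
        return [p.strip() for p in value.split(",") if p.strip()]
    return None


def _scan_json_objects(raw: str):
    decoder = json.JSONDecoder()
    for m in re.finditer(r"\{", raw):
        try:
            obj, _ = decoder.raw_decode(raw, m.start())
        except ValueError:
            continue
        if isinstance(obj, dict):
            yield obj


# Fallback lexicon for effective-but-not-parseable replies. Negation
# patterns are checked first so "no evidence found" reads negative.
_NEGATION_PATTERNS = [
    r"^\s*no\b",
    r"\bno evidence\b",
    r"\bno signs?\b",
    r"\bnot (?:identified|found|present|detected|indicated)\b",
    r"\bnegative\b",
    r"\bdenies\b",
    r"\bdoes not\b",
    r"\babsent\b",
]
_AFFIRMATION_PATTERNS = [
    r"^\s*yes\b",
    r"\byes\b",
    r"\bevidence (?:of|found|present)\b",
    r"\bpositive\b",
    r"\bidentified\b",
    r"\bpresent\b",
]
_KEYWORD_LINE_RE = re.compile(r"keywords?\s*[:\-–]\s*(.+)", re.IGNORECASE)


def _fallback_verdict(raw: str) -> int | None:
    low = raw.lower()
    for pat in _NEGATION_PATTERNS:
        if re.search(pat, low):
            return 0
    for pat in _AFFIRMATION_PATTERNS:
        if re.search(pat, low):
            return 1
    return None


def _fallback_keywords(raw: str) -> list[str] | None:
    m = _KEYWORD_LINE_RE.search(raw)
    if not m:
        return None
    line = m.group(1).splitlines()[0]
    parts = [p.strip(" .;'\"") for p in re.split(r"[,;]", line)]
    parts = [p for p in parts if p]
    return parts or None


def triage_reply(raw: str) -> LLMReply:
    """Map any raw response string to exactly one effectiveness category.

    First well-formed JSON object carrying both required keys wins
    (*effective and parseable*); otherwise a fallback pattern scan must
    recover both a yes/no verdict and a keyword list (*effective but not
    parseable*); otherwise the reply is *not effective*.
    """
    for obj in _scan_json_objects(raw):
        if VERDICT_KEY in obj and KEYWORDS_KEY in obj:
            verdict = _coerce_verdict(obj[VERDICT_KEY])
            keywords = _coerce_keywords(obj[KEYWORDS_KEY])
            if verdict is not None and keywords is not None:
                return LLMReply(raw, EFFECTIVE_PARSEABLE, verdict, keywords)
    verdict = _fallback_verdict(raw)
    keywords = _fallback_keywords(raw)
    if verdict is not None and keywords is not None:
        return LLMReply(raw, EFFECTIVE_UNPARSEABLE, verdict, keywords)
    return LLMReply(raw, NOT_EFFECTIVE)


def effective_rate(replies: Sequence[LLMReply], include_unparseable: bool = True) -> float:
    """Share of replies answering both questions.

    Whether non-JSON-but-complete replies count as effective is reported
    both ways: the default includes them; ``include_unparseable=False``
    gives the strictly-parseable rate.
    """
    if not replies:
        raise ValueError("effective_rate requires a non-empty reply list")
    if include_unparseable:
        good = sum(r.effective for r in replies)
    else:
        good = sum(r.category == EFFECTIVE_PARSEABLE for r in replies)
    return good / len(replies)


# --------------------------------------------------------------- embedding


class Embedder(Protocol):
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic feature-hashing text embedder.

    Each token is hashed (blake2b, 8 bytes) to a signed bucket; vectors are
    L2-normalized. Index 0 is a constant bias bucket so non-empty text
    always has non-zero norm. Suitable as an offline stand-in wherever an
    embedding service would plug in.
    """

    def __init__(self, dim: int = 256):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        tokens = tokenize(text)
        if text.strip():
            v[0] += 1.0
        for tok in tokens:
            h = int.from_bytes(
                hashlib.blake2b(tok.encode("utf-8"), digest_size=8).digest(), "big"
            )
            idx = 1 + h % (self.dim - 1)
            sign = 1.0 if (h >> 32) & 1 else -1.0
            v[idx] += sign
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    def embed_corpus(self, corpus: Corpus) -> np.ndarray:
        return np.stack([self.embed(s.text) for s in corpus.sections])


# ------------------------------------------------------- example selection


def select_random(pool: Corpus, k: int = 5, seed: int = 0) -> list[NoteSection]:
    """k distinct pool sections, uniformly at random (seeded)."""
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} sections, need {k}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool.sections[i] for i in idx]


def select_targeted(
    pool: Corpus, prior_error_ids: set[str], k: int = 5, seed: int = 0
) -> list[NoteSection]:
    """k sections from the subset the model previously got wrong."""
    errors = [s for s in pool.sections if s.section_id in prior_error_ids]
    if len(errors) < k:
        raise ValueError(
            f"only {len(errors)} prior-error sections available in pool, need {k}"
        )
    if len(errors) == k:
        return errors
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(errors), size=k, replace=False)
    return [errors[i] for i in idx]


def select_kmeans(
    pool: Corpus, embedder: Embedder, k: int = 5, seed: int = 0
) -> list[NoteSection]:
    """Medoids of k seeded k-means clusters over pool embeddings.

    Cluster centers themselves are synthetic points; the returned examples
    are the pool members nearest each centroid (Euclidean), distinct.
    """
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} sections, need {k}")
    X = np.stack([embedder.embed(t) for t in pool.texts])
    km = KMeans(n_clusters=k, n_init=10, max_iter=100, random_state=seed)
    km.fit(X)
    used: set[int] = set()
    medoids = []
    for center in km.cluster_centers_:
        order = np.argsort(np.linalg.norm(X - center, axis=1), kind="stable")
        pick = next(int(i) for i in order if int(i) not in used)
        used.add(pick)
        medoids.append(pool.sections[pick])
    return medoids


def select_dynamic(
    query: NoteSection, pool: Corpus, embedder: Embedder, k: int = 5
) -> list[NoteSection]:
    """The k pool sections most cosine-similar to the query, descending;
    ties broken by section_id."""
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} sections, need {k}")
    q = embedder.embed(query.text)
    qn = np.linalg.norm(q)
    sims = []
    for s in pool.sections:
        v = embedder.embed(s.text)
        vn = np.linalg.norm(v)
        sim = float(q @ v / (qn * vn)) if qn > 0 and vn > 0 else 0.0
        sims.append((-sim, s.section_id, s))
    sims.sort(key=lambda t: (t[0], t[1]))
    return [s for _, _, s in sims[:k]]


# ----------------------------------------------- error-analysis instructions

# Error-category taxonomy seeded by the qualitative error-review findings:
# tag -> cautionary description used in the instruction paragraph.
ERROR_CATEGORIES: dict[str, str] = {
    "misread-negation": (
        "treating negated mentions (e.g., 'no memory loss') as evidence of "
        "cognitive decline"
    ),
    "transient-cause": (
        "labeling transient, reversible causes such as medication-induced "
        "memory loss as positive; these are negative by definition"
    ),
    "over-conservative": (
        "failing to recognize cognitive decline despite strong evidence in "
        "the section"
    ),
    "overinterpretation": (
        "overinterpreting benign uses of cognitive vocabulary (e.g., sleep "
        "or mood described as stable) as evidence"
    ),
    "unrelated-condition": (
        "misattributing signs or symptoms to cognitive decline when they "
        "indicate an unrelated clinical condition"
    ),
    "misread-test-result": (
        "misreading cognitive testing results such as MoCA or MMSE scores"
    ),
}


def build_error_instructions(
    categorized_errors: Iterable[tuple[str, str]]
) -> str:
    """Deterministic paragraph enumerating distinct error categories,
    most frequent first (ties alphabetical), one directive per category.

    ``categorized_errors`` is an iterable of (section_id, category_tag);
    tags must come from :data:`ERROR_CATEGORIES`. Empty input yields "".
    """
    counts: dict[str, int] = {}
    for _sid, tag in categorized_errors:
        if tag not in ERROR_CATEGORIES:
            raise ValueError(
                f"unknown error category {tag!r}; known: {sorted(ERROR_CATEGORIES)}"
            )
        counts[tag] = counts.get(tag, 0) + 1
    if not counts:
        return ""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    lines = [
        "In earlier runs the model made the following kinds of errors; pay "
        "particular attention to avoiding each of them:"
    ]
    for tag, n in ordered:
        case_word = "case" if n == 1 else "cases"
        lines.append(f"- {ERROR_CATEGORIES[tag]} ({n} {case_word}).")
    return "\n".join(lines)


# ----------------------------------------------------------------- backends


@dataclass
class BackendConfig:
    """Backend selection and decoding contract.

    ``temperature`` is fixed at 0 for study-replication runs (deterministic
    decoding). The ``mock_*`` fields only apply to the mock backend.
    """

    backend_name: str = "mock"
    temperature: float = 0.0
    max_retries: int = 3
    seed: int = 0
    mock_error_rate: float = 0.0
    mock_unparseable_rate: float = 0.0
    mock_ineffective_rate: float = 0.0

    def validate_for_replication(self) -> None:
        if self.temperature != 0.0:
            raise ValueError("study-replication runs require temperature 0")


class MockBackend:
    """Deterministic stand-in for a remote LLM.

    The verdict equals the section's gold label, flipped independently with
    probability ``mock_error_rate`` (one seeded stream; call order fixes the
    sequence). Reported keywords are the planted cue phrases found verbatim
    in the text, falling back to matched screening keywords. Optional rates
    emit free-text (parseable-by-fallback) or ineffective replies so the
    triage path is exercised.
    """

    def __init__(self, config: BackendConfig, patterns: list[KeywordPattern] | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.patterns = patterns if patterns is not None else expert_patterns()

    def _keywords_for(self, section: NoteSection) -> list[str]:
        cues = [c for c in section.meta.get("cues", []) if c in section.text]
        if cues:
            return cues
        matched = matching_keywords(section.text, self.patterns)
        return matched or ["cognitive decline"]

    def classify(self, section: NoteSection, prompt: str | None = None) -> LLMReply:
        cfg = self.config
        flip = self.rng.random() < cfg.mock_error_rate
        verdict = section.label ^ int(flip)
        keywords = self._keywords_for(section) if verdict else []
        roll = self.rng.random()
        if roll < cfg.mock_ineffective_rate:
            raw = "I am unable to answer that."
        elif roll < cfg.mock_ineffective_rate + cfg.mock_unparseable_rate:
            kws = ", ".join(keywords) if keywords else "none"
            if verdict:
                raw = f"Yes, there is evidence of cognitive decline. Keywords: {kws}."
            else:
                raw = f"No evidence of cognitive decline. Keywords: {kws}."
        else:
            raw = json.dumps({VERDICT_KEY: bool(verdict), KEYWORDS_KEY: keywords})
        return triage_reply(raw)


BACKEND_REGISTRY: dict[str, Callable[[BackendConfig], object]] = {
    "mock": MockBackend,
}


def make_backend(config: BackendConfig):
    try:
        factory = BACKEND_REGISTRY[config.backend_name]
    except KeyError:
        raise ValueError(
            f"unknown backend {config.backend_name!r}; register an adapter in "
            f"BACKEND_REGISTRY (available: {sorted(BACKEND_REGISTRY)})"
        ) from None
    return factory(config)


def classify_with_backend(
    config_or_backend,
    section: NoteSection,
    prompt: str | None = None,
):
    """Send one prompt through a backend and triage the reply.

    Real adapters are retried ``max_retries`` times with exponential
    backoff; the mock backend never fails and never retries.
    """
    backend = (
        make_backend(config_or_backend)
        if isinstance(config_or_backend, BackendConfig)
        else config_or_backend
    )
    if isinstance(backend, MockBackend):
        return backend.classify(section, prompt)
    retries = getattr(backend, "max_retries", 3)
    delay = 0.1
    last: Exception | None = None
    for _ in range(retries + 1):
        try:
            return backend.classify(section, prompt)
        except Exception as exc:  # transport failure
            last = exc
            time.sleep(delay)
            delay *= 2
    raise RuntimeError(f"backend failed after {retries} retries") from last


# --------------------------------------------------------------- run driver

STRATEGIES = ("none", "random", "targeted", "kmeans", "dynamic")


def run_prompting(
    backend,
    template: PromptTemplate,
    corpus: Corpus,
    strategy: str = "none",
    pool: Corpus | None = None,
    embedder: Embedder | None = None,
    k: int = 5,
    seed: int = 0,
    prior_error_ids: set[str] | None = None,
) -> list[dict]:
    """Prompt the backend for every section; returns one log entry per
    section: section_id, prompt hash, raw reply, category, verdict, keywords.

    Static (hard) strategies pick the examples once for all queries; the
    dynamic (soft) strategy re-selects nearest neighbors per query.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy != "none" and pool is None:
        raise ValueError(f"strategy {strategy!r} requires an example pool")
    if strategy in ("kmeans", "dynamic") and embedder is None:
        embedder = HashingEmbedder()

    static_examples: list[NoteSection] = []
    if strategy == "random":
        static_examples = select_random(pool, k, seed)
    elif strategy == "targeted":
        static_examples = select_targeted(pool, prior_error_ids or set(), k, seed)
    elif strategy == "kmeans":
        static_examples = select_kmeans(pool, embedder, k, seed)

    entries = []
    for section in corpus.sections:
        if strategy == "dynamic":
            examples = select_dynamic(section, pool, embedder, k)
        elif strategy == "none":
            examples = []
        else:
            examples = static_examples
        tpl = template.with_examples(examples) if examples else template
        prompt = render_prompt(tpl, section)
        reply = classify_with_backend(backend, section, prompt)
        entries.append(
            {
                "section_id": section.section_id,
                "prompt_sha256": hashlib.sha256(prompt.encode("utf-8")).hexdigest(),
                "strategy": strategy,
                "raw": reply.raw,
                "category": reply.category,
                "verdict": reply.verdict,
                "keywords": reply.keywords,
            }
        )
    return entries


def replies_to_jsonl(entries: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(e, ensure_ascii=False, sort_keys=True) + "\n")


def replies_from_jsonl(path: str | Path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out


def entries_to_replies(entries: list[dict]) -> list[LLMReply]:
    return [
        LLMReply(e["raw"], e["category"], e["verdict"], e["keywords"]) for e in entries
    ]


# ---------------------------------------------------- manual template tuning


@dataclass
class TuningAttempt:
    template_name: str
    effective_rate: float


class TemplateTuningLog:
    """Bookkeeping for the manual template-tuning loop.

    Records each attempt's effective response rate and flags the stopping
    condition: a perfect rate, or three consecutive attempts without
    improvement over the running best. Paraphrasing itself stays manual.
    """

    def __init__(self, stall_limit: int = 3):
        self.stall_limit = stall_limit
        self.attempts: list[TuningAttempt] = []

    def record(self, template_name: str, rate: float) -> None:
        if not (0.0 <= rate <= 1.0):
            raise ValueError("effective rate must lie in [0, 1]")
        self.attempts.append(TuningAttempt(template_name, rate))

    @property
    def best(self) -> TuningAttempt | None:
        if not self.attempts:
            return None
        return max(self.attempts, key=lambda a: a.effective_rate)

    @property
    def attempts_since_improvement(self) -> int:
        best_rate = -1.0
        stall = 0
        for a in self.attempts:
            if a.effective_rate > best_rate:
                best_rate = a.effective_rate
                stall = 0
            else:
                stall += 1
        return stall

    @property
    def should_stop(self) -> bool:
        if not self.attempts:
            return False
        if self.best.effective_rate >= 1.0:
            return True
        return self.attempts_since_improvement >= self.stall_limit
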