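"""Synthetic labeled note-section corpora.

Real EHR note sections cannot be distributed, so every downstream stage is
exercised on generated corpora that reproduce the statistical shape of the
study datasets: a keyword-filtered development corpus (~4,949 sections,
mean 850 characters, range 26-9,323, 29.4% positive) and an unfiltered test
corpus (~1,996 sections, mean 464 characters, range 26-14,740, 3.5%
positive).

Positive sections embed 1-3 cognitive-decline cue phrases verbatim
(recorded in ``meta["cues"]`` so the learnable signal is recoverable by
substring search). Negative sections mix unrelated clinical filler with two
hard distractor families: negated cues ("no memory loss") and
transient-cause cues (medication-induced memory loss), the latter negative
by labeling rule. In keyword-filtered mode every section — positive or
negative — contains at least one screening keyword, as the keyword screen
used to build the development corpus guarantees.

Section lengths follow a log-normal law truncated to hard bounds by
resampling; text is scaffolded from template sentences padded with clinical
filler until the drawn target length is reached. Generation is a pure
function of the :class:`~notesift.corpus.CorpusSpec` (one integer seed
drives a single numpy Generator; sampling order is fixed).
"""

from __future__ import annotations

import numpy as np

from .corpus import Corpus, CorpusSpec, LengthLaw, NoteSection

# Cue phrases for positive sections: (phrase, contains-screening-keyword,
# relative usage weight). The boolean guarantees retention in filtered mode;
# the skewed weights emulate how memory complaints dominate real notes while
# drug names and formal diagnoses are rarer, which gives the downstream
# mean + 2*SD frequency reports a non-degenerate distribution.
POSITIVE_CUES: list[tuple[str, bool, float]] = [
    ("forgetfulness", True, 8.0),
    ("memory loss", True, 9.0),
    ("short term memory loss", True, 3.0),
    ("cognitive decline", True, 6.0),
    ("mild cognitive impairment", True, 4.0),
    ("dementia", True, 6.0),
    ("probable Alzheimer disease", True, 2.0),
    ("confusion", True, 5.0),
    ("disorientation", True, 3.0),
    ("poor recall", True, 4.0),
    ("word finding difficulties", True, 2.0),
    ("impaired executive functioning", False, 1.5),
    ("MoCA score of 22", True, 3.0),
    ("MMSE score of 24", True, 2.0),
    ("neuropsychological testing", True, 2.0),
    ("donepezil", False, 1.5),
    ("Aricept", False, 1.0),
    ("memory complaints", True, 5.0),
    ("delayed recall deficits", True, 1.5),
    ("cognitive impairment", True, 4.0),
]

# Sentence frames shared by positive and negative cores, so frame words
# ("reports", "notes", "referral") carry no class signal; only the slotted
# content phrase separates the classes.
SECTION_TEMPLATES = [
    "Patient reports {cue} over the past six months.",
    "Daughter notes {cue} at home.",
    "Assessment notes {cue} documented today.",
    "Referral placed for {cue}.",
    "Chart review significant for {cue}.",
    "Ongoing concern for {cue} discussed with family.",
]

# Benign content phrases containing a screening keyword: slotted into the
# shared frames they build filtered-mode negatives the screen retains.
BENIGN_KEYWORD_PHRASES = [
    "good sleep quality",
    "stable mood",
    "mild ankle swelling",
    "clear and fluent speech",
    "an independent drive to appointments",
    "a reassuring PHQ-2 score",
    "an unremarkable physical exam",
    "attention to wound care",
    "a two-pound weight loss",
    "normal renal function",
    "a question about medication refills",
]

# Benign keyword-free content phrases for unfiltered-mode negatives.
NEUTRAL_PHRASES = [
    "improved energy",
    "better appetite",
    "stable hypertension",
    "intermittent knee pain",
    "osteoarthritis of the right hip",
    "gradual weight gain",
    "seasonal allergies",
    "well-controlled diabetes",
]

NEGATED_CUE_SENTENCES = [
    "No memory loss reported.",
    "Denies confusion or disorientation.",
    "No evidence of cognitive decline on review.",
    "Memory intact; no forgetfulness noted.",
    "No word finding difficulties observed.",
]

TRANSIENT_CUE_SENTENCES = [
    "Transient memory loss attributed to medication, resolved after discontinuation.",
    "Brief confusion following anesthesia, fully resolved.",
    "Delirium secondary to urinary tract infection, now cleared.",
    "Medication-induced memory loss, improved off zolpidem.",
]

# Keyword-free clinical filler used only for length padding; appears in
# both classes with equal probability. None of these sentences match any
# expert screening pattern.
FILLER_SENTENCES = [
    "Blood pressure 128/76, heart rate 72.",
    "Continue lisinopril 10 mg daily.",
    "Knee pain improved with physical therapy.",
    "Abdomen soft and nontender.",
    "Influenza vaccination administered today.",
    "Follow-up visit in three months.",
    "Labs reviewed, A1c 6.8 and stable.",
    "Lungs clear to auscultation bilaterally.",
    "Medication list reconciled with the patient.",
    "Gait steady with a cane.",
    "Appetite and weight unchanged.",
    "No chest pain or shortness of breath.",
    "Right shoulder range of motion improved.",
    "Skin warm and dry without rash.",
    "Plan to repeat a basic metabolic panel.",
    "Lives with spouse in a single-story home.",
    "Denies fever, chills, or night sweats.",
    "Hypertension well controlled on current regimen.",
    "Colonoscopy up to date.",
    "Discussed diet and regular walking.",
]

# Default length laws matching the study datasets' printed characteristics.
FILTERED_LENGTH_LAW = LengthLaw(mean_chars=850.0, min_chars=26, max_chars=9323)
UNFILTERED_LENGTH_LAW = LengthLaw(mean_chars=464.0, min_chars=26, max_chars=14740)

# Share of negatives carrying each hard-distractor family.
NEGATED_SHARE = 0.10
TRANSIENT_SHARE = 0.10
# Benign keyword mentions occur in both classes (a positive section can
# also note good sleep): share of non-cue frame slots carrying one, and
# share of random unfiltered sections mentioning any at all.
BENIGN_SLOT_SHARE = 0.3
BENIGN_IN_UNFILTERED_SHARE = 0.2


def filtered_spec(n_sections: int = 4949, prevalence: float = 0.294, seed: int = 0) -> CorpusSpec:
    """Spec emulating the keyword-filtered development corpus."""
    return CorpusSpec(n_sections, prevalence, FILTERED_LENGTH_LAW, True, seed)


def unfiltered_spec(n_sections: int = 1996, prevalence: float = 0.035, seed: int = 0) -> CorpusSpec:
    """Spec emulating the unfiltered final-test corpus."""
    return CorpusSpec(n_sections, prevalence, UNFILTERED_LENGTH_LAW, False, seed)


def _draw_length(rng: np.random.Generator, law: LengthLaw) -> int:
    for _ in range(1000):
        val = rng.lognormal(law.mu, law.sigma)
        if law.min_chars <= val <= law.max_chars:
            return int(round(val))
    return int(np.clip(round(val), law.min_chars, law.max_chars))


def _pad_to_target(
    rng: np.random.Generator, parts: list[str], target: int, law: LengthLaw
) -> str:
    def cur() -> int:
        return len(" ".join(parts))

    while cur() < target:
        s = FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]
        if cur() + 1 + len(s) > law.max_chars:
            break
        parts.append(s)
    text = " ".join(parts)
    while len(text) < law.min_chars:
        text = text + " " + FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]
    if len(text) > law.max_chars:
        text = text[: law.max_chars].rstrip()
    return text


def _weighted_draws(
    rng: np.random.Generator, weights: np.ndarray, k: int, first_allowed=None
) -> list[int]:
    """k distinct weighted draws; the first draw may be restricted."""
    chosen: list[int] = []
    for j in range(k):
        w = weights.copy()
        w[chosen] = 0.0
        if j == 0 and first_allowed is not None:
            masked = np.zeros_like(w)
            masked[first_allowed] = w[first_allowed]
            w = masked
        chosen.append(int(rng.choice(len(w), p=w / w.sum())))
    return chosen


_CUE_WEIGHTS = np.array([w for _, _, w in POSITIVE_CUES])
_KEYWORD_BEARING = [i for i, (_, bearing, _) in enumerate(POSITIVE_CUES) if bearing]


def _frame(rng: np.random.Generator, phrase: str) -> str:
    tpl = SECTION_TEMPLATES[rng.integers(len(SECTION_TEMPLATES))]
    return tpl.format(cue=phrase)


def _framed_sentences(rng: np.random.Generator, phrases: list[str], k: int) -> list[str]:
    picks = rng.choice(len(phrases), size=min(k, len(phrases)), replace=False)
    return [_frame(rng, phrases[i]) for i in picks]


def _n_frames(rng: np.random.Generator) -> int:
    # same frame-count law for every section kind: frame words and sentence
    # counts carry no class signal
    return int(rng.integers(2, 5))


def _benign_neutral_fill(rng: np.random.Generator, k: int, benign_prob: float) -> list[str]:
    parts = []
    for _ in range(k):
        if rng.random() < benign_prob:
            parts += _framed_sentences(rng, BENIGN_KEYWORD_PHRASES, 1)
        else:
            parts += _framed_sentences(rng, NEUTRAL_PHRASES, 1)
    return parts


def _make_positive(rng: np.random.Generator, spec: CorpusSpec) -> tuple[str, dict]:
    k = _n_frames(rng)
    n_cues = min(int(rng.integers(1, 4)), k)
    first_allowed = _KEYWORD_BEARING if spec.keyword_filtered else None
    chosen = _weighted_draws(rng, _CUE_WEIGHTS, n_cues, first_allowed)
    cues = [POSITIVE_CUES[i][0] for i in chosen]
    parts = [_frame(rng, cue) for cue in cues]
    # remaining frame slots carry benign/neutral content, exactly as in
    # negatives, so only the cue phrases separate the classes
    parts += _benign_neutral_fill(rng, k - n_cues, BENIGN_SLOT_SHARE)
    meta = {"kind": "positive", "cues": cues, "negated": False, "transient": False}
    return " ".join(parts), meta


def _make_negative(rng: np.random.Generator, spec: CorpusSpec) -> tuple[str, dict]:
    k = _n_frames(rng)
    roll = rng.random()
    if roll < NEGATED_SHARE:
        n_neg = int(rng.integers(1, 3))
        picks = rng.choice(len(NEGATED_CUE_SENTENCES), size=n_neg, replace=False)
        parts = [NEGATED_CUE_SENTENCES[i] for i in picks]
        parts += _benign_neutral_fill(rng, max(k - n_neg, 0), BENIGN_SLOT_SHARE)
        meta = {"kind": "negated", "cues": [], "negated": True, "transient": False}
    elif roll < NEGATED_SHARE + TRANSIENT_SHARE:
        parts = [TRANSIENT_CUE_SENTENCES[rng.integers(len(TRANSIENT_CUE_SENTENCES))]]
        parts += _benign_neutral_fill(rng, k - 1, BENIGN_SLOT_SHARE)
        meta = {"kind": "transient", "cues": [], "negated": False, "transient": True}
    elif spec.keyword_filtered:
        # one guaranteed benign keyword mention keeps the section screenable
        parts = _framed_sentences(rng, BENIGN_KEYWORD_PHRASES, 1)
        parts += _benign_neutral_fill(rng, k - 1, BENIGN_SLOT_SHARE)
        meta = {"kind": "benign_keyword", "cues": [], "negated": False, "transient": False}
    else:
        # a share of random unfiltered sections mentions sleep, mood etc. in
        # passing — these are the negatives a keyword screen retains
        benign_prob = BENIGN_SLOT_SHARE if rng.random() < BENIGN_IN_UNFILTERED_SHARE else 0.0
        parts = _benign_neutral_fill(rng, k, benign_prob)
        if not parts:
            parts = _framed_sentences(rng, NEUTRAL_PHRASES, 1)
        meta = {"kind": "neutral", "cues": [], "negated": False, "transient": False}
    return " ".join(parts), meta


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a corpus per ``spec``; identical specs yield identical corpora."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sections = []
    for i in range(spec.n_sections):
        label = int(rng.random() < spec.prevalence)
        target = _draw_length(rng, spec.length_law)
        if label:
            core, meta = _make_positive(rng, spec)
        else:
            core, meta = _make_negative(rng, spec)
        text = _pad_to_target(rng, [core], target, spec.length_law)
        meta["target_chars"] = target
        sections.append(
            NoteSection(section_id=f"s{spec.seed}-{i:05d}", text=text, label=label, meta=meta)
        )
    return Corpus(sections, spec=spec)


def split_corpus(corpus: Corpus, sizes: list[int], seed: int) -> list[Corpus]:
    """Partition ``corpus`` into disjoint subsets of the requested sizes.

    A seeded shuffle assigns sections to consecutive chunks; within each
    subset the parent's original order is preserved. Sizes must be
    nonnegative and sum to at most the corpus size.
    """
    if any(s < 0 for s in sizes):
        raise ValueError("split sizes must be nonnegative")
    if sum(sizes) > len(corpus):
        raise ValueError(
            f"split sizes sum to {sum(sizes)} but corpus has {len(corpus)} sections"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(corpus))
    out = []
    start = 0
    for size in sizes:
        idx = sorted(perm[start : start + size])
        out.append(Corpus([corpus.sections[j] for j in idx]))
        start += size
    return out
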