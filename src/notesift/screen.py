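"""Expert-keyword screening of note sections.

The screen is a deliberately high-recall pre-filter: a section is retained
when its lower-cased text contains at least one keyword match. Keywords
ending in ``-`` are prefix stems ("forget-" matches "forgetful",
"forgetfulness", ...); all other keywords match as whole tokens. Matches
are token-initial: a word boundary must precede the stem, so "alter" does
not fire inside "realtor".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .corpus import Corpus


@dataclass(frozen=True)
class KeywordPattern:
    """One compiled screening keyword: a lower-cased stem and wildcard flag."""

    stem: str
    prefix_wildcard: bool

    @property
    def regex(self) -> re.Pattern:
        if self.prefix_wildcard:
            return re.compile(r"\b" + re.escape(self.stem))
        return re.compile(r"\b" + re.escape(self.stem) + r"\b")


def compile_patterns(keywords: list[str]) -> list[KeywordPattern]:
    """Turn raw keyword strings into :class:`KeywordPattern` objects.

    A trailing hyphen is stripped and recorded as a prefix wildcard.
    """
    keywords = [k.strip() for k in keywords if k and k.strip()]
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    patterns = []
    for kw in keywords:
        kw = kw.lower()
        wildcard = kw.endswith("-")
        stem = kw.rstrip("-") if wildcard else kw
        if not stem:
            raise ValueError(f"keyword {kw!r} has an empty stem")
        patterns.append(KeywordPattern(stem=stem, prefix_wildcard=wildcard))
    return patterns


def load_keywords(path: str | Path | None = None) -> list[str]:
    """Read a one-keyword-per-line file; default is the shipped expert list."""
    if path is None:
        text = resources.files("notesift.data").joinpath("expert_keywords.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def expert_patterns() -> list[KeywordPattern]:
    """The shipped expert screening list, compiled."""
    return compile_patterns(load_keywords())


def matching_keywords(text: str, patterns: list[KeywordPattern]) -> list[str]:
    """Stems of patterns that match ``text`` (case-insensitive), in list order."""
    low = text.lower()
    return [p.stem for p in patterns if p.regex.search(low)]


def text_matches(text: str, patterns: list[KeywordPattern]) -> bool:
    low = text.lower()
    return any(p.regex.search(low) for p in patterns)


def screen_sections(corpus: Corpus, patterns: list[KeywordPattern]) -> Corpus:
    """Retain exactly the sections with >= 1 keyword match, order preserved."""
    kept = [s for s in corpus.sections if text_matches(s.text, patterns)]
    return Corpus(kept, spec=corpus.spec)
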