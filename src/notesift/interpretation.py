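"""Model-interpretation keyword reports via the mean + 2*SD selection rule.

Three sources of evidence are summarized the same way the study's Table of
contributing keywords is organized:

* ``llm_output`` — frequency of each normalized keyword across effective
  LLM replies; a keyword is selected when its count strictly exceeds the
  population mean plus two standard deviations.
* ``attention`` — per section, tokens whose attention weight strictly
  exceeds that section's mean weight plus two standard deviations are
  flagged; the report aggregates flag counts across sections (the rule is
  within-section by construction, so the aggregated report's threshold is
  0: selected = flagged at least once).
* ``gain`` — total boosted-tree information gain per feature, thresholded
  at mean + 2*SD over the nonzero-gain features (the untouched vocabulary
  would otherwise dilute the threshold).

The standard deviation is the population SD (divide by n) by default;
``ddof`` is configurable. Keywords are normalized by lower-casing and
whitespace collapsing; multi-word phrases are kept intact.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import AttentionMap
from .prompting import LLMReply

SOURCES = ("llm_output", "attention", "gain", "expert")


def normalize_keyword(kw: str) -> str:
    return re.sub(r"\s+", " ", kw.strip().lower())


def mean_plus_2sd(values: np.ndarray, ddof: int = 0) -> float:
    values = np.asarray(values, dtype=float)
    return float(values.mean() + 2.0 * values.std(ddof=ddof))


@dataclass
class KeywordReport:
    """Keyword statistics for one source plus the mean+2SD selection."""

    source: str
    stats: dict[str, float]
    threshold: float
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        expected = sorted(k for k, v in self.stats.items() if v > self.threshold)
        if sorted(self.selected) != expected:
            raise ValueError("selected must equal {k: stats[k] > threshold}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["keyword", "source", "statistic", "threshold", "selected"])
            for kw in sorted(self.stats, key=lambda k: (-self.stats[k], k)):
                w.writerow(
                    [kw, self.source, self.stats[kw], self.threshold, int(kw in self.selected)]
                )


def _select(source: str, stats: dict[str, float], threshold: float) -> KeywordReport:
    selected = sorted(k for k, v in stats.items() if v > threshold)
    return KeywordReport(source, stats, threshold, selected)


def llm_keyword_report(replies: list[LLMReply], ddof: int = 0) -> KeywordReport:
    """Keywords appearing in effective replies more often than mean + 2*SD.

    Counting is per reply: each effective reply contributes each of its
    distinct normalized keywords once.
    """
    counts: dict[str, float] = {}
    for r in replies:
        if not r.effective or not r.keywords:
            continue
        for kw in {normalize_keyword(k) for k in r.keywords if k.strip()}:
            counts[kw] = counts.get(kw, 0.0) + 1.0
    if not counts:
        raise ValueError("no keywords found in any effective reply")
    threshold = mean_plus_2sd(np.array(list(counts.values())), ddof=ddof)
    return _select("llm_output", counts, threshold)


def flag_attention_tokens(
    amap: AttentionMap, ddof: int = 0
) -> list[str]:
    """Tokens in one section whose weight strictly exceeds the section's
    mean weight + 2*SD. Uniform maps flag nothing (SD = 0, strict rule)."""
    if len(amap.tokens) != len(amap.weights):
        raise ValueError("attention map tokens and weights are misaligned")
    if len(amap.tokens) == 0:
        return []
    w = np.asarray(amap.weights, dtype=float)
    cut = mean_plus_2sd(w, ddof=ddof)
    return [tok for tok, wt in zip(amap.tokens, w) if wt > cut]


def attention_keyword_report(maps: list[AttentionMap], ddof: int = 0) -> KeywordReport:
    """Aggregate within-section attention flags into a keyword report.

    The selection rule operates inside each section; the report's statistic
    is the number of sections in which a token was flagged, and every token
    flagged at least once is selected (threshold 0).
    """
    if not maps:
        raise ValueError("attention report requires at least one map")
    counts: dict[str, float] = {}
    for amap in maps:
        for tok in set(flag_attention_tokens(amap, ddof=ddof)):
            key = normalize_keyword(tok)
            counts[key] = counts.get(key, 0.0) + 1.0
    return _select("attention", counts, 0.0)


def gain_keyword_report(
    model, ddof: int = 0, include_zero_gain: bool = False
) -> KeywordReport:
    """Boosted-tree features with total gain above mean + 2*SD.

    By default the statistic population is restricted to features with
    nonzero gain (the untouched vocabulary would dilute the threshold);
    ``include_zero_gain=True`` thresholds over every exported feature
    instead, which is the appropriate population when the export itself
    already lists the full vocabulary.
    """
    gains = {normalize_keyword(k): float(v) for k, v in model.feature_gains().items()}
    if not include_zero_gain:
        gains = {k: v for k, v in gains.items() if v > 0}
    if not gains:
        raise ValueError("model exposes no nonzero feature gains")
    threshold = mean_plus_2sd(np.array(list(gains.values())), ddof=ddof)
    selected = sorted(k for k, v in gains.items() if v > threshold)
    if not include_zero_gain:
        return KeywordReport("gain", gains, threshold, selected)
    # keep the zero-gain features out of the reported stats table but honor
    # the vocabulary-wide threshold
    nonzero = {k: v for k, v in gains.items() if v > 0}
    return KeywordReport("gain", nonzero, threshold,
                         sorted(k for k in selected if k in nonzero))


def merged_report(
    reports: list[KeywordReport], expert_keywords: list[str]
) -> pd.DataFrame:
    """Keyword x source membership table, expert list included.

    One row per keyword; boolean membership per source; ``unique_to`` names
    the only source containing that keyword (empty when shared). Mirrors
    the observation that some sources surface terms (e.g., medications)
    absent everywhere else.
    """
    membership: dict[str, set[str]] = {}
    for kw in expert_keywords:
        membership.setdefault(normalize_keyword(kw), set()).add("expert")
    for rep in reports:
        for kw in rep.selected:
            membership.setdefault(normalize_keyword(kw), set()).add(rep.source)
    rows = []
    for kw in sorted(membership):
        srcs = membership[kw]
        rows.append(
            {
                "keyword": kw,
                **{s: s in srcs for s in SOURCES},
                "unique_to": next(iter(srcs)) if len(srcs) == 1 else "",
            }
        )
    return pd.DataFrame(rows, columns=["keyword", *SOURCES, "unique_to"])


def merged_report_markdown(table: pd.DataFrame) -> str:
    lines = ["| keyword | " + " | ".join(SOURCES) + " | unique_to |"]
    lines.append("|" + "---|" * (len(SOURCES) + 2))
    for _, row in table.iterrows():
        cells = [row["keyword"]] + [
            "x" if row[s] else "" for s in SOURCES
        ] + [row["unique_to"]]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
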