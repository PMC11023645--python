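"""Containers and I/O for labeled clinical note-section corpora.

A *note section* is one contiguous segment of a clinical note treated as a
single binary classification unit: positive when it documents any sign,
symptom, assessment or treatment evidence of cognitive decline, negative
otherwise (including transient causes such as medication-induced memory
loss, which are negative by definition).

Corpora round-trip through JSONL (one section per line), a two-column
id/label CSV, and a plain-text directory (one ``.txt`` file per section).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class ValidationError(ValueError):
    """Raised when a spec or section violates an invariant; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class NoteSection:
    """One clinical note section with its gold label and generation record.

    ``meta`` holds provenance for synthetic sections: planted cue phrases
    (``cues``), negation/transient flags, and the template id used. For
    sections read from external files it may be empty.
    """

    section_id: str
    text: str
    label: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError("label", f"must be 0 or 1, got {self.label!r}")
        if len(self.text) < 1:
            raise ValidationError("text", "must be non-empty")

    @property
    def n_chars(self) -> int:
        return len(self.text)

    def to_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "text": self.text,
            "label": self.label,
            "n_chars": self.n_chars,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoteSection":
        return cls(
            section_id=str(d["section_id"]),
            text=d["text"],
            label=int(d["label"]),
            meta=d.get("meta", {}) or {},
        )


@dataclass
class LengthLaw:
    """Log-normal character-length law with hard min/max bounds.

    ``mean_chars`` is the mean of the *untruncated* log-normal; out-of-bound
    draws are resampled, so the realized mean sits slightly below it when the
    upper bound bites.
    """

    mean_chars: float
    min_chars: int = 26
    max_chars: int = 9323
    sigma: float = 1.0

    def validate(self) -> None:
        if self.min_chars < 26:
            raise ValidationError("length_law.min_chars", "must be >= 26")
        if self.max_chars <= self.min_chars:
            raise ValidationError("length_law.max_chars", "must exceed min_chars")
        if not (self.mean_chars > 0):
            raise ValidationError("length_law.mean_chars", "must be positive")
        if not (self.sigma > 0):
            raise ValidationError("length_law.sigma", "must be positive")

    @property
    def mu(self) -> float:
        """Log-scale location parameter implied by the arithmetic mean."""
        return math.log(self.mean_chars) - self.sigma**2 / 2.0


@dataclass
class CorpusSpec:
    """Recipe for one synthetic corpus: size, prevalence, length law, mode."""

    n_sections: int
    prevalence: float
    length_law: LengthLaw = field(default_factory=lambda: LengthLaw(850.0))
    keyword_filtered: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections <= 0:
            raise ValidationError("n_sections", "must be > 0")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError("prevalence", "must lie in [0, 1]")
        if self.n_sections > 1 and not (0.0 < self.prevalence < 1.0):
            raise ValidationError(
                "prevalence", "must be strictly between 0 and 1 when n_sections > 1"
            )
        self.length_law.validate()


@dataclass
class Corpus:
    """Ordered collection of sections, optionally carrying its generating spec."""

    sections: list[NoteSection]
    spec: CorpusSpec | None = None

    def __post_init__(self) -> None:
        ids = [s.section_id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValidationError("sections", "section_ids must be unique")

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self) -> Iterator[NoteSection]:
        return iter(self.sections)

    def __getitem__(self, i: int) -> NoteSection:
        return self.sections[i]

    @property
    def ids(self) -> list[str]:
        return [s.section_id for s in self.sections]

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.sections]

    @property
    def texts(self) -> list[str]:
        return [s.text for s in self.sections]

    @property
    def realized_prevalence(self) -> float:
        if not self.sections:
            return float("nan")
        return sum(self.labels) / len(self.sections)

    def by_id(self, section_id: str) -> NoteSection:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def subset(self, ids: Iterable[str]) -> "Corpus":
        wanted = set(ids)
        return Corpus([s for s in self.sections if s.section_id in wanted])

    # ---------------------------------------------------------------- I/O

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for s in self.sections:
                fh.write(json.dumps(s.to_dict(), ensure_ascii=False, sort_keys=True))
                fh.write("\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "Corpus":
        sections = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    sections.append(NoteSection.from_dict(json.loads(line)))
        return cls(sections)

    def labels_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["section_id", "label"])
            for s in self.sections:
                w.writerow([s.section_id, s.label])

    @staticmethod
    def labels_from_csv(path: str | Path) -> dict[str, int]:
        out: dict[str, int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out[row["section_id"]] = int(row["label"])
        return out

    def to_text_dir(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for s in self.sections:
            (d / f"{s.section_id}.txt").write_text(s.text, encoding="utf-8")
        self.labels_to_csv(d / "labels.csv")

    @classmethod
    def from_text_dir(cls, directory: str | Path) -> "Corpus":
        d = Path(directory)
        labels = cls.labels_from_csv(d / "labels.csv")
        sections = [
            NoteSection(sid, (d / f"{sid}.txt").read_text(encoding="utf-8"), lab)
            for sid, lab in labels.items()
        ]
        return cls(sections)


def align_labels(ids: Sequence[str], table: dict[str, int]) -> list[int]:
    """Order a ``section_id -> label`` table along ``ids``; missing ids error."""
    missing = [i for i in ids if i not in table]
    if missing:
        raise KeyError(f"labels missing for section ids: {missing[:5]}")
    return [table[i] for i in ids]
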