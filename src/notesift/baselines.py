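"""Boosted-tree baseline classifier over lexical features.

Gradient-boosted trees (XGBoost) on tf-idf weighted word unigram+bigram
features, with per-feature total information gain exposed for the
interpretation stage. Scores are thresholded at 0.5, the boundary counting
as positive.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

from .corpus import Corpus
from .tokenize import TOKEN_RE

CUTOFF = 0.5  # probability >= CUTOFF is labeled positive


@dataclass(frozen=True)
class ModelScore:
    """A section's predicted probability and its label at the 0.5 cutoff."""

    section_id: str
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def label(self) -> int:
        return int(self.probability >= CUTOFF)


def scores_to_csv(scores: list[ModelScore], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "probability", "label"])
        for s in scores:
            w.writerow([s.section_id, f"{s.probability:.6f}", s.label])


def scores_from_csv(path: str | Path) -> list[ModelScore]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(ModelScore(row["section_id"], float(row["probability"])))
    return out


def scores_to_table(scores: list[ModelScore]) -> dict[str, int]:
    return {s.section_id: s.label for s in scores}


class GbtClassifier:
    """tf-idf + XGBoost section classifier.

    Parameters
    ----------
    weighting : "tfidf" | "tf"
        Feature weighting scheme.
    min_df : int
        Minimum document frequency for a feature to enter the vocabulary.
    seed : int
        Drives both the (deterministic) booster and the single-thread
        contract required for reproducibility.
    """

    FORMAT_VERSION = 1

    def __init__(
        self,
        weighting: str = "tfidf",
        ngram_range: tuple[int, int] = (1, 2),
        min_df: int = 2,
        n_estimators: int = 200,
        max_depth: int = 4,
        learning_rate: float = 0.2,
        seed: int = 0,
    ):
        self.weighting = weighting
        self.ngram_range = ngram_range
        self.min_df = min_df
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.seed = seed
        self._vectorizer = None
        self._booster = None

    def _make_vectorizer(self):
        cls = TfidfVectorizer if self.weighting == "tfidf" else CountVectorizer
        return cls(
            lowercase=True,
            token_pattern=TOKEN_RE.pattern,
            ngram_range=self.ngram_range,
            min_df=self.min_df,
        )

    def _train_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "seed": self.seed,
            "nthread": 1,
            "tree_method": "hist",
            "eval_metric": "logloss",
        }

    def fit(self, train: Corpus) -> "GbtClassifier":
        y = np.asarray(train.labels)
        if len(set(train.labels)) < 2:
            raise ValueError("training corpus must contain both classes")
        self._vectorizer = self._make_vectorizer()
        X = self._vectorizer.fit_transform(train.texts)
        dtrain = xgb.DMatrix(X, label=y)
        self._booster = xgb.train(
            self._train_params(), dtrain, num_boost_round=self.n_estimators
        )
        return self

    def _check_fitted(self) -> None:
        if self._booster is None:
            raise RuntimeError("model is not fitted")

    def predict_proba(self, corpus: Corpus) -> np.ndarray:
        self._check_fitted()
        X = self._vectorizer.transform(corpus.texts)
        return self._booster.predict(xgb.DMatrix(X))

    def predict(self, corpus: Corpus) -> list[ModelScore]:
        probs = self.predict_proba(corpus)
        return [
            ModelScore(sid, float(p)) for sid, p in zip(corpus.ids, probs)
        ]

    @property
    def vocabulary(self) -> list[str]:
        self._check_fitted()
        return list(self._vectorizer.get_feature_names_out())

    def feature_gains(self) -> dict[str, float]:
        """Total split gain per feature name; untouched features omitted
        (they carry zero gain)."""
        self._check_fitted()
        raw = self._booster.get_score(importance_type="total_gain")
        names = self.vocabulary
        out = {}
        for key, gain in raw.items():
            idx = int(key.lstrip("f"))
            out[names[idx]] = float(gain)
        return out

    # ------------------------------------------------------------ persistence

    def save(self, directory: str | Path) -> None:
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self._booster.save_model(d / "booster.json")
        vocab = self._vectorizer.vocabulary_
        idf = getattr(self._vectorizer, "idf_", None)
        meta = {
            "format_version": self.FORMAT_VERSION,
            "model": "gbt",
            "weighting": self.weighting,
            "ngram_range": list(self.ngram_range),
            "min_df": self.min_df,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "vocabulary": {k: int(v) for k, v in vocab.items()},
            "idf": None if idf is None else [float(x) for x in idf],
        }
        (d / "meta.json").write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "GbtClassifier":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        self = cls(
            weighting=meta["weighting"],
            ngram_range=tuple(meta["ngram_range"]),
            min_df=meta["min_df"],
            n_estimators=meta["n_estimators"],
            max_depth=meta["max_depth"],
            learning_rate=meta["learning_rate"],
            seed=meta["seed"],
        )
        vocab = {k: int(v) for k, v in meta["vocabulary"].items()}
        if meta["idf"] is not None:
            self._vectorizer = TfidfVectorizer(
                lowercase=True,
                token_pattern=TOKEN_RE.pattern,
                ngram_range=self.ngram_range,
                min_df=self.min_df,
                vocabulary=vocab,
            )
            # restore the fitted idf diagonal without refitting
            self._vectorizer.idf_ = np.asarray(meta["idf"], dtype=float)
            self._vectorizer._validate_vocabulary()
        else:
            self._vectorizer = CountVectorizer(
                lowercase=True,
                token_pattern=TOKEN_RE.pattern,
                ngram_range=self.ngram_range,
                min_df=self.min_df,
                vocabulary=vocab,
            )
            self._vectorizer._validate_vocabulary()
        self._booster = xgb.Booster()
        self._booster.load_model(d / "booster.json")
        return self


def chance_level_f1(prevalence: float, positive_rate: float | None = None) -> float:
    """Expected F1 of a guesser predicting positive with rate ``positive_rate``
    (default: prevalence-matched) on a corpus with the given prevalence.

    Precision of such a guesser equals the prevalence, recall equals its
    positive rate, so F1 = 2pq/(p+q); at q=p this is simply p.
    """
    q = prevalence if positive_rate is None else positive_rate
    if prevalence + q == 0:
        return 0.0
    return 2 * prevalence * q / (prevalence + q)
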