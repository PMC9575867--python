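"""Three-class tweet sentiment and the user-level sentiment strength.

Classification is pluggable: any callable taking a list of texts and
returning an equal-length list of ``negative`` / ``neutral`` / ``positive``
labels can stand in for the transformer used in production settings. The
bundled fallback is a deterministic signed-lexicon scorer (count of positive
terms minus negative terms; the sign decides the label, zero is neutral).

The sentiment strength of a user is driven by the majority class of their
tweets::

    strength = 1e-6                     if the majority class is neutral
             =  n_positive / total      if positive
             = -n_negative / total      if negative

Ties between majority classes resolve to neutral — the most conservative
choice, avoiding an arbitrary sign.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

NEGATIVE = "negative"
NEUTRAL = "neutral"
POSITIVE = "positive"
LABELS = (NEGATIVE, NEUTRAL, POSITIVE)

NEUTRAL_SENTINEL = 1e-6

Classifier = Callable[[Sequence[str]], Sequence[str]]

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


@dataclasses.dataclass(frozen=True)
class SentimentSummary:
    """Per-user three-class label counts."""

    user_id: str
    n_negative: int
    n_neutral: int
    n_positive: int

    def __post_init__(self) -> None:
        if min(self.n_negative, self.n_neutral, self.n_positive) < 0:
            raise ValueError("negative label count")
        if self.total < 1:
            raise ValueError("summary must cover at least one tweet")

    @property
    def total(self) -> int:
        return self.n_negative + self.n_neutral + self.n_positive


class LexiconClassifier:
    """Deterministic signed-lexicon sentiment scorer.

    Scores a text as the sum of term polarities (+1/-1) over its lowercased
    word tokens; positive score -> positive, negative -> negative, zero ->
    neutral. Serves as the offline stand-in for a trained three-class model.
    """

    def __init__(self, polarities: Mapping[str, int] | None = None) -> None:
        if polarities is None:
            polarities = load_polarity_lexicon()
        bad = {t: p for t, p in polarities.items() if p not in (-1, 1)}
        if bad:
            raise ValueError(f"polarities must be -1 or +1, got {bad}")
        self.polarities = {t.lower(): p for t, p in polarities.items()}

    def __call__(self, texts: Sequence[str]) -> list[str]:
        labels = []
        for text in texts:
            score = sum(
                self.polarities.get(tok.lower(), 0)
                for tok in _TOKEN_RE.findall(text)
            )
            labels.append(POSITIVE if score > 0 else NEGATIVE if score < 0 else NEUTRAL)
        return labels


def load_polarity_lexicon(path: str | Path | None = None) -> dict[str, int]:
    """Load a ``term,polarity`` CSV (polarity in {-1, +1}).

    Without a path, the small lexicon bundled with the package is used.
    """
    if path is None:
        source = resources.files("osascore.data").joinpath("sentiment_lexicon.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lex: dict[str, int] = {}
    for row in csv.DictReader(text.splitlines()):
        lex[row["term"].strip().lower()] = int(row["polarity"])
    return lex


def classify(texts: Sequence[str], classifier: Classifier | None = None) -> list[str]:
    """Label each text negative/neutral/positive, order preserved.

    A classifier emitting a label outside the three-class vocabulary is an
    error (the contract every plugin must honour).
    """
    if classifier is None:
        classifier = LexiconClassifier()
    labels = list(classifier(texts))
    if len(labels) != len(texts):
        raise ValueError(
            f"classifier returned {len(labels)} labels for {len(texts)} texts"
        )
    bad = sorted({lab for lab in labels if lab not in LABELS})
    if bad:
        raise ValueError(f"classifier returned out-of-vocabulary labels: {bad}")
    return labels


def summarize(user_id: str, labels: Iterable[str]) -> SentimentSummary:
    """Count labels into a per-user summary."""
    counts = {lab: 0 for lab in LABELS}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown label {lab!r}")
        counts[lab] += 1
    return SentimentSummary(
        user_id=user_id,
        n_negative=counts[NEGATIVE],
        n_neutral=counts[NEUTRAL],
        n_positive=counts[POSITIVE],
    )


def sentiment_strength(summary: SentimentSummary) -> float:
    """Signed majority-class fraction with the 1e-6 neutral sentinel."""
    counts = {
        NEGATIVE: summary.n_negative,
        NEUTRAL: summary.n_neutral,
        POSITIVE: summary.n_positive,
    }
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    if len(winners) > 1 or winners[0] == NEUTRAL:
        return NEUTRAL_SENTINEL
    if winners[0] == POSITIVE:
        return summary.n_positive / summary.total
    return -summary.n_negative / summary.total


def daily_majority_strength(
    user_id: str, dated_labels: Sequence[tuple["object", str]]
) -> float:
    """Alternative aggregation: majority label per day, then the strength
    formula over the day-level labels.

    ``dated_labels`` pairs each tweet's date with its label. Day-level ties
    resolve to neutral, as at the user level.
    """
    by_day: dict[object, dict[str, int]] = {}
    for day, lab in dated_labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        by_day.setdefault(day, {l: 0 for l in LABELS})[lab] += 1
    day_labels = []
    for counts in by_day.values():
        top = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == top]
        day_labels.append(NEUTRAL if len(winners) > 1 else winners[0])
    return sentiment_strength(summarize(user_id, day_labels))
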