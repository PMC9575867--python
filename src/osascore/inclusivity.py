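"""Community-keyword matching and inclusivity-and-diversity strength.

A community lexicon lists keywords referring to communities along five
axes — gender, age, cultural inference, ethnicity and employment sector —
optionally scoped to a country. A user's inclusivity-and-diversity strength
is the fraction of their tweets that mention at least one community::

    id_strength = n_community_mention_tweets / total_tweets
                = 1e-6   when no tweet mentions any community

Matching is case-insensitive on unicode word boundaries; multi-word keywords
match as contiguous phrases. A tweet counts once no matter how many keywords
it contains.

The lexicon bundled with the package (``data/community_lexicon.csv``) is a
synthetic, category-balanced stand-in (~100 terms, country="all") intended
for simulation and testing; real analyses should supply country-specific
lists, so strengths computed with the bundled file are not comparable to any
published per-country figure.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Sequence

from .types import TweetRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("gender", "age", "culture", "ethnicity", "employment")

ZERO_SENTINEL = 1e-6


@dataclasses.dataclass(frozen=True)
class LexiconEntry:
    keyword: str
    category: str
    country: str = "all"


@dataclasses.dataclass(frozen=True)
class CommunityLexicon:
    entries: tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon is empty")
        seen = set()
        for e in self.entries:
            key = (e.keyword, e.country)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)

    def keywords_for(self, country: str = "all") -> list[str]:
        """Keywords applicable to ``country`` (its own plus the "all" pool)."""
        return [
            e.keyword
            for e in self.entries
            if e.country == "all" or e.country == country
        ]


@dataclasses.dataclass(frozen=True)
class InclusivitySummary:
    user_id: str
    community_mention_tweets: int
    total_tweets: int

    def __post_init__(self) -> None:
        if self.total_tweets < 1:
            raise ValueError("summary must cover at least one tweet")
        if not 0 <= self.community_mention_tweets <= self.total_tweets:
            raise ValueError("community_mention_tweets out of [0, total_tweets]")


def _build_entries(rows: Sequence[dict]) -> CommunityLexicon:
    entries: list[LexiconEntry] = []
    seen = set()
    for row in rows:
        category = row["category"].strip().lower()
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown lexicon category {category!r}; expected one of {CATEGORIES}"
            )
        keyword = row["keyword"].strip().lower()
        country = (row.get("country") or "all").strip().lower()
        key = (keyword, country)
        if key in seen:
            logger.warning("duplicate lexicon entry %s dropped", key)
            continue
        seen.add(key)
        entries.append(LexiconEntry(keyword=keyword, category=category, country=country))
    return CommunityLexicon(entries=tuple(entries))


def load_lexicon(path: str | Path | None = None) -> CommunityLexicon:
    """Load a community lexicon from CSV or JSON.

    CSV header: ``keyword,category,country``. JSON: a list of objects with
    the same keys. Keywords are lowercased and deduplicated per (keyword,
    country); an unknown category is an error. Without a path the bundled
    synthetic stand-in lexicon is loaded.
    """
    if path is None:
        text = (
            resources.files("osascore.data")
            .joinpath("community_lexicon.csv")
            .read_text(encoding="utf-8")
        )
        return _build_entries(list(csv.DictReader(text.splitlines())))
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
    else:
        rows = list(csv.DictReader(path.read_text(encoding="utf-8").splitlines()))
    return _build_entries(rows)


def _keyword_pattern(keywords: Sequence[str]) -> re.Pattern:
    # One alternation anchored on word boundaries; longest-first so that
    # multi-word phrases win over their prefixes.
    parts = sorted(keywords, key=len, reverse=True)
    escaped = "|".join(re.escape(k) for k in parts)
    return re.compile(rf"\b(?:{escaped})\b", re.IGNORECASE | re.UNICODE)


def count_community_mentions(
    tweets: Sequence[TweetRecord],
    lexicon: CommunityLexicon,
    country: str = "all",
    user_id: str = "",
) -> InclusivitySummary:
    """Count tweets mentioning at least one community keyword.

    A tweet counts at most once however many keywords it contains. Matching
    is whole-word and case-insensitive: "nurse" does not match "nurses" —
    inflected variants must be listed explicitly.
    """
    if not tweets:
        raise ValueError("empty tweet list")
    keywords = lexicon.keywords_for(country)
    if not keywords:
        return InclusivitySummary(
            user_id=user_id, community_mention_tweets=0, total_tweets=len(tweets)
        )
    pattern = _keyword_pattern(keywords)
    n = sum(1 for t in tweets if pattern.search(t.text))
    return InclusivitySummary(
        user_id=user_id, community_mention_tweets=n, total_tweets=len(tweets)
    )


def id_strength(summary: InclusivitySummary) -> float:
    """Community-mention fraction, or the 1e-6 sentinel at zero mentions."""
    if summary.community_mention_tweets == 0:
        return ZERO_SENTINEL
    return summary.community_mention_tweets / summary.total_tweets
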