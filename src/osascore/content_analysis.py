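"""Top-k hashtag and mention frequency tables.

Frequencies count token usage: a tweet using the same hashtag twice
contributes two (switchable to tweet-presence counting). Rows sort by count
descending, then token lexicographically, so truncation at any k is
deterministic.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Literal, Sequence

from .tweet_io import extract_entities
from .types import TweetRecord


@dataclasses.dataclass(frozen=True)
class FrequencyTable:
    scope: str
    kind: Literal["hashtag", "mention"]
    rows: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for token, count in self.rows:
            if count < 1:
                raise ValueError(f"non-positive count for {token!r}")


def _top_tokens(
    tweets: Sequence[TweetRecord],
    kind: Literal["hashtag", "mention"],
    k: int,
    scope: str,
    unique_per_tweet: bool,
) -> FrequencyTable:
    if k < 1:
        raise ValueError("k must be >= 1")
    counter: Counter[str] = Counter()
    for t in tweets:
        hashtags, mentions = extract_entities(t.text)
        tokens = hashtags if kind == "hashtag" else mentions
        if unique_per_tweet:
            tokens = list(dict.fromkeys(tokens))
        counter.update(tokens)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return FrequencyTable(scope=scope, kind=kind, rows=tuple(ordered[:k]))


def top_hashtags(
    tweets: Sequence[TweetRecord],
    k: int = 10,
    scope: str = "all",
    unique_per_tweet: bool = False,
) -> FrequencyTable:
    """Most frequent hashtags (lowercased, ``#`` stripped) across tweets."""
    return _top_tokens(tweets, "hashtag", k, scope, unique_per_tweet)


def top_mentions(
    tweets: Sequence[TweetRecord],
    k: int = 10,
    scope: str = "all",
    unique_per_tweet: bool = False,
) -> FrequencyTable:
    """Most frequently mentioned accounts (lowercased, ``@`` stripped)."""
    return _top_tokens(tweets, "mention", k, scope, unique_per_tweet)


def table_rows(table: FrequencyTable) -> list[dict]:
    """Flatten a table for CSV export: scope, kind, token, count, rank."""
    return [
        {
            "scope": table.scope,
            "kind": table.kind,
            "token": token,
            "count": count,
            "rank": i + 1,
        }
        for i, (token, count) in enumerate(table.rows)
    ]
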