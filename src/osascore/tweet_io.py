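"""Reading, validating and canonicalizing tweet/profile records.

Two dialects are supported: JSON Lines shaped like Twitter API v2 tweet
objects (``text``, ``created_at``, ``public_metrics.{like_count,reply_count,
retweet_count,quote_count}``) and a flat CSV. A roster CSV maps account
handles to canonical users so that, e.g., a head of government tweeting from
a personal and an office account is analyzed as one user.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import ValidationError

from .types import TweetRecord, UserGroup, UserProfile

logger = logging.getLogger(__name__)

FLAT_CSV_FIELDS = [
    "tweet_id",
    "author_handle",
    "created_at",
    "text",
    "like_count",
    "reply_count",
    "retweet_count",
    "quote_count",
]

PROFILE_CSV_FIELDS = [
    "user_id",
    "handles",
    "display_name",
    "group",
    "country",
    "followers",
    "following",
    "listed_count",
    "total_tweet_count",
    "profile_created_at",
]

# Hashtag/mention grammar: marker followed by one or more unicode word
# characters; punctuation terminates the token.
_HASHTAG_RE = re.compile(r"#(\w+)", re.UNICODE)
_MENTION_RE = re.compile(r"@(\w+)", re.UNICODE)


class TweetParseError(ValueError):
    """A malformed or invalid record, annotated with its source line."""


def _parse_timestamp(value: str) -> dt.datetime:
    """Parse an RFC 3339 timestamp; naive values are taken as UTC."""
    ts = dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=dt.timezone.utc)
    return ts


def _record_from_api_v2(obj: dict, lineno: int) -> TweetRecord:
    try:
        metrics = obj["public_metrics"]
        return TweetRecord(
            tweet_id=str(obj.get("tweet_id") or obj["id"]),
            author_handle=str(obj.get("author_handle") or obj["author_id"]),
            created_at=_parse_timestamp(obj["created_at"]),
            text=obj["text"],
            like_count=metrics["like_count"],
            reply_count=metrics["reply_count"],
            retweet_count=metrics["retweet_count"],
            quote_count=metrics["quote_count"],
            lang=obj.get("lang"),
        )
    except KeyError as exc:
        raise TweetParseError(f"line {lineno}: missing field {exc}") from exc
    except ValidationError as exc:
        raise TweetParseError(f"line {lineno}: {exc}") from exc


def _record_from_flat_csv(row: dict, lineno: int) -> TweetRecord:
    try:
        return TweetRecord(
            tweet_id=row["tweet_id"],
            author_handle=row["author_handle"],
            created_at=_parse_timestamp(row["created_at"]),
            text=row["text"],
            like_count=int(row["like_count"]),
            reply_count=int(row["reply_count"]),
            retweet_count=int(row["retweet_count"]),
            quote_count=int(row["quote_count"]),
        )
    except (KeyError, TypeError) as exc:
        raise TweetParseError(f"line {lineno}: missing field {exc}") from exc
    except (ValidationError, ValueError) as exc:
        raise TweetParseError(f"line {lineno}: {exc}") from exc


def read_tweets(
    path: str | Path,
    dialect: Literal["api_v2_jsonl", "flat_csv"] = "api_v2_jsonl",
) -> list[TweetRecord]:
    """Read and validate tweet records from ``path``.

    Every record is validated against the TweetRecord invariants (counts
    non-negative, parsable timestamp). A malformed line raises
    :class:`TweetParseError` naming the line number. An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    if dialect == "api_v2_jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise TweetParseError(f"line {lineno}: invalid JSON: {exc}") from exc
                records.append(_record_from_api_v2(obj, lineno))
    elif dialect == "flat_csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):  # header is line 1
                records.append(_record_from_flat_csv(row, lineno))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if not records:
        logger.warning("no tweet records found in %s", path)
    return records


def write_tweets(
    records: Iterable[TweetRecord],
    path: str | Path,
    dialect: Literal["api_v2_jsonl", "flat_csv"] = "api_v2_jsonl",
) -> None:
    """Write records to the JSONL or flat-CSV dialect ``read_tweets`` accepts."""
    path = Path(path)
    if dialect == "api_v2_jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                obj = {
                    "id": rec.tweet_id,
                    "author_handle": rec.author_handle,
                    "created_at": rec.created_at.isoformat(),
                    "text": rec.text,
                    "public_metrics": {
                        "like_count": rec.like_count,
                        "reply_count": rec.reply_count,
                        "retweet_count": rec.retweet_count,
                        "quote_count": rec.quote_count,
                    },
                }
                if rec.lang is not None:
                    obj["lang"] = rec.lang
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif dialect == "flat_csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=FLAT_CSV_FIELDS)
            writer.writeheader()
            for rec in records:
                writer.writerow(
                    {
                        "tweet_id": rec.tweet_id,
                        "author_handle": rec.author_handle,
                        "created_at": rec.created_at.isoformat(),
                        "text": rec.text,
                        "like_count": rec.like_count,
                        "reply_count": rec.reply_count,
                        "retweet_count": rec.retweet_count,
                        "quote_count": rec.quote_count,
                    }
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_profiles(path: str | Path) -> list[UserProfile]:
    """Read user profiles from CSV (handles separated by ``;``)."""
    profiles = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            profiles.append(
                UserProfile(
                    user_id=row["user_id"],
                    handles=row["handles"].split(";"),
                    display_name=row.get("display_name", ""),
                    group=UserGroup(row["group"]),
                    country=row.get("country", ""),
                    followers=int(row["followers"]),
                    following=int(row["following"]),
                    listed_count=int(row["listed_count"]),
                    total_tweet_count=int(row["total_tweet_count"]),
                    profile_created_at=dt.date.fromisoformat(row["profile_created_at"]),
                )
            )
    return profiles


def write_profiles(profiles: Iterable[UserProfile], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=PROFILE_CSV_FIELDS)
        writer.writeheader()
        for p in profiles:
            writer.writerow(
                {
                    "user_id": p.user_id,
                    "handles": ";".join(p.handles),
                    "display_name": p.display_name,
                    "group": p.group.value,
                    "country": p.country,
                    "followers": p.followers,
                    "following": p.following,
                    "listed_count": p.listed_count,
                    "total_tweet_count": p.total_tweet_count,
                    "profile_created_at": p.profile_created_at.isoformat(),
                }
            )


def read_roster(path: str | Path) -> dict[str, dict]:
    """Read a roster CSV ``handle,user_id,group,country,primary``.

    Returns a mapping from handle to its roster row. ``primary`` marks the
    handle whose profile metrics represent a multi-handle user.
    """
    roster: dict[str, dict] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            handle = row["handle"]
            if handle in roster and roster[handle]["user_id"] != row["user_id"]:
                raise ValueError(
                    f"handle {handle!r} maps to two user_ids: "
                    f"{roster[handle]['user_id']!r} and {row['user_id']!r}"
                )
            roster[handle] = {
                "user_id": row["user_id"],
                "group": row.get("group", ""),
                "country": row.get("country", ""),
                "primary": str(row.get("primary", "")).strip().lower()
                in {"1", "true", "yes", "y"},
            }
    return roster


def write_roster(profiles: Iterable[UserProfile], path: str | Path) -> None:
    """Write the roster implied by a set of canonical profiles.

    The first handle of each profile is marked primary.
    """
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["handle", "user_id", "group", "country", "primary"]
        )
        writer.writeheader()
        for p in profiles:
            for i, handle in enumerate(p.handles):
                writer.writerow(
                    {
                        "handle": handle,
                        "user_id": p.user_id,
                        "group": p.group.value,
                        "country": p.country,
                        "primary": "true" if i == 0 else "false",
                    }
                )


def merge_handles(
    profiles: list[UserProfile],
    tweets: list[TweetRecord],
    roster: dict[str, dict],
) -> tuple[list[UserProfile], dict[str, list[TweetRecord]]]:
    """Merge per-handle profiles into canonical users and re-key tweets.

    Tweet streams of a multi-handle user are unioned; profile metrics
    (followers, listed count, ...) are taken from the roster-designated
    primary handle, never summed — summing follower counts would double-count
    overlapping audiences. Raises ``ValueError`` listing any tweet handle
    absent from the roster.
    """
    orphans = sorted({t.author_handle for t in tweets} - set(roster))
    if orphans:
        raise ValueError(f"handles not in roster: {orphans}")

    by_handle = {h: p for p in profiles for h in p.handles}

    # Group handles by canonical user, primary handle first.
    user_handles: dict[str, list[str]] = {}
    for handle, row in roster.items():
        user_handles.setdefault(row["user_id"], [])
        if row["primary"]:
            user_handles[row["user_id"]].insert(0, handle)
        else:
            user_handles[row["user_id"]].append(handle)

    tweets_by_user: dict[str, list[TweetRecord]] = {}
    for t in tweets:
        uid = roster[t.author_handle]["user_id"]
        tweets_by_user.setdefault(uid, []).append(t)

    canonical: list[UserProfile] = []
    for uid, handles in user_handles.items():
        source = next((by_handle[h] for h in handles if h in by_handle), None)
        if source is None:
            continue  # roster user without any supplied profile
        row = roster[handles[0]]
        canonical.append(
            UserProfile(
                user_id=uid,
                handles=handles,
                display_name=source.display_name,
                group=UserGroup(row["group"]) if row["group"] else source.group,
                country=row["country"] or source.country,
                followers=source.followers,
                following=source.following,
                listed_count=source.listed_count,
                total_tweet_count=sum(
                    by_handle[h].total_tweet_count for h in handles if h in by_handle
                ),
                profile_created_at=source.profile_created_at,
            )
        )
    return canonical, tweets_by_user


def extract_entities(text: str) -> tuple[list[str], list[str]]:
    """Extract (hashtags, mentions) as lowercase tokens, markers stripped.

    Order of appearance and within-text duplicates are preserved; a token is
    a maximal run of unicode word characters after ``#`` or ``@``. The text
    is lowercased before tokenizing, so extraction is idempotent under
    lowercasing of the input.
    """
    lowered = text.lower()
    hashtags = [m.group(1) for m in _HASHTAG_RE.finditer(lowered)]
    mentions = [m.group(1) for m in _MENTION_RE.finditer(lowered)]
    return hashtags, mentions


def profile_age_days(profile: UserProfile, window) -> int:
    """Whole days from profile creation to the window's reference date.

    The impact formula divides by the squared age, so a profile created on
    or after the reference date is an error.
    """
    age = (window.reference_date - profile.profile_created_at).days
    if age <= 0:
        raise ValueError(
            f"profile {profile.user_id!r} created on/after reference date "
            f"({profile.profile_created_at} >= {window.reference_date})"
        )
    return age


def filter_window(
    tweets: Iterable[TweetRecord], window, flag_only: bool = False
) -> list[TweetRecord]:
    """Return tweets whose UTC date falls inside the analysis window."""
    inside = [t for t in tweets if window.contains(t.date)]
    return inside
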