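import datetime as dt

import pytest

from osascore.types import AnalysisWindow, TweetRecord, UserGroup, UserProfile


@pytest.fixture
def window():
    """Short analysis window for toy corpora."""
    return AnalysisWindow(
        start_date=dt.date(2021, 1, 1),
        end_date=dt.date(2021, 3, 31),
        reference_date=dt.date(2021, 12, 31),
    )


@pytest.fixture
def make_tweet():
    counter = {"n": 0}

    def _make(
        text="hello",
        handle="@alice",
        date=dt.date(2021, 1, 15),
        likes=0,
        replies=0,
        retweets=0,
        quotes=0,
        hour=12,
    ):
        counter["n"] += 1
        return TweetRecord(
            tweet_id=f"fx{counter['n']:06d}",
            author_handle=handle,
            created_at=dt.datetime.combine(date, dt.time(hour), tzinfo=dt.timezone.utc),
            text=text,
            like_count=likes,
            reply_count=replies,
            retweet_count=retweets,
            quote_count=quotes,
        )

    return _make


@pytest.fixture
def make_profile():
    def _make(
        user_id="alice",
        group=UserGroup.LEADER,
        followers=1_000_000,
        following=100,
        listed_count=50,
        total_tweet_count=1000,
        created=dt.date(2010, 1, 1),
        country="all",
        handles=None,
    ):
        return UserProfile(
            user_id=user_id,
            handles=handles or [f"@{user_id}"],
            display_name=user_id,
            group=group,
            country=country,
            followers=followers,
            following=following,
            listed_count=listed_count,
            total_tweet_count=total_tweet_count,
            profile_created_at=created,
        )

    return _make
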