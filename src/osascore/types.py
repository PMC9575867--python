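"""Core domain types for the online-societal-association (OSA) pipeline.

The pipeline scores public social-media accounts (political leaders and
health organizations) during a health crisis on three components —
impact-weighted daily engagement, sentiment strength, and inclusivity-and-
diversity strength — whose product is the OSA composite. These models hold
the validated inputs and outputs of every stage.
"""

from __future__ import annotations

import datetime as dt
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, NonNegativeInt, model_validator


class UserGroup(str, enum.Enum):
    """Account category within which scores are normalized."""

    LEADER = "leader"
    HEALTH_ORG = "health_org"


class TweetRecord(BaseModel):
    """One tweet with its text, timestamp and the four public engagement counts."""

    model_config = ConfigDict(frozen=True)

    tweet_id: str
    author_handle: str
    created_at: dt.datetime
    text: str
    like_count: NonNegativeInt
    reply_count: NonNegativeInt
    retweet_count: NonNegativeInt
    quote_count: NonNegativeInt
    lang: Optional[str] = None

    @property
    def engagement(self) -> int:
        """Total public interactions: likes + replies + retweets + quotes."""
        return self.like_count + self.reply_count + self.retweet_count + self.quote_count

    @property
    def date(self) -> dt.date:
        """UTC calendar date of the tweet (all daily grouping is UTC)."""
        if self.created_at.tzinfo is not None:
            return self.created_at.astimezone(dt.timezone.utc).date()
        return self.created_at.date()


class UserProfile(BaseModel):
    """Account metadata feeding the user-impact score.

    ``followers``, ``following``, ``listed_count``, ``total_tweet_count`` and
    the profile age (days from ``profile_created_at`` to the analysis
    reference date) are the inputs of the tanh impact formula.
    ``total_tweet_count`` is the number of tweets collected for the account
    within the analysis window, not the lifetime statistic.
    """

    user_id: str
    handles: list[str] = Field(min_length=1)
    display_name: str = ""
    group: UserGroup
    country: str = ""
    followers: NonNegativeInt = 0
    following: NonNegativeInt = 0
    listed_count: NonNegativeInt = 0
    total_tweet_count: NonNegativeInt = 0
    profile_created_at: dt.date


class AnalysisWindow(BaseModel):
    """Half-open-free date window plus the profile-age anchor date.

    ``reference_date`` anchors profile-age computation (the last analysis
    day); it is usually the window end but may lie after it.
    """

    model_config = ConfigDict(frozen=True)

    start_date: dt.date
    end_date: dt.date
    reference_date: dt.date

    @model_validator(mode="after")
    def _check_order(self) -> "AnalysisWindow":
        if self.start_date > self.end_date:
            raise ValueError(
                f"start_date {self.start_date} is after end_date {self.end_date}"
            )
        return self

    def contains(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


# Default analysis window: the COVID-19 outbreak-to-vaccination period.
DEFAULT_WINDOW = AnalysisWindow(
    start_date=dt.date(2019, 12, 1),
    end_date=dt.date(2021, 12, 31),
    reference_date=dt.date(2021, 12, 31),
)
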