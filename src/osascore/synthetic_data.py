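"""Seeded synthetic tweet cohorts with the structure the scoring assumes.

The generator emulates a two-year corpus of tweets by political leaders and
national health organizations: per-user daily tweet streams (Poisson), heavy
-tailed per-tweet engagement (negative binomial) with event-driven spike
days, a categorical three-class sentiment mixture, and Bernoulli community-
keyword mentions. Sentiment is realized as an inserted lexicon token so the
bundled fallback classifier recovers the planted label exactly, making the
whole pipeline testable without a trained model.

Default parameters state a world resembling the published two-year corpus:
10 leaders and 10 health organizations over Dec 1 2019 – Dec 31 2021, with
Poisson tweet rates of 4.8/day (leaders) and 17.9/day (health organizations)
so group totals land near 36.8k and 136.7k tweets (~173k overall).

``plant_known_strengths`` builds cohorts whose sentiment and community-
mention fractions are placed exactly (not sampled), so the downstream
strengths are analytically known.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import DEFAULT_WINDOW, AnalysisWindow, TweetRecord, UserGroup, UserProfile

COUNTRIES = [
    "chile", "ireland", "uae", "finland", "canada",
    "colombia", "turkey", "spain", "sweden", "uk",
]

# Token pools. None of the filler/hashtag/mention tokens carry sentiment
# polarity, and none collide with the community lexicon, so planted labels
# and mention fractions survive the round trip through text.
FILLER_WORDS = [
    "update", "briefing", "measures", "vaccination", "testing", "guidance",
    "announcement", "campaign", "situation", "report", "daily", "numbers",
    "statement", "policy", "meeting", "response",
]
HASHTAG_POOL = [
    "covid19", "stayhome", "vaccines2021", "publichealth", "lockdown",
    "washyourhands", "flattenthecurve", "budget2021", "cop25", "tokyo2020",
]
MENTION_POOL = ["who", "healthagency", "govhealth", "pmoffice", "redcross", "unicef"]
KEYWORD_POOL = [
    "nurses", "children", "women", "elderly", "refugees",
    "teachers", "indigenous", "youth", "workers", "doctors",
]
POSITIVE_TOKEN = "wonderful"
NEGATIVE_TOKEN = "terrible"

# Total interactions are split across the four count fields with fixed
# likes-heavy proportions; only the sum enters the daily average, so the
# split is free.
ENGAGEMENT_SPLIT = (0.6, 0.1, 0.25, 0.05)  # likes, replies, retweets, quotes


class SpikeEvent(BaseModel):
    """An event day on which expected engagement is multiplied."""

    model_config = ConfigDict(frozen=True)

    date: dt.date
    multiplier: float = Field(gt=0)


class SimulationConfig(BaseModel):
    """Fully describes one synthetic cohort; a seed makes it reproducible."""

    seed: int = 0
    window: AnalysisWindow = DEFAULT_WINDOW
    n_leaders: int = Field(default=10, ge=0)
    n_health_orgs: int = Field(default=10, ge=0)
    leader_tweet_rate: float = Field(default=4.8, ge=0)
    health_org_tweet_rate: float = Field(default=17.9, ge=0)
    engagement_mean: float = Field(default=40.0, gt=0)
    engagement_dispersion: float = Field(default=0.3, gt=0)
    spike_schedule: list[SpikeEvent] = Field(
        default_factory=lambda: [
            SpikeEvent(date=dt.date(2020, 4, 10), multiplier=8.0),
            SpikeEvent(date=dt.date(2020, 10, 30), multiplier=10.0),
        ]
    )
    sentiment_mix: tuple[float, float, float] = (0.25, 0.45, 0.30)
    mention_prob: float = Field(default=0.4, ge=0, le=1)
    hashtag_prob: float = Field(default=0.5, ge=0, le=1)
    mention_token_prob: float = Field(default=0.3, ge=0, le=1)

    @model_validator(mode="after")
    def _check_mix(self) -> "SimulationConfig":
        mix = self.sentiment_mix
        if any(p < 0 or p > 1 for p in mix):
            raise ValueError(f"sentiment_mix probabilities must be in [0,1]: {mix}")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError(f"sentiment_mix must sum to 1, got {sum(mix)}")
        return self


def _spike_map(config: SimulationConfig) -> dict[dt.date, float]:
    mult: dict[dt.date, float] = {}
    for ev in config.spike_schedule:
        mult[ev.date] = mult.get(ev.date, 1.0) * ev.multiplier
    return mult


def _negbin_counts(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # Negative binomial parametrized by mean mu and size r:
    # variance = mu + mu^2 / r.
    r = dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _split_engagement(rng: np.random.Generator, total: int) -> tuple[int, int, int, int]:
    if total == 0:
        return 0, 0, 0, 0
    likes, replies, retweets, quotes = rng.multinomial(total, ENGAGEMENT_SPLIT)
    return int(likes), int(replies), int(retweets), int(quotes)


def _make_profile(
    rng: np.random.Generator, user_id: str, group: UserGroup, country: str
) -> UserProfile:
    followers = int(rng.lognormal(mean=13.0 if group is UserGroup.LEADER else 12.0, sigma=1.0)) + 1
    following = int(rng.integers(50, 2000))
    listed = int(max(1, followers * rng.uniform(1e-4, 1e-3)))
    created = dt.date(2008, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365 * 8)))
    return UserProfile(
        user_id=user_id,
        handles=[f"@{user_id}"],
        display_name=user_id.upper(),
        group=group,
        country=country,
        followers=followers,
        following=following,
        listed_count=listed,
        total_tweet_count=0,
        profile_created_at=created,
    )


def _compose_text(
    rng: np.random.Generator,
    config: SimulationConfig,
    label: str,
    with_keyword: Optional[bool] = None,
) -> str:
    words = list(rng.choice(FILLER_WORDS, size=3, replace=True))
    if label == "positive":
        words.insert(int(rng.integers(0, len(words) + 1)), POSITIVE_TOKEN)
    elif label == "negative":
        words.insert(int(rng.integers(0, len(words) + 1)), NEGATIVE_TOKEN)
    if with_keyword is None:
        with_keyword = rng.random() < config.mention_prob
    if with_keyword:
        words.append(str(rng.choice(KEYWORD_POOL)))
    if rng.random() < config.hashtag_prob:
        words.append("#" + str(rng.choice(HASHTAG_POOL)))
    if rng.random() < config.mention_token_prob:
        words.append("@" + str(rng.choice(MENTION_POOL)))
    return " ".join(words)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[UserProfile], list[TweetRecord]]:
    """Simulate a full cohort; byte-identical for a fixed seed.

    One global random stream, seeded once, drives every draw in a fixed user
    and day order, so the corpus is fully deterministic. Spike-day tweets
    draw engagement from the baseline negative binomial with the mean
    multiplied by the active event multiplier. Profiles carry the realized
    in-window tweet count in ``total_tweet_count``.
    """
    rng = np.random.default_rng(config.seed)
    spikes = _spike_map(config)
    labels = np.array(["negative", "neutral", "positive"])
    mix = np.asarray(config.sentiment_mix, dtype=float)

    users: list[tuple[str, UserGroup, float]] = []
    for i in range(config.n_leaders):
        users.append((f"leader_{i:02d}", UserGroup.LEADER, config.leader_tweet_rate))
    for i in range(config.n_health_orgs):
        users.append((f"org_{i:02d}", UserGroup.HEALTH_ORG, config.health_org_tweet_rate))

    profiles: list[UserProfile] = []
    tweets: list[TweetRecord] = []
    tid = 0
    for idx, (user_id, group, rate) in enumerate(users):
        country = COUNTRIES[idx % len(COUNTRIES)]
        profile = _make_profile(rng, user_id, group, country)
        n_user = 0
        day = config.window.start_date
        while day <= config.window.end_date:
            mult = spikes.get(day, 1.0)
            n_today = int(rng.poisson(rate))
            for _ in range(n_today):
                label = str(rng.choice(labels, p=mix))
                total_eng = _negbin_counts(
                    rng, config.engagement_mean * mult, config.engagement_dispersion
                )
                likes, replies, retweets, quotes = _split_engagement(rng, total_eng)
                seconds = int(rng.integers(0, 86400))
                tweets.append(
                    TweetRecord(
                        tweet_id=f"t{tid:08d}",
                        author_handle=f"@{user_id}",
                        created_at=dt.datetime.combine(
                            day, dt.time(), tzinfo=dt.timezone.utc
                        )
                        + dt.timedelta(seconds=seconds),
                        text=_compose_text(rng, config, label),
                        like_count=likes,
                        reply_count=replies,
                        retweet_count=retweets,
                        quote_count=quotes,
                    )
                )
                tid += 1
                n_user += 1
            day += dt.timedelta(days=1)
        profiles.append(profile.model_copy(update={"total_tweet_count": n_user}))
    return profiles, tweets


class PlantedTarget(BaseModel):
    """Exact per-user component targets for recovery tests.

    ``sentiment_fraction`` of the ``n_tweets`` carry ``sentiment_label``
    (the rest are neutral); ``mention_fraction`` carry a community keyword.
    Both fractions must be exactly expressible at ``n_tweets``. A fixed
    ``engagement_per_tweet`` makes the engagement component deterministic.
    """

    model_config = ConfigDict(frozen=True)

    group: UserGroup = UserGroup.LEADER
    n_tweets: int = Field(ge=1)
    sentiment_label: Literal["negative", "neutral", "positive"] = "positive"
    sentiment_fraction: float = Field(default=0.0, ge=0, le=1)
    mention_fraction: float = Field(default=0.0, ge=0, le=1)
    engagement_per_tweet: Optional[int] = Field(default=None, ge=0)


def _exact_count(fraction: float, n: int, what: str) -> int:
    count = fraction * n
    if abs(count - round(count)) > 1e-9:
        raise ValueError(
            f"{what} fraction {fraction} is not exactly expressible "
            f"with {n} tweets"
        )
    return int(round(count))


def plant_known_strengths(
    config: SimulationConfig,
    targets: dict[str, PlantedTarget],
) -> tuple[list[UserProfile], list[TweetRecord]]:
    """Build a cohort whose component scores are analytically known.

    Label and keyword counts are *placed*, not sampled: user ``u`` with
    target (label=positive, sentiment_fraction=0.6, n_tweets=10) has exactly
    6 positive and 4 neutral tweets, so the recovered sentiment strength is
    exactly 0.6. Tweets are laid one per day from the window start
    (wrapping), and all planted profiles within a group are identical so
    impact never confounds a recovery test.
    """
    if not targets:
        raise ValueError("no planted targets")
    rng = np.random.default_rng(config.seed)
    profiles: list[UserProfile] = []
    tweets: list[TweetRecord] = []
    tid = 0
    n_days = config.window.n_days
    for user_id in sorted(targets):
        t = targets[user_id]
        n_label = _exact_count(t.sentiment_fraction, t.n_tweets, "sentiment")
        n_mention = _exact_count(t.mention_fraction, t.n_tweets, "mention")
        profiles.append(
            UserProfile(
                user_id=user_id,
                handles=[f"@{user_id}"],
                display_name=user_id.upper(),
                group=t.group,
                country="all",
                followers=1_000_000,
                following=100,
                listed_count=500,
                total_tweet_count=t.n_tweets,
                profile_created_at=dt.date(2010, 1, 1),
            )
        )
        # Decouple the two plantings so sentiment and mentions are not
        # systematically co-located on the same tweets.
        mention_slots = set(rng.permutation(t.n_tweets)[:n_mention].tolist())
        for i in range(t.n_tweets):
            label = t.sentiment_label if i < n_label else "neutral"
            if t.engagement_per_tweet is not None:
                total_eng = t.engagement_per_tweet
            else:
                total_eng = _negbin_counts(
                    rng, config.engagement_mean, config.engagement_dispersion
                )
            likes, replies, retweets, quotes = _split_engagement(rng, total_eng)
            day = config.window.start_date + dt.timedelta(days=i % n_days)
            words = ["planted", "cohort", "tweet"]
            if label == "positive":
                words.append(POSITIVE_TOKEN)
            elif label == "negative":
                words.append(NEGATIVE_TOKEN)
            if i in mention_slots:
                words.append(KEYWORD_POOL[i % len(KEYWORD_POOL)])
            tweets.append(
                TweetRecord(
                    tweet_id=f"p{tid:08d}",
                    author_handle=f"@{user_id}",
                    created_at=dt.datetime.combine(
                        day, dt.time(hour=12), tzinfo=dt.timezone.utc
                    ),
                    text=" ".join(words),
                    like_count=likes,
                    reply_count=replies,
                    retweet_count=retweets,
                    quote_count=quotes,
                )
            )
            tid += 1
    return profiles, tweets
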