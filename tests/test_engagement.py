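"""User impact, daily engagement aggregation and the smoothing chain."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from osascore import engagement as eng
from osascore.engagement import (
    DailyEngagement,
    EngagementSeries,
    SmoothingParams,
    aggregate_daily,
    daily_avg_engagement,
    daily_series,
    remove_outliers,
    scale_impacts,
    smooth_series,
    tweetwise_engagement,
    user_engagement,
    user_impact,
)


class TestUserImpact:
    def test_zero_listed_count_gives_zero(self, make_profile, window):
        p = make_profile(listed_count=0)
        assert user_impact(p, window) == 0.0

    def test_unit_ratio_gives_zero(self, make_profile, window):
        # sqrt(100)/10 = 1, log10(1) = 0
        p = make_profile(followers=100, following=10)
        assert user_impact(p, window) == 0.0

    def test_high_precision_closed_form(self, make_profile, window):
        # tanh(log10(sqrt(1e6)/100) * 50 * 1000) / 1000**2 = tanh(5e4)/1e6;
        # frozen from a 30-digit symbolic evaluation: exactly 1e-6 in double.
        p = make_profile(
            followers=1_000_000,
            following=100,
            listed_count=50,
            total_tweet_count=1000,
            created=window.reference_date - dt.timedelta(days=1000),
        )
        assert user_impact(p, window) == 1e-6

    def test_zero_following_is_error(self, make_profile, window):
        with pytest.raises(ValueError, match="following"):
            user_impact(make_profile(following=0), window)

    def test_zero_followers_is_error(self, make_profile, window):
        with pytest.raises(ValueError, match="followers"):
            user_impact(make_profile(followers=0), window)

    def test_tweet_count_override(self, make_profile, window):
        p = make_profile(total_tweet_count=1000)
        assert user_impact(p, window, tweet_count=0) == 0.0

    @settings(max_examples=200, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        followers=st.integers(1, 10**8),
        following=st.integers(1, 10**6),
        listed=st.integers(0, 10**5),
        tweets=st.integers(0, 10**5),
        age=st.integers(1, 10**4),
    )
    def test_tanh_bound(self, make_profile, window, followers, following, listed, tweets, age):
        """|impact| < 1/age^2 for every valid profile (tanh range).

        Strict mathematically; in double precision tanh saturates to exactly
        1.0 for large arguments, so equality is attainable and asserted as <=.
        """
        p = make_profile(
            followers=followers,
            following=following,
            listed_count=listed,
            total_tweet_count=tweets,
            created=window.reference_date - dt.timedelta(days=age),
        )
        assert abs(user_impact(p, window)) <= 1.0 / age**2


class TestScaleImpacts:
    def test_min_max_by_hand(self):
        scores = scale_impacts([("a", 2.0), ("b", 1.0), ("c", 0.0)])
        assert {s.user_id: s.scaled_impact for s in scores} == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_degenerate_range_all_one(self):
        scores = scale_impacts([("a", 0.7), ("b", 0.7)])
        assert all(s.scaled_impact == 1.0 for s in scores)

    def test_singleton_group(self):
        (s,) = scale_impacts([("solo", -3.0)])
        assert s.scaled_impact == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            scale_impacts([])

    @settings(max_examples=50, deadline=None)
    @given(raws=st.lists(st.floats(-10, 10), min_size=2, max_size=20))
    def test_scaled_in_unit_interval_with_max_one(self, raws):
        scores = scale_impacts([(f"u{i}", r) for i, r in enumerate(raws)])
        vals = [s.scaled_impact for s in scores]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert max(vals) == 1.0


class TestDailyAverage:
    @pytest.mark.parametrize(
        "likes, replies, retweets, quotes, n, expected",
        [(10, 2, 4, 0, 1, 4.0), (0, 0, 0, 0, 1, 0.0), (8, 4, 4, 0, 2, 2.0)],
    )
    def test_examples(self, likes, replies, retweets, quotes, n, expected):
        day = DailyEngagement(
            date=dt.date(2021, 1, 1), likes=likes, replies=replies,
            retweets=retweets, quotes=quotes, daily_tweet_count=n,
        )
        assert daily_avg_engagement(day) == expected

    def test_zero_tweet_row_cannot_exist(self):
        with pytest.raises(ValueError, match="daily_tweet_count"):
            DailyEngagement(
                date=dt.date(2021, 1, 1), likes=0, replies=0, retweets=0,
                quotes=0, daily_tweet_count=0,
            )

    def test_scale_equivariance(self, make_tweet):
        """Doubling every raw count doubles every raw daily average."""
        tweets = [
            make_tweet(date=dt.date(2021, 1, d), likes=3 * d, replies=d, retweets=2, quotes=1)
            for d in range(1, 11)
        ]
        doubled = [
            t.model_copy(
                update={
                    "like_count": 2 * t.like_count,
                    "reply_count": 2 * t.reply_count,
                    "retweet_count": 2 * t.retweet_count,
                    "quote_count": 2 * t.quote_count,
                }
            )
            for t in tweets
        ]
        base = daily_series(aggregate_daily(tweets)).to_numpy()
        twice = daily_series(aggregate_daily(doubled)).to_numpy()
        np.testing.assert_array_equal(twice, 2 * base)


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        x = np.full(60, 3.25)
        out = smooth_series(x, SmoothingParams())
        # the degree-8 polynomial fit is numerically ill-conditioned; constants
        # survive the chain to ~1e-7 relative, not to machine precision
        np.testing.assert_allclose(out, x, rtol=1e-5)

    def test_savgol_window_degree_plus_one_is_identity(self):
        """window = degree + 1 fits an interpolating polynomial: identity."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, size=50)
        params = SmoothingParams(ema_span=1, z_threshold=1e9, savgol_window=9, savgol_degree=8)
        np.testing.assert_allclose(smooth_series(x, params), x, atol=1e-8)

    def test_spike_removed_by_outlier_stage(self):
        """A 100x single-day spike stops being the maximum after |z|>3 removal.

        Oracle: brute-force z-scores on the toy series confirm only the
        spike crosses the threshold.
        """
        x = np.ones(31)
        x[15] = 100.0
        z = (x - x.mean()) / x.std()
        assert np.abs(z).argmax() == 15 and abs(z[15]) > 3
        assert sum(abs(v) > 3 for v in z) == 1
        cleaned = remove_outliers(x, z_threshold=3.0)
        assert cleaned.argmax() != 15 or cleaned[15] == pytest.approx(1.0)
        assert cleaned.max() == pytest.approx(1.0)

    def test_short_series_error_mentions_window(self):
        with pytest.raises(ValueError, match="smaller window"):
            smooth_series(np.ones(10), SmoothingParams(savgol_window=31))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SmoothingParams(savgol_window=30)

    def test_window_must_exceed_degree(self):
        with pytest.raises(ValueError, match="exceed"):
            SmoothingParams(savgol_window=7, savgol_degree=8)

    def test_output_finite_on_spiky_series(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(5, size=200)
        x[50] = 1e6
        out = smooth_series(x, SmoothingParams())
        assert np.all(np.isfinite(out)) and len(out) == len(x)


class TestTweetwiseAndUserEngagement:
    def test_zero_impact_annihilates(self):
        np.testing.assert_array_equal(tweetwise_engagement([1.0, 2.0], 0.0), [0.0, 0.0])

    def test_unit_impact_identity(self):
        np.testing.assert_array_equal(tweetwise_engagement([1.5, 2.5], 1.0), [1.5, 2.5])

    def test_hand_product(self):
        np.testing.assert_array_equal(tweetwise_engagement([2.0, 4.0], 0.5), [1.0, 2.0])

    @pytest.mark.parametrize("weighted, expected", [([1, 2, 3], 2.0), ([5], 5.0), ([0, 0], 0.0)])
    def test_user_mean(self, weighted, expected):
        series = _series(np.asarray(weighted, dtype=float))
        assert user_engagement(series) == expected

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            user_engagement(_series(np.array([])))


def _series(weighted: np.ndarray) -> EngagementSeries:
    dates = [dt.date(2021, 1, 1) + dt.timedelta(days=i) for i in range(len(weighted))]
    return EngagementSeries(
        user_id="u", dates=dates, raw_daily_avg=weighted, smoothed_daily_avg=weighted,
        impact_weighted=weighted, user_mean=float(weighted.mean()) if len(weighted) else 0.0,
        smoothing_params=SmoothingParams(),
    )


@settings(max_examples=50, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 50), st.integers(0, 4)),
        min_size=1, max_size=30,
    ),
    bump=st.integers(1, 20),
    data=st.data(),
)
def test_monotonicity_without_smoothing(make_tweet, counts, bump, data):
    """Raising any single like count never lowers the user engagement mean
    (smoothing off, positive impact)."""
    tweets = [
        make_tweet(date=dt.date(2021, 1, 1) + dt.timedelta(days=day), likes=likes, replies=rep)
        for day, likes, rep in counts
    ]
    idx = data.draw(st.integers(0, len(tweets) - 1))
    bumped = list(tweets)
    bumped[idx] = bumped[idx].model_copy(
        update={"like_count": bumped[idx].like_count + bump}
    )

    def mean_eng(ts):
        weighted = tweetwise_engagement(daily_series(aggregate_daily(ts)).to_numpy(), 0.7)
        return float(np.mean(weighted))

    assert mean_eng(bumped) >= mean_eng(tweets) - 1e-12


def test_vectorized_daily_aggregation_matches_per_tweet_loop(make_tweet):
    """Dense-calendar daily averages equal a brute-force per-tweet loop."""
    rng = np.random.default_rng(42)
    start = dt.date(2021, 1, 1)
    tweets = [
        make_tweet(
            date=start + dt.timedelta(days=int(rng.integers(0, 30))),
            likes=int(rng.integers(0, 100)),
            replies=int(rng.integers(0, 20)),
            retweets=int(rng.integers(0, 50)),
            quotes=int(rng.integers(0, 10)),
        )
        for _ in range(200)
    ]
    # oracle: plain dict accumulation and Eq-by-hand daily average
    acc = {}
    for t in tweets:
        d = t.created_at.date()
        tot, n = acc.get(d, (0, 0))
        acc[d] = (tot + t.like_count + t.reply_count + t.retweet_count + t.quote_count, n + 1)
    expected = {d: tot / (4 * n) for d, (tot, n) in acc.items()}

    series = daily_series(aggregate_daily(tweets))
    for d, val in expected.items():
        assert series[np.datetime64(d)] == val
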