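"""End-to-end orchestration: from canonical users and tweets to OSA results.

The score pipeline, per canonical user:

1. restrict tweets to the analysis window and count them (this count feeds
   the impact formula);
2. compute the raw user impact and min-max scale it within the user group;
3. build the dense daily engagement series, smooth it (EMA → z-score →
   Savitzky–Golay), weight by the (scaled) impact and average over days;
4. classify tweet sentiment and compute the signed sentiment strength;
5. match community keywords and compute the inclusivity strength;
6. multiply the three components into the raw OSA and normalize within each
   user group by the group maximum.

The pipeline is a pure function of its inputs and configuration: reruns on
the same files produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field

from . import engagement as eng
from . import inclusivity as incl
from . import osa as osa_mod
from . import sentiment as senti
from .types import DEFAULT_WINDOW, AnalysisWindow, TweetRecord, UserGroup, UserProfile

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Scoring configuration; every default mirrors the published setup
    where one is stated (EMA span 151, Savitzky–Golay degree 8, top-10
    content tables, Dec 2019 – Dec 2021 window), and is documented where the
    choice was open (z threshold 3, filter window 31 days)."""

    window: AnalysisWindow = DEFAULT_WINDOW
    ema_span: int = 151
    z_threshold: float = 3.0
    savgol_window: int = 31
    savgol_degree: int = 8
    smoothing: bool = True
    use_scaled_impact: bool = True
    normalization: Literal["group_max", "min_max"] = "group_max"
    sentiment_mode: Literal["window", "daily_majority"] = "window"
    k: int = Field(default=10, ge=1)

    def smoothing_params(self) -> eng.SmoothingParams:
        return eng.SmoothingParams(
            ema_span=self.ema_span,
            z_threshold=self.z_threshold,
            savgol_window=self.savgol_window,
            savgol_degree=self.savgol_degree,
        )


@dataclasses.dataclass
class UserScore:
    """All per-user intermediates the pipeline produced."""

    result: osa_mod.OSAResult
    impact: eng.ImpactScore
    series: eng.EngagementSeries
    sentiment_summary: senti.SentimentSummary
    inclusivity_summary: incl.InclusivitySummary


def _adjusted_params(
    params: eng.SmoothingParams, series_len: int
) -> Optional[eng.SmoothingParams]:
    """Shrink the Savitzky–Golay window to fit a short series.

    Returns params usable on ``series_len`` points, or None when no odd
    window larger than the polynomial degree fits (smoothing is then skipped
    with a warning).
    """
    if series_len > params.savgol_window:
        return params
    win = series_len - 1
    if win % 2 == 0:
        win -= 1
    if win <= params.savgol_degree:
        return None
    logger.warning(
        "series of %d points shorter than savgol_window=%d; shrinking window to %d",
        series_len, params.savgol_window, win,
    )
    return dataclasses.replace(params, savgol_window=win)


def score_users(
    profiles: Sequence[UserProfile],
    tweets_by_user: dict[str, list[TweetRecord]],
    config: PipelineConfig = PipelineConfig(),
    classifier: Optional[senti.Classifier] = None,
    lexicon: Optional[incl.CommunityLexicon] = None,
) -> list[UserScore]:
    """Score every canonical user and normalize OSA within each group."""
    if lexicon is None:
        lexicon = incl.load_lexicon()
    params = config.smoothing_params()

    # Window restriction + in-window tweet counts feed the impact formula.
    window_tweets: dict[str, list[TweetRecord]] = {}
    for p in profiles:
        ts = [t for t in tweets_by_user.get(p.user_id, []) if config.window.contains(t.date)]
        if not ts:
            raise ValueError(f"user {p.user_id!r} has no tweets inside the window")
        window_tweets[p.user_id] = sorted(ts, key=lambda t: (t.created_at, t.tweet_id))

    # Impacts, scaled per group.
    impacts_by_group: dict[UserGroup, list[tuple[str, float]]] = {}
    for p in profiles:
        raw = eng.user_impact(p, config.window, tweet_count=len(window_tweets[p.user_id]))
        impacts_by_group.setdefault(p.group, []).append((p.user_id, raw))
    impact_index: dict[str, eng.ImpactScore] = {}
    for group, pairs in impacts_by_group.items():
        for score in eng.scale_impacts(pairs):
            impact_index[score.user_id] = score

    scores: list[UserScore] = []
    results_by_group: dict[UserGroup, list[osa_mod.OSAResult]] = {}
    for p in profiles:
        ts = window_tweets[p.user_id]
        impact = impact_index[p.user_id]
        weight = impact.scaled_impact if config.use_scaled_impact else impact.raw_impact

        dense = eng.daily_series(eng.aggregate_daily(ts))
        raw = dense.to_numpy()
        smoothed = raw.copy()
        if config.smoothing:
            fitted = _adjusted_params(params, len(raw))
            if fitted is not None:
                smoothed = eng.smooth_series(raw, fitted)
            else:
                logger.warning(
                    "user %s: series too short for any Savitzky–Golay window; "
                    "smoothing skipped", p.user_id,
                )
        weighted = eng.tweetwise_engagement(smoothed, weight)
        series = eng.EngagementSeries(
            user_id=p.user_id,
            dates=[d.date() for d in dense.index],
            raw_daily_avg=raw,
            smoothed_daily_avg=smoothed,
            impact_weighted=weighted,
            user_mean=float(weighted.mean()),
            smoothing_params=params,
        )
        engagement_score = eng.user_engagement(series)

        labels = senti.classify([t.text for t in ts], classifier)
        summary = senti.summarize(p.user_id, labels)
        if config.sentiment_mode == "daily_majority":
            strength = senti.daily_majority_strength(
                p.user_id, list(zip((t.date for t in ts), labels))
            )
        else:
            strength = senti.sentiment_strength(summary)

        inc_summary = incl.count_community_mentions(
            ts, lexicon, country=p.country or "all", user_id=p.user_id
        )
        inc_strength = incl.id_strength(inc_summary)

        result = osa_mod.OSAResult(
            user_id=p.user_id,
            group=p.group,
            country=p.country,
            daily_avg_eng_user=engagement_score,
            senti_strength=strength,
            id_strength=inc_strength,
            raw_osa=osa_mod.compose_osa(engagement_score, strength, inc_strength),
            normalized_osa=None,
        )
        results_by_group.setdefault(p.group, []).append(result)
        scores.append(
            UserScore(
                result=result,
                impact=impact,
                series=series,
                sentiment_summary=summary,
                inclusivity_summary=inc_summary,
            )
        )

    for group, results in results_by_group.items():
        normalized = osa_mod.normalize_within_group(results, mode=config.normalization)
        by_id = {r.user_id: r for r in normalized}
        for s in scores:
            if s.result.group is group:
                s.result = by_id[s.result.user_id]
    return scores


def results_table(scores: Sequence[UserScore]) -> list[dict]:
    """Flatten scores for CSV/JSON export."""
    return [
        {
            "user_id": s.result.user_id,
            "group": s.result.group.value,
            "country": s.result.country,
            "raw_impact": s.impact.raw_impact,
            "scaled_impact": s.impact.scaled_impact,
            "daily_avg_eng_user": s.result.daily_avg_eng_user,
            "senti_strength": s.result.senti_strength,
            "id_strength": s.result.id_strength,
            "raw_osa": s.result.raw_osa,
            "normalized_osa": s.result.normalized_osa,
        }
        for s in scores
    ]
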