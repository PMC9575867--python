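"""The online-societal-association composite: product, normalization, ranking.

The raw OSA of a user is the equally-weighted product of the three
components::

    osa = engagement * sentiment_strength * id_strength

Engagement is the impact-weighted mean daily engagement; sentiment strength
is signed (a negative-majority user contributes a negative OSA); the
inclusivity strength is positive (1e-6 sentinel at zero mentions). Scores
are normalized within each user group — leaders and health organizations are
never scaled against each other — by dividing by the group maximum, so the
top user of each group scores exactly 1.0 and negatives stay negative.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

from .types import UserGroup


@dataclasses.dataclass
class OSAResult:
    user_id: str
    group: UserGroup
    country: str
    daily_avg_eng_user: float
    senti_strength: float
    id_strength: float
    raw_osa: float
    normalized_osa: float | None = None


def compose_osa(eng: float, senti: float, incl: float) -> float:
    """Raw composite: plain product of the three equally-weighted components."""
    if incl <= 0:
        raise ValueError(f"id_strength must be positive, got {incl}")
    if abs(senti) > 1:
        raise ValueError(f"|senti_strength| must be <= 1, got {senti}")
    return eng * senti * incl


def normalize_within_group(
    results: Sequence[OSAResult],
    mode: Literal["group_max", "min_max"] = "group_max",
) -> list[OSAResult]:
    """Scale raw OSA within one user group so the group maximum is 1.0.

    ``group_max`` (default) divides by the group's maximum raw OSA,
    preserving ratios and signs; ``min_max`` maps the group range onto
    [0, 1]. All scores non-positive is an error — report raw values instead.
    """
    if not results:
        raise ValueError("empty group")
    groups = {r.group for r in results}
    if len(groups) > 1:
        raise ValueError(f"normalize one group at a time, got {sorted(g.value for g in groups)}")
    raws = [r.raw_osa for r in results]
    top = max(raws)
    if top <= 0:
        raise ValueError(
            "all raw OSA values are <= 0 in group; normalization undefined"
        )
    out = []
    for r in results:
        if mode == "group_max":
            norm = r.raw_osa / top
        elif mode == "min_max":
            lo = min(raws)
            norm = 1.0 if top == lo else (r.raw_osa - lo) / (top - lo)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        out.append(dataclasses.replace(r, normalized_osa=norm))
    return out


def rank_report(results: Sequence[OSAResult], k: int = 5) -> list[OSAResult]:
    """Top-k of a group, descending by normalized OSA, ties by user_id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    key = lambda r: (
        -(r.normalized_osa if r.normalized_osa is not None else r.raw_osa),
        r.user_id,
    )
    return sorted(results, key=key)[:k]
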