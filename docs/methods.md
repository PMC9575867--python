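# Methods

This note documents the model implemented by `osascore`, the parameters that
matter, the synthetic-data generator's stated world, and the numerical and
design choices made where the procedure was genuinely open.

## The composite score

The online societal association of a user over an analysis window is the
product of three equally weighted components:

```
OSA_u = dailyAvgEng_u × sentiStrength_u × iDStrength_u
```

The product form means any component near zero collapses the composite: a
neutral-majority account (sentiment sentinel `1e-6`) or an account that never
references any community (inclusivity sentinel `1e-6`) scores orders of
magnitude below an account that is strong on all three axes. The sign of the
composite follows the sentiment sign — a negative-majority account carries a
negative OSA, which we preserve through normalization rather than clamp,
because the sign is information.

### Engagement with impact

1. **Daily average engagement.** For each UTC calendar day on which the user
   tweeted, `(likes + replies + retweets + quotes) / (4 × dailyTweetCount)`.
   The divisor's factor 4 is the number of interaction kinds in the
   numerator, making the value an average per interaction-kind per tweet.
   Days with zero tweets emit no row — the ratio is undefined there — and the
   calendar between the first and last active day is filled by linear
   interpolation so downstream filters see an evenly sampled series. Leading/
   trailing empty days outside the active span are not fabricated.

2. **Smoothing chain**, in order: exponential moving average → z-score
   outlier replacement → Savitzky–Golay filter. The order follows the
   procedure's description; each stage is configurable.

3. **User impact.**

   ```
   impact = tanh( log10(√followers / following) × listedCount × tweetCount ) / profileAge²
   ```

   The follower/following ratio under `√`/`log10` tames outliers; listed
   count proxies earned curation; `tweetCount` is the number of tweets
   *collected in the window* (not the lifetime statistic), per the formula's
   definition of its terms; dividing by the squared profile age (days to the
   reference date) favours accounts that earned influence quickly. `tanh`
   bounds the numerator, so |impact| ≤ 1/age² (equality only through float
   saturation of tanh). `following = 0` and `followers = 0` are rejected —
   the ratio and the log are undefined.

   Raw impacts are min-max scaled to [0, 1] *within each user group*, so the
   group's most impactful account maps to exactly 1. Degenerate ranges
   (singleton group, all-equal impacts) map everyone to 1.0, keeping the
   "top account = 1.000" convention. Note min-max sends the group's least
   impactful account to 0, which zeroes its weighted engagement and OSA;
   that is a property of the published convention, not an accident.

4. **Weighting and averaging.** The smoothed daily series is multiplied by
   the scaled impact and averaged over the dense calendar days, giving
   `dailyAvgEng_u`.

Two points were open and are config-exposed:

- *Smoothing before or after impact weighting*: smoothing is applied to the
  raw daily series, before multiplying by the (constant) impact. For the
  default group-max normalization the choice is mostly immaterial — the
  impact is a constant factor per user — but it is a flag.
- *Raw vs scaled impact in the weighting*: the pipeline uses the scaled
  [0, 1] impact by default (`use_scaled_impact=True`), matching the
  convention in which reported impacts are on the unit scale. Raw impacts of
  realistic profiles are ~1e-6 and would make all OSA magnitudes opaque;
  within-group rankings are unchanged for the top account either way.

### Sentiment strength

Tweets are classified into {negative, neutral, positive} by a pluggable
classifier: any callable mapping a list of texts to an equal-length list of
those labels. The bundled fallback is a deterministic signed lexicon
(`data/sentiment_lexicon.csv`, 40 terms at polarity ±1): the text score is
the sum of term polarities over lowercased word tokens, and the sign gives
the label. It is *not* a competitive sentiment model — it exists so the
pipeline is exactly testable offline; production use should plug in a
trained three-class model via the classifier interface.

User strength: with the majority class positive, `n_pos/total`; negative,
`−n_neg/total`; neutral, the sentinel `1e-6`. Ties between majority classes
resolve to neutral — the most conservative rule, avoiding an arbitrary sign.
The primary mode computes one summary over the whole window; an optional
`daily_majority` mode first takes the majority label per day and then applies
the formula to the day-level labels (the day-level phrasing and the single
per-user figure are mutually inconsistent in the source procedure, so both
readings are provided; the window mode is the default).

### Inclusivity and diversity strength

The fraction of the user's tweets mentioning at least one community keyword,
with sentinel `1e-6` at zero mentions. A tweet counts once however many
keywords it contains (the numerator counts *tweets*, not keyword hits).
Matching is case-insensitive on unicode word boundaries; multi-word keywords
match as contiguous phrases; inflected variants must be listed explicitly
("nurse" does not match "nurses") — boundary matching avoids substring false
positives and is deterministic. The bundled lexicon
(`data/community_lexicon.csv`, 100 terms, 20 per category, country="all") is
a **synthetic stand-in**: the original per-country keyword lists are not
available, so strengths computed with it are internally consistent but not
comparable to any published per-country figure.

### Normalization and ranking

Within each user group, raw OSA is divided by the group maximum: the top
account scores exactly 1.000, ratios and signs are preserved. Min-max is
available as a flag but is not the default, because reported non-top scores
behave like ratios rather than range positions, and min-max would force the
bottom account to 0. A group whose raw scores are all ≤ 0 cannot be
normalized this way and is an error — report raw scores instead. Leaders and
health organizations are never normalized against each other. Ranking ties
break lexicographically by user id.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `ema_span` | 151 | days | stated value of the source procedure (grid-searched there) |
| `savgol_degree` | 8 | — | stated value of the source procedure |
| `savgol_window` | 31 | days | unstated; one month of context around each point; must be odd and > degree |
| `z_threshold` | 3.0 | σ | unstated; the conventional three-sigma rule |
| `window` | 2019-12-01 → 2021-12-31 | dates | the outbreak-to-vaccination crisis period |
| `reference_date` | 2021-12-31 | date | last analysis day; anchors profile age |
| `k` (content tables) | 10 | — | stated top-10 convention |
| `normalization` | `group_max` | — | see above |
| `sentiment_mode` | `window` | — | see above |

## Synthetic cohorts: the stated world

`simulate_cohort` defaults describe a world shaped like the two-year crisis
corpus the method was built for: 10 leaders + 10 health organizations;
Poisson tweet rates 4.8/day (leaders) and 17.9/day (health organizations),
reproducing the observed group totals (~36.8k and ~136.7k tweets over 762
days, ~173k overall); per-tweet engagement negative-binomial with mean 40
and dispersion 0.3 (variance ≈ mean + mean²/0.3 — the heavy right tail
typical of engagement counts; the mean is a realism choice, not an observed
value); two spike events (2020-04-10 ×8, 2020-10-30 ×10) standing in for the
kind of emergency announcements that drove observed engagement peaks; a
(0.25, 0.45, 0.30) negative/neutral/positive sentiment mixture (most
accounts neutral-majority, as observed); community-keyword mention
probability 0.4. One global `numpy` random stream is seeded once per
simulation, so cohorts are byte-identical for a fixed seed.

Sentiment is realized as an inserted polarity token (e.g. "wonderful") so
the fallback classifier recovers the planted label *exactly*; filler,
hashtag and keyword vocabularies are disjoint from the polarity lexicon.
Total interactions are split across likes/replies/retweets/quotes
multinomially at fixed (0.6, 0.1, 0.25, 0.05) — only the sum enters the
daily average, so the split is free.

What the generator does **not** emulate — and therefore what a green test
does not establish: retweet cascades and network topology, follower growth,
multilingual text (real corpora required machine translation; here a
preprocessing hook slot is the extension point), topical drift, bursty
within-day timing, and real lexicon semantics. Green tests establish that
the *arithmetic* of the pipeline is right and deterministic, not that the
scores are externally valid for any real account.

`plant_known_strengths` places exact label and keyword counts (rejecting
fractions not expressible at the tweet count), lays tweets one per day, and
gives all planted users identical profiles within a group so impact scaling
degenerates to 1.0 and never confounds a recovery test. Recovery of a
planted sentiment fraction requires the planted class to be the strict
majority; otherwise the neutral sentinel correctly fires.

## Numerical choices and degenerate inputs

- EMA uses the recursive (adjust-free) form: `y_t = (1−α) y_{t−1} + α x_t`,
  `α = 2/(span+1)`; constants are exact fixed points.
- z-score outliers use the population standard deviation of the (EMA'd)
  series; a zero-variance series has no outliers by definition. Flagged
  points are replaced by linear interpolation of their neighbours
  (edge points take the nearest valid value) rather than deleted, so the
  series length — and hence the filter window and the day-mean denominator —
  is preserved.
- The degree-8 Savitzky–Golay fit is numerically ill-conditioned: constants
  survive the full chain to ~1e-7 relative error, not machine precision;
  tests assert 1e-5. With window = degree+1 the filter interpolates and is
  the identity (asserted to 1e-8).
- `smooth_series` refuses series no longer than the filter window, telling
  the caller to configure a smaller window. The *pipeline* instead shrinks
  the window to the largest odd value that fits (> degree) and, failing
  that, skips the Savitzky–Golay stage with a logged warning — short
  synthetic cohorts remain scorable without silently changing the library
  primitive's contract.
- Multi-handle accounts: tweet streams are unioned; profile metrics come
  from the roster-designated primary handle and are never summed (summed
  follower counts double-count overlapping audiences).
- All daily grouping is UTC; timestamps are RFC 3339, naive values taken as
  UTC.
- Entity grammar: `#`/`@` followed by a maximal run of unicode word
  characters; the text is lowercased *before* tokenizing, making extraction
  idempotent under lowercasing even for characters (e.g. "İ") whose
  lowercase form introduces combining marks.
- Hashtag/mention frequencies count token usage (a tweet using a tag twice
  contributes two); a tweet-presence mode is a flag.

## Known limitations

- The fallback sentiment classifier is a testing device; real sentiment
  conclusions require plugging in a trained model.
- The bundled community lexicon is a stand-in; inclusivity strengths are not
  comparable across studies without the real country-specific lists.
- Eq-level ambiguities (day-level vs window-level sentiment aggregation,
  smoothing-vs-weighting order, raw-vs-scaled impact in the weighting) are
  resolved by documented defaults with flags, not by a claim about the
  original procedure's exact behaviour.
- Engagement rate in the impressions sense is out of scope: impressions are
  not public metrics.
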