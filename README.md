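# osascore

Scoring pipeline for the **online societal association (OSA)** of public
social-media accounts — political leaders and national health organizations —
during a health crisis. Given each account's tweets and profile metadata, the
package quantifies how strongly the account associates with its audience as
the product of three equally weighted components, and normalizes the result
within each user group (leaders are never scaled against health agencies).

## The score

For a user *u* over an analysis window:

```
OSA_u = dailyAvgEng_u × sentiStrength_u × iDStrength_u
```

**Engagement with impact** (`dailyAvgEng_u`). Per calendar day with at least
one tweet, the average engagement per tweet is

```
dailyAvgEng = (likes + replies + retweets + quotes) / (4 × dailyTweetCount)
```

The daily series is standardized by an exponential moving average (span 151
days), cleaned of outliers (|z| > 3 replaced by linear interpolation), and
smoothed with a degree-8 Savitzky–Golay filter. It is then weighted by the
user impact

```
impact_u = tanh( log10(√followers / following) × listedCount × tweetCount ) / profileAge²
```

(min-max scaled to [0, 1] within the user group; `tweetCount` is the number
of tweets collected in the window, `profileAge` is in days to the reference
date) and averaged over days.

**Sentiment strength** (`sentiStrength_u ∈ [−1, 1]`). Tweets are classified
negative / neutral / positive by a pluggable classifier (a deterministic
signed-lexicon fallback is bundled; a transformer can be plugged in). The
strength is `+n_pos/total` if positive is the majority class, `−n_neg/total`
if negative, and the sentinel `1e-6` if neutral (ties resolve to neutral).

**Inclusivity and diversity strength** (`iDStrength_u ∈ {1e-6} ∪ (0, 1]`).
The fraction of the user's tweets mentioning at least one community keyword
(gender, age, culture, ethnicity, employment sector; case-insensitive
whole-word matching), with the sentinel `1e-6` when no tweet mentions any
community. The bundled ~100-term lexicon is a synthetic stand-in; supply
country-specific lists for real analyses.

Raw OSA values are divided by the group maximum, so each group's top user
scores exactly 1.000 and negative (negative-sentiment) scores stay negative.

The package also ships a seeded synthetic-cohort generator (Poisson daily
tweet streams, negative-binomial engagement with event spikes, categorical
sentiment mixtures, Bernoulli keyword mentions) and top-k hashtag/mention
content analysis.

## Worked example

Simulate a small six-account cohort and score it:

```sh
cat > example.yaml <<EOF
seed: 42
window: {start_date: 2021-01-01, end_date: 2021-06-30, reference_date: 2021-12-31}
n_leaders: 3
n_health_orgs: 3
leader_tweet_rate: 3.0
health_org_tweet_rate: 6.0
EOF

osascore simulate --config example.yaml --out demo
# wrote 5015 tweets for 6 users to demo

osascore score --config example.yaml --tweets demo/tweets.jsonl \
  --profiles demo/profiles.csv --roster demo/roster.csv --out demo_scores
```

prints, per group, the normalized OSA alongside its components:

```
top 3 leaders by normalized OSA:
  leader_01        osa=1.000 eng=7.4442 senti=0.000 incl=0.390
  leader_02        osa=0.587 eng=4.5108 senti=0.000 incl=0.378
  leader_00        osa=0.000 eng=0.0000 senti=0.000 incl=0.401
```

Reading the rows: `leader_01` has the group's highest raw OSA, so its
normalized score is exactly 1.000. `eng` is the impact-weighted mean daily
engagement (interactions per tweet per day, scaled by the [0, 1] impact);
`senti` prints as 0.000 because all three accounts have a neutral tweet
majority, so their sentiment strength is the 1e-6 sentinel; `incl` says
roughly 39% of each account's tweets mention a community. `leader_00` is the
group's least impactful account: min-max scaling maps its impact to 0, which
zeroes its weighted engagement and hence its OSA. Full per-user components
land in `demo_scores/osa.csv`, the smoothed series in
`demo_scores/engagement_series.csv`.

Content tables (`osascore content --tweets demo/tweets.jsonl --k 3 --out
demo_content`) list the most-used hashtags and most-mentioned accounts:

```
scope,kind,token,count,rank
all,hashtag,lockdown,262,1
all,hashtag,flattenthecurve,260,2
all,hashtag,tokyo2020,257,3
```

The same functionality is available as a library; see
`osascore.score_users`, `osascore.simulate_cohort` and the module docstrings.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the default cohort (20 accounts, Dec 2019 – Dec 2021, ~173k
tweets), runs the complete scoring pipeline and the content analysis with
the given seed, asserts the structural invariants of the results (group
maxima normalized to exactly 1, impacts in [0, 1], strengths in range), and
writes the results JSON. It prints progress and the top accounts per group
to stderr; the full run takes well under a minute.

## Documentation

`docs/methods.md` describes the model, every tunable parameter with its
default and rationale, what the synthetic cohorts do and do not emulate, and
the package's numerical choices and limitations.
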