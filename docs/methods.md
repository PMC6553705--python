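# Methods

`netwell` implements a three-part analysis of the coupling between social
communication structure and wearable-measured health behavior in a
longitudinal cohort, plus a synthetic-cohort simulator that makes the whole
pipeline testable end to end.

## Data model and week indexing

Three input tables drive the analysis: a communication event log (timestamp,
source id, target id, channel call/text, optional call duration and answered
flag), a minute-level wearable stream (heart rate in bpm, steps, one of four
activity states), and a one-row-per-participant wellness survey with ordinal
Likert labels — stress 1–4, happiness 1–4, positive attitude 1–5,
self-assessed health 1–4.

Weeks are consecutive 7-day bins anchored at the configured study start
(`week = floor(days_since_start / 7)`), not calendar ISO weeks; this makes
week indices reproducible without locale assumptions. Ids are opaque
strings; whether an id is a participant is decided solely by roster
membership. Duplicate participant-minutes are resolved keep-first with a
warning, and self-loop events are rejected — the input format does not
guarantee either.

## Weekly communication networks

Calls and texts are pooled into undirected, unweighted weekly graphs. A pair
of ids is admitted as a potential edge only if it has at least
`edge_min_events` (default 3) events over the *entire* study window — a spam
filter applied globally, not per week. A retained pair contributes an edge
to week *w* iff it has at least one event that week. Two variants are built
per week: the **whole network** (participants plus external contacts active
that week) and the **participant network** (roster members only). Isolated
roster members stay in the graph with degree 0 so every participant-week has
a complete feature vector.

Five structural features per node and week: degree, triangle count, local
clustering coefficient, betweenness centrality normalized by (n−1)(n−2)/2,
and Wasserman–Faust component-scaled closeness
((r−1)/(n−1))·((r−1)/Σd), r = reachable nodes including self; isolated nodes
get closeness 0. Weekly communication graphs are usually disconnected, and
the scaled variants keep every feature in [0, 1]. Implementation is
networkx; correctness is pinned to an independent brute-force oracle
(exhaustive BFS shortest-path enumeration) on random graphs of ≤ 8 nodes.

## Wear filtering and behavioral features

A worn minute is one with a recorded heart rate (the standard optical-HR
wear proxy). A participant-day is valid when worn minutes ≥ 1140 (19 of 24
hours, i.e. 80% daily wear); invalid days are removed individually — a week
keeps its remaining valid days. `weekly_behavior_table` exposes
`min_valid_days` (default 1) for analysts who want to drop sparse weeks
rather than guess whether whole participants should be excluded.

Per participant-week, 12 features: pooled mean and **population variance**
of minute heart rate; mean and **sample (n−1) standard deviation** of daily
step totals and of daily minutes in each of the four activity states. The
variance/sd mix is intentional: the minute pool is near-census while daily
totals are a small sample of days. With a single valid day the sample sd is
0 by convention, so nothing downstream sees an undefined value.

## Structure–behavior correlation

"Normalized cross-correlation" here is the zero-lag Pearson coefficient of
two weekly series (a lag scan is available behind `ncc_lag_scan` but a
single zero-lag coefficient per pair is the reported statistic). The
p-value is the usual two-sided t transform at n−2 df. Constant series and
series shorter than 3 usable weeks are flagged undefined and never counted
as correlated.

* **Cohort level:** 60 pairs = 10 structure columns (5 metrics × 2 network
  variants) × 6 behavioral weekly means, correlating the cross-participant
  weekly mean series (a median mode is provided). Counting uses |r| ≥ τ
  inclusive, at τ = 0.5 and 0.7.
* **Person level:** the same coefficients per participant, counting the
  participants at |r| ≥ 0.5 per pair and, per behavior feature, for ≥ 1
  structural feature of the participant / whole / either network.
  Participants with fewer than 3 usable weeks are excluded from numerator
  and denominator. |r| (not signed r) is the default because strong negative
  structure–behavior correlations are as informative as positive ones; a
  signed mode exists. Percentages are rounded half away from zero.
* **High/low tests:** per pair, weeks are split at the median of the
  structure series (ties join the low side so both sides stay populated) and
  the behavior values of high vs low weeks are compared with a Welch
  two-sample t-test; Benjamini–Hochberg at α = 0.05 corrects across the 60
  tests (Bonferroni available). The median split is a parameter-free and
  balanced reading of "high and low value ranges"; it is one admissible
  design, and the FDR property is verified under the simulator's null.

A one-way ANOVA of participant mean heart rate across the ordinal levels of
each wellness attribute is provided as `anova_by_level`.

## Wellness prediction (weighted-voting ensemble)

Each attribute is a K-class problem (K = 4 or 5) over participant-week
instances under three feature sets: baseline (gender + 12 behavior
features), network-only (10 structure features), full (all 23). Gender is a
binary indicator (male = 0, female = 1); unreported-gender rows are excluded
from modelling.

The harness: 75/25 train/test split; five base learners (KNN, CART, SVM —
probability outputs enabled, LR, RF) tuned by grid search under stratified
5-fold CV (the RF grid spans 10–100 trees in steps of 5, with 35 as the
fixed default); the three highest-CV-accuracy learners form the ensemble;
scaling lives inside each model pipeline so only training statistics are
used. The ensemble rule is

    y_vote = argmax_j Σ_{i=1..3} w_ij · p_ij

with p the base classifiers' class probabilities and w chosen on held-out
training folds from a step-0.1 grid, maximising mean macro F1. The default
weight mode is one scalar weight per classifier on the 3-simplex (66 grid
points); a per-class mode constrains each classifier's row to the K-simplex
(286 rows at K = 4) and is searched by monotone coordinate ascent, with an
exhaustive scan behind a flag — the full cartesian product (286³ ≈ 2.3×10⁷)
is disproportionate for routine use. All ties (vote and grid) break
deterministically toward the lowest index / first enumeration position.

Two split units are provided. The default groups all weeks of a participant
on one side of the split: instance labels are constant per participant
within a semester, so a row-level split would leak participant identity into
the test set. A stratified row split is kept as a compatibility mode. The
default is the defensible evaluation; its absolute F1 values are lower than
a leaky row split would give.

Reported metrics: per-level F1 (zero when precision+recall = 0), macro F1
("overall"), and a support-weighted variant. The random baseline draws
uniform classes; its per-class F1 concentrates on 2p/(Kp+1) for prevalence p
(precision → p, recall = 1/K), which the Monte-Carlo report reproduces.
Improvement percentages are `round(100·(full − base)/base)`, half away from
zero, computed from the table's own 2-decimal rows so every report is
internally consistent at display precision.

## Synthetic cohort

The simulator plants exactly the structure the analysis is meant to detect,
with defaults chosen once so the full pipeline runs in well under two
minutes on one CPU (60 participants, 120 external contacts, 22 weeks;
325 participants mimics a full cohort):

* **Heterogeneity:** per-person sociability and fitness are lognormal
  (heavy-tailed contact rates and step scales), `exp(0.6·Z)` and
  `exp(0.4·Z)`.
* **Shared weekly factor** S_w: two sinusoids plus a linear drift, scaled to
  [−1, 1] — the minimal smooth semester-long trend that makes 22-point
  weekly mean series co-vary.
* **Communication:** weekly pair event counts are Poisson with rate
  `comm_rate·s_i·s_j/n·(1 + ρ·S_w)`; ρ (`coupling_rho`, default 0.9) is the
  planted structure–behavior coupling. Many pairs total fewer than 3 events,
  so the spurious-edge filter is genuinely exercised.
* **Wearables:** minute heart rate = personal baseline + activity-state
  increment (0/10/25/45 bpm) + Gaussian noise; daily steps ∝
  fitness·(1 + ρ·S_w); daily state minutes are multinomial with
  very/fairly-active shares rising in fitness and S_w; a configurable 10% of
  participant-days are generated short of the wear threshold. A fast path
  draws the identical per-day quantities and aggregates on the fly, so
  default-sized studies never materialise ~13M minute rows; the minute-level
  stream itself is generated for small configs and format tests.
* **Labels:** a latent-threshold (cumulative) model per attribute —
  latent = β_b·z(fitness) + β_n·z(sociability) + noise (defaults 1.0, 1.0,
  1.0) — cut at normal quantiles matching a realistic Likert level profile,
  so marginal label distributions look like a college cohort at any effect
  size. β_n > 0 is what makes network features genuinely informative beyond
  behavior.

What the simulator does **not** emulate: circadian structure within days,
community/cluster structure in the network (triads arise only by chance),
weekday/weekend effects, device artefacts, or any attempt to fit real
cohort distributions. Passing tests therefore demonstrate the pipeline's
correctness and its ability to separate coupled from uncoupled regimes —
not that real data would yield any particular coefficient.

## Numerical and design choices

* Pearson r is clipped to [−1, 1]; |r| = 1 maps to p = 0.
* A spread below float resolution is treated as a constant series
  (undefined correlation) rather than propagating division noise.
* Improvement rounding carries a 1e−9 epsilon so clean decimal inputs hit
  their exact half-way values.
* All randomness descends from named `numpy` SeedSequence substreams per
  generator stage; every experiment is a pure function of its seed list.
* Monte-Carlo problem sizes used by the validation experiments: 10 seeds for
  recovery and headline direction, 50 for FDR control, 1000 repetitions for
  the random-baseline closed form, 200 random graphs for the metric oracle.

## Known limitations

* The high/low t-test design (median split on weeks) is one reading of an
  under-specified procedure; alternatives (e.g. tercile splits) are not
  implemented.
* Ordinal labels are modelled as plain multiclass targets; no ordinal
  regression.
* The per-class exhaustive weight search is provided but impractical beyond
  toy sizes; coordinate ascent is a heuristic without a global optimality
  guarantee.
* `anova_by_level` assumes homoscedastic groups (classical one-way ANOVA).
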