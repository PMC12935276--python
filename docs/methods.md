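# Methods

## The EDRan pipeline

**Field partition.** The pitch is the 120 × 80 coordinate grid used by
StatsBomb-style event logs, with locations already oriented toward the
possessing team's attack (the library performs no flipping). The default
partition is 5 rows × 6 columns = 30 equal-area rectangles; 12 × 8 and 5 × 3
variants are configuration. Cells are half-open with the upper field boundary
closed, so every in-range coordinate maps to exactly one region; the flat
index is row-major (row from y, column from x).

**Temporal segmentation.** Each half, *including its injury time*, is divided
into five equal intervals, giving ten intervals that never mix halves. The
interval length δt therefore differs between halves but not within one.
Events are assigned to the interval containing their start time; events
spanning an interval boundary are not split (their full duration stays with
the starting interval). An event timed exactly at the period end falls in the
half's last interval.

**Possession matrices and distributions.** Per team and interval, each
ball-movement event adds its duration to the cell of the region where it
occurred. Dividing by the team's total duration in that interval yields the
probability vector p. An interval with zero accumulated duration is flagged
`empty`; its entropy is recorded as 0 (with the flag carried through) so every
match keeps the full 10-feature shape the models require.

**Entropy.** EDRan is the Rényi entropy H_α(p) = log(Σ pᵢ^α)/(1−α), computed
in nats by default (base-2 available; every downstream use — correlations,
tree models, orderings — is base-invariant). Special cases: α = 0 counts the
support with strict pᵢ > 0 (durations are exact sums, so true zeros survive
division); |α − 1| ≤ 1e-9 switches to the Shannon limit with 0·log 0 = 0;
zero entries are skipped otherwise. The default α grid is
{0, 0.1, 0.5, 1, 1.5, 2}.

**Features.** ΔH_α(tᵢ) = (H_α^A − H_α^B)/δtᵢ with δt in minutes by default —
the normalization compensates for injury-time differences between halves, and
minutes keep feature magnitudes O(0.01–0.1); seconds are a flag away. The
choice of unit rescales features uniformly and cannot affect rank
correlations or tree-based models.

**Filtering.** Off-ball events are excluded. Since no canonical list of
on-ball types exists, the default included set is
{pass, carry, dribble, shot, clearance, goalkeeper-distribution}, exposed as
configuration; zero-duration events are dropped by default because they add
no weight to the matrices.

## Screening and evaluation

The winner/loser curves average EDRan by *role* (winner vs loser, not side),
with mean ± 1 sd bands and the running sum of per-interval mean differences
as the cumulative curve. Feature screening uses Shapiro–Wilk as a gate (any
rejection at 0.05 recommends rank-based methods) and Spearman ρ with average
ranks against the binary result; no multiplicity correction is applied at the
screening stage (coefficients, not decisions, are the output there).

Model evaluation is 50 repeats × 5 folds of shuffled (non-stratified by
default) k-fold cross-validation — 250 held-out evaluations — with the
shuffle seed of repetition r equal to r and the Random-Forest seed fixed at
42. Hyperparameters are tuned *inside* each training set by accuracy-scored
grid search (5 inner folds); the full grid is n_estimators {50,100,200},
max_depth {None,10,20,30}, min_samples_split {2,5,10}, min_samples_leaf
{1,2,4}, bootstrap {True,False}. A reduced grid (n_estimators {100},
max_depth {None,10}) is the desk-scale default used by the tests, the
analysis drivers, and the acceptance script; protocol sizes there are 5 × 5
so a full six-α comparison completes in minutes on one CPU. Metric
distributions are summarized as mean, sample sd, and mean ± 1.96·sd/√n.
Pairwise comparisons against the Shannon (α → 1) baseline use MCC (robust to
the mild class imbalance), Welch's t with Satterthwaite df, Hedges' g
(pooled-sd Cohen's d times 1 − 3/(4(n₁+n₂)−9)), and both Bonferroni
(min(K·p, 1)) and Holm step-down corrections at family-wise 0.05. A
single-class training fold would be skipped and logged; at the sample sizes
and class balances used here it does not occur.

**MCC convention.** A zero denominator (a degenerate margin) yields MCC = 0,
the usual no-information convention.

**Power.** The post-hoc power of the two-sided one-sample proportion test
uses the unpooled normal approximation: rejection bounds p₀ ± z₀.₉₇₅·SE₀ with
SE₀ = √(p₀(1−p₀)/n), and the alternative's sampling distribution with
SE₁ = √(p̂(1−p̂)/n). An exact-binomial option builds the rejection region from
the null binomial at α/2 per tail; it is slightly conservative (e.g. 0.865 vs
0.871 at n = 608, p̂ = 0.5625) because discrete tails undershoot the nominal
level.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes — not
football tactics. Per match:

- Each team plays on a random *support* of regions. One designated team is
  broad: `base_support + breadth_gap` regions (defaults 18 + 8 = 26 of 30)
  against `base_support` for the other. In intervals 8–10 the gap shrinks by
  the damping factor (default 0.5), reproducing the late-game narrowing of
  the winner-loser entropy gap.
- Within its support, a team's per-interval usage probabilities are Dirichlet
  draws. The concentration θ is jittered per team-interval (log-uniform
  0.6–3.0 around the default θ = 1.8) *independently of the outcome*: breadth
  mode plants support size as the genuinely informative signal, so
  within-support concentration must be noise. Without the jitter, collision
  entropy would track the support size almost as cleanly as Max entropy and
  the α-ordering would be a matter of sampling noise rather than mechanism.
- Event counts are Poisson (mean 45 per team-interval), durations Gamma
  (shape 2, scale 1.2 s — Gamma rather than exponential so near-zero
  durations do not dominate after the zero-duration filter), locations
  uniform within the drawn region's cell, times uniform within the interval.
  10% of events are tagged as off-ball pressure and 5% get zero duration, so
  the filtering stage has real work to do. Period lengths are 2700 s plus
  Uniform(0, 300) s of injury time per half.
- The result is Bernoulli with P(Team A wins) = logistic(β · mean over
  intervals of (H₀^A − H₀^B)), β = 3, on the plain nats scale. Defining the
  link on the unnormalized entropy gap (rather than the per-minute feature)
  keeps β interpretable — one nat of average breadth advantage shifts the
  log-odds by β — and independent of the δt unit convention. With the default
  gap this gives the broad team a ≈ 0.72 win probability.
- `signal="concentration"` is the converse mechanism: both teams share a
  support size, the designated team is flatter within it (θ scaled by the
  concentration ratio), and the label links to the true collision-entropy
  gap — the control showing that when frequency skew, not breadth, drives
  winning, α = 2 models are not worse than α = 0. `signal="none"` plants
  nothing and the label is a fair coin.
- Randomness is one global seed feeding a counter-based per-match substream
  (`SeedSequence([seed, match_index])`), so individual matches can be
  regenerated and runs are byte-reproducible.

What the generator does **not** emulate: pass networks, formations, scoreline
dynamics, team identity across matches, draws, or realistic possession
totals. Passing tests on this generator therefore shows that the pipeline
measures what it claims and that the α-ordering responds to the planted
mechanism — it does not by itself validate the tactical interpretation on
real event data.

## Numerical and protocol choices

- Normalization tolerance 1e-12 on distributions; entropy input must sum to
  1 within 1e-9.
- Support counting at α = 0 uses strict positivity, no tolerance.
- Empty-interval entropies enter ΔH as 0; the empty flag is preserved in the
  series output.
- Coordinates/durations round-trip through the text formats at 6 decimals.
- Desk-scale problem sizes: 600 simulated matches and the 5 × 5 reduced-grid
  protocol for the pipeline-level checks; 1000-2000 matches (ground truth
  only, no event logs) for the law-of-large-numbers checks of the outcome
  link.

## Known limitations

- The on-ball event-type list is a documented default, not ground truth from
  any data provider's ontology.
- Events spanning the half-time whistle are not truncated or split; their
  duration stays in the first half's last interval.
- The winner/loser cumulative curve is the running sum of per-interval mean
  differences (the match-then-interval summation order coincides up to
  scaling).
- Real-data adapters are out of scope; the reader accepts the documented flat
  schema only, and conclusions about real match play require real event logs.
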