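# edran — spatial Event Distribution Randomness in football

`edran` quantifies how unpredictably a football team spreads its on-ball play
across the pitch, and asks which flavour of "unpredictability" actually tracks
winning: breadth across *all* field regions, or randomness concentrated in a
team's dominant zones. It is aimed at sports-performance analysts working with
event-log data (StatsBomb-style: one row per on-ball event with location,
possessing team, and duration).

## The metric

The pitch (120 × 80) is tiled into 30 equal-area regions (5 rows × 6 columns);
each half of a match — injury time included — is cut into five equal intervals,
giving ten intervals t₁…t₁₀. Per team and interval, a *region-based cumulative
possession matrix* accumulates event durations by region; normalizing it gives
a probability vector p over regions. The Event Distribution Randomness (EDRan)
of that interval is its Rényi entropy of order α:

    H_α(p) = log(Σᵢ pᵢ^α) / (1 − α)

with the familiar special cases H₀ = log |{i : pᵢ > 0}| (Max/Hartley entropy —
pure support breadth), H₁ = −Σ pᵢ log pᵢ (Shannon, the α → 1 limit), and
H₂ = −log Σ pᵢ² (collision entropy — dominated by frequently used regions).
Small α weights rare regions up; large α weights dominant regions up.

Per match, the ten duration-normalized team differences

    ΔH_α(tᵢ) = (H_α^A(tᵢ) − H_α^B(tᵢ)) / δtᵢ

are the feature vector for screening (Spearman correlation with the result)
and for a Random-Forest match-winner classifier evaluated with 50 × 5-fold
repeated cross-validation, per α, with Welch/Holm-corrected pairwise
comparisons against the Shannon baseline.

Because the public event data cannot be redistributed, the package ships a
synthetic generator that plants the structure this analysis assumes — a
breadth advantage for one team, a logistic outcome link on the entropy gap,
and a late-game narrowing — so the whole pipeline is testable end to end.

## Worked example

```python
from edran import (SimulationConfig, simulate_dataset, filter_ball_movement_events,
                   compute_edran_series, delta_features, spearman_profile)

records, truth = simulate_dataset(SimulationConfig())   # 600 matches, seed 7
filtered = [filter_ball_movement_events(r) for r in records]
series = compute_edran_series(filtered, alphas=(0.0, 2.0))
features = delta_features(series, records, alpha=0.0)
print(spearman_profile(features)["mean_rho"].iloc[0])
```

Running the numbered drivers in `analysis/` on these defaults prints, among
other things:

```
Team A win rate: 0.510
broad-support team win rate: 0.718
alpha=0.0: cumulative winner-loser gap +0.911 nats, per-interval gap early +0.1024 vs late +0.0646
alpha=0.0: mean Spearman rho +0.3076 (rank-based recommended: True)
alpha=2.0: mean Spearman rho +0.2445 (rank-based recommended: False)
   men 608   342 0.5625         0.871       0.8651
 women 374   206 0.5508         0.502       0.4800
```

Read: the planted breadth advantage makes winners' EDRan exceed losers' in
every interval (cumulative gap +0.91 nats at α = 0), the gap narrows late as
configured, and the Spearman screen of the ΔH features is strongest at α = 0
and decays as α grows — support breadth, not dominant-region randomness, is
what carries the outcome signal here. The last rows are the post-hoc power of
the two-sided one-sample proportion test for the two public cohort
compositions: a 608-match cohort at 56.25% is adequately powered (0.87), a
374-match cohort at 55.08% is not (0.50).

The `edran` CLI wires the same stages for shell use
(`edran simulate | ingest | compute | features | correlate | power | evaluate |
compare | report`); every subcommand writes a manifest with content hashes so
reruns are verifiable.

## Layout

- `src/edran/` — the library: `event_data` (schema + I/O), `core` (partition,
  intervals, possession matrices, Rényi entropy, ΔH features), `stats`
  (curves, normality gate, Spearman screen, proportion power), `model_eval`
  (repeated CV, MCC, Welch/Hedges, Holm/Bonferroni), `simulate` (generator),
  `cli`.
- `analysis/01…05_*.py` — narrative drivers writing tidy tables to `results/`.
- `tests/` — unit, property, and end-to-end acceptance tests.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
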