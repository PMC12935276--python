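"""Synthetic labeled match event logs with controllable spatial structure.

The generator emulates the statistical skeleton the EDRan analysis assumes,
not football tactics: two teams per match, per-interval duration-weighted
region-usage distributions of controllable spatial breadth, a positive link
between the entropy gap and winning, and a late-game narrowing of that gap.

Mechanism (``signal="breadth"``, the default): each match designates one
team as the broad side. Teams play on a random support of field regions —
``base_support`` regions for the narrow side, ``base_support + breadth_gap``
for the broad side; within the support, per-interval usage probabilities are
Dirichlet draws whose concentration θ is jittered per team-interval
independently of the outcome, so support breadth (Max entropy, α = 0) is the
genuinely informative statistic while collision-entropy features carry
concentration noise. In the late intervals (8-10) the breadth gap shrinks by
the damping factor, reproducing the end-of-match narrowing. The winner label
is Bernoulli with P(Team A wins) = logistic(β · mean_i (H₀ᴬ(tᵢ) - H₀ᴮ(tᵢ)))
on the plain nats scale.

``signal="concentration"`` plants the converse mechanism — both teams share
a support size, the designated team is flatter within it, and the label is
linked to the collision-entropy (α = 2) gap. ``signal="none"`` plants
nothing (equal supports; the link collapses to a fair coin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import model_eval
from .core import (
    FieldPartition,
    N_INTERVALS,
    compute_edran_series,
    delta_features,
    renyi_entropy,
)
from .event_data import EventFilterConfig, MatchEvent, MatchRecord, filter_ball_movement_events

_LATE_INTERVALS = (8, 9, 10)  # 1-based; breadth gap damped here
_ONBALL_TYPES = ("pass", "carry", "dribble", "shot")
_ONBALL_PROBS = (0.55, 0.30, 0.10, 0.05)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions used
    throughout the tests and analysis scripts."""

    n_matches: int = 600
    seed: int = 7
    theta: float = 1.8  # central Dirichlet concentration within the support
    theta_jitter: tuple[float, float] | None = (0.6, 3.0)  # log-uniform range
    base_support: int = 18  # regions used by the narrow team (of 30)
    breadth_gap: int = 8  # extra regions for the broad team
    events_per_interval: float = 45.0  # Poisson mean per team per interval
    duration_shape: float = 2.0  # Gamma shape of event durations
    duration_scale: float = 1.2  # Gamma scale (seconds)
    beta: float = 3.0  # logistic slope on the mean entropy gap (nats)
    damping: float = 0.5  # late-interval shrink factor of the breadth gap
    signal: str = "breadth"  # breadth | concentration | none
    concentration_ratio: float = 3.0  # θ multiplier/divisor in concentration mode
    offball_rate: float = 0.10  # fraction of events tagged as off-ball pressure
    zero_duration_rate: float = 0.05  # fraction of on-ball events with 0 duration
    regular_period_s: float = 2700.0
    max_injury_s: float = 300.0
    n_rows: int = 5
    n_cols: int = 6

    def __post_init__(self) -> None:
        checks = {
            "n_matches": self.n_matches >= 1,
            "theta": self.theta > 0,
            "base_support": 1 <= self.base_support <= self.n_rows * self.n_cols,
            "breadth_gap": 0 <= self.breadth_gap <= self.n_rows * self.n_cols - self.base_support,
            "events_per_interval": self.events_per_interval > 0,
            "duration_shape": self.duration_shape > 0,
            "duration_scale": self.duration_scale > 0,
            "damping": 0 <= self.damping <= 1,
            "signal": self.signal in ("breadth", "concentration", "none"),
            "concentration_ratio": self.concentration_ratio >= 1,
            "offball_rate": 0 <= self.offball_rate < 1,
            "zero_duration_rate": 0 <= self.zero_duration_rate < 1,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SimulationConfig.{name}: {getattr(self, name)!r}")

    @property
    def n_regions(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class GroundTruth:
    """What the generator actually planted, per match.

    ``per_match`` has one row per match: the two support sizes, the true mean
    entropy gap feeding the logistic link, the win probability, and the drawn
    label. ``true_h0``/``true_h2`` hold the noiseless per-interval entropies,
    shape ``(n_matches, 2 teams, 10 intervals)`` in nats.
    """

    per_match: pd.DataFrame
    true_h0: np.ndarray
    true_h2: np.ndarray
    prefs: list[np.ndarray] = field(default_factory=list)  # per match: (2, 10, n_regions)


def _match_rng(seed: int, match_index: int) -> np.random.Generator:
    # counter-based substream: any match can be regenerated independently
    return np.random.default_rng(np.random.SeedSequence([seed, match_index]))


def _support_sizes(cfg: SimulationConfig, broad_team: int, interval: int) -> tuple[int, int]:
    """Support sizes (team A, team B) for a 1-based interval."""
    gap = cfg.breadth_gap
    if interval in _LATE_INTERVALS:
        gap = int(round(cfg.breadth_gap * cfg.damping))
    if cfg.signal == "breadth":
        sizes = [cfg.base_support, cfg.base_support]
        sizes[broad_team] += gap
        return sizes[0], sizes[1]
    # concentration/none: both teams share the same (wider) support size
    shared = min(cfg.n_regions, cfg.base_support + cfg.breadth_gap)
    return shared, shared


def simulate_dataset(
    cfg: SimulationConfig | None = None, generate_events: bool = True
) -> tuple[list[MatchRecord], GroundTruth]:
    """Draw a labeled synthetic dataset (and its ground truth).

    With ``generate_events=False`` only the ground truth (true distributions,
    win probabilities, labels) is produced — used by convergence checks that
    do not need event logs. Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    sigmoid = lambda z: 1.0 / (1.0 + np.exp(-z))
    records: list[MatchRecord] = []
    truth_rows = []
    true_h0 = np.zeros((cfg.n_matches, 2, N_INTERVALS))
    true_h2 = np.zeros((cfg.n_matches, 2, N_INTERVALS))
    prefs_all: list[np.ndarray] = []
    cell_w = 120.0 / cfg.n_cols
    cell_h = 80.0 / cfg.n_rows

    for m in range(cfg.n_matches):
        rng = _match_rng(cfg.seed, m)
        match_id = f"sim-{m:05d}"
        period_end = {
            1: cfg.regular_period_s + rng.uniform(0, cfg.max_injury_s),
            2: cfg.regular_period_s + rng.uniform(0, cfg.max_injury_s),
        }
        broad_team = int(rng.integers(2))  # 0 = A, 1 = B is the designated side

        prefs = np.zeros((2, N_INTERVALS, cfg.n_regions))
        # one base support mask per team; late intervals subsample the broad
        # team's extras so the gap narrows without reshuffling its identity
        masks: dict[tuple[int, int], np.ndarray] = {}
        sizes_first = _support_sizes(cfg, broad_team, 1)
        base_masks = [
            rng.choice(cfg.n_regions, size=sizes_first[team], replace=False) for team in (0, 1)
        ]
        for team in (0, 1):
            for iv in range(1, N_INTERVALS + 1):
                sizes = _support_sizes(cfg, broad_team, iv)
                size = sizes[team]
                mask = base_masks[team]
                if size < mask.size:
                    mask = mask[:size]  # drop trailing extras deterministically
                masks[(team, iv)] = mask

        for team in (0, 1):
            for iv in range(1, N_INTERVALS + 1):
                mask = masks[(team, iv)]
                if cfg.signal == "concentration":
                    ratio = cfg.concentration_ratio
                    theta = cfg.theta * ratio if team == broad_team else cfg.theta / ratio
                elif cfg.theta_jitter is not None:
                    lo, hi = cfg.theta_jitter
                    theta = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    theta = cfg.theta
                p = np.zeros(cfg.n_regions)
                p[mask] = rng.dirichlet(np.full(mask.size, theta))
                prefs[team, iv - 1] = p
                true_h0[m, team, iv - 1] = renyi_entropy(p, 0.0)
                true_h2[m, team, iv - 1] = renyi_entropy(p, 2.0)

        if cfg.signal == "concentration":
            gap = float(np.mean(true_h2[m, 0] - true_h2[m, 1]))
        else:
            gap = float(np.mean(true_h0[m, 0] - true_h0[m, 1]))
        p_win = float(sigmoid(cfg.beta * gap))
        result = int(rng.random() < p_win)

        events: list[MatchEvent] = []
        if generate_events:
            for team in (0, 1):
                for iv in range(1, N_INTERVALS + 1):
                    period = 1 if iv <= 5 else 2
                    dt = period_end[period] / 5
                    start = ((iv - 1) % 5) * dt
                    n_ev = int(rng.poisson(cfg.events_per_interval))
                    if n_ev == 0:
                        continue
                    regions = rng.choice(cfg.n_regions, size=n_ev, p=prefs[team, iv - 1])
                    cols = regions % cfg.n_cols
                    rows_ = regions // cfg.n_cols
                    xs = (cols + rng.random(n_ev)) * cell_w
                    ys = (rows_ + rng.random(n_ev)) * cell_h
                    times = np.sort(start + rng.random(n_ev) * dt)
                    durs = rng.gamma(cfg.duration_shape, cfg.duration_scale, size=n_ev)
                    durs[rng.random(n_ev) < cfg.zero_duration_rate] = 0.0
                    offball = rng.random(n_ev) < cfg.offball_rate
                    kinds = rng.choice(_ONBALL_TYPES, size=n_ev, p=_ONBALL_PROBS)
                    # keep every event inside its period, duration included
                    durs = np.minimum(durs, np.maximum(period_end[period] - times, 0.0))
                    for j in range(n_ev):
                        events.append(
                            MatchEvent(
                                match_id=match_id,
                                team="AB"[team],
                                period=period,
                                time_s=float(times[j]),
                                duration_s=float(durs[j]),
                                x=float(min(xs[j], 120.0)),
                                y=float(min(ys[j], 80.0)),
                                event_type="pressure" if offball[j] else str(kinds[j]),
                            )
                        )
            events.sort(key=lambda ev: (ev.period, ev.time_s))
        records.append(
            MatchRecord(match_id=match_id, events=events, result=result, period_end_s=period_end)
        )
        sizes_early = _support_sizes(cfg, broad_team, 1)
        truth_rows.append(
            {
                "match_id": match_id,
                "broad_team": "AB"[broad_team],
                "support_a": sizes_early[0],
                "support_b": sizes_early[1],
                "true_mean_dH0": float(np.mean(true_h0[m, 0] - true_h0[m, 1])),
                "true_mean_dH2": float(np.mean(true_h2[m, 0] - true_h2[m, 1])),
                "p_win": p_win,
                "result": result,
            }
        )
        prefs_all.append(prefs)

    truth = GroundTruth(
        per_match=pd.DataFrame(truth_rows),
        true_h0=true_h0,
        true_h2=true_h2,
        prefs=prefs_all,
    )
    return records, truth


def planted_alpha_ordering_check(
    cfg: SimulationConfig | None = None,
    alphas: Iterable[float] = (0.0, 2.0),
    n_repeats: int = 5,
    n_folds: int = 5,
    grid_mode: str = "reduced",
    shuffle_labels_seed: int | None = None,
    filter_cfg: EventFilterConfig | None = None,
) -> dict[float, float]:
    """Mean held-out MCC per α after running the full pipeline on simulated data.

    Simulates a dataset, filters it, computes the EDRan series, builds ΔH
    features at each requested α, and evaluates the repeated-CV Random-Forest
    protocol (reduced grid by default). With ``shuffle_labels_seed`` set, the
    labels are permuted before model fitting — the permutation-null control.
    """
    cfg = cfg or SimulationConfig()
    alphas = list(alphas)
    records, _ = simulate_dataset(cfg)
    filtered = [filter_ball_movement_events(r, filter_cfg) for r in records]
    partition = FieldPartition(n_rows=cfg.n_rows, n_cols=cfg.n_cols)
    series = compute_edran_series(filtered, partition=partition, alphas=alphas)
    labels = {r.match_id: r.result for r in records}
    if shuffle_labels_seed is not None:
        rng = np.random.default_rng(shuffle_labels_seed)
        ids = list(labels)
        shuffled = rng.permutation([labels[i] for i in ids])
        labels = dict(zip(ids, (int(v) for v in shuffled)))
    protocol = model_eval.CVProtocol(n_repeats=n_repeats, n_folds=n_folds)
    out: dict[float, float] = {}
    for a in alphas:
        table = delta_features(series, labels, alpha=a)
        result = model_eval.repeated_cv_evaluate(
            table, protocol=protocol, grid_mode=grid_mode, capture_importance=False
        )
        out[a] = float(result.metrics["mcc"].mean())
    return out
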