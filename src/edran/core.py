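"""EDRan core: field partition, half-aware intervals, possession matrices,
and the Rényi-entropy family.

Event Distribution Randomness (EDRan) quantifies how unpredictably a team
spreads its on-ball events over the pitch. The pitch is tiled into equal-area
rectangular regions (default 5 rows x 6 columns = 30 regions on the 120x80
grid), each half of the match — injury time included — is split into five
equal intervals, and per team/interval a region-based cumulative possession
matrix accumulates event durations by region. Normalizing that matrix gives a
probability distribution p over regions, whose Rényi entropy of order α,

    H_α(p) = log(Σ_i p_i^α) / (1 - α),

is the EDRan value. Special cases: α = 0 is Hartley/Max entropy log|{p_i > 0}|
(support breadth), α → 1 the Shannon limit -Σ p_i log p_i, α = 2 the collision
entropy -log Σ p_i². Small α emphasizes rarely used regions; large α the
dominant ones.

The per-interval team difference, normalized by interval duration,

    ΔH_α(t_i) = (H_α^A(t_i) - H_α^B(t_i)) / δt_i,

is the 10-dimensional feature vector used for screening and match-winner
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .event_data import FIELD_LENGTH, FIELD_WIDTH, MatchRecord

#: α grid used throughout: Max entropy, near-zero probe, 0.5, Shannon limit,
#: 1.5, collision entropy.
DEFAULT_ALPHAS = (0.0, 0.1, 0.5, 1.0, 1.5, 2.0)

#: half-width of the α-window treated as the Shannon limit
SHANNON_EPS = 1e-9

N_INTERVALS = 10
_INTERVALS_PER_HALF = 5


@dataclass(frozen=True)
class FieldPartition:
    """Equal-area rectangular tiling of the pitch.

    Columns run along x (field length), rows along y (width); cells are
    half-open with the upper field boundary closed, flat index is row-major
    (``row * n_cols + col``).
    """

    n_rows: int = 5
    n_cols: int = 6
    field_length: float = FIELD_LENGTH
    field_width: float = FIELD_WIDTH

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("partition must have at least one row and column")

    @property
    def n_regions(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return (self.field_length / self.n_cols) * (self.field_width / self.n_rows)

    def region_of(self, x: float, y: float) -> tuple[int, int, int]:
        """Map a coordinate to ``(row, col, flat_index)``."""
        row, col = self.region_of_array(np.asarray([x]), np.asarray([y]))
        return int(row[0]), int(col[0]), int(row[0] * self.n_cols + col[0])

    def region_of_array(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < 0) | (x > self.field_length)) or np.any((y < 0) | (y > self.field_width)):
            raise ValueError("coordinate outside the field")
        col = np.minimum((x / self.field_length * self.n_cols).astype(int), self.n_cols - 1)
        row = np.minimum((y / self.field_width * self.n_rows).astype(int), self.n_rows - 1)
        return row, col

    def flat_region_of_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.region_of_array(x, y)
        return row * self.n_cols + col


def region_of(x: float, y: float, partition: FieldPartition | None = None) -> tuple[int, int, int]:
    """Module-level convenience for :meth:`FieldPartition.region_of`."""
    return (partition or FieldPartition()).region_of(x, y)


@dataclass(frozen=True)
class Interval:
    index: int  # 1..10
    period: int  # 1 or 2
    start_s: float
    end_s: float

    @property
    def dt_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class IntervalScheme:
    """Ten half-aware intervals: 1-5 tile period 1, 6-10 tile period 2."""

    intervals: tuple[Interval, ...]

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    @property
    def dt_s(self) -> np.ndarray:
        return np.array([iv.dt_s for iv in self.intervals])

    def interval_index_of(self, time_s: np.ndarray, period: np.ndarray) -> np.ndarray:
        """0-based interval index per event, assigned by event start time.

        Bins are half-open; an event exactly at the period end lands in the
        last interval of its half.
        """
        time_s = np.asarray(time_s, dtype=float)
        period = np.asarray(period, dtype=int)
        dt1 = self.intervals[0].dt_s
        dt2 = self.intervals[_INTERVALS_PER_HALF].dt_s
        dt = np.where(period == 1, dt1, dt2)
        idx = np.minimum((time_s / dt).astype(int), _INTERVALS_PER_HALF - 1)
        return idx + np.where(period == 1, 0, _INTERVALS_PER_HALF)


def build_interval_scheme(record: MatchRecord) -> IntervalScheme:
    """Split each half (injury time included) into five equal intervals."""
    intervals: list[Interval] = []
    for period in (1, 2):
        end = record.period_end_s.get(period)
        if end is None or end <= 0:
            raise ValueError(
                f"match {record.match_id}: period {period} duration missing or non-positive"
            )
        dt = end / _INTERVALS_PER_HALF
        base = (period - 1) * _INTERVALS_PER_HALF
        for k in range(_INTERVALS_PER_HALF):
            intervals.append(Interval(base + k + 1, period, k * dt, (k + 1) * dt))
    return IntervalScheme(tuple(intervals))


# ---------------------------------------------------------------------------
# Possession matrices and distributions
# ---------------------------------------------------------------------------


@dataclass
class RegionDistribution:
    """Probability vector over regions; ``empty_flag`` marks an interval with
    zero accumulated duration (no information, entropy recorded as 0)."""

    p: np.ndarray
    empty_flag: bool = False


def accumulate_possession(
    record: MatchRecord,
    scheme: IntervalScheme,
    partition: FieldPartition | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Region-based cumulative possession matrices.

    Returns ``{(team, interval_index 1..10): (n_rows, n_cols) array}`` — 20
    matrices per match. Each event adds its duration to the cell of the region
    where it occurred; events are assigned to intervals by start time.
    """
    partition = partition or FieldPartition()
    cells = np.zeros((2, N_INTERVALS, partition.n_rows, partition.n_cols))
    if record.events:
        team = np.array([0 if ev.team == "A" else 1 for ev in record.events])
        period = np.array([ev.period for ev in record.events])
        time_s = np.array([ev.time_s for ev in record.events])
        dur = np.array([ev.duration_s for ev in record.events])
        x = np.array([ev.x for ev in record.events])
        y = np.array([ev.y for ev in record.events])
        row, col = partition.region_of_array(x, y)
        iv = scheme.interval_index_of(time_s, period)
        np.add.at(cells, (team, iv, row, col), dur)
    return {
        (t, i + 1): cells[ti, i]
        for ti, t in enumerate("AB")
        for i in range(N_INTERVALS)
    }


def normalize_distribution(matrix: np.ndarray) -> RegionDistribution:
    """Flatten a possession matrix into a probability vector (or flag empty)."""
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("possession matrix has negative cells")
    total = m.sum()
    if total == 0:
        return RegionDistribution(p=np.zeros(m.size), empty_flag=True)
    return RegionDistribution(p=(m / total).ravel(), empty_flag=False)


# ---------------------------------------------------------------------------
# Rényi entropy
# ---------------------------------------------------------------------------


def _log_fn(log_base: str):
    if log_base == "e":
        return np.log
    if log_base == "2":
        return np.log2
    raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")


def renyi_entropy(
    p: RegionDistribution | Sequence[float] | np.ndarray,
    alpha: float,
    log_base: str = "e",
) -> float:
    """Rényi entropy of order ``alpha`` of a probability vector.

    ``alpha == 0`` counts the support (strict ``p_i > 0``, no tolerance);
    ``|alpha - 1| <= 1e-9`` uses the Shannon limit with the ``0·log 0 = 0``
    convention; otherwise ``log(Σ p_i^α)/(1-α)`` with zero entries skipped.
    An empty (all-zero, flagged) distribution is recorded as 0.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    log = _log_fn(log_base)
    if isinstance(p, RegionDistribution):
        if p.empty_flag:
            return 0.0
        vec = np.asarray(p.p, dtype=float)
    else:
        vec = np.asarray(p, dtype=float)
    if np.any(vec < 0):
        raise ValueError("probabilities must be non-negative")
    total = vec.sum()
    if total == 0:
        return 0.0  # empty distribution, flag handled by the caller
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"distribution not normalized (sum={total!r})")
    nz = vec[vec > 0]
    if alpha == 0:
        return float(log(nz.size))
    if abs(alpha - 1.0) <= SHANNON_EPS:
        return float(-(nz * log(nz)).sum())
    return float(log((nz**alpha).sum()) / (1.0 - alpha))


def shannon_entropy(p, log_base: str = "e") -> float:
    """Shannon entropy (the α → 1 Rényi limit)."""
    return renyi_entropy(p, 1.0, log_base=log_base)


# ---------------------------------------------------------------------------
# Series and features
# ---------------------------------------------------------------------------


def compute_edran_series(
    dataset: Sequence[MatchRecord] | MatchRecord,
    partition: FieldPartition | None = None,
    alphas: Iterable[float] = DEFAULT_ALPHAS,
    log_base: str = "e",
) -> pd.DataFrame:
    """EDRan time series for a dataset.

    Returns a tidy frame with one row per match x team x interval x α:
    columns ``match_id, team, interval, alpha, H, dt_s, empty_flag``.
    Input records are expected to be already filtered to ball-movement events.
    """
    partition = partition or FieldPartition()
    alphas = list(alphas)
    if isinstance(dataset, MatchRecord):
        dataset = [dataset]
    out: dict[str, list] = {k: [] for k in ("match_id", "team", "interval", "alpha", "H", "dt_s", "empty_flag")}
    for rec in dataset:
        try:
            scheme = build_interval_scheme(rec)
            mats = accumulate_possession(rec, scheme, partition)
        except ValueError as exc:
            raise ValueError(f"match {rec.match_id}: {exc}") from exc
        for team in "AB":
            for iv in scheme:
                dist = normalize_distribution(mats[(team, iv.index)])
                for a in alphas:
                    out["match_id"].append(rec.match_id)
                    out["team"].append(team)
                    out["interval"].append(iv.index)
                    out["alpha"].append(a)
                    out["H"].append(renyi_entropy(dist, a, log_base=log_base))
                    out["dt_s"].append(iv.dt_s)
                    out["empty_flag"].append(dist.empty_flag)
    return pd.DataFrame(out)


def delta_features(
    series: pd.DataFrame,
    labels: Mapping[str, int] | Sequence[MatchRecord],
    alpha: float,
    dt_unit: str = "min",
) -> pd.DataFrame:
    """Per-match ΔH_α(t_i) feature table at one α.

    ΔH_α(t_i) = (H_α^A(t_i) - H_α^B(t_i)) / δt_i, with δt in minutes by
    default (``dt_unit`` in {"min", "s"}). Returns one row per match with
    columns ``match_id, dH_t1..dH_t10, result``.
    """
    if dt_unit not in ("min", "s"):
        raise ValueError(f"dt_unit must be 'min' or 's', got {dt_unit!r}")
    if not isinstance(labels, Mapping):
        labels = {rec.match_id: rec.result for rec in labels}
    sub = series[np.isclose(series["alpha"], alpha)]
    if sub.empty:
        raise ValueError(f"alpha={alpha} not present in the series")
    wide = sub.pivot_table(index=["match_id", "interval"], columns="team", values="H")
    if "A" not in wide.columns or "B" not in wide.columns:
        raise ValueError("series must contain both teams")
    dt = sub.drop_duplicates(["match_id", "interval"]).set_index(["match_id", "interval"])["dt_s"]
    scale = 60.0 if dt_unit == "min" else 1.0
    delta = (wide["A"] - wide["B"]) / (dt / scale)
    rows = []
    for match_id, grp in delta.groupby(level="match_id"):
        vals = grp.droplevel("match_id").reindex(range(1, N_INTERVALS + 1))
        if vals.isna().any():
            missing = [i for i in range(1, N_INTERVALS + 1) if math.isnan(vals.get(i, float("nan")))]
            raise ValueError(f"match {match_id}: missing interval(s) {missing}")
        if match_id not in labels:
            raise ValueError(f"match {match_id}: no result label")
        row = {"match_id": match_id}
        row.update({f"dH_t{i}": vals[i] for i in range(1, N_INTERVALS + 1)})
        row["result"] = int(labels[match_id])
        rows.append(row)
    return pd.DataFrame(rows)


FEATURE_COLUMNS = tuple(f"dH_t{i}" for i in range(1, N_INTERVALS + 1))
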