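"""Match event logs: schema, readers/writers, filtering, and dataset summaries.

An event log is a flat table of on-ball events, one row per event, with the
columns ``match_id, team, period, time_s, duration_s, x, y, event_type``.
Coordinates live on the standard 120x80 grid and are already oriented in the
direction of the possessing team's attack; the library never flips them.
Match results (1 = Team A win, 0 = Team B win) come from a separate two-column
CSV. Drawn matches are not representable and must be excluded upstream.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

FIELD_LENGTH = 120.0
FIELD_WIDTH = 80.0

#: Event types treated as ball movement by default. The duration-weighted
#: possession matrices only care about events during which a team carries or
#: plays the ball, so pressure/duel style off-ball tags are excluded. The set
#: is configuration, not a fixed ontology.
DEFAULT_INCLUDED_TYPES = frozenset(
    {"pass", "carry", "dribble", "shot", "clearance", "goalkeeper-distribution"}
)

_EVENT_FIELDS = ("match_id", "team", "period", "time_s", "duration_s", "x", "y", "event_type")


class SchemaError(ValueError):
    """Raised when an event-log row or results row violates the schema."""


@dataclass(frozen=True)
class MatchEvent:
    """One on-ball event.

    ``time_s`` counts from the start of the event's own period; ``x`` runs
    along the field length (0-120) toward the possessing team's attacking
    goal, ``y`` across the width (0-80).
    """

    match_id: str
    team: str  # "A" or "B"
    period: int  # 1 or 2
    time_s: float
    duration_s: float
    x: float
    y: float
    event_type: str

    def validate(self) -> None:
        if self.team not in ("A", "B"):
            raise SchemaError(f"team must be 'A' or 'B', got {self.team!r}")
        if self.period not in (1, 2):
            raise SchemaError(f"period must be 1 or 2, got {self.period!r}")
        if not (self.time_s >= 0 and math.isfinite(self.time_s)):
            raise SchemaError(f"time_s must be finite and >= 0, got {self.time_s!r}")
        if not (self.duration_s >= 0 and math.isfinite(self.duration_s)):
            raise SchemaError(f"duration_s must be finite and >= 0, got {self.duration_s!r}")
        if not (0.0 <= self.x <= FIELD_LENGTH):
            raise SchemaError(f"x out of range [0, {FIELD_LENGTH:g}]: {self.x!r}")
        if not (0.0 <= self.y <= FIELD_WIDTH):
            raise SchemaError(f"y out of range [0, {FIELD_WIDTH:g}]: {self.y!r}")


@dataclass
class MatchRecord:
    """A labeled two-team match: its events, result, and period durations.

    ``period_end_s`` maps period -> full duration of that period in seconds,
    injury time included. When not supplied it is inferred as
    ``max(time_s + duration_s)`` over the period's events.
    """

    match_id: str
    events: list[MatchEvent] = field(default_factory=list)
    result: int = 0  # 1 = Team A win, 0 = Team B win
    period_end_s: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.result not in (0, 1):
            raise SchemaError(
                f"match {self.match_id}: result must be 0 or 1 (draws must be "
                f"excluded upstream), got {self.result!r}"
            )
        if not self.period_end_s:
            self.period_end_s = self._infer_period_ends()
        for ev in self.events:
            end = self.period_end_s.get(ev.period)
            if end is not None and ev.time_s > end + 1e-9:
                raise SchemaError(
                    f"match {self.match_id}: event at time_s={ev.time_s} exceeds "
                    f"period {ev.period} duration {end}"
                )

    def _infer_period_ends(self) -> dict[int, float]:
        ends: dict[int, float] = {}
        for ev in self.events:
            ends[ev.period] = max(ends.get(ev.period, 0.0), ev.time_s + ev.duration_s)
        return ends

    def total_duration_s(self) -> float:
        return float(sum(ev.duration_s for ev in self.events))


@dataclass(frozen=True)
class EventFilterConfig:
    """Which event types count as ball movement, and whether to drop
    zero-duration events (they carry no weight in the possession matrices)."""

    included_event_types: frozenset[str] = DEFAULT_INCLUDED_TYPES
    drop_zero_duration: bool = True

    def __post_init__(self) -> None:
        if not self.included_event_types:
            raise ValueError("included_event_types must be non-empty")


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _coerce_row(raw: Mapping[str, object], row_no: int) -> MatchEvent:
    missing = [k for k in _EVENT_FIELDS if k not in raw or raw[k] in (None, "")]
    if missing:
        raise SchemaError(f"row {row_no}: missing field(s) {', '.join(missing)}")
    try:
        ev = MatchEvent(
            match_id=str(raw["match_id"]),
            team=str(raw["team"]),
            period=int(raw["period"]),
            time_s=float(raw["time_s"]),
            duration_s=float(raw["duration_s"]),
            x=float(raw["x"]),
            y=float(raw["y"]),
            event_type=str(raw["event_type"]),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"row {row_no}: {exc}") from exc
    try:
        ev.validate()
    except SchemaError as exc:
        raise SchemaError(f"row {row_no}: {exc}") from exc
    return ev


def read_results(path: str | Path) -> dict[str, int]:
    """Read a ``match_id,result`` CSV into a mapping. A result outside {0,1}
    (e.g. a draw code) is an error: drawn matches must be excluded upstream."""
    results: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"match_id", "result"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: results file must have columns match_id,result")
        for row_no, row in enumerate(reader, start=2):
            raw = row["result"].strip()
            try:
                value = int(raw)
            except ValueError as exc:
                raise SchemaError(f"{path} row {row_no}: non-integer result {raw!r}") from exc
            if value not in (0, 1):
                raise SchemaError(
                    f"{path} row {row_no}: result {value} is not 0/1 — drawn or "
                    "unresolved matches must be excluded before ingestion"
                )
            results[row["match_id"]] = value
    return results


def read_period_ends(path: str | Path) -> dict[str, dict[int, float]]:
    """Read an optional ``match_id,period,end_s`` CSV of period durations."""
    out: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.setdefault(row["match_id"], {})[int(row["period"])] = float(row["end_s"])
    return out


def read_event_log(
    events_path: str | Path,
    format: str = "jsonl",
    results: str | Path | Mapping[str, int] | None = None,
    period_ends: str | Path | Mapping[str, Mapping[int, float]] | None = None,
) -> list[MatchRecord]:
    """Read an event log (plus results) into validated :class:`MatchRecord` s.

    Parameters
    ----------
    events_path:
        JSON-lines or CSV event file in the documented flat schema.
    format:
        ``"jsonl"`` (canonical) or ``"csv"``.
    results:
        ``match_id -> result`` mapping or path to a ``match_id,result`` CSV.
        Required: matches without a winner label cannot be represented.
    period_ends:
        Optional explicit period durations (mapping or ``match_id,period,end_s``
        CSV). Missing entries are inferred from the events.
    """
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
    if results is None:
        raise ValueError("a results mapping or results CSV path is required")
    if not isinstance(results, Mapping):
        results = read_results(results)
    if period_ends is not None and not isinstance(period_ends, Mapping):
        period_ends = read_period_ends(period_ends)

    events_by_match: dict[str, list[MatchEvent]] = {}
    with open(events_path, newline="") as fh:
        if format == "jsonl":
            rows: Iterable[Mapping[str, object]] = (
                json.loads(line) for line in fh if line.strip()
            )
        else:
            rows = csv.DictReader(fh)
        for row_no, raw in enumerate(rows, start=1):
            ev = _coerce_row(raw, row_no)
            events_by_match.setdefault(ev.match_id, []).append(ev)

    records = []
    for match_id, events in events_by_match.items():
        if match_id not in results:
            raise SchemaError(f"match {match_id}: no result label found")
        ends = dict((period_ends or {}).get(match_id, {}))
        records.append(
            MatchRecord(
                match_id=match_id,
                events=events,
                result=int(results[match_id]),
                period_end_s={int(k): float(v) for k, v in ends.items()},
            )
        )
    return records


def write_event_log(
    records: Sequence[MatchRecord],
    events_path: str | Path,
    results_path: str | Path | None = None,
    periods_path: str | Path | None = None,
    format: str = "jsonl",
    float_decimals: int = 6,
) -> None:
    """Write records back to the flat schema (events + results + periods).

    Coordinates and durations are rounded to ``float_decimals`` places, the
    round-trip stability contract of the format.
    """
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")

    def row_of(ev: MatchEvent) -> dict[str, object]:
        return {
            "match_id": ev.match_id,
            "team": ev.team,
            "period": ev.period,
            "time_s": round(ev.time_s, float_decimals),
            "duration_s": round(ev.duration_s, float_decimals),
            "x": round(ev.x, float_decimals),
            "y": round(ev.y, float_decimals),
            "event_type": ev.event_type,
        }

    with open(events_path, "w", newline="") as fh:
        if format == "jsonl":
            for rec in records:
                for ev in rec.events:
                    fh.write(json.dumps(row_of(ev)) + "\n")
        else:
            writer = csv.DictWriter(fh, fieldnames=list(_EVENT_FIELDS))
            writer.writeheader()
            for rec in records:
                for ev in rec.events:
                    writer.writerow(row_of(ev))

    if results_path is not None:
        with open(results_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["match_id", "result"])
            for rec in records:
                writer.writerow([rec.match_id, rec.result])

    if periods_path is not None:
        with open(periods_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["match_id", "period", "end_s"])
            for rec in records:
                for period in sorted(rec.period_end_s):
                    writer.writerow(
                        [rec.match_id, period, round(rec.period_end_s[period], float_decimals)]
                    )


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------


def filter_ball_movement_events(
    record: MatchRecord, cfg: EventFilterConfig | None = None
) -> MatchRecord:
    """Keep only ball-movement events (and, by default, positive durations).

    Idempotent. If a team ends up with no events over the whole match, a
    warning is logged but the record is still returned — downstream intervals
    for that team simply become empty distributions.
    """
    cfg = cfg or EventFilterConfig()
    kept = [
        ev
        for ev in record.events
        if ev.event_type in cfg.included_event_types
        and (not cfg.drop_zero_duration or ev.duration_s > 0)
    ]
    dropped = len(record.events) - len(kept)
    if dropped:
        logger.info("match %s: dropped %d of %d events", record.match_id, dropped, len(record.events))
    for team in ("A", "B"):
        if not any(ev.team == team for ev in kept):
            logger.warning("match %s: team %s has no events after filtering", record.match_id, team)
    return replace(record, events=kept, period_end_s=dict(record.period_end_s))


def class_balance(dataset: Sequence[MatchRecord]) -> float:
    """Proportion of matches won by Team A (label 1)."""
    if len(dataset) == 0:
        raise ValueError("class_balance of an empty dataset is undefined")
    return sum(rec.result for rec in dataset) / len(dataset)
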