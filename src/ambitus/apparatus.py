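"""Static model of the Ambitus apparatus, tasks, trial schedule and event-log format.

The Ambitus is a rectangular Plexiglas corridor with 16 side boxes (2 inner +
2 outer per corridor segment) used to deliver 20 mg puffed-rice rewards, and
one infrared locomotion sensor at the midpoint of each corridor.  Trials last
300 s and sensor events are logged at 1 ms resolution.  This module holds the
apparatus geometry, the three baiting tasks, the pre/post trial schedule, and
a CSV event-log dialect with validation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

TRIAL_DURATION_MS = 300_000
REWARD_MASS_MG = 20.0

PHASES = ("PRE_ALL", "PRE_IN", "POST_ALL", "POST_EX", "POST_IN")

#: Each phase runs exactly one baiting task.
PHASE_TASK = {
    "PRE_ALL": 1,
    "PRE_IN": 2,
    "POST_ALL": 1,
    "POST_EX": 3,
    "POST_IN": 2,
}

EVENT_KINDS = ("corridor_cross", "box_entry", "box_exit", "reward_consumed")


@dataclass(frozen=True)
class Box:
    """One side box: corridor index 0-3, side 'inner'|'outer', position 0|1."""

    box_id: str
    corridor: int
    side: str
    position: int


@dataclass(frozen=True)
class ApparatusLayout:
    """The corridor rectangle: 16 boxes and 4 corridor-midpoint sensors."""

    boxes: tuple[Box, ...]
    midpoints: tuple[str, ...]

    @property
    def box_ids(self) -> tuple[str, ...]:
        return tuple(b.box_id for b in self.boxes)

    def boxes_on_side(self, side: str) -> tuple[str, ...]:
        return tuple(b.box_id for b in self.boxes if b.side == side)

    def boxes_in_corridor(self, corridor: int) -> tuple[Box, ...]:
        return tuple(b for b in self.boxes if b.corridor == corridor)

    def validate(self) -> None:
        if len(self.boxes) != 16:
            raise ValueError(f"expected 16 boxes, got {len(self.boxes)}")
        ids = [b.box_id for b in self.boxes]
        if len(set(ids)) != 16:
            raise ValueError("box identifiers must be unique")
        for side in ("inner", "outer"):
            if len(self.boxes_on_side(side)) != 8:
                raise ValueError(f"expected 8 {side} boxes")
        for c in range(4):
            per_side = {
                s: sum(1 for b in self.boxes_in_corridor(c) if b.side == s)
                for s in ("inner", "outer")
            }
            if per_side != {"inner": 2, "outer": 2}:
                raise ValueError(f"corridor {c} must hold 2 inner + 2 outer boxes")
        if len(self.midpoints) != 4:
            raise ValueError("expected one midpoint sensor per corridor")


def build_layout() -> ApparatusLayout:
    """Construct the standard 16-box layout.

    Corridors are indexed 0-3 clockwise from the start corner.  Box ids encode
    side and ordinal: I1..I8 inner, O1..O8 outer, numbered clockwise.
    """
    boxes = []
    for c in range(4):
        for pos in range(2):
            n = 2 * c + pos + 1
            boxes.append(Box(f"I{n}", c, "inner", pos))
            boxes.append(Box(f"O{n}", c, "outer", pos))
    midpoints = tuple(f"M{c}" for c in range(4))
    layout = ApparatusLayout(tuple(boxes), midpoints)
    layout.validate()
    return layout


@dataclass(frozen=True)
class TaskConfig:
    """A baiting task: which of the 16 boxes hold a reward.

    Task 1 baits all 16 boxes (symmetric); Task 2 baits the 8 inner boxes;
    Task 3 baits the 8 outer boxes.  The asymmetric tasks (2 and 3) are the
    only ones under which side-memory parameters are defined.
    """

    task_id: int
    baited: frozenset[str]
    duration_ms: int = TRIAL_DURATION_MS
    reward_mass_mg: float = REWARD_MASS_MG

    @property
    def reward_count(self) -> int:
        return len(self.baited)

    @property
    def symmetric(self) -> bool:
        layout = build_layout()
        return self.baited == frozenset(layout.box_ids)


def make_task(task_id: int, layout: ApparatusLayout | None = None) -> TaskConfig:
    """Task 1: all boxes; Task 2: inner boxes; Task 3: outer boxes."""
    layout = layout or build_layout()
    if task_id == 1:
        baited = frozenset(layout.box_ids)
    elif task_id == 2:
        baited = frozenset(layout.boxes_on_side("inner"))
    elif task_id == 3:
        baited = frozenset(layout.boxes_on_side("outer"))
    else:
        raise ValueError(f"unknown task id {task_id}")
    return TaskConfig(task_id=task_id, baited=baited)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: phase, task, day, and within-day ordinal."""

    trial_id: int
    phase: str
    task_id: int
    day: int
    within_day_index: int
    interval_tag: str  # "2min" within a session, "3h" between sessions, "day" overnight


@dataclass(frozen=True)
class StudySchedule:
    trials: tuple[TrialSpec, ...]

    @property
    def pre_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.phase.startswith("PRE"))

    @property
    def post_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.phase.startswith("POST"))

    def phase_of(self, trial_id: int) -> str:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t.phase
        raise KeyError(f"trial {trial_id} not in schedule")


def make_schedule() -> StudySchedule:
    """The study design: 4 pre-treatment trials on one day, then 16
    post-treatment trials over days 11-14.

    Pre-treatment (baseline, day 0): trials 1-2 PRE_ALL (Task 1, morning) and
    trials 3-4 PRE_IN (Task 2, 3 h later).  Post-treatment: trials 1-2
    POST_ALL (Task 1, day 11), trials 3-8 POST_EX (Task 3; 3-4 on day 11, 5-8
    on day 12), trials 9-16 POST_IN (Task 2, days 13-14).
    """
    trials: list[TrialSpec] = []

    def add(trial_id, phase, day, idx):
        tag = "2min" if idx % 2 == 1 else ("3h" if idx == 2 else "day")
        trials.append(TrialSpec(trial_id, phase, PHASE_TASK[phase], day, idx, tag))

    # Baseline day: two morning Task-1 trials, two afternoon Task-2 trials.
    for i in range(2):
        add(i + 1, "PRE_ALL", 0, i)
    for i in range(2):
        add(i + 3, "PRE_IN", 0, i + 2)

    post_plan = [
        ("POST_ALL", 11), ("POST_ALL", 11),
        ("POST_EX", 11), ("POST_EX", 11),
        ("POST_EX", 12), ("POST_EX", 12), ("POST_EX", 12), ("POST_EX", 12),
        ("POST_IN", 13), ("POST_IN", 13), ("POST_IN", 13), ("POST_IN", 13),
        ("POST_IN", 14), ("POST_IN", 14), ("POST_IN", 14), ("POST_IN", 14),
    ]
    day_counts: dict[int, int] = {}
    for i, (phase, day) in enumerate(post_plan):
        idx = day_counts.get(day, 0)
        day_counts[day] = idx + 1
        add(100 + i + 1, phase, day, idx)

    return StudySchedule(tuple(trials))


@dataclass(frozen=True)
class EventRecord:
    """A single beam-break record at millisecond resolution."""

    timestamp: int
    kind: str
    location: str
    animal_id: str
    trial_id: int


@dataclass
class EventStream:
    """Time-ordered sensor events for one animal-trial."""

    animal_id: str
    trial_id: int
    phase: str
    task_id: int
    events: list[EventRecord] = field(default_factory=list)
    group: str | None = None

    def __len__(self) -> int:
        return len(self.events)


EVENT_LOG_COLUMNS = [
    "animal_id", "trial_id", "phase", "task", "timestamp_ms", "kind", "location",
]


class EventLogError(ValueError):
    """Malformed or invalid event-log input."""


def write_event_log(streams: Iterable[EventStream]) -> str:
    """Serialize streams to the canonical CSV dialect (one trial = one block)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(EVENT_LOG_COLUMNS)
    for s in streams:
        for e in s.events:
            w.writerow([s.animal_id, s.trial_id, s.phase, s.task_id,
                        e.timestamp, e.kind, e.location])
    return buf.getvalue()


def read_event_log(source: str) -> list[EventStream]:
    """Parse the CSV event-log dialect into one EventStream per (animal, trial).

    ``source`` is a path or the CSV text itself (anything containing a
    newline is treated as text).  Rows are grouped by (animal_id, trial_id);
    rows of a trial are validated to be time-sorted.  Raises
    :class:`EventLogError` with a line number on malformed rows.
    """
    if "\n" in source or "," in source:
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    layout = build_layout()
    known_locations = set(layout.box_ids) | set(layout.midpoints)

    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise EventLogError("empty file: missing header")
    if [h.strip() for h in header] != EVENT_LOG_COLUMNS:
        raise EventLogError(f"bad header {header!r}; expected {EVENT_LOG_COLUMNS}")

    streams: dict[tuple[str, int], EventStream] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != 7:
            raise EventLogError(f"line {lineno}: expected 7 fields, got {len(row)}")
        animal, trial_s, phase, task_s, ts_s, kind, loc = (v.strip() for v in row)
        try:
            trial = int(trial_s)
            task = int(task_s)
            ts = int(ts_s)
        except ValueError as exc:
            raise EventLogError(f"line {lineno}: non-integer field ({exc})")
        if kind not in EVENT_KINDS:
            raise EventLogError(f"line {lineno}: unknown event kind {kind!r}")
        if loc not in known_locations:
            raise EventLogError(f"line {lineno}: unknown location {loc!r}")
        if phase not in PHASES:
            raise EventLogError(f"line {lineno}: unknown phase {phase!r}")
        if PHASE_TASK[phase] != task:
            raise EventLogError(
                f"line {lineno}: phase {phase} implies task {PHASE_TASK[phase]}, got {task}")
        key = (animal, trial)
        if key not in streams:
            streams[key] = EventStream(animal, trial, phase, task)
        s = streams[key]
        if s.events and ts < s.events[-1].timestamp:
            raise EventLogError(
                f"non-monotone timestamps in trial {trial} of animal {animal} "
                f"(line {lineno})")
        s.events.append(EventRecord(ts, kind, loc, animal, trial))

    out = list(streams.values())
    for s in out:
        task = make_task(s.task_id, layout)
        report = validate_event_stream(s, task, layout)
        if report:
            raise EventLogError(
                f"invalid stream (animal {s.animal_id}, trial {s.trial_id}): "
                + "; ".join(report))
    return out


def validate_event_stream(
    stream: EventStream,
    task: TaskConfig,
    layout: ApparatusLayout | None = None,
) -> list[str]:
    """Return a list of invariant violations (empty list = valid).

    Checks: timestamps within [0, 300 000] and non-decreasing; locations exist;
    corridor crossings at midpoints and box events at boxes; reward_consumed
    only at baited boxes, at most once per box; box_exit never before its
    box_entry.
    """
    layout = layout or build_layout()
    midpoints = set(layout.midpoints)
    box_ids = set(layout.box_ids)
    violations: list[str] = []
    rewarded: set[str] = set()
    entered: dict[str, int] = {}
    prev_ts = -1
    for e in stream.events:
        if not (0 <= e.timestamp <= task.duration_ms):
            violations.append(
                f"timestamp {e.timestamp} outside [0, {task.duration_ms}]")
        if e.timestamp < prev_ts:
            violations.append(f"timestamp {e.timestamp} decreases after {prev_ts}")
        prev_ts = max(prev_ts, e.timestamp)
        if e.kind == "corridor_cross":
            if e.location not in midpoints:
                violations.append(f"corridor_cross at non-midpoint {e.location}")
            continue
        if e.location not in box_ids:
            violations.append(f"{e.kind} at unknown box {e.location}")
            continue
        if e.kind == "box_entry":
            entered[e.location] = entered.get(e.location, 0) + 1
        elif e.kind == "box_exit":
            if entered.get(e.location, 0) <= 0:
                violations.append(f"box_exit at {e.location} before any box_entry")
            else:
                entered[e.location] -= 1
        elif e.kind == "reward_consumed":
            if e.location not in task.baited:
                violations.append(
                    f"reward_consumed at unbaited box {e.location} (task {task.task_id})")
            if e.location in rewarded:
                violations.append(f"duplicate reward_consumed at {e.location}")
            rewarded.add(e.location)
    return violations
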