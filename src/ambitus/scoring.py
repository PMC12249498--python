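"""Behavioral parameters computed from a single trial's event stream.

Eleven parameters are scored per trial:

==============  =====================================================
Loco            corridor-midpoint crossings in the 300 s trial
Expl            box visits (entries) in the 300 s trial
Expl_FR_RW      rewarded-box visits up to Eat_T, scaled to per-300 s
Expl_FR_NRW     non-rewarded-box visits up to Eat_T, per-300 s
Lat_RW          latency (s) to the first rewarded-box visit
Lat_NRW         latency (s) to the first non-rewarded-box visit
Skipping        corridor crossings before the first box visit
A_E             % of pre-Eat_T explorations that yielded a reward
L_C             Eat_N*300*100 / (n_rewards * Eat_T)  (learning capacity)
W_M             % of rewarded-box visits (up to Eat_T) that yielded a
                reward; penalizes revisits (working memory)
R_M             % of all visits (up to Eat_T) aimed at rewarded boxes
                (reference memory)
==============  =====================================================

Eat_N is the number of rewards consumed and Eat_T (s) the time at which the
last reward was collected, censored at the full 300 s window when collection
is incomplete.  The side-discriminating parameters (Expl_FR_NRW, Lat_NRW,
W_M, R_M) are undefined under the symmetric all-baited task and reported as
missing, never zero.

Conventions: "up to Eat_T" windows are closed (timestamp <= Eat_T*1000, the
reward-consuming visit included); a box class never visited gets latency
censored at 300 s; visits at exactly t = 300 000 ms count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .apparatus import EventStream, StudySchedule, TaskConfig, make_task


@dataclass(frozen=True)
class EatingSummary:
    eat_n: int
    eat_t: float  # seconds; = last-reward time iff all rewards collected, else 300
    all_collected: bool


@dataclass(frozen=True)
class TrialScores:
    loco: int
    expl: int
    expl_fr_rw: float
    expl_fr_nrw: float | None
    lat_rw: float
    lat_nrw: float | None
    skipping: int
    a_e: float | None
    l_c: float
    w_m: float | None
    r_m: float | None
    eat_n: int
    eat_t: float
    all_collected: bool
    symmetric_task: bool
    na_reasons: dict = None  # field name -> reason code for N/A entries

    def as_dict(self) -> dict:
        return {
            "loco": self.loco, "expl": self.expl,
            "expl_fr_rw": self.expl_fr_rw, "expl_fr_nrw": self.expl_fr_nrw,
            "lat_rw": self.lat_rw, "lat_nrw": self.lat_nrw,
            "skipping": self.skipping, "a_e": self.a_e, "l_c": self.l_c,
            "w_m": self.w_m, "r_m": self.r_m,
            "eat_n": self.eat_n, "eat_t": self.eat_t,
        }


#: Parameter columns of the long-format score table, in report order.
PARAMETERS = [
    "loco", "expl", "expl_fr_rw", "expl_fr_nrw", "lat_rw", "lat_nrw",
    "skipping", "a_e", "l_c", "w_m", "r_m",
]


def compute_eating_summary(stream: EventStream, task: TaskConfig) -> EatingSummary:
    """Eat_N and Eat_T for one trial.

    Eat_T is the time of the last reward consumption when every baited box
    was emptied, otherwise the full 300 s window (so that L_C degrades to
    the fraction of rewards collected).
    """
    reward_times = [e.timestamp for e in stream.events if e.kind == "reward_consumed"]
    eat_n = len(reward_times)
    duration_s = task.duration_ms / 1000.0
    if eat_n >= task.reward_count and reward_times:
        return EatingSummary(eat_n, max(reward_times) / 1000.0, True)
    return EatingSummary(eat_n, duration_s, False)


def score_trial(stream: EventStream, task: TaskConfig) -> TrialScores:
    """Score all eleven behavioral parameters for one trial."""
    summary = compute_eating_summary(stream, task)
    eat_t_ms = summary.eat_t * 1000.0
    duration_ms = task.duration_ms
    duration_s = duration_ms / 1000.0
    na: dict[str, str] = {}

    crossings = [e for e in stream.events
                 if e.kind == "corridor_cross" and e.timestamp <= duration_ms]
    visits = [e for e in stream.events
              if e.kind == "box_entry" and e.timestamp <= duration_ms]

    loco = len(crossings)
    expl = len(visits)

    rw_visits = [v for v in visits if v.location in task.baited]
    nrw_visits = [v for v in visits if v.location not in task.baited]

    # windowed counts: events up to and including Eat_T
    visits_w = [v for v in visits if v.timestamp <= eat_t_ms]
    rw_w = sum(1 for v in visits_w if v.location in task.baited)
    all_w = len(visits_w)
    nrw_w = all_w - rw_w

    expl_fr_rw = rw_w * duration_s / summary.eat_t

    lat_rw = min((v.timestamp for v in rw_visits), default=duration_ms) / 1000.0

    first_visit_ts = visits[0].timestamp if visits else None
    if first_visit_ts is None:
        skipping = 0
    else:
        skipping = sum(1 for c in crossings if c.timestamp < first_visit_ts)

    if all_w > 0:
        a_e = summary.eat_n * 100.0 / all_w
    else:
        a_e = None
        na["a_e"] = "no explorations before Eat_T"

    l_c = (summary.eat_n * duration_s * 100.0) / (task.reward_count * summary.eat_t)

    if task.symmetric:
        expl_fr_nrw = lat_nrw = w_m = r_m = None
        for f in ("expl_fr_nrw", "lat_nrw", "w_m", "r_m"):
            na[f] = "symmetric task"
    else:
        expl_fr_nrw = nrw_w * duration_s / summary.eat_t
        lat_nrw = min((v.timestamp for v in nrw_visits), default=duration_ms) / 1000.0
        if rw_w > 0:
            w_m = summary.eat_n * 100.0 / rw_w
        else:
            w_m = None
            na["w_m"] = "no rewarded-box visits (division by zero)"
        if all_w > 0:
            r_m = rw_w * 100.0 / all_w
        else:
            r_m = None
            na["r_m"] = "no explorations before Eat_T"

    return TrialScores(
        loco=loco, expl=expl, expl_fr_rw=expl_fr_rw, expl_fr_nrw=expl_fr_nrw,
        lat_rw=lat_rw, lat_nrw=lat_nrw, skipping=skipping, a_e=a_e, l_c=l_c,
        w_m=w_m, r_m=r_m, eat_n=summary.eat_n, eat_t=summary.eat_t,
        all_collected=summary.all_collected, symmetric_task=task.symmetric,
        na_reasons=na,
    )


def score_dataset(
    streams: list[EventStream],
    schedule: StudySchedule,
) -> pd.DataFrame:
    """Score every stream against its scheduled trial.

    Returns a long-format table, one row per animal-trial, with columns
    animal_id, group, trial_id, phase, task, eat_n, eat_t and the eleven
    parameters.  Undefined parameters are NaN (missing), never sentinels.
    """
    scheduled = {t.trial_id: t for t in schedule.trials}
    rows = []
    for s in streams:
        spec = scheduled.get(s.trial_id)
        if spec is None:
            raise KeyError(
                f"trial {s.trial_id} of animal {s.animal_id} has no schedule entry")
        if spec.phase != s.phase:
            raise KeyError(
                f"trial {s.trial_id}: stream phase {s.phase} != scheduled {spec.phase}")
        task = make_task(spec.task_id)
        sc = score_trial(s, task)
        row = {
            "animal_id": s.animal_id,
            "group": s.group,
            "trial_id": s.trial_id,
            "phase": s.phase,
            "task": spec.task_id,
            "eat_n": sc.eat_n,
            "eat_t": sc.eat_t,
        }
        for p in PARAMETERS:
            v = getattr(sc, p)
            row[p] = math.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)
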