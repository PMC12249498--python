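import numpy as np
import pytest

from ambitus.apparatus import EventRecord, EventStream, make_task


def _ev(ts, kind, loc, animal="R1", trial=3):
    return EventRecord(ts, kind, loc, animal, trial)


@pytest.fixture(scope="session")
def task2():
    return make_task(2)


@pytest.fixture(scope="session")
def task1():
    return make_task(1)


@pytest.fixture(scope="session")
def toy_stream():
    """Hand-worked Task-2 trial used as the scoring reference fixture.

    10 corridor crossings; 11 box visits (9 to inner/rewarded incl. one I1
    revisit, 2 to outer); all 8 rewards collected, the last at 80 500 ms.
    Hand-computed scores: loco=10, expl=11, skipping=2, lat_rw=6.0,
    lat_nrw=10.0, eat_n=8, eat_t=80.5, expl_fr_rw=9*300/80.5,
    expl_fr_nrw=1*300/80.5, a_e=80, l_c=100*300/80.5, w_m=800/9, r_m=90.
    """
    events = [
        _ev(2_000, "corridor_cross", "M0"),
        _ev(4_000, "corridor_cross", "M1"),
        _ev(6_000, "box_entry", "I1"),
        _ev(6_500, "reward_consumed", "I1"),
        _ev(10_000, "box_entry", "O1"),
        _ev(12_000, "box_entry", "I2"),
        _ev(12_500, "reward_consumed", "I2"),
        _ev(20_000, "box_entry", "I3"),
        _ev(20_500, "reward_consumed", "I3"),
        _ev(30_000, "box_entry", "I4"),
        _ev(30_500, "reward_consumed", "I4"),
        _ev(40_000, "box_entry", "I5"),
        _ev(40_500, "reward_consumed", "I5"),
        _ev(50_000, "box_entry", "I6"),
        _ev(50_500, "reward_consumed", "I6"),
        _ev(60_000, "box_entry", "I7"),
        _ev(60_500, "reward_consumed", "I7"),
        _ev(70_000, "box_entry", "I1"),
        _ev(80_000, "box_entry", "I8"),
        _ev(80_500, "reward_consumed", "I8"),
        _ev(90_000, "box_entry", "O2"),
    ]
    events += [_ev(95_000 + 5_000 * i, "corridor_cross", f"M{(2 + i) % 4}")
               for i in range(8)]
    return EventStream("R1", 3, "PRE_IN", 2, events)


def brute_force_scores(stream, task):
    """Independent reference scorer: single literal pass over the event list.

    Re-states every parameter definition directly, with no shared code or
    windowing shortcuts, as the oracle for score_trial.
    """
    dur = task.duration_ms
    rewards = [e for e in stream.events
               if e.kind == "reward_consumed" and e.timestamp <= dur]
    eat_n = len(rewards)
    if eat_n == task.reward_count:
        eat_t = rewards[-1].timestamp / 1000.0
    else:
        eat_t = dur / 1000.0

    loco = 0
    expl = 0
    first_visit = None
    first_rw = None
    first_nrw = None
    rw_upto = 0
    nrw_upto = 0
    crossing_times = []
    for e in stream.events:
        if e.timestamp > dur:
            continue
        if e.kind == "corridor_cross":
            loco += 1
            crossing_times.append(e.timestamp)
        elif e.kind == "box_entry":
            expl += 1
            if first_visit is None:
                first_visit = e.timestamp
            if e.location in task.baited:
                if first_rw is None:
                    first_rw = e.timestamp
                if e.timestamp <= eat_t * 1000.0:
                    rw_upto += 1
            else:
                if first_nrw is None:
                    first_nrw = e.timestamp
                if e.timestamp <= eat_t * 1000.0:
                    nrw_upto += 1

    all_upto = rw_upto + nrw_upto
    out = {
        "loco": loco,
        "expl": expl,
        "eat_n": eat_n,
        "eat_t": eat_t,
        "expl_fr_rw": rw_upto * 300.0 / eat_t,
        "lat_rw": (first_rw if first_rw is not None else dur) / 1000.0,
        # strictly earlier than the first box visit (same-ms ties excluded)
        "skipping": (sum(1 for t in crossing_times if t < first_visit)
                     if first_visit is not None else 0),
        "a_e": eat_n * 100.0 / all_upto if all_upto else None,
        "l_c": eat_n * 300.0 * 100.0 / (task.reward_count * eat_t),
    }
    if task.symmetric:
        out.update(expl_fr_nrw=None, lat_nrw=None, w_m=None, r_m=None)
    else:
        out["expl_fr_nrw"] = nrw_upto * 300.0 / eat_t
        out["lat_nrw"] = (first_nrw if first_nrw is not None else dur) / 1000.0
        out["w_m"] = eat_n * 100.0 / rw_upto if rw_upto else None
        out["r_m"] = rw_upto * 100.0 / all_upto if all_upto else None
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240613)
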