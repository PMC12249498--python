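"""Agent-based simulator of rats foraging in the corridor maze, plus
synthetic generators for saturation-binding and densitometry datasets.

The behavioral simulator is a discrete-event model on the corridor graph.
A rat circulates clockwise; inter-transition times are exponential with rate
``move_rate`` and each transition fires the corridor-midpoint beam.  On each
corridor pass the rat may explore one adjacent side box, governed by latent
traits:

- ``explore_prob``: probability a pass includes a box visit;
- ``lapse_prob``: probability exploration is suppressed for a pass
  (attentional lapse — raises skipping and corridor-only laps);
- ``baited_side_bias``: probability an exploration targets the baited side
  under asymmetric baiting (reference-memory proxy; ignored when all boxes
  are baited, where side choice is uniform);
- ``revisit_prob``: probability the rat re-enters an already-emptied baited
  box instead of redirecting (working-memory-failure proxy);
- ``consume_prob``: probability the rat eats on entering a baited, non-empty
  box; each box yields its reward at most once;
- ``dwell_ms``: mean in-box dwell (exponential), during which the clock
  advances.

These traits are not fitted to any animal; they exist so that cohorts with
group-structured trait contrasts produce the qualitative score contrasts a
pharmacological experiment would (stimulants raise locomotion, side-biased
explorers score high reference memory, lapse-prone animals skip corridors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .apparatus import (
    EventRecord,
    EventStream,
    StudySchedule,
    TaskConfig,
    build_layout,
    make_schedule,
    make_task,
)

_PROB_FIELDS = ("explore_prob", "baited_side_bias", "revisit_prob",
                "consume_prob", "lapse_prob")
_RATE_FIELDS = ("move_rate", "dwell_ms")
TRAIT_FIELDS = _RATE_FIELDS[:1] + _PROB_FIELDS + _RATE_FIELDS[1:]


@dataclass(frozen=True)
class RatProfile:
    """Latent behavioral traits of one simulated rat."""

    move_rate: float = 0.10        # corridor transitions per second
    explore_prob: float = 0.6
    baited_side_bias: float = 0.5  # naive side choice by default
    revisit_prob: float = 0.25
    consume_prob: float = 0.9
    lapse_prob: float = 0.15
    dwell_ms: float = 4000.0

    def validate(self) -> None:
        for f in _PROB_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside [0, 1]")
        for f in _RATE_FIELDS:
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative trait modifiers for one treatment group.

    ``multipliers`` maps trait name -> factor applied to the baseline;
    ``cv`` maps trait name -> between-animal coefficient of variation
    (lognormal, so modified traits stay positive).  Probabilities are
    clipped to [0, 1] after modification.
    """

    label: str
    multipliers: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    def validate(self) -> None:
        for k, v in self.cv.items():
            if v < 0:
                raise ValueError(f"cv[{k}]={v} negative")
        for k in list(self.multipliers) + list(self.cv):
            if k not in TRAIT_FIELDS:
                raise ValueError(f"unknown trait {k!r}")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    animals_per_group: int
    groups: tuple[GroupEffect, ...]
    baseline: RatProfile = RatProfile()
    schedule: StudySchedule | None = None
    default_cv: float = 0.2

    def validate(self) -> None:
        self.baseline.validate()
        for g in self.groups:
            g.validate()
        if self.animals_per_group < 1:
            raise ValueError("animals_per_group must be >= 1")


def _draw_profile(baseline: RatProfile, effect: GroupEffect,
                  default_cv: float, rng: np.random.Generator) -> RatProfile:
    """One animal's traits: baseline x group multiplier x lognormal(cv)."""
    values = {}
    for f in TRAIT_FIELDS:
        v = getattr(baseline, f) * effect.multipliers.get(f, 1.0)
        cv = effect.cv.get(f, default_cv)
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv * cv))
            v *= rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma)
        if f in _PROB_FIELDS:
            v = float(min(1.0, max(0.0, v)))
        values[f] = float(v)
    return RatProfile(**values)


def simulate_trial(
    profile: RatProfile,
    task: TaskConfig,
    seed: int | np.random.SeedSequence,
    animal_id: str = "A0",
    trial_id: int = 1,
    phase: str = "PRE_ALL",
) -> EventStream:
    """Simulate one 300 s trial; identical (profile, task, seed) give a
    byte-identical stream."""
    profile.validate()
    rng = np.random.default_rng(seed)
    layout = build_layout()
    events: list[EventRecord] = []
    remaining = set(task.baited)

    def emit(ts: float, kind: str, loc: str) -> bool:
        ts_i = int(round(ts))
        if ts_i > task.duration_ms:
            return False
        events.append(EventRecord(ts_i, kind, loc, animal_id, trial_id))
        return True

    t = 0.0
    corridor = int(rng.integers(4))
    while True:
        t += rng.exponential(1000.0 / profile.move_rate)
        if t > task.duration_ms:
            break
        if not emit(t, "corridor_cross", f"M{corridor}"):
            break
        # one exploration opportunity per corridor pass
        if rng.random() >= profile.lapse_prob and rng.random() < profile.explore_prob:
            if task.symmetric:
                side = "inner" if rng.random() < 0.5 else "outer"
            else:
                baited_side = "inner" if task.task_id == 2 else "outer"
                other = "outer" if baited_side == "inner" else "inner"
                side = baited_side if rng.random() < profile.baited_side_bias else other
            cands = [b for b in layout.boxes_in_corridor(corridor) if b.side == side]
            box = cands[int(rng.integers(len(cands)))]
            if box.box_id in task.baited and box.box_id not in remaining:
                # emptied baited box: revisit, or redirect to its unemptied
                # neighbour on the same side, or skip the visit entirely
                if rng.random() >= profile.revisit_prob:
                    alt = next((b for b in cands if b.box_id in remaining), None)
                    box = alt
            if box is not None:
                t_entry = t + rng.exponential(300.0)
                if not emit(t_entry, "box_entry", box.box_id):
                    break
                dwell = rng.exponential(profile.dwell_ms)
                if (box.box_id in remaining
                        and rng.random() < profile.consume_prob):
                    t_eat = t_entry + min(dwell * 0.5, 500.0 + rng.exponential(200.0))
                    if emit(t_eat, "reward_consumed", box.box_id):
                        remaining.discard(box.box_id)
                t_exit = t_entry + dwell
                if not emit(t_exit, "box_exit", box.box_id):
                    break
                t = t_exit
        corridor = (corridor + 1) % 4
    events.sort(key=lambda e: e.timestamp)
    return EventStream(animal_id, trial_id, phase, task.task_id, events)


def simulate_cohort(config: SimConfig) -> tuple[list[EventStream], pd.DataFrame]:
    """Simulate every (animal, scheduled trial) of a multi-group cohort.

    Returns the event streams and a table of the latent per-animal traits
    (one row per animal) for parameter-recovery checks.  Reproducibility:
    a root ``SeedSequence(config.seed)`` is split per animal (traits) and
    per (animal, trial) (trial stream), so any sub-run is re-derivable.
    """
    config.validate()
    schedule = config.schedule or make_schedule()
    root = np.random.SeedSequence(config.seed)
    streams: list[EventStream] = []
    truth_rows = []
    animal_no = 0
    for g_idx, effect in enumerate(config.groups):
        for a in range(config.animals_per_group):
            animal_id = f"{effect.label}_{a:02d}"
            trait_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy,
                                       spawn_key=(g_idx, a, 0)))
            profile = _draw_profile(config.baseline, effect,
                                    config.default_cv, trait_rng)
            truth_rows.append({"animal_id": animal_id, "group": effect.label,
                               **{f: getattr(profile, f) for f in TRAIT_FIELDS}})
            for t_idx, spec in enumerate(schedule.trials):
                task = make_task(spec.task_id)
                ss = np.random.SeedSequence(entropy=root.entropy,
                                            spawn_key=(g_idx, a, 1 + t_idx))
                s = simulate_trial(profile, task, ss, animal_id=animal_id,
                                   trial_id=spec.trial_id, phase=spec.phase)
                s.group = effect.label
                streams.append(s)
            animal_no += 1
    return streams, pd.DataFrame(truth_rows)


def generate_saturation_dataset(
    bmax: float,
    kd: float,
    concentrations: np.ndarray | list[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | None = 0,
    ns_slope: float = 20.0,
) -> pd.DataFrame:
    """Synthetic one-site saturation-binding table.

    Specific binding is Bmax*L/(Kd+L) + N(0, noise_sd); nonspecific binding
    is linear in L (``ns_slope`` fmol/mg per nM, plus the same noise), and
    total = specific + nonspecific, so both measured columns are populated.
    Columns: conc_nM, replicate, total, nonspecific (fmol/mg protein).
    """
    if bmax <= 0 or kd <= 0:
        raise ValueError("bmax and kd must be positive")
    L = np.asarray(concentrations, dtype=float)
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        specific = bmax * L / (kd + L)
        nonspecific = ns_slope * L
        if noise_sd > 0:
            specific = specific + rng.normal(0.0, noise_sd, size=L.shape)
            nonspecific = nonspecific + rng.normal(0.0, noise_sd, size=L.shape)
        for conc, ns, sp in zip(L, nonspecific, specific):
            rows.append({"conc_nM": conc, "replicate": rep,
                         "total": sp + ns, "nonspecific": ns})
    return pd.DataFrame(rows)


def generate_densitometry_dataset(
    true_ratios: dict,
    n_per_group: int,
    noise: float = 0.0,
    seed: int | None = 0,
    actin_od: float = 100.0,
    background: float = 10.0,
) -> pd.DataFrame:
    """Synthetic blot-densitometry table with beta-actin structure.

    For each group label -> true target/actin ratio, emits ``n_per_group``
    samples with raw band and local-background optical densities built so
    the background-subtracted normalized ratio has the given mean; ``noise``
    is the SD of a multiplicative Gaussian on the per-sample ratio.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, ratio in true_ratios.items():
        for i in range(n_per_group):
            r = ratio * (1.0 + rng.normal(0.0, noise)) if noise > 0 else ratio
            net_actin = actin_od
            rows.append({
                "sample_id": f"{group}_{i:02d}",
                "group": group,
                "target_od": background + r * net_actin,
                "target_background": background,
                "actin_od": background + net_actin,
                "actin_background": background,
            })
    return pd.DataFrame(rows)
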