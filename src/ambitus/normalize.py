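"""Phase-level aggregation and z-score normalization of behavioral scores.

Raw trial scores are first reduced to one value per (animal, phase,
parameter) — the mean over the phase's trials — and then z-scored within
each (phase, parameter) cell over all animals pooled across groups:
z = (x - mean) / SD.  For parameters where a *higher* raw value marks an
impairment (the two latencies and skipping) the z-score is inverted, so an
impaired animal always plots negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PARAMETERS

#: Higher raw value = worse performance; z sign flipped for these.
INVERTED_PARAMETERS = frozenset({"lat_rw", "lat_nrw", "skipping"})


def aggregate_phase(scores: pd.DataFrame,
                    parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-animal phase means of the trial-level score table.

    Missing trial values are ignored in the mean; a phase in which a
    parameter is never defined yields a missing value.  Returns a long
    table with columns animal_id, group, phase, parameter, value.
    """
    parameters = parameters or PARAMETERS
    keep = [c for c in ("animal_id", "group", "phase") if c in scores.columns]
    long = scores.melt(id_vars=keep, value_vars=parameters,
                       var_name="parameter", value_name="value")
    grouped = (long.groupby([c for c in keep if c != "group"] + ["parameter"],
                            dropna=False)
               .agg(value=("value", "mean"),
                    **({"group": ("group", "first")} if "group" in keep else {}))
               .reset_index())
    return grouped


@dataclass
class ZScoreTable:
    """Normalized scores plus the phase-population statistics behind them."""

    table: pd.DataFrame          # animal_id, [group,] phase, parameter, raw, z
    population: pd.DataFrame     # phase, parameter, mean, sd, n, degenerate
    inverted: frozenset


def zscore_phase(
    phase_means: pd.DataFrame,
    inverted: frozenset | set | None = None,
    ddof: int = 1,
) -> ZScoreTable:
    """Z-score phase means within each (phase, parameter) over all animals.

    ``ddof=1`` (sample SD) by default; set ``ddof=0`` for the population
    divisor.  Cells with SD = 0 or fewer than two values are flagged
    degenerate and their z left missing rather than zero-filled.
    """
    inverted = frozenset(INVERTED_PARAMETERS if inverted is None else inverted)
    df = phase_means.reset_index(drop=True)
    pop_rows = []
    z = np.full(len(df), np.nan)
    for (phase, param), idx in df.groupby(["phase", "parameter"]).groups.items():
        vals = df.loc[idx, "value"].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        n = int(ok.sum())
        mean = float(np.mean(vals[ok])) if n else np.nan
        sd = float(np.std(vals[ok], ddof=ddof)) if n > ddof else np.nan
        degenerate = n < 2 or not np.isfinite(sd) or sd == 0.0
        pop_rows.append({"phase": phase, "parameter": param,
                         "mean": mean, "sd": sd, "n": n,
                         "degenerate": degenerate})
        if not degenerate:
            cell = (vals - mean) / sd
            if param in inverted:
                cell = -cell
            z[np.asarray(idx)] = cell
    df["raw"] = df["value"]
    df["z"] = z
    df = df.drop(columns=["value"])
    return ZScoreTable(df, pd.DataFrame(pop_rows), inverted)
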