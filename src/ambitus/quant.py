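"""Blot-densitometry normalization and fluid-intake / drug-dose accounting.

Densitometry: band optical densities are background-subtracted locally and
normalized to beta-actin, then screened per group with the mean +/- 2 SD
outlier rule.  Intake: daily fluid consumption normalized to body weight
(mL/kg/day) times the drug concentration in the drinking water (mg/mL)
gives the oral dose (mg/kg/day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import exclude_outliers

#: Drug concentrations in drinking water, mg/mL.
DRUG_CONCENTRATIONS = {"caffeine": 0.5, "metformin": 1.0, "furosemide": 0.1}


def normalize_densitometry(records: pd.DataFrame,
                           screen_outliers: bool = True) -> pd.DataFrame:
    """Background-subtracted, actin-normalized expression per sample.

    value = (target_od - target_background) / (actin_od - actin_background).
    Samples with non-positive net actin are flagged invalid and excluded;
    with ``screen_outliers`` the mean +/- 2 SD rule is applied per group
    (skipped for groups of fewer than three valid samples).
    """
    req = ["target_od", "target_background", "actin_od", "actin_background"]
    for col in req:
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    df = records.copy()
    net_target = df["target_od"] - df["target_background"]
    net_actin = df["actin_od"] - df["actin_background"]
    df["invalid"] = net_actin <= 0
    df["exclusion_reason"] = np.where(df["invalid"], "non-positive net actin OD", "")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["normalized"] = np.where(df["invalid"], np.nan, net_target / net_actin)
    df["outlier"] = False
    if screen_outliers and "group" in df.columns:
        for g, idx in df.groupby("group").groups.items():
            vals = df.loc[idx, "normalized"]
            ok = vals.notna()
            if ok.sum() < 3:
                continue
            _, excluded = exclude_outliers(vals[ok].to_numpy())
            out_mask = ok & vals.isin(excluded)
            df.loc[idx[out_mask], "outlier"] = True
            df.loc[idx[out_mask], "exclusion_reason"] = "beyond mean +/- 2 SD"
    return df


def compute_intake_dose(
    records: pd.DataFrame,
    concentrations: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-animal daily fluid intake (mL/kg/day) and drug doses (mg/kg/day).

    ``records`` needs animal_id, fluid_ml, weight_kg (and optionally group,
    day, plus per-drug concentration columns named ``conc_<drug>`` in mg/mL;
    absent columns fall back to ``concentrations``).  Daily values are
    computed first, then averaged across days per animal.
    """
    for col in ("animal_id", "fluid_ml", "weight_kg"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    if records["weight_kg"].isna().any() or (records["weight_kg"] <= 0).any():
        bad = records.loc[records["weight_kg"].isna()
                          | (records["weight_kg"] <= 0), "animal_id"].tolist()
        raise ValueError(f"missing or non-positive body weight for {bad}")
    concentrations = dict(concentrations or {})
    df = records.copy()
    df["fluid_ml_per_kg"] = df["fluid_ml"] / df["weight_kg"]
    drug_cols = {}
    for drug, conc in concentrations.items():
        col = f"conc_{drug}"
        if col not in df.columns:
            df[col] = conc
    for col in df.columns:
        if col.startswith("conc_"):
            drug = col[len("conc_"):]
            dose_col = f"dose_{drug}_mg_per_kg"
            df[dose_col] = df["fluid_ml_per_kg"] * df[col]
            drug_cols[drug] = dose_col
    keys = [c for c in ("animal_id", "group") if c in df.columns]
    per_animal = (df.groupby(keys, as_index=False)
                  [["fluid_ml_per_kg"] + list(drug_cols.values())].mean())
    return per_animal


def group_summary(per_animal: pd.DataFrame,
                  by: str = "group") -> pd.DataFrame:
    """Mean +/- SEM of intake and dose columns per group."""
    value_cols = [c for c in per_animal.columns
                  if c == "fluid_ml_per_kg" or c.startswith("dose_")]

    def sem(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    out = per_animal.groupby(by)[value_cols].agg(["mean", sem, "count"])
    out.columns = [f"{c}_{s if s != '<lambda>' else 'sem'}"
                   for c, s in out.columns]
    out.columns = [c.replace("_sem_", "_sem") for c in out.columns]
    return out.reset_index()
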