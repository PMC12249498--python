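"""Saturation radioligand-binding analysis (one-site specific binding).

Specific binding at free ligand concentration L follows the hyperbola

    B(L) = Bmax * L / (Kd + L)

with Bmax the maximal binding capacity (fmol receptor per mg membrane
protein) and Kd the equilibrium dissociation constant (nM).  The workflow
mirrors a standard bench analysis: within-assay duplicates are averaged per
concentration, specific = total - nonspecific, the hyperbola is fitted by
unweighted nonlinear least squares, and independent assay repeats are the
units of the group comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import TTestResult, unpaired_t

#: 1 Ci = 2.22e12 dpm, so one Ci/mmol of specific activity is 2.22 dpm/fmol.
DPM_PER_FMOL_PER_CI_MMOL = 2.22
SPIPERONE_SPECIFIC_ACTIVITY = 80.2  # Ci/mmol, [3H]spiperone


@dataclass(frozen=True)
class BindingFitResult:
    bmax: float           # fmol/mg protein
    kd: float             # nM
    bmax_se: float
    kd_se: float
    rss: float
    converged: bool
    poorly_constrained: bool = False
    note: str = ""


def one_site(L: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """The one-site specific-binding hyperbola."""
    return bmax * L / (kd + L)


def specific_binding(dataset: pd.DataFrame) -> pd.DataFrame:
    """Specific binding per concentration: mean(total) - mean(nonspecific).

    Expects columns conc_nM, total, nonspecific (replicate rows allowed;
    duplicates are averaged within each concentration first).  Negative
    specific values are kept for fitting but flagged.
    """
    for col in ("conc_nM", "total", "nonspecific"):
        if col not in dataset.columns:
            raise ValueError(f"missing column {col!r}")
    if dataset["nonspecific"].isna().any():
        bad = dataset.loc[dataset["nonspecific"].isna(), "conc_nM"].tolist()
        raise ValueError(f"missing nonspecific binding at L={bad}")
    agg = (dataset.groupby("conc_nM", as_index=False)
           .agg(total=("total", "mean"), nonspecific=("nonspecific", "mean")))
    agg["specific"] = agg["total"] - agg["nonspecific"]
    agg["negative_flag"] = agg["specific"] < 0
    return agg.sort_values("conc_nM").reset_index(drop=True)


def fit_one_site(specific: pd.DataFrame) -> BindingFitResult:
    """Fit B(L) = Bmax L / (Kd + L) by unweighted nonlinear least squares.

    Deterministic start heuristic: Bmax0 = 1.2 x max specific value, Kd0 =
    the concentration at half of Bmax0 (linear interpolation of the curve).
    Standard errors come from the estimate covariance.  A Kd fitted far
    above the top concentration is flagged poorly constrained.
    """
    L = specific["conc_nM"].to_numpy(dtype=float)
    B = specific["specific"].to_numpy(dtype=float)
    if len(np.unique(L)) < 3:
        raise ValueError("need at least three distinct concentrations")
    bmax0 = 1.2 * float(B.max())
    if bmax0 <= 0:
        raise ValueError("no positive specific binding to fit")
    half = bmax0 / 2.0
    order = np.argsort(L)
    Ls, Bs = L[order], B[order]
    kd0 = float(np.interp(half, Bs, Ls)) if Bs.max() >= half else float(Ls[-1])
    kd0 = max(kd0, 1e-6)
    try:
        popt, pcov = curve_fit(one_site, L, B, p0=(bmax0, kd0), maxfev=10000)
    except RuntimeError as exc:
        return BindingFitResult(math.nan, math.nan, math.nan, math.nan,
                                math.nan, converged=False, note=str(exc))
    bmax, kd = (float(v) for v in popt)
    resid = B - one_site(L, bmax, kd)
    rss = float((resid ** 2).sum())
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    poorly = kd > 3.0 * L.max()
    note = "Kd above 3x top concentration; poorly constrained" if poorly else ""
    return BindingFitResult(bmax, kd, float(ses[0]), float(ses[1]), rss,
                            converged=True, poorly_constrained=poorly,
                            note=note)


def dpm_to_fmol(dpm: float, specific_activity: float = SPIPERONE_SPECIFIC_ACTIVITY,
                efficiency: float = 1.0, protein_mg: float = 1.0) -> float:
    """Convert counted dpm to fmol bound per mg protein.

    fmol/mg = (dpm / efficiency) / (2.22 * specific_activity) / protein_mg,
    with specific activity in Ci/mmol (1 Ci = 2.22e12 dpm and 1 mmol =
    1e12 fmol, hence 2.22 dpm per fmol per Ci/mmol).
    """
    if specific_activity <= 0 or dpm < 0:
        raise ValueError("specific activity must be positive, dpm non-negative")
    if not 0 < efficiency <= 1:
        raise ValueError("counting efficiency must be in (0, 1]")
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    true_dpm = dpm / efficiency
    fmol = true_dpm / (DPM_PER_FMOL_PER_CI_MMOL * specific_activity)
    return fmol / protein_mg


def compare_binding(
    group_fits: dict[str, list[BindingFitResult]],
) -> pd.DataFrame:
    """Pairwise unpaired t-tests on Bmax and Kd across groups of assay fits.

    Each group's replicate fits (independent assay repeats) are the test
    units.  Returns one row per (pair, parameter) with t, df, p, and the
    across-assay means/SEMs alongside the fit-derived SEs.
    """
    for g, fits in group_fits.items():
        if len(fits) < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicate fits")
    labels = list(group_fits)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            for param in ("bmax", "kd"):
                va = np.array([getattr(f, param) for f in group_fits[a]])
                vb = np.array([getattr(f, param) for f in group_fits[b]])
                res: TTestResult = unpaired_t(va, vb)
                rows.append({
                    "group_a": a, "group_b": b, "parameter": param,
                    "mean_a": va.mean(), "sem_a": va.std(ddof=1) / np.sqrt(va.size),
                    "mean_b": vb.mean(), "sem_b": vb.std(ddof=1) / np.sqrt(vb.size),
                    "t": res.t, "df": res.df, "p": res.p,
                    "significant": res.p < 0.05,
                })
    return pd.DataFrame(rows)
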