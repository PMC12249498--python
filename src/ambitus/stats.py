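"""The study's statistical battery.

One-way ANOVA, two-factor mixed (between-group x within-phase)
repeated-measures ANOVA with the Greenhouse-Geisser sphericity correction,
Fisher's LSD post hoc, the pooled-variance unpaired two-tailed t-test, and
the single-pass mean +/- 2 SD outlier-exclusion rule.

All routines are computed from explicit sums of squares so that every
statistic is auditable against a textbook ANOVA table; the test suite
cross-checks them against scipy/pingouin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f: float
    df1: float
    df2: float
    p: float
    ms_effect: float
    ms_error: float
    epsilon: float | None = None      # GG epsilon, within effects only
    gg_applied: bool = False
    sphericity_p: float | None = None  # Mauchly p, within effects only
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class PosthocResult:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    df: float
    p: float
    degenerate: bool = False
    note: str = "Fisher LSD: unadjusted pairwise p; multiplicity uncontrolled"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    degenerate: bool = False


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def one_way_anova(groups: dict[str, "np.ndarray | list[float]"]) -> AnovaResult:
    """Classical between-groups one-way ANOVA.

    ``groups`` maps label -> values.  F = MS_between / MS_within with
    df (k-1, N-k).  Zero within-group variance is flagged degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: _clean(v) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than two values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1, df2 = k - 1, n_total - k
    ms_b = ss_between / df1
    ms_w = ss_within / df2
    if ms_w == 0.0:
        degenerate = ss_between > 0
        f = math.inf if degenerate else 0.0
        p = 0.0 if degenerate else 1.0
        return AnovaResult("group", f, df1, df2, p, ms_b, ms_w,
                           degenerate=True,
                           note="zero within-group variance")
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult("group", float(f), df1, df2, p, float(ms_b), float(ms_w))


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k within-subject covariance.

    Double-center the covariance and form epsilon = tr(S)^2 / ((k-1) tr(S^2));
    bounded in [1/(k-1), 1]."""
    k = cov.shape[0]
    row = cov.mean(axis=0, keepdims=True)
    centered = cov - row - row.T + cov.mean()
    tr = np.trace(centered)
    tr2 = np.trace(centered @ centered)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / ((k - 1) * tr2)
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def _mauchly_p(cov: np.ndarray, n_subjects: int, n_groups: int = 1) -> float:
    """Mauchly's sphericity test on the orthonormal-contrast covariance.

    Returns the chi-square approximation p-value; p = 1 when the contrast
    space is 1-dimensional (k = 2, sphericity trivially holds)."""
    k = cov.shape[0]
    if k <= 2:
        return 1.0
    # orthonormal contrasts: Helmert basis, normalized
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    S = C.T @ cov @ C
    d = k - 1
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (eig.mean() ** d)
    n_err = n_subjects - n_groups
    f_corr = 1.0 - (2 * d * d + d + 2) / (6.0 * d * n_err)
    chi2 = -f_corr * n_err * math.log(W)
    dof = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, dof))


def mixed_anova_gg(
    data: pd.DataFrame,
    dv: str = "z",
    subject: str = "animal_id",
    within: str = "phase",
    between: str = "group",
    gg: str = "auto",
) -> list[AnovaResult]:
    """Two-factor mixed ANOVA (between-subjects group x within-subject phase).

    Expects a long table with one row per (subject, phase).  Subjects with
    any missing phase are dropped listwise.  Returns results for the three
    effects: group (between), phase (within), and the interaction.

    ``gg`` controls the Greenhouse-Geisser df correction on the within
    effects: "auto" applies it when Mauchly's test rejects sphericity at
    p < 0.05, "always"/"never" override.
    """
    if gg not in ("auto", "always", "never"):
        raise ValueError("gg must be auto|always|never")
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, aggfunc="mean")
    phases = list(wide.columns)
    k = len(phases)
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    note = f"{dropped} subject(s) dropped listwise" if dropped else ""
    groups = wide.index.get_level_values(between)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    counts = {g: int((groups == g).sum()) for g in labels}
    if min(counts.values()) < 2:
        raise ValueError("need at least two complete subjects per group")

    Y = wide.to_numpy(dtype=float)          # subjects x phases
    N = Y.shape[0]
    g = len(labels)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    phase_means = Y.mean(axis=0)
    group_means = np.array([Y[groups == lab].mean() for lab in labels])
    n_i = np.array([counts[lab] for lab in labels], dtype=float)

    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_i * (group_means - grand) ** 2).sum()
    ss_subj_within_group = ss_subjects - ss_group
    ss_phase = N * ((phase_means - grand) ** 2).sum()
    cell_means = np.vstack([Y[groups == lab].mean(axis=0) for lab in labels])
    dev = cell_means - group_means[:, None] - phase_means[None, :] + grand
    ss_interaction = (n_i[:, None] * dev ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_error_within = (ss_total - ss_subjects - ss_phase - ss_interaction)

    df_group = g - 1
    df_subj = N - g
    df_phase = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (N - g) * (k - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within_group / df_subj
    ms_phase = ss_phase / df_phase
    ms_inter = ss_interaction / df_inter
    ms_err_w = ss_error_within / df_err_w

    # pooled within-group covariance of the phase measures
    cov = np.zeros((k, k))
    for lab in labels:
        Yg = Y[groups == lab]
        cov += (Yg - Yg.mean(axis=0)).T @ (Yg - Yg.mean(axis=0))
    cov /= (N - g)
    eps = _gg_epsilon(cov)
    mauchly_p = _mauchly_p(cov, N, g)
    apply_gg = {"auto": mauchly_p < 0.05, "always": True, "never": False}[gg]

    results = []
    f_group = ms_group / ms_subj if ms_subj > 0 else math.inf
    results.append(AnovaResult(
        "group", float(f_group), df_group, df_subj,
        float(sps.f.sf(f_group, df_group, df_subj)) if ms_subj > 0 else 0.0,
        float(ms_group), float(ms_subj), degenerate=ms_subj == 0, note=note))

    for name, ms, df1 in ((within, ms_phase, df_phase),
                          (f"{between} * {within}", ms_inter, df_inter)):
        if ms_err_w > 0:
            f = ms / ms_err_w
            a1, a2 = (df1 * eps, df_err_w * eps) if apply_gg else (df1, df_err_w)
            p = float(sps.f.sf(f, a1, a2))
            results.append(AnovaResult(name, float(f), a1, a2, p, float(ms),
                                       float(ms_err_w), epsilon=eps,
                                       gg_applied=apply_gg,
                                       sphericity_p=mauchly_p, note=note))
        else:
            results.append(AnovaResult(name, math.inf, df1, df_err_w, 0.0,
                                       float(ms), 0.0, epsilon=eps,
                                       gg_applied=apply_gg,
                                       sphericity_p=mauchly_p,
                                       degenerate=True, note=note))
    return results


def fisher_lsd(groups: dict[str, "np.ndarray | list[float]"],
               anova: AnovaResult | None = None) -> list[PosthocResult]:
    """Fisher's LSD: pairwise t with the ANOVA pooled error MS, unadjusted.

    t_ij = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j)), df = ANOVA error df.
    """
    anova = anova or one_way_anova(groups)
    arrays = {k: _clean(v) for k, v in groups.items()}
    mse, df = anova.ms_error, anova.df2
    out = []
    labels = list(arrays)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = arrays[a].mean() - arrays[b].mean()
            if mse == 0.0:
                out.append(PosthocResult(a, b, float(diff), math.inf, df, 0.0,
                                         degenerate=True))
                continue
            se = math.sqrt(mse * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
            t = diff / se
            p = float(2 * sps.t.sf(abs(t), df))
            out.append(PosthocResult(a, b, float(diff), float(t), df, p))
    return out


def unpaired_t(a, b, welch: bool = False) -> TTestResult:
    """Unpaired two-tailed t-test, pooled-variance (Student) by default.

    ``welch=True`` switches to the unequal-variance form."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            return TTestResult(math.inf if diff else 0.0,
                               a.size + b.size - 2, 0.0 if diff else 1.0,
                               float(diff), degenerate=True)
        t = diff / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        if sp2 == 0:
            return TTestResult(math.inf if diff else 0.0, df,
                               0.0 if diff else 1.0, float(diff),
                               degenerate=True)
        t = diff / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, float(diff))


def exclude_outliers(values, n_sd: float = 2.0,
                     ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass mean +/- 2 SD exclusion rule.

    Drops x with \\|x - mean\\| > n_sd * SD, mean and SD taken over all
    values; the rule is not iterated.  Returns (retained, excluded)."""
    a = _clean(values)
    if a.size < 3:
        raise ValueError("need at least three values")
    sd = a.std(ddof=ddof)
    if sd == 0:
        return a, np.array([])
    mask = np.abs(a - a.mean()) > n_sd * sd
    return a[~mask], a[mask]
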