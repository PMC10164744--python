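"""Nonparametric group statistics for the E-I measures.

The statistical layer mirrors a clinical resting-state comparison: extreme
outliers (beyond 3x the interquartile range outside the quartiles) are
flagged before testing; overall group differences use Kruskal-Wallis;
pairwise differences between each group and the reference (healthy elderly)
use two-sided Mann-Whitney U tests reported with pooled mean ranks;
per-frequency power comparisons are corrected with the two-stage
Benjamini-Krieger-Yekutieli step-up FDR procedure at q = 1%; associations
with the cognitive score use Spearman rank correlations.

scipy.stats provides the test statistics; the two-stage FDR procedure and
mean-rank bookkeeping are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sstats

FDR_Q = 0.01


def iqr_outliers(values, k: float = 3.0):
    """Flag values beyond ``k`` interquartile ranges outside Q1/Q3.

    Quartiles use linear interpolation between order statistics (the numpy
    default). Returns ``(kept_values, flagged_indices)``. With fewer than 4
    values no flagging is attempted (warning).
    """
    v = np.asarray(values, float)
    if v.size < 4:
        warnings.warn("fewer than 4 values; outlier rule not applied", stacklevel=2)
        return v, np.array([], dtype=int)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    bad = (v > q3 + k * iqr) | (v < q1 - k * iqr)
    return v[~bad], np.flatnonzero(bad)


def kruskal_wallis(groups):
    """Kruskal-Wallis H with tie correction; chi-square p with df = k - 1.

    Identical values across all groups give H = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("pooled sample size must be >= 3")
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = sstats.kruskal(*groups)
    return float(h), df, float(p)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    u: float
    mean_rank_a: float
    mean_rank_b: float
    n_a: int
    n_b: int
    p: float


def _mean_ranks(a, b):
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    return float(ranks[: len(a)].mean()), float(ranks[len(a):].mean())


def mann_whitney(a, b, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U with pooled mean ranks.

    U is the statistic of the first sample (number of pairs where ``a``
    exceeds ``b``, with half-counts for ties). The exact null distribution
    is used when both samples have at most ``exact_max_n`` observations and
    no ties are present; otherwise the tie-corrected normal approximation
    (with continuity correction) applies.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    ra, rb = _mean_ranks(a, b)
    return float(res.statistic), ra, rb, float(res.pvalue)


def mann_whitney_pairwise(reference, others: dict, reference_label: str = "ref"):
    """Mann-Whitney U of each group against the reference group."""
    out = []
    for label, vals in others.items():
        u, ra, rb, p = mann_whitney(reference, vals)
        out.append(PairwiseResult(reference_label, label, u, ra, rb,
                                  len(np.asarray(reference)), len(np.asarray(vals)), p))
    return out


def bky_fdr(pvalues, q: float = FDR_Q) -> np.ndarray:
    """Two-stage Benjamini-Krieger-Yekutieli step-up FDR; boolean mask.

    Stage 1 runs a linear step-up (BH) test at q' = q/(1+q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns the step-up at level
    q' * m / m0. With r1 = 0 nothing is rejected; with m0 = 0 everything is.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    r1 = _bh_reject_count(p, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    q2 = q1 * m / m0
    r2 = _bh_reject_count(p, q2)
    order = np.argsort(p, kind="mergesort")
    mask = np.zeros(m, dtype=bool)
    mask[order[:r2]] = True
    return mask


def _bh_reject_count(p: np.ndarray, q: float) -> int:
    m = p.size
    ps = np.sort(p)
    below = ps <= q * (np.arange(1, m + 1) / m)
    return int(np.max(np.flatnonzero(below)) + 1) if below.any() else 0


def spearman(x, y):
    """Spearman rank correlation with two-sided p.

    For n <= 9 (no ties) the p-value is computed by exact enumeration over
    all rank permutations; otherwise the t-distribution approximation of
    scipy applies. Zero rank variance gives (nan, nan) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("zero variance in ranks; rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(sstats.spearmanr(x, y).statistic)
    n = x.size
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 9 and not has_ties:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(sstats.spearmanr(x, y).pvalue)
    return rho, p


def _spearman_exact_p(x, y, rho_obs, atol=1e-12):
    # tie-free ranks: rho = 1 - 6 sum(d^2) / (n (n^2 - 1)); enumerate all
    # n! rank assignments vectorized
    n = x.size
    rx = sstats.rankdata(x)
    perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
    d2 = np.sum((perms - rx[None, :]) ** 2, axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - atol))


@dataclass
class GroupComparison:
    """Omnibus + pairwise comparison of one measure in one region."""

    measure: str
    region: str
    h: float
    df: int
    p: float
    pairwise: list = field(default_factory=list)


def compare_groups(values_by_group: dict, measure: str = "", region: str = "",
                   reference: str | None = None,
                   outlier_k: float = 3.0) -> GroupComparison:
    """Outlier removal, Kruskal-Wallis omnibus, pairwise U vs reference.

    NaN entries (missingness codes upstream) are dropped per group before
    the outlier rule. Pairwise results are reported regardless of omnibus
    significance.
    """
    cleaned = {}
    for label, vals in values_by_group.items():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if v.size >= 4:
            v, _ = iqr_outliers(v, k=outlier_k)
        cleaned[label] = v
    usable = {k: v for k, v in cleaned.items() if v.size >= 1}
    h, df, p = kruskal_wallis(list(usable.values()))
    pairwise = []
    if reference is not None and reference in usable:
        others = {k: v for k, v in usable.items() if k != reference}
        pairwise = mann_whitney_pairwise(usable[reference], others,
                                         reference_label=reference)
    return GroupComparison(measure=measure, region=region, h=h, df=df, p=p,
                           pairwise=pairwise)


def per_frequency_comparison(spectra_by_group: dict, reference_group: str,
                             q: float = FDR_Q) -> pd.DataFrame:
    """Per-bin Mann-Whitney U of each group against the reference, with the
    two-stage FDR applied per (group, region) family across bins.

    ``spectra_by_group`` maps group label -> (n_subjects, n_bins) array on a
    common frequency grid; pass the grid via a 'freqs' key or separately.
    Returns a tidy frame with columns group, freq_index, p, significant,
    direction (+1 where the group exceeds the reference median).
    """
    freqs = spectra_by_group.pop("freqs", None)
    ref = np.asarray(spectra_by_group[reference_group], float)
    rows = []
    for label, mat in spectra_by_group.items():
        if label == reference_group:
            continue
        mat = np.asarray(mat, float)
        if mat.shape[1] != ref.shape[1]:
            raise ValueError("frequency grids differ between groups")
        ps = np.empty(mat.shape[1])
        direction = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            _, _, _, ps[j] = mann_whitney(ref[:, j], mat[:, j])
            direction[j] = np.sign(np.median(mat[:, j]) - np.median(ref[:, j]))
        mask = bky_fdr(ps, q=q)
        for j in range(mat.shape[1]):
            rows.append({
                "group": label,
                "freq_index": j,
                "freq_hz": float(freqs[j]) if freqs is not None else np.nan,
                "p": ps[j],
                "significant": bool(mask[j]),
                "direction": direction[j],
            })
    return pd.DataFrame(rows)


def significant_ranges(df: pd.DataFrame, group: str) -> list[tuple[float, float]]:
    """Contiguous significant frequency ranges for one group (Fig-2-style
    red-bar summary)."""
    sub = df[df["group"] == group].sort_values("freq_index")
    ranges = []
    start = None
    prev_f = None
    for _, row in sub.iterrows():
        if row["significant"]:
            if start is None:
                start = row["freq_hz"]
            prev_f = row["freq_hz"]
        elif start is not None:
            ranges.append((start, prev_f))
            start = None
    if start is not None:
        ranges.append((start, prev_f))
    return ranges
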