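"""Paired nonparametric comparisons across plan conditions.

Three constraint levels (Conv, BVS-90%, BVS-80%) are compared within each
modality on a complete patients x conditions table: an omnibus Friedman test
(rank-based, average ranks for ties, chi-square reference with k-1 df),
followed — when the omnibus test is significant at alpha = 0.05 — by
post-hoc pairwise Wilcoxon signed-rank tests with Bonferroni correction over
the three pairs. Percent-reduction summaries report the mean of per-patient
reductions relative to a baseline column plus median (min-max) of the raw
metric, the presentation convention used for all study endpoints.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "friedman_test",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "bonferroni_adjust",
    "reduction_summary",
    "compare_levels",
]

ALPHA = 0.05


def _as_table(t) -> np.ndarray:
    arr = t.to_numpy(dtype=float) if isinstance(t, pd.DataFrame) else np.asarray(t, dtype=float)
    if arr.ndim != 2:
        raise DomainError("paired metric table must be 2-D (patients x conditions)")
    if np.isnan(arr).any():
        raise DomainError("paired metric table has missing cells")
    if arr.shape[0] < 2:
        raise DomainError("need at least 2 patients")
    return arr


#: largest number of within-row permutation arrangements enumerated exactly
_EXACT_LIMIT = 500_000


def friedman_test(table, method: str = "auto") -> tuple[float, float]:
    """Friedman rank test across >= 3 related conditions.

    Rows are subjects, columns conditions. Ties within a row get average
    ranks; the statistic uses the tie-corrected form
    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / sum_ij (r_ij - (k+1)/2)^2,
    which reduces to the classical 12/(nk(k+1)) formula without ties.

    The p-value comes from exhaustive enumeration of all (k!)^n within-row
    rank arrangements when that count is small enough (``method="auto"`` or
    ``"exact"``), and from the chi-square(k-1) reference distribution
    otherwise. Returns (statistic, p).
    """
    arr = _as_table(table)
    n, k = arr.shape
    if k < 3:
        raise DomainError("Friedman test needs >= 3 conditions")
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    center = (k + 1) / 2.0
    den = np.sum((ranks - center) ** 2)
    if den == 0:  # all rows fully tied: no rank variation at all
        return 0.0, 1.0
    stat = float((k - 1) * np.sum((col_sums - n * center) ** 2) / den)

    if method not in ("auto", "exact", "asymptotic"):
        raise DomainError(f"unknown method {method!r}")
    n_arrangements = math.factorial(k) ** n if k <= 6 else np.inf
    if method != "asymptotic" and k == 3 and n <= 500:
        p = _friedman_exact_p_k3(ranks, stat, den)
    elif method != "asymptotic" and n_arrangements <= _EXACT_LIMIT:
        p = _friedman_exact_p(ranks, stat, den, k)
    elif method == "exact":
        raise DomainError("table too large for exact Friedman enumeration")
    else:
        p = float(sps.chi2.sf(stat, k - 1))
    return stat, p


def _friedman_exact_p_k3(ranks: np.ndarray, stat: float, den: float) -> float:
    """Exact permutation p for k = 3 by dynamic programming.

    Tracks the joint distribution of the first two column rank sums over all
    equally likely within-row arrangements; ranks are doubled so average
    ranks from ties stay integral.
    """
    r2 = np.round(2 * ranks).astype(int)
    n = r2.shape[0]
    m = int(r2.max(axis=1).sum())
    dist = np.zeros((m + 1, m + 1))
    dist[0, 0] = 1.0
    perms = list(itertools.permutations(range(3)))
    for row in r2:
        new = np.zeros_like(dist)
        for p_ in perms:
            a, b = int(row[p_[0]]), int(row[p_[1]])
            new[a:, b:] += dist[: m + 1 - a, : m + 1 - b]
        dist = new / len(perms)
    i, j = np.nonzero(dist)
    prob = dist[i, j]
    total = float(r2.sum()) / 2.0
    c1, c2 = i / 2.0, j / 2.0
    c3 = total - c1 - c2
    center = n * 2.0  # n(k+1)/2 with k = 3
    stats_all = 2.0 * ((c1 - center) ** 2 + (c2 - center) ** 2
                       + (c3 - center) ** 2) / den
    return float(prob[stats_all >= stat - 1e-12].sum())


def _friedman_exact_p(ranks: np.ndarray, stat: float, den: float, k: int) -> float:
    """Exact permutation p: all within-row rearrangements of the rank rows.

    Under exchangeability every ordering of each row is equally likely; the
    denominator of the tie-corrected statistic is permutation-invariant, so
    only column sums need enumerating.
    """
    perms = np.array(list(itertools.permutations(range(k))))
    col_sums = np.zeros((1, k))
    for row in ranks:
        row_perms = row[perms]  # (k!, k) arrangements of this row
        col_sums = (col_sums[:, None, :] + row_perms[None, :, :]).reshape(-1, k)
    n = ranks.shape[0]
    center = (k + 1) / 2.0
    stats_all = (k - 1) * np.sum((col_sums - n * center) ** 2, axis=1) / den
    return float(np.mean(stats_all >= stat - 1e-12))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p: float
    n_effective: int  # pairs remaining after zero-difference removal
    all_zero: bool  # every difference was zero: p = 1 by convention
    method: str


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (Wilcoxon's convention); if all differences
    are zero the test is degenerate and p = 1 is returned with a flag. The
    exact null distribution is used for n <= 25 when the absolute
    differences are tie-free; otherwise the normal approximation with tie
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DomainError("paired vectors must be 1-D, equal length >= 2")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, "degenerate")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # exact null distribution of W+ (handles tied absolute differences)
        p = _signed_rank_exact_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, False, "exact")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=False, zero_method="wilcox")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n, False,
                          "approx")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank sum, by convolution.

    Each rank independently enters W+ with probability 1/2 under the null;
    ranks are doubled so tied (average) ranks stay integral. The two-sided
    p is the doubled smaller tail, capped at 1 — identical to full
    enumeration of the 2^n sign patterns.
    """
    r2 = np.round(2 * ranks).astype(int)
    m = int(r2.sum())
    pmf = np.zeros(m + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: m + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p) per value; monotone in p."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise DomainError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def reduction_summary(table: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Per-condition summary vs a baseline column.

    Returns one row per condition with the median and (min, max) of the raw
    metric and the mean per-patient percent reduction
    100 * (baseline - condition) / baseline. Patients whose baseline value is
    zero are excluded from the reduction mean with a warning.
    """
    if baseline not in table.columns:
        raise DomainError(f"baseline column {baseline!r} not in table")
    base = table[baseline].to_numpy(dtype=float)
    ok = base != 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} patient(s) with zero baseline excluded from "
            "percent-reduction summary", stacklevel=2)
    rows = []
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        red = 100.0 * (base[ok] - vals[ok]) / base[ok]
        rows.append({
            "condition": col,
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean_percent_reduction": float(red.mean()),
        })
    return pd.DataFrame(rows).set_index("condition")


def compare_levels(table: pd.DataFrame, alpha: float = ALPHA,
                   always_posthoc: bool = False) -> dict:
    """Omnibus Friedman + conditional Bonferroni-corrected post-hoc Wilcoxon.

    Post-hoc pairwise tests over all column pairs run only when the Friedman
    p-value is below ``alpha`` (set ``always_posthoc`` to run them anyway);
    the Bonferroni family size is the number of pairs.
    """
    stat, p = friedman_test(table)
    out = {"friedman_statistic": stat, "friedman_p": p, "posthoc": {}}
    if p < alpha or always_posthoc:
        pairs = list(itertools.combinations(table.columns, 2))
        raw = [wilcoxon_signed_rank(table[x], table[y]).p for x, y in pairs]
        adj = bonferroni_adjust(raw, m=len(pairs))
        out["posthoc"] = {
            f"{x} vs {y}": {"p_raw": float(pr), "p_adjusted": float(pa)}
            for (x, y), pr, pa in zip(pairs, raw, adj)
        }
    return out
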