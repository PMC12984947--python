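"""Agreement and group-comparison statistics.

Three validation statistics accompany the measurement chain:

* Spearman rank correlation (mid-ranks for ties, two-sided p via the
  large-sample t approximation) between the radiologic and histologic
  measurements, and between muscle volume and muscle wet weight;
* the intraclass correlation coefficient for intra-observer reliability,
  computed as the two-way, absolute-agreement, single-measurement ICC
  — ICC(2,1) — from the mean-square decomposition

      ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

  with n subjects and k repeated reads; the variant tag is always carried
  in the result, since an ICC without its variant is meaningless;
* one-way ANOVA across the study arms with Bonferroni-adjusted pairwise
  Welch-free (pooled-variance) t tests, adjusted p = min(1, raw p x
  number of pairs).

All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import FivolError


class StatsError(FivolError):
    pass


@dataclass
class CorrelationResult:
    rho: float
    p_value: Optional[float]
    n: int
    undefined: bool = False


@dataclass
class ReliabilityResult:
    icc: float
    model: str
    p_value: float
    n_subjects: int
    n_reads: int


@dataclass
class GroupComparison:
    omnibus_f: float
    omnibus_p: float
    pairwise: list[tuple[tuple[int, int], float, float]]  # (pair, raw p, adjusted p)
    degenerate: bool = False


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with two-sided t-approximation p-value.

    A constant vector has no rank ordering: rho is returned as nan with
    ``undefined`` set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise StatsError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p_value=None, n=x.size, undefined=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def icc(ratings: np.ndarray, variant: str = "ICC(2,1)") -> ReliabilityResult:
    """Two-way absolute-agreement single-measurement ICC on a subjects x reads matrix.

    Missing values are rejected rather than imputed. The p-value tests
    ICC = 0 via F = MSR / MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    Only the ICC(2,1) variant is implemented; the tag travels with the
    result.
    """
    if variant != "ICC(2,1)":
        raise StatsError(f"unsupported ICC variant {variant!r}")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise StatsError("ratings must be a (>=2 subjects) x (>=2 reads) matrix")
    if not np.all(np.isfinite(m)):
        raise StatsError("missing or non-finite ratings are rejected (no imputation)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_val = (msr - mse) / denom if denom != 0 else float("nan")
    if mse == 0:
        p = 0.0 if msr > 0 else 1.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ReliabilityResult(
        icc=float(icc_val), model=variant, p_value=p, n_subjects=n, n_reads=k
    )


def anova_bonferroni(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Bonferroni-adjusted pairwise t tests.

    Pairwise comparisons use two-sample pooled-variance t tests over all
    group pairs; adjusted p = min(1, raw p x number of pairs). All groups
    constant and equal leaves F undefined (degenerate flag, p = 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise StatsError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = list(combinations(range(len(arrays)), 2))
        return GroupComparison(
            omnibus_f=float("nan"),
            omnibus_p=1.0,
            pairwise=[(p, 1.0, 1.0) for p in pairs],
            degenerate=True,
        )
    f, p = sps.f_oneway(*arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
            raw = 1.0
        else:
            raw = float(sps.ttest_ind(arrays[i], arrays[j], equal_var=True).pvalue)
        pairwise.append(((i, j), raw, min(1.0, raw * m)))
    return GroupComparison(omnibus_f=float(f), omnibus_p=float(p), pairwise=pairwise)
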