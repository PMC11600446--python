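"""Nonparametric statistical battery for calibration stopping and reports.

Thin, convention-pinning wrappers over scipy.stats: Mann-Whitney (exact p
for combined n <= 20 without ties), Wilcoxon signed rank (zero differences
dropped, exact p for n <= 15 pairs without ties), and Spearman correlation
(full permutation p for n <= 10, t approximation otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
    "similarity_report",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y) -> TestResult:
    """Two-sided rank-sum test (tie-corrected U)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need size >= 2")
    exact = (x.size + y.size) <= 20 and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(int(x.size), int(y.size)),
        note="exact" if exact else "normal approximation with tie correction",
    )


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon's original convention) and the
    dropped count is reported; all-zero differences give the degenerate
    p = 1 with a note.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    diff = post - pre
    nz = diff[diff != 0.0]
    dropped = diff.size - nz.size
    if nz.size == 0:
        return TestResult(
            test="wilcoxon",
            statistic=0.0,
            p_value=1.0,
            n=(int(pre.size),),
            note=f"degenerate: all {dropped} differences zero",
        )
    exact = nz.size <= 15 and len(np.unique(np.abs(nz))) == nz.size
    res = sps.wilcoxon(
        nz, method="exact" if exact else "approx", zero_method="wilcox"
    )
    note = ("exact" if exact else "normal approximation") + (
        f"; {dropped} zero pair(s) dropped" if dropped else ""
    )
    return TestResult(
        test="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(int(nz.size),),
        note=note,
    )


def _spearman_rho(rx, ry) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with permutation p for n <= 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= 10:
        # exhaust all n! orderings of y's ranks, chunked and vectorized
        cx = rx - rx.mean()
        denom_x = np.sqrt(np.sum(cx**2))
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        perm_iter = itertools.permutations(ry)
        while True:
            chunk = np.array(list(itertools.islice(perm_iter, 200_000)))
            if chunk.size == 0:
                break
            cy = chunk - chunk.mean(axis=1, keepdims=True)
            denom_y = np.sqrt(np.sum(cy**2, axis=1))
            rhos = (cy @ cx) / (denom_x * denom_y)
            count += int(np.sum(np.abs(rhos) >= target))
            total += chunk.shape[0]
        p = count / total
        note = "exact permutation"
    else:
        res = sps.spearmanr(x, y)
        p = float(res.pvalue)
        note = "t approximation"
    return TestResult(
        test="spearman", statistic=rho, p_value=float(min(p, 1.0)), n=(int(n),),
        note=note,
    )


def similarity_report(virtual: dict, cohort: dict, alpha: float = 0.05):
    """Four-dimension Mann-Whitney comparison; pass iff all p > alpha.

    ``virtual`` and ``cohort`` map dimension name -> sample; both must
    provide the same four dimensions.
    """
    dims = list(cohort.keys())
    missing = [d for d in dims if d not in virtual]
    if missing or len(dims) < 4:
        raise ValueError(f"missing dimensions: {missing or dims}")
    results = {d: mann_whitney(virtual[d], cohort[d]) for d in dims}
    passed = all(r.p_value > alpha for r in results.values())
    return results, passed
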