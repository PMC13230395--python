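"""Repeated-measures significance testing across image sets.

The same subjects (volumes or lesions) are measured under several processing
conditions (e.g. raw fast, Gaussian-filtered, NLM, learned denoiser), so the
omnibus comparison is the Friedman rank test and the post-hoc pairwise
comparison is the Wilcoxon signed-rank test. Significance is declared at
strictly p < alpha (default 0.05) with no multiple-comparison correction by
default; an optional Holm step-down mode is available.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "friedman",
    "wilcoxon_signed_rank",
    "significance_report",
    "TestResult",
]


@dataclasses.dataclass
class TestResult:
    statistic: float
    pvalue: float
    n: int


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a complete 2-D table with >=2 rows and >=2 columns")
    if not np.isfinite(arr).all():
        raise ValueError("Friedman test requires a complete table (no NaN)")
    return arr


def friedman(table) -> TestResult:
    """Friedman chi-square for repeated measures, with tie correction.

    Rows are subjects, columns the repeated conditions. Each row is ranked
    with average ranks for ties; the statistic

        Q = [12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C,
        C = 1 - sum(t^3 - t) / (n k (k^2 - 1)),

    is referred to a chi-square with k-1 degrees of freedom. A table of
    identical columns (all ties) returns statistic 0 and p = 1.
    """
    arr = _as_table(table)
    n, k = arr.shape
    ranks = sps.rankdata(arr, axis=1)
    rank_sums = ranks.sum(axis=0)
    q_num = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction over rows
    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts.astype(np.float64) ** 3 - counts))
    c = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if c <= 0:
        return TestResult(0.0, 1.0, n)
    q = q_num / c
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult(float(q), p, n)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original policy); the null
    distribution is exact for n <= 25 non-zero pairs (when untied) and a
    tie-corrected normal approximation beyond. All differences zero is
    degenerate and yields NaN with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero: test undefined", stacklevel=2)
        return TestResult(float("nan"), float("nan"), 0)
    method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), int(nz.size))


def significance_report(
    table: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Omnibus + pairwise significance annotation for one metric table.

    ``table`` holds one row per subject and one column per image set. Output:
    one row for the Friedman test plus one per condition pair (Wilcoxon),
    each flagged ``significant`` when p < alpha strictly. No multiplicity
    correction is applied unless ``holm=True``.
    """
    df = pd.DataFrame(table)
    res = friedman(df.to_numpy())
    rows = [
        {
            "test": "friedman",
            "pair": "all",
            "statistic": res.statistic,
            "pvalue": res.pvalue,
            "n": res.n,
        }
    ]
    pairs = list(itertools.combinations(df.columns, 2))
    for a, b in pairs:
        r = wilcoxon_signed_rank(df[a].to_numpy(), df[b].to_numpy())
        rows.append(
            {
                "test": "wilcoxon",
                "pair": f"{a} vs {b}",
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "n": r.n,
            }
        )
    out = pd.DataFrame(rows)
    pvals = out["pvalue"].to_numpy()
    if holm:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        out["pvalue_holm"] = adj
        out["significant"] = adj < alpha
    else:
        out["significant"] = pvals < alpha
    return out
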