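"""Impact of MITE presence on host-gene expression.

For every MITE-related gene (>=1 interaction in >=1 accession), accessions
split into a with-MITE and a without-MITE group; RPKM values of the two
groups are compared with a two-sided Mann-Whitney U test, pooled over all
genes and per gene (with Benjamini-Hochberg adjustment across genes).

The small-sample path of the U test is exact: with no ties the exact null
distribution of U is computed by the standard counting recurrence; with
ties, all group assignments are enumerated (combined n <= 20, at most
C(20,10) = 184756 arrangements).  Larger samples use the normal
approximation with tie correction and continuity correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionTable

logger = logging.getLogger(__name__)

EXACT_MAX_N = 20


@dataclass
class MannWhitneyResult:
    u_a: float
    u_b: float
    p_value: float
    method: str  # "exact", "permutation", "asymptotic"

    @property
    def u(self) -> float:
        return min(self.u_a, self.u_b)


@dataclass
class ExpressionComparison:
    scope: str  # "pooled" or "per-gene:<gene_id>"
    group_with: list[float]
    group_without: list[float]
    statistic: float = float("nan")
    p_value: float = float("nan")
    adjusted_p: float = float("nan")
    mean_with: float = float("nan")
    mean_without: float = float("nan")
    testable: bool = True
    reason: str = ""


def normalize_accessions(
    table: ExpressionTable, method: str = "median"
) -> ExpressionTable:
    """Scale accession columns so their summaries over commonly expressed genes agree.

    ``method``: "median" (default) equalises per-accession medians over the
    genes expressed (>0, non-missing) in every accession; "upper_quartile"
    equalises 75th percentiles; "none" is the identity transform.
    """
    if method == "none":
        return ExpressionTable(table.frame)
    frame = table.frame
    common = frame.dropna(axis=0)
    common = common[(common > 0).all(axis=1)]
    if common.empty:
        raise ValueError("no commonly expressed genes to normalize on")
    if method == "median":
        anchors = common.median(axis=0)
    elif method == "upper_quartile":
        anchors = common.quantile(0.75, axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if (anchors <= 0).any():
        bad = list(anchors.index[anchors <= 0])
        raise ValueError(f"accession(s) with non-positive anchor: {bad}")
    target = float(anchors.mean())
    return ExpressionTable(frame * (target / anchors))


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    n_a, n_b = len(a), len(b)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2
    return u_a, n_a * n_b - u_a


def _exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Counts of U_a values 0..n_a*n_b under the no-ties null (recurrence)."""
    # counting recurrence: c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u)
    table: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n_a + 1):
        for j in range(n_b + 1):
            arr = np.zeros(i * j + 1)
            if i == 0 or j == 0:
                arr[0] = 1.0
            else:
                left = table[(i - 1, j)]
                right = table[(i, j - 1)]
                arr[j:] += left[: max(0, i * j - j + 1)]
                arr[: i * j - i + 1] += right
            table[(i, j)] = arr
    return table[(n_a, n_b)]


def _exact_p(u_a: float, n_a: int, n_b: int) -> float:
    counts = _exact_u_distribution(n_a, n_b)
    total = counts.sum()
    u_min = min(u_a, n_a * n_b - u_a)
    lo = counts[: int(math.floor(u_min + 1e-9)) + 1].sum()
    hi = counts[int(math.ceil(n_a * n_b - u_min - 1e-9)) :].sum()
    if u_min >= n_a * n_b - u_min - 1e-9:  # tails meet or cross
        return 1.0
    return float(min(1.0, (lo + hi) / total))


def _permutation_p(a: np.ndarray, b: np.ndarray, u_obs_min: float) -> float:
    combined = np.concatenate([a, b])
    n = len(combined)
    n_a = len(a)
    ranks = stats.rankdata(combined)
    total = 0
    extreme = 0
    prod = n_a * (n - n_a)
    for idx in itertools.combinations(range(n), n_a):
        r_a = ranks[list(idx)].sum()
        u_a = r_a - n_a * (n_a + 1) / 2
        u_min = min(u_a, prod - u_a)
        total += 1
        if u_min <= u_obs_min + 1e-9:
            extreme += 1
    return extreme / total


def mann_whitney_u(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact for combined n <= 20 (enumeration when ties are present), normal
    approximation with tie and continuity corrections beyond.  The two-sided
    exact p is the null probability that min(U_a, U_b) is at most the
    observed min(U_a, U_b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u_a, u_b = _u_statistics(a, b)
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    if n <= EXACT_MAX_N:
        if has_ties:
            p = _permutation_p(a, b, min(u_a, u_b))
            method = "permutation"
        else:
            p = _exact_p(u_a, len(a), len(b))
            method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return MannWhitneyResult(u_a=u_a, u_b=u_b, p_value=min(1.0, p), method=method)


# ---------------------------------------------------------------------------
# Pooled and per-gene comparisons


def _groups_for_gene(
    gene: str, presence: pd.DataFrame, frame: pd.DataFrame
) -> tuple[list[float], list[float]]:
    with_vals: list[float] = []
    without_vals: list[float] = []
    if gene not in frame.index:
        return with_vals, without_vals
    for acc in presence.columns:
        flag = presence.at[gene, acc]
        if pd.isna(flag) or acc not in frame.columns:
            continue
        val = frame.at[gene, acc]
        if pd.isna(val):
            continue
        (with_vals if flag > 0 else without_vals).append(float(val))
    return with_vals, without_vals


def pooled_comparison(
    presence: pd.DataFrame,
    table: ExpressionTable,
    unit: str = "per-accession-value",
) -> ExpressionComparison:
    """Pooled with-vs-without comparison over all MITE-related genes.

    ``unit``: "per-accession-value" pools every (gene, accession) RPKM;
    "per-gene-mean" pools one mean per gene per group.
    """
    frame = table.frame
    group_with: list[float] = []
    group_without: list[float] = []
    for gene in presence.index:
        w, wo = _groups_for_gene(gene, presence, frame)
        if unit == "per-accession-value":
            group_with += w
            group_without += wo
        elif unit == "per-gene-mean":
            if w:
                group_with.append(float(np.mean(w)))
            if wo:
                group_without.append(float(np.mean(wo)))
        else:
            raise ValueError(f"unknown pooling unit {unit!r}")
    comp = ExpressionComparison(
        scope="pooled", group_with=group_with, group_without=group_without
    )
    if not group_with or not group_without:
        comp.testable = False
        comp.reason = "one group empty"
        return comp
    res = mann_whitney_u(group_with, group_without)
    comp.statistic = res.u
    comp.p_value = res.p_value
    comp.mean_with = float(np.mean(group_with))
    comp.mean_without = float(np.mean(group_without))
    return comp


def per_gene_comparison(
    presence: pd.DataFrame, table: ExpressionTable
) -> list[ExpressionComparison]:
    """One exact test per gene, BH-adjusted across testable genes."""
    frame = table.frame
    comparisons: list[ExpressionComparison] = []
    for gene in presence.index:
        w, wo = _groups_for_gene(gene, presence, frame)
        comp = ExpressionComparison(
            scope=f"per-gene:{gene}", group_with=w, group_without=wo
        )
        if not w or not wo:
            comp.testable = False
            comp.reason = "one group empty"
        else:
            res = mann_whitney_u(w, wo)
            comp.statistic = res.u
            comp.p_value = res.p_value
            comp.mean_with = float(np.mean(w))
            comp.mean_without = float(np.mean(wo))
        comparisons.append(comp)
    testable = [c for c in comparisons if c.testable]
    if testable:
        adjusted = stats.false_discovery_control(
            [c.p_value for c in testable], method="bh"
        )
        for c, q in zip(testable, adjusted):
            c.adjusted_p = float(q)
    return comparisons
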