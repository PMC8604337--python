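"""Autosomal CNA-burden summation and rank-sum group comparison.

Per-tumor autosomal copy-number-aberration counts are summed (sex
chromosomes excluded) and compared between tumor subtype groups with a
Mann-Whitney U test implemented from first principles: U from joint
mid-ranks, an exact two-sided p by full enumeration of the permutation
null for small untied samples, and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import is_sex_chromosome

__all__ = ["GroupComparison", "sum_autosomal_burden", "mann_whitney", "compare_groups"]

#: combined sample size at or below which the exact enumeration is used (no ties)
EXACT_ENUMERATION_LIMIT = 12

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group rank-sum comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float  # U for group_a
    p_value: float  # two-sided
    method: str  # "exact" | "normal-approximation"

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "U": self.u_statistic,
            "p_two_sided": self.p_value,
            "method": self.method,
        }


def _is_autosome(name: str) -> bool:
    if is_sex_chromosome(name):
        return False
    if _AUTOSOME_RE.match(str(name)):
        return True
    raise ValueError(f"unrecognized chromosome label: {name!r}")


def sum_autosomal_burden(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor autosomal CNA totals with subtype labels.

    Accepts either a per-chromosome layout (tumor, subtype, chromosome,
    count) — sex-chromosome rows are dropped, counts summed per tumor —
    or a pre-summed layout (tumor, subtype, total), which passes through
    unchanged. A ``count`` column may hold event counts or single
    gain/loss calls (counting 1 each).
    """
    cols = set(table.columns)
    if {"tumor", "subtype", "total"} <= cols:
        return table[["tumor", "subtype", "total"]].copy()
    if not {"tumor", "subtype", "chromosome", "count"} <= cols:
        raise ValueError(
            "burden table needs columns (tumor, subtype, chromosome, count) "
            "or (tumor, subtype, total)"
        )
    if (pd.to_numeric(table["count"], errors="coerce") < 0).any():
        raise ValueError("CNA counts must be >= 0")
    keep = table["chromosome"].map(_is_autosome)
    kept = table[keep]
    totals = (
        kept.groupby(["tumor", "subtype"], sort=False)["count"]
        .sum()
        .reset_index()
        .rename(columns={"count": "total"})
    )
    # tumors whose every row is sex-chromosomal still appear, with total 0
    all_tumors = table[["tumor", "subtype"]].drop_duplicates()
    totals = all_tumors.merge(totals, on=["tumor", "subtype"], how="left").fillna({"total": 0})
    totals["total"] = totals["total"].astype(table["count"].dtype, errors="ignore")
    return totals


# ----------------------------------------------------------------------
# rank-sum test


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, ties averaged) computed with argsort only."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _u_from_ranks(ranks: np.ndarray, idx_a: np.ndarray, n_a: int) -> float:
    return float(ranks[idx_a].sum() - n_a * (n_a + 1) / 2)


def mann_whitney(group_a, group_b, method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test of two samples.

    U is computed from joint mid-ranks. With ``n_a + n_b`` at most
    :data:`EXACT_ENUMERATION_LIMIT` and no ties, the two-sided p comes
    from full enumeration of every group labeling (doubling the smaller
    tail, capped at 1); otherwise a normal approximation with tie and
    continuity corrections is used. Completely tied data yields p = 1.
    ``method`` forces one path: "exact" | "approx" | "auto".
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    idx_a = np.arange(n_a)
    u = _u_from_ranks(ranks, idx_a, n_a)

    has_ties = len(np.unique(pooled)) < n
    use_exact = method == "exact" or (
        method == "auto" and n <= EXACT_ENUMERATION_LIMIT and not has_ties
    )
    if use_exact:
        # full enumeration of the C(n, n_a) equally likely labelings
        us = np.array(
            [_u_from_ranks(ranks, np.array(comb), n_a) for comb in combinations(range(n), n_a)]
        )
        m = len(us)
        p_low = np.sum(us <= u + 1e-9) / m
        p_high = np.sum(us >= u - 1e-9) / m
        p = min(1.0, 2.0 * min(p_low, p_high))
        return GroupComparison("a", "b", n_a, n_b, u, float(p), "exact")

    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return GroupComparison("a", "b", n_a, n_b, u, 1.0, "normal-approximation")
    # continuity correction shrinks |U - mean| by 0.5
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (0.5 * math.erfc(z / math.sqrt(2.0))))
    return GroupComparison("a", "b", n_a, n_b, u, float(p), "normal-approximation")


def compare_groups(
    totals: pd.DataFrame, group_a: str, group_b: str
) -> GroupComparison:
    """Mann-Whitney comparison of per-tumor totals between two subtypes."""
    va = totals.loc[totals["subtype"] == group_a, "total"].to_numpy(float)
    vb = totals.loc[totals["subtype"] == group_b, "total"].to_numpy(float)
    if va.size == 0 or vb.size == 0:
        missing = group_a if va.size == 0 else group_b
        raise ValueError(f"no tumors with subtype {missing!r}")
    res = mann_whitney(va, vb)
    return GroupComparison(group_a, group_b, res.n_a, res.n_b, res.u_statistic, res.p_value, res.method)
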