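"""Region- and site-type-stratified mutation-rate estimation.

The genome is partitioned into three disjoint chromatin strata — the
pericentromeric regions (PR), the remaining H3K9me3 blocks (non-PR H3K9me3)
and everything else (non-H3K9me3) — and mutation rates are expressed either
per genome per day (count / (lines x days)) or per bp per day
(count / (exposure bp x line-days)), optionally restricted to A/T or G/C
reference sites with the matching base-composition exposure.  Group
comparisons use the Mann-Whitney U rank test on per-line rates, with exact
enumeration for small groups and midranks for ties.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import A, C, G, T
from .intervals import IntervalSet

#: the three-way chromatin partition, in decreasing expected mutability
STRATA = ("PR", "nonPR_H3K9me3", "non_H3K9me3")
SITE_TYPES = ("AT", "GC")


@dataclass
class RegionAnnotation:
    """Chromatin annotation defining the three-way genome partition."""

    h3k9me3: IntervalSet
    pr: IntervalSet
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.pr.subtract(self.h3k9me3).total_bp > 0:
            raise ValueError("PR intervals must be a subset of the H3K9me3 blocks")

    @classmethod
    def from_bundle(cls, bundle) -> "RegionAnnotation":
        return cls(h3k9me3=bundle.h3k9me3, pr=bundle.pr, chrom_lengths=bundle.chrom_lengths)

    def stratum_intervals(self) -> dict[str, IntervalSet]:
        return {
            "PR": self.pr,
            "nonPR_H3K9me3": self.h3k9me3.subtract(self.pr),
            "non_H3K9me3": self.h3k9me3.complement(self.chrom_lengths),
        }

    def stratum_bp(self) -> dict[str, int]:
        bp = {k: v.total_bp for k, v in self.stratum_intervals().items()}
        assert sum(bp.values()) == sum(self.chrom_lengths.values())
        return bp

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def site_type_bp(self, sequences: dict[str, np.ndarray]) -> pd.DataFrame:
        """A/T and G/C base counts within each stratum."""
        rows = {}
        for name, ivset in self.stratum_intervals().items():
            at = gc = 0
            for chrom, s, e in ivset:
                codes = sequences[chrom][s:e]
                is_gc = (codes == C) | (codes == G)
                gc += int(is_gc.sum())
                at += int(codes.size - is_gc.sum())
            rows[name] = {"AT": at, "GC": gc}
        return pd.DataFrame(rows).T.loc[list(STRATA)]


def assign_strata(mutations: pd.DataFrame, regions: RegionAnnotation) -> pd.DataFrame:
    """Attach ``stratum`` and ``site_type`` columns to a mutation table.

    Every mutation lands in exactly one stratum; the site type is A/T or G/C
    by reference base (NaN for indels).  Positions outside the genome raise.
    """
    out = mutations.copy()
    stratum = np.empty(len(out), dtype=object)
    for chrom, sub in out.groupby("chrom", sort=False):
        length = regions.chrom_lengths.get(str(chrom))
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        if length is None or (pos0 < 0).any() or (pos0 >= length).any():
            raise ValueError(f"mutation position outside genome bounds on {chrom}")
        in_pr = regions.pr.contains_positions(str(chrom), pos0)
        in_k9 = regions.h3k9me3.contains_positions(str(chrom), pos0)
        lab = np.where(in_pr, "PR", np.where(in_k9, "nonPR_H3K9me3", "non_H3K9me3"))
        stratum[sub.index.to_numpy()] = lab
    out["stratum"] = stratum
    ref = out["ref"].astype(str).str.upper()
    snv = (ref.str.len() == 1) & (out["alt"].astype(str).str.len() == 1)
    out["site_type"] = np.where(
        snv, np.where(ref.isin(["A", "T"]), "AT", "GC"), None
    )
    return out


def stratify(mutations: pd.DataFrame, regions: RegionAnnotation) -> pd.DataFrame:
    """Counts per line x stratum x site type (SNVs only for site types)."""
    df = assign_strata(mutations, regions)
    counts = (
        df.groupby(["line_id", "stratum", "site_type"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


def per_genome_rate(count: int, n_lines: int, days: float) -> float:
    """Mutations per genome per day: count / (n_lines x days)."""
    if n_lines <= 0 or days <= 0:
        raise ValueError("n_lines and days must be positive")
    return count / (n_lines * days)


def per_bp_rate(count: int, exposure_bp: float, line_days: float) -> float:
    """Mutations per bp per day: count / (exposure_bp x line-days)."""
    if exposure_bp <= 0 or line_days <= 0:
        raise ValueError("exposure and line-days must be positive")
    return count / (exposure_bp * line_days)


def rule_of_three_upper(exposure_bp: float, line_days: float) -> float:
    """One-sided 95% upper rate bound for a zero count (~3/n)."""
    return 3.0 / (exposure_bp * line_days)


@dataclass
class RateEstimate:
    """A per-bp/day rate with its exposure bookkeeping and per-line rates."""

    count: int
    exposure_bp: float
    line_days: float
    per_line: pd.Series  # per-line per-bp/day rates, indexed by line_id

    @property
    def rate(self) -> float:
        return per_bp_rate(self.count, self.exposure_bp, self.line_days)

    @property
    def upper95(self) -> float | None:
        return rule_of_three_upper(self.exposure_bp, self.line_days) if self.count == 0 else None

    @property
    def poisson_se(self) -> float:
        return math.sqrt(max(self.count, 1)) / (self.exposure_bp * self.line_days)


def estimate_rates(
    mutations: pd.DataFrame,
    regions: RegionAnnotation,
    days_per_line: Mapping[str, float],
    sequences: dict[str, np.ndarray] | None = None,
    site_type: str | None = None,
) -> dict[str, RateEstimate]:
    """Per-stratum rate estimates.

    ``days_per_line`` must list every sequenced line (including lines with no
    retained mutation) — the exposure is summed over all of them.  With
    ``site_type`` of ``"AT"`` or ``"GC"`` the counts are restricted to that
    reference-base class and the exposure uses the matching base counts from
    ``sequences``.
    """
    df = mutations if "stratum" in mutations.columns else assign_strata(mutations, regions)
    if site_type is not None:
        if site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        if sequences is None:
            raise ValueError("site-type rates need the genome for exposure counting")
        df = df[df["site_type"] == site_type]
        exposure = regions.site_type_bp(sequences)[site_type].to_dict()
    else:
        exposure = regions.stratum_bp()
    line_days = float(sum(days_per_line.values()))
    out: dict[str, RateEstimate] = {}
    for stratum in STRATA:
        sub = df[df["stratum"] == stratum]
        per_line = pd.Series(
            {
                line: (sub["line_id"] == line).sum() / (exposure[stratum] * days)
                for line, days in days_per_line.items()
            }
        )
        out[stratum] = RateEstimate(
            count=int(len(sub)),
            exposure_bp=float(exposure[stratum]),
            line_days=line_days,
            per_line=per_line,
        )
    return out


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio ``rate_a / rate_b``; NaN (undefined) when the denominator is 0,
    as happens for strata with no observed mutation."""
    if rate_b == 0:
        return float("nan")
    return rate_a / rate_b


# ---------------------------------------------------------------------------
# Rank-based group comparison
# ---------------------------------------------------------------------------


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    alternative: str


def _u_of(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def compare_rates(a, b, alternative: str = "two-sided", exact_max_n: int = 8) -> RankTestResult:
    """Mann-Whitney U comparison of two per-line rate vectors.

    Ties get midranks.  When both groups have at most ``exact_max_n``
    observations the null distribution of U is enumerated over all
    C(n+m, n) group assignments; larger groups use the normal approximation
    with continuity correction.  ``alternative`` follows scipy's convention
    for the first group: "two-sided", "greater" or "less".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = _u_of(ranks[:n], n)
    if n <= exact_max_n and m <= exact_max_n:
        mu = n * m / 2.0
        eps = 1e-9
        us = np.fromiter(
            (_u_of(ranks[list(idx)], n) for idx in combinations(range(n + m), n)),
            dtype=float,
        )
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + eps))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return RankTestResult(u_obs, p, "exact", alternative)
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic",
                             use_continuity=True)
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic", alternative)
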