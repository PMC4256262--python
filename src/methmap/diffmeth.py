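"""Differential methylation: pooled Fisher tests, Benjamini-Hochberg FDR,
clustering of differential cytosines into regions, and set-overlap
enrichment.

The two-sided Fisher exact p-value is computed by exhaustive hypergeometric
enumeration in exact integer arithmetic (minimum-likelihood rule: the
p-value sums the probabilities of all tables, at the observed margins,
whose probability does not exceed that of the observed table, with exact
tie comparison). Replicate counts are pooled per group before testing;
the methylation difference is computed on conversion-corrected pooled
percentages.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .calling import apply_site_filters, corrected_methylation


@lru_cache(maxsize=200_000)
def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...]]:
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    return kmin, tuple(comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0:
        raise ValueError("zero total in a group")
    if c1 == 0 or c1 == r1 + r2:
        return 1.0
    kmin, nums = _hypergeom_numerators(r1, r2, c1)
    observed = nums[a - kmin]
    acc = sum(n for n in nums if n <= observed)
    return min(1.0, acc / comb(r1 + r2, c1))


def fisher_test_pooled(
    group1_counts: list[tuple[int, int]],
    group2_counts: list[tuple[int, int]],
    r1: float = 1.0,
    r2: float = 1.0,
) -> tuple[float, float]:
    """Pool replicate (c, t) counts per group, test independence of group
    and converted/unconverted status, and return (p, delta_m) where
    delta_m = corrected m(group1) - m(group2) in percentage points."""
    c1 = sum(c for c, _ in group1_counts)
    t1 = sum(t for _, t in group1_counts)
    c2 = sum(c for c, _ in group2_counts)
    t2 = sum(t for _, t in group2_counts)
    p = fisher_exact_two_sided(c1, t1, c2, t2)
    dm = corrected_methylation(c1, t1, r1) - corrected_methylation(c2, t2, r2)
    return p, float(dm)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cluster_sites_into_regions(
    sites: pd.DataFrame, gap: int = 500, value_column: str | None = None
) -> pd.DataFrame:
    """Group sites (columns chrom, pos) into regions in which consecutive
    members are at most ``gap`` bp apart, irrespective of direction.

    Returns one row per region: chrom, start, end (1-based inclusive),
    n_cpgs, is_singleton, and — when ``value_column`` is given —
    direction_consistent plus the mean of the value column.
    """
    if sites.empty:
        cols = ["chrom", "start", "end", "n_cpgs", "is_singleton"]
        if value_column:
            cols += ["direction_consistent", f"mean_{value_column}"]
        return pd.DataFrame(columns=cols)
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    new_chrom = sites["chrom"] != sites["chrom"].shift()
    far = sites["pos"] - sites["pos"].shift() > gap
    region = (new_chrom | far).cumsum()
    rows = []
    for _, sub in sites.groupby(region):
        row = {
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["pos"].min()),
            "end": int(sub["pos"].max()),
            "n_cpgs": len(sub),
            "is_singleton": len(sub) == 1,
        }
        if value_column:
            values = sub[value_column]
            row["direction_consistent"] = bool(
                (values > 0).all() or (values < 0).all()
            )
            row[f"mean_{value_column}"] = float(values.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def call_dmcs_and_dmrs(
    pileups: pd.DataFrame,
    groups: dict[str, list[str]],
    conversion_rates: dict[str, float] | None = None,
    variants: pd.DataFrame | None = None,
    fdr: float = 0.05,
    gap: int = 500,
    min_coverage: int = 5,
    min_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differentially methylated cytosines and regions between two groups.

    Sites are filtered (coverage in both groups, variant-free dyads)
    before testing; BH correction runs over the post-filter universe.
    Significant sites (q < ``fdr``) are clustered into regions with the
    ``gap`` rule; sites >= gap away from any other significant site are
    singletons.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name1, samples1), (name2, samples2) = groups.items()
    sites = apply_site_filters(
        pileups, groups, variants, min_coverage, min_replicates
    )
    if sites.empty:
        return sites.assign(p=[], q=[], delta_m=[], significant=[]), pd.DataFrame()

    key = ["chrom", "pos", "strand"]
    r_by_sample = conversion_rates or {}

    def pooled(samples: list[str]) -> pd.DataFrame:
        sub = pileups[pileups["sample_id"].isin(samples)]
        agg = sub.groupby(key)[["c_count", "t_count"]].sum()
        return agg.reindex(pd.MultiIndex.from_frame(sites[key])).fillna(0).astype(int)

    pool1 = pooled(samples1)
    pool2 = pooled(samples2)
    r1 = float(np.mean([r_by_sample.get(s, 1.0) for s in samples1]))
    r2 = float(np.mean([r_by_sample.get(s, 1.0) for s in samples2]))

    pvals = np.empty(len(sites))
    for i, (row1, row2) in enumerate(
        zip(pool1.itertuples(index=False), pool2.itertuples(index=False))
    ):
        pvals[i] = fisher_exact_two_sided(
            row1.c_count, row1.t_count, row2.c_count, row2.t_count
        )
    dm = corrected_methylation(
        pool1["c_count"].to_numpy(), pool1["t_count"].to_numpy(), r1
    ) - corrected_methylation(
        pool2["c_count"].to_numpy(), pool2["t_count"].to_numpy(), r2
    )

    dmc = sites.copy()
    dmc["c1"] = pool1["c_count"].to_numpy()
    dmc["t1"] = pool1["t_count"].to_numpy()
    dmc["c2"] = pool2["c_count"].to_numpy()
    dmc["t2"] = pool2["t_count"].to_numpy()
    dmc["p"] = pvals
    dmc["q"] = bh_fdr(pvals)
    dmc["delta_m"] = dm
    dmc["significant"] = dmc["q"] < fdr

    dmr = cluster_sites_into_regions(
        dmc[dmc["significant"]][["chrom", "pos", "delta_m"]],
        gap=gap,
        value_column="delta_m",
    )
    return dmc, dmr


def overlap_enrichment(
    set_a: set, set_b: set, universe: set
) -> tuple[float, float, float]:
    """Fold enrichment of |A ∩ B| over the random expectation
    |A||B|/|U|, with a 1-df Pearson chi-square on the 2x2 membership
    table (no continuity correction). Returns (fold, chi2, p)."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a_and_b = len(set_a & set_b)
    expected = len(set_a) * len(set_b) / n
    fold = a_and_b / expected if expected > 0 else float("nan")
    table = np.array(
        [
            [a_and_b, len(set_a) - a_and_b],
            [len(set_b) - a_and_b, n - len(set_a) - len(set_b) + a_and_b],
        ]
    )
    if table.min() < 0:
        raise ValueError("inconsistent set sizes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # a degenerate margin (e.g. A = B = U) carries no information
        return float(fold), float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(fold), float(chi2), float(p)
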