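"""Quantitative trait methylation: phenotype/methylation correlation
across the RI panel after per-strain outlier removal.

Outliers are removed from raw replicate measurements within each strain
in a single pass by the union of three tests at alpha = 0.05: the boxplot
rule (outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]), the Grubbs test (G =
max|x - mean|/s against its t-based critical value) and the Nalimov test
(q = |x - mean|/s * sqrt(n/(n-1)); its critical value follows from the
Grubbs one through the same sqrt(n/(n-1)) factor). With fewer than three
values only the boxplot rule applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_fdr


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def nalimov_critical(n: int, alpha: float = 0.05) -> float:
    return grubbs_critical(n, alpha) * np.sqrt(n / (n - 1))


@dataclass
class OutlierRemoval:
    retained: np.ndarray
    removed: np.ndarray
    reasons: list[set[str]]  # per removed value


def remove_outliers(values, alpha: float = 0.05) -> OutlierRemoval:
    """Single-pass union of boxplot, Grubbs and Nalimov flags."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    flags: list[set[str]] = [set() for _ in range(n)]
    if n >= 1:
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for i, v in enumerate(x):
            if v < lo or v > hi:
                flags[i].add("boxplot")
    if n >= 3:
        s = x.std(ddof=1)
        if s > 0:
            g = np.abs(x - x.mean()) / s
            q = g * np.sqrt(n / (n - 1))
            g_crit = grubbs_critical(n, alpha)
            q_crit = nalimov_critical(n, alpha)
            for i in range(n):
                if g[i] > g_crit:
                    flags[i].add("grubbs")
                if q[i] > q_crit:
                    flags[i].add("nalimov")
    keep = np.array([not f for f in flags])
    return OutlierRemoval(
        retained=x[keep],
        removed=x[~keep],
        reasons=[f for f in flags if f],
    )


def summarize_phenotypes(phenotypes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per (strain, trait): outlier-cleaned mean, standard error and the
    number of removed replicates."""
    rows = []
    for (strain, trait), sub in phenotypes.groupby(["strain", "trait"]):
        removal = remove_outliers(sub["value"].to_numpy(), alpha)
        x = removal.retained
        rows.append(
            {
                "strain": strain,
                "trait": trait,
                "mean": float(x.mean()) if len(x) else np.nan,
                "se": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
                "n": len(x),
                "n_removed": len(removal.removed),
            }
        )
    return pd.DataFrame(rows)


def correlate_traits(
    methylation: pd.DataFrame,
    phenotype_summaries: pd.DataFrame,
    min_strains: int = 8,
) -> pd.DataFrame:
    """Pearson correlation of every methylation locus against every
    phenotype over strain means, BH-corrected over all tested pairs.

    ``methylation``: columns locus, strain, value (strain means).
    Constant vectors are skipped (logged with r = NaN, not tested).
    """
    meth_wide = methylation.pivot(index="strain", columns="locus", values="value")
    pheno_wide = phenotype_summaries.pivot(index="strain", columns="trait", values="mean")
    rows = []
    for locus in meth_wide.columns:
        for trait in pheno_wide.columns:
            pair = pd.DataFrame(
                {"m": meth_wide[locus], "y": pheno_wide[trait]}
            ).dropna()
            if len(pair) < min_strains:
                continue
            if pair["m"].std() == 0 or pair["y"].std() == 0:
                rows.append(
                    {"locus": locus, "trait": trait, "r": np.nan, "p": np.nan,
                     "n_strains": len(pair), "tested": False}
                )
                continue
            r, p = stats.pearsonr(pair["m"], pair["y"])
            rows.append(
                {"locus": locus, "trait": trait, "r": float(r), "p": float(p),
                 "n_strains": len(pair), "tested": True}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out
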