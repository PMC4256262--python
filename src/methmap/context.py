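"""Sequence context around differentially methylated CpGs: nearest-SNP
distance statistics, background-corrected nucleotide-preference
signatures, and the effect of immediately adjacent allele changes.

The nucleotide-preference signature is a position frequency matrix over
the 5 bp up- and downstream of the CpG dyad (positions -5..-1, +1..+5; a
12 bp window including the dyad itself). Per-position information content
is the relative entropy against the genomic background composition
(A 0.29, C 0.21, G 0.21, T 0.29), so a column at background frequencies
carries zero information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffmeth import fisher_exact_two_sided

BACKGROUND = {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}
BASES = ["A", "C", "G", "T"]
WINDOW_OFFSETS = [-5, -4, -3, -2, -1, 1, 2, 3, 4, 5]


# ---------------------------------------------------------------------------
# nearest-SNP distances


def nearest_snp_distances(
    cpg_sites: pd.DataFrame,
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Per CpG dyad: distance to the nearest SNP outside the dyad and to
    the nearest CpG-disrupting SNP (inside the dyad counts as distance 0).

    ``cpg_sites`` needs chrom, pos, strand; each dyad contributes once
    (its forward-strand coordinate). Distances are in bp between the
    cytosine and the SNP.
    """
    if variants.empty:
        raise ValueError("empty variant table")
    snps = variants[variants["kind"] == "snp"]
    dyads = cpg_sites.copy()
    dyads["c_pos"] = np.where(dyads["strand"] == "+", dyads["pos"], dyads["pos"] - 1)
    dyads = dyads.drop_duplicates(subset=["chrom", "c_pos"])
    rows = []
    snp_by_chrom = {c: np.sort(sub["pos"].to_numpy()) for c, sub in snps.groupby("chrom")}
    for row in dyads.itertuples():
        positions = snp_by_chrom.get(row.chrom, np.array([], dtype=int))
        dyad = {row.c_pos, row.c_pos + 1}
        outside = positions[~np.isin(positions, list(dyad))]
        inside = positions[np.isin(positions, list(dyad))]
        d = int(np.min(np.abs(outside - row.c_pos))) if len(outside) else None
        rows.append(
            {
                "chrom": row.chrom,
                "pos": int(row.c_pos),
                "nearest_snp_bp": d,
                "has_disrupting_snp": len(inside) > 0,
            }
        )
    return pd.DataFrame(rows)


def cumulative_snp_curve(distances: pd.Series, max_bp: int = 1000) -> np.ndarray:
    """Fraction of CpGs with a SNP within x bp for x = 1..max_bp
    (monotone non-decreasing, bounded by 1)."""
    d = distances.dropna().to_numpy(dtype=float)
    n = len(distances)
    if n == 0:
        raise ValueError("no CpGs")
    xs = np.arange(1, max_bp + 1)
    return np.searchsorted(np.sort(d), xs, side="right") / n


def nearest_snp_stats(
    cpg_sets: dict[str, pd.DataFrame],
    variants: pd.DataFrame,
    max_bp: int = 1000,
    enrichment_cutoffs: tuple[int, ...] = (5, 250),
) -> dict:
    """Distance distributions, cumulative curves and pairwise fold
    enrichment between the named CpG sets at the stated cutoffs."""
    tables = {name: nearest_snp_distances(s, variants) for name, s in cpg_sets.items()}
    curves = {
        name: cumulative_snp_curve(t["nearest_snp_bp"], max_bp)
        for name, t in tables.items()
    }
    enrichment = {}
    names = list(cpg_sets)
    for cutoff in enrichment_cutoffs:
        for a in names:
            for b in names:
                if a == b:
                    continue
                fa = curves[a][cutoff - 1]
                fb = curves[b][cutoff - 1]
                enrichment[(a, b, cutoff)] = fa / fb if fb > 0 else np.inf
    return {"tables": tables, "curves": curves, "fold_enrichment": enrichment}


# ---------------------------------------------------------------------------
# position frequency matrices and information content


def extract_windows(
    reference: dict[str, str],
    dyads: pd.DataFrame,
    flank: int = 5,
) -> list[str]:
    """Flanking sequence around each dyad: ``flank`` bases upstream of the
    C and downstream of the G, dyad excluded (length 2*flank). Dyads too
    close to a contig edge are skipped."""
    out = []
    for row in dyads.itertuples():
        seq = reference[row.chrom]
        c = row.pos  # 1-based C of the dyad
        if c - flank < 1 or c + 1 + flank > len(seq):
            continue
        out.append(seq[c - 1 - flank : c - 1] + seq[c + 1 : c + 1 + flank])
    return out


def build_pfm_ic(
    sequences: list[str],
    background: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Position frequency matrix and per-position information content.

    ``sequences`` are equal-length windows (dyad excluded); positions are
    labelled -flank..-1, +1..+flank. IC_j = sum_i p_ij log2(p_ij / b_i)
    with 0 log 0 = 0.
    """
    if not sequences:
        raise ValueError("empty sequence class")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("windows must be equal length")
    if width % 2 != 0:
        raise ValueError("window length must be even (dyad excluded)")
    bg = background or BACKGROUND
    flank = width // 2
    labels = list(range(-flank, 0)) + list(range(1, flank + 1))
    counts = pd.DataFrame(0, index=BASES, columns=labels)
    for s in sequences:
        for j, base in enumerate(s):
            if base in BASES:
                counts.loc[base, labels[j]] += 1
    totals = counts.sum(axis=0)
    ic = pd.Series(0.0, index=labels)
    for j in labels:
        if totals[j] == 0:
            continue
        p = counts[j] / totals[j]
        b = pd.Series(bg)
        nonzero = p > 0
        ic[j] = float((p[nonzero] * np.log2(p[nonzero] / b[nonzero])).sum())
    return counts, ic


def column_information_content(
    frequencies: dict[str, float],
    background: dict[str, float] | None = None,
) -> float:
    """Relative entropy of one PFM column against the background."""
    bg = background or BACKGROUND
    ic = 0.0
    for base, p in frequencies.items():
        if p > 0:
            ic += p * np.log2(p / bg[base])
    return float(ic)


# ---------------------------------------------------------------------------
# adjacent allele changes


def _classify_change(bn: str, shr: str) -> str:
    at = {"A", "T"}
    gc = {"G", "C"}
    if bn in at and shr in gc:
        return "AT->GC"
    if bn in gc and shr in at:
        return "GC->AT"
    return "neutral"


def adjacent_allele_effects(
    dm_dyads: pd.DataFrame,
    variants: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Cross-tabulate the BN-to-SHR allele-change class at the base
    immediately flanking a differentially methylated CpG against the
    direction of the methylation change.

    ``dm_dyads`` needs chrom, pos (forward-strand C), delta_shr (percent
    methylation SHR - BN). Flanking positions are pos-1 (upstream of the
    C) and pos+2 (downstream of the G). Returns (table, odds_ratio, p)
    where the 2x2 excludes neutral changes and the odds ratio is for
    AT->GC changes producing increased SHR methylation.
    """
    snps = variants[variants["kind"] == "snp"]
    snp_lookup = {
        (v.chrom, v.pos): (v.bn_allele, v.shr_allele) for v in snps.itertuples()
    }
    rows = []
    for row in dm_dyads.itertuples():
        for flank_pos in (row.pos - 1, row.pos + 2):
            alleles = snp_lookup.get((row.chrom, flank_pos))
            if alleles is None:
                continue
            rows.append(
                {
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "flank_pos": flank_pos,
                    "change": _classify_change(*alleles),
                    "direction": "up_in_shr" if row.delta_shr > 0 else "down_in_shr",
                }
            )
    if not rows:
        raise ValueError("no differentially methylated CpGs with flanking SNPs")
    table = pd.DataFrame(rows)
    counts = pd.crosstab(table["change"], table["direction"]).reindex(
        index=["AT->GC", "GC->AT"], columns=["up_in_shr", "down_in_shr"], fill_value=0
    )
    a, b = int(counts.loc["AT->GC", "up_in_shr"]), int(counts.loc["AT->GC", "down_in_shr"])
    c, d = int(counts.loc["GC->AT", "up_in_shr"]), int(counts.loc["GC->AT", "down_in_shr"])
    if min(a, b, c, d) == 0:
        # Haldane-Anscombe correction keeps the odds ratio finite
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    p = fisher_exact_two_sided(a, b, c, d) if (a + b) and (c + d) else np.nan
    return table, float(odds), float(p)
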