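"""Phasing of F1 bisulfite reads by parental genotype and detection of
allele-specific (ASM) and parent-of-origin (PO) methylation.

Reads are assigned to the BN or SHR haplotype by majority vote over the
SNP alleles they cover. C/T SNPs are never usable (bisulfite conversion is
indistinguishable from the allelic difference) and G/A SNPs are excluded
on the reverse-converted (G2A) strand for the same reason on the opposite
strand. Exact allele ties are discarded as ambiguous; reads covering no
usable SNP remain unphased.

The reciprocal-cross comparison scheme (dam named first, so in BNxSHR the
BN allele is maternal):

* ASM — maternal comparison: BN allele in BNxSHR vs SHR allele in SHRxBN;
  paternal comparison: BN allele in SHRxBN vs SHR allele in BNxSHR. A CpG
  is allele-specifically methylated if significant in either or both
  (each comparison BH-corrected over its own universe).
* PO — within the BN-derived chromosomes: BN allele in BNxSHR (maternal)
  vs BN allele in SHRxBN (paternal); analogously within SHR-derived
  chromosomes. A PO CpG is significant with the same maternal-paternal
  sign in both; PO CpGs are clustered into regions with the 500 bp rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffmeth import bh_fdr, cluster_sites_into_regions, fisher_exact_two_sided
from .reads import AlignedPair, pileup_cytosines

KEY = ["chrom", "pos", "strand"]

# ASM comparisons: (name, (cross, allele) cell 1, cell 2)
ASM_COMPARISONS = [
    ("maternal", ("BNxSHR", "BN"), ("SHRxBN", "SHR")),
    ("paternal", ("SHRxBN", "BN"), ("BNxSHR", "SHR")),
]
# PO comparisons: maternal cell first, paternal cell second
PO_COMPARISONS = [
    ("bn_background", ("BNxSHR", "BN"), ("SHRxBN", "BN")),
    ("shr_background", ("SHRxBN", "SHR"), ("BNxSHR", "SHR")),
]


# ---------------------------------------------------------------------------
# read phasing


def _usable_snp(v, conv_strand: str) -> bool:
    """A SNP row (bn_allele/shr_allele attributes) usable for phasing on
    the given converted strand."""
    alleles = {v.bn_allele, v.shr_allele}
    if alleles == {"C", "T"}:
        return False
    if conv_strand == "G2A" and alleles == {"G", "A"}:
        return False
    return True


def _allele_match(base: str, allele: str, conv_strand: str) -> bool:
    """Conversion-aware allele matching: on the C2T strand an allele C may
    read as T, on the G2A strand an allele G may read as A."""
    if base == allele:
        return True
    if conv_strand == "C2T" and allele == "C" and base == "T":
        return True
    if conv_strand == "G2A" and allele == "G" and base == "A":
        return True
    return False


def phase_read_pair(pair: AlignedPair, variants: pd.DataFrame) -> str:
    """Classify a read pair as 'BN', 'SHR', 'ambiguous' (exact allele
    tie, discarded downstream) or 'unphased' (no usable SNP covered)."""
    snps = variants[
        (variants["kind"] == "snp") & (variants["chrom"] == pair.read1.chrom)
    ]
    bn_votes = 0
    shr_votes = 0
    seen: set[int] = set()
    for v in snps.itertuples():
        if not _usable_snp(v, pair.conv_strand):
            continue
        for read in (pair.read1, pair.read2):
            if v.pos in seen:
                break
            base = read.base_at(v.pos)
            if base is None:
                continue
            seen.add(v.pos)
            bn = _allele_match(base, v.bn_allele, pair.conv_strand)
            shr = _allele_match(base, v.shr_allele, pair.conv_strand)
            if bn and not shr:
                bn_votes += 1
            elif shr and not bn:
                shr_votes += 1
    if bn_votes == 0 and shr_votes == 0:
        return "unphased"
    if bn_votes == shr_votes:
        return "ambiguous"
    return "BN" if bn_votes > shr_votes else "SHR"


def build_allele_profiles(
    pairs_by_sample: dict[tuple[str, int], list[AlignedPair]],
    variants: pd.DataFrame,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Phase reads and accumulate allele-resolved pileups.

    ``pairs_by_sample`` maps (cross, replicate) to that sample's filtered
    pairs. Ambiguous and unphased pairs are excluded. Returns the
    phased-pileup table (chrom, pos, strand, cross, replicate, allele,
    c_count, t_count).
    """
    frames = []
    for (cross, replicate), pairs in pairs_by_sample.items():
        assigned: dict[str, list[AlignedPair]] = {"BN": [], "SHR": []}
        for pair in pairs:
            call = phase_read_pair(pair, variants)
            if call in assigned:
                assigned[call].append(pair)
        for allele, subset in assigned.items():
            if not subset:
                continue
            pile = pileup_cytosines(subset, sites, sample_id="x")
            pile = pile[pile[["c_count", "t_count", "other_count"]].sum(axis=1) > 0]
            frames.append(
                pile.drop(columns=["sample_id", "other_count"]).assign(
                    cross=cross, replicate=replicate, allele=allele
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=KEY + ["cross", "replicate", "allele", "c_count", "t_count"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out[KEY + ["cross", "replicate", "allele", "c_count", "t_count"]]


# ---------------------------------------------------------------------------
# cell pooling and filtering


def _cell_pools(
    profiles: pd.DataFrame,
    min_coverage: int,
    min_replicates: int,
) -> tuple[pd.DataFrame, pd.MultiIndex]:
    """Pool counts per (site, cross, allele) cell and find the sites
    testable in all four cells (>= min_coverage in >= min_replicates
    phased replicate sets per cell)."""
    profiles = profiles.assign(cov=profiles["c_count"] + profiles["t_count"])
    cells = profiles.groupby(KEY + ["cross", "allele"])[["c_count", "t_count"]].sum()
    deep = profiles[profiles["cov"] >= min_coverage]
    reps = deep.groupby(KEY + ["cross", "allele"])["replicate"].nunique()
    ok = reps[reps >= min_replicates].reset_index()
    cell_count = ok.groupby(KEY).size()
    testable = cell_count[cell_count == 4].index
    return cells, pd.MultiIndex.from_tuples(testable, names=KEY)


def _comparison_frame(
    cells: pd.DataFrame,
    testable: pd.MultiIndex,
    comparisons: list,
    fdr: float,
) -> pd.DataFrame:
    """Run the pooled Fisher test for each comparison at every testable
    site; BH per comparison over its own universe."""
    out = pd.DataFrame(index=testable).reset_index()
    for name, cell1, cell2 in comparisons:
        p = np.empty(len(out))
        delta = np.empty(len(out))
        for i, site in enumerate(out[KEY].itertuples(index=False)):
            k1 = (*site, *cell1)
            k2 = (*site, *cell2)
            c1, t1 = cells.loc[k1]
            c2, t2 = cells.loc[k2]
            p[i] = fisher_exact_two_sided(int(c1), int(t1), int(c2), int(t2))
            m1 = 100.0 * c1 / (c1 + t1)
            m2 = 100.0 * c2 / (c2 + t2)
            delta[i] = m1 - m2
        out[f"p_{name}"] = p
        out[f"q_{name}"] = bh_fdr(p) if len(p) else p
        out[f"delta_{name}"] = delta
        out[f"sig_{name}"] = out[f"q_{name}"] < fdr
    return out


def detect_asm(
    profiles: pd.DataFrame,
    fdr: float = 0.05,
    min_coverage: int = 5,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Allele-specific methylation: significant in the maternal and/or the
    paternal reciprocal comparison. Sites failing the four-cell filter are
    absent from the output (not-tested, distinct from not-significant).
    A site significant in both comparisons with opposite signs is still
    ASM but flagged ``discordant``."""
    cells, testable = _cell_pools(profiles, min_coverage, min_replicates)
    if len(testable) == 0:
        return pd.DataFrame(columns=KEY)
    out = _comparison_frame(cells, testable, ASM_COMPARISONS, fdr)
    out["is_asm"] = out["sig_maternal"] | out["sig_paternal"]
    out["discordant"] = (
        out["sig_maternal"]
        & out["sig_paternal"]
        & (np.sign(out["delta_maternal"]) != np.sign(out["delta_paternal"]))
    )
    return out


def detect_po(
    profiles: pd.DataFrame,
    fdr: float = 0.05,
    gap: int = 500,
    min_coverage: int = 5,
    min_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parent-of-origin methylation: maternal-vs-paternal significant with
    a consistent direction on both genotype backgrounds. PO CpGs are
    clustered into regions; each region reports the largest mean
    maternal-paternal difference across backgrounds and which parental
    allele is hypermethylated ('M' or 'P')."""
    cells, testable = _cell_pools(profiles, min_coverage, min_replicates)
    if len(testable) == 0:
        empty = pd.DataFrame(columns=KEY)
        return empty, pd.DataFrame()
    out = _comparison_frame(cells, testable, PO_COMPARISONS, fdr)
    same_sign = np.sign(out["delta_bn_background"]) == np.sign(
        out["delta_shr_background"]
    )
    out["is_po"] = out["sig_bn_background"] & out["sig_shr_background"] & same_sign

    po_sites = out[out["is_po"]].copy()
    if po_sites.empty:
        return out, pd.DataFrame()
    po_sites["delta_mp"] = (
        po_sites["delta_bn_background"] + po_sites["delta_shr_background"]
    ) / 2.0
    regions = cluster_sites_into_regions(
        po_sites[["chrom", "pos", "delta_mp"]], gap=gap, value_column="delta_mp"
    )
    region_rows = []
    for row in regions.itertuples():
        members = po_sites[
            (po_sites["chrom"] == row.chrom)
            & (po_sites["pos"] >= row.start)
            & (po_sites["pos"] <= row.end)
        ]
        mean_bn = members["delta_bn_background"].mean()
        mean_shr = members["delta_shr_background"].mean()
        max_diff = max(abs(mean_bn), abs(mean_shr))
        region_rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_cpgs": row.n_cpgs,
                "max_mean_difference": float(max_diff),
                "hypermethylated_allele": "M" if members["delta_mp"].mean() > 0 else "P",
            }
        )
    return out, pd.DataFrame(region_rows)


def detect_cross_dm(
    f1_pileups: pd.DataFrame,
    cross_samples: dict[str, list[str]],
    conversion_rates: dict[str, float] | None = None,
    variants: pd.DataFrame | None = None,
    fdr: float = 0.05,
    min_coverage: int = 5,
    min_replicates: int = 3,
):
    """Differential methylation between the reciprocal crosses on the
    unphased F1 pileups (delegates to the standard pipeline)."""
    from .diffmeth import call_dmcs_and_dmrs

    return call_dmcs_and_dmrs(
        f1_pileups,
        cross_samples,
        conversion_rates=conversion_rates,
        variants=variants,
        fdr=fdr,
        min_coverage=min_coverage,
        min_replicates=min_replicates,
    )
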