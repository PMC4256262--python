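import numpy as np
import pandas as pd
import pytest

from methmap import phasing, simulate
from methmap.reads import AlignedPair, AlignedRead


def _pair(seq1, pos1=10, conv="C2T", seq2="A", pos2=500):
    return AlignedPair(
        read1=AlignedRead("contig1", pos1, seq1, [40] * len(seq1)),
        read2=AlignedRead("contig1", pos2, seq2, [40] * len(seq2)),
        mapq=60,
        conv_strand=conv,
    )


def _variants(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "bn_allele", "shr_allele", "kind"]
    )


def test_majority_vote_and_tie_handling():
    variants = _variants(
        [("contig1", 11, "A", "G", "snp"), ("contig1", 13, "A", "G", "snp")]
    )
    assert phasing.phase_read_pair(_pair("TATAT"), variants) == "BN"
    assert phasing.phase_read_pair(_pair("TGTGT"), variants) == "SHR"
    assert phasing.phase_read_pair(_pair("TATGT"), variants) == "ambiguous"


def test_ct_snps_never_usable():
    variants = _variants([("contig1", 11, "C", "T", "snp")])
    assert phasing.phase_read_pair(_pair("TCTTT"), variants) == "unphased"
    assert phasing.phase_read_pair(_pair("TTTTT"), variants) == "unphased"


def test_ga_snps_unusable_on_reverse_converted_strand():
    variants = _variants([("contig1", 11, "G", "A", "snp")])
    assert phasing.phase_read_pair(_pair("TGTTT", conv="G2A"), variants) == "unphased"
    # ... but usable on the C2T strand, where G/A is unaffected
    assert phasing.phase_read_pair(_pair("TGTTT", conv="C2T"), variants) == "BN"


def test_conversion_aware_allele_matching():
    # C/A SNP on the C2T strand: a T call is a converted BN cytosine
    variants = _variants([("contig1", 11, "C", "A", "snp")])
    assert phasing.phase_read_pair(_pair("TTTTT"), variants) == "BN"
    assert phasing.phase_read_pair(_pair("TATTT"), variants) == "SHR"
    # G/T SNP on the G2A strand: an A call is a converted BN guanine
    variants = _variants([("contig1", 11, "G", "T", "snp")])
    assert phasing.phase_read_pair(_pair("TATTT", conv="G2A"), variants) == "BN"


def test_indels_not_used_for_phasing():
    variants = _variants([("contig1", 11, "AAA", "A", "indel")])
    assert phasing.phase_read_pair(_pair("TATTT"), variants) == "unphased"


def test_phasing_simulation_identity(truth):
    pairs = simulate.simulate_f1_reads(truth, 600, seed=61)
    snps = truth.variants[truth.variants["kind"] == "snp"]
    n_checked = 0
    for pair in pairs:
        call = phasing.phase_read_pair(pair, truth.variants)
        if call in ("BN", "SHR"):
            assert call == pair.true_haplotype
            n_checked += 1
        elif call == "unphased":
            usable = [
                v
                for v in snps.itertuples()
                if v.chrom == pair.read1.chrom
                and phasing._usable_snp(v, pair.conv_strand)
                and (
                    pair.read1.base_at(v.pos) is not None
                    or pair.read2.base_at(v.pos) is not None
                )
            ]
            # unphased pairs may cover usable SNPs only when every covered
            # allele was consumed by bisulfite conversion ambiguity; with
            # conversion-aware matching that cannot happen
            assert not usable
    assert n_checked > 100


def test_allele_profiles_match_truth_partition(truth):
    pairs = simulate.simulate_f1_reads(truth, 400, seed=62)
    sites = truth.sites[truth.sites["chrom"] == "contig1"][["chrom", "pos", "strand"]]
    profiles = phasing.build_allele_profiles(
        {("BNxSHR", 1): pairs}, truth.variants, sites
    )
    # compare against a direct pileup of the truth-partitioned phaseable reads
    from methmap.reads import pileup_cytosines

    for allele in ("BN", "SHR"):
        subset = [
            p
            for p in pairs
            if p.true_haplotype == allele
            and phasing.phase_read_pair(p, truth.variants) == allele
        ]
        direct = pileup_cytosines(subset, sites, "x")
        direct = direct[direct[["c_count", "t_count", "other_count"]].sum(axis=1) > 0]
        got = profiles[profiles["allele"] == allele]
        merged = direct.merge(got, on=["chrom", "pos", "strand"], how="outer")
        assert (merged["c_count_x"] == merged["c_count_y"]).all()
        assert (merged["t_count_x"] == merged["t_count_y"]).all()


def _allele_rows(site_pos, cell_counts, reps=4):
    """cell_counts: {(cross, allele): (c, t)} replicated per replicate."""
    rows = []
    for (cross, allele), (c, t) in cell_counts.items():
        for rep in range(1, reps + 1):
            rows.append(
                {
                    "chrom": "c1",
                    "pos": site_pos,
                    "strand": "+",
                    "cross": cross,
                    "replicate": rep,
                    "allele": allele,
                    "c_count": c,
                    "t_count": t,
                }
            )
    return rows


def test_asm_detected_for_strong_allelic_difference():
    rows = _allele_rows(
        100,
        {
            ("BNxSHR", "BN"): (18, 2),
            ("BNxSHR", "SHR"): (2, 18),
            ("SHRxBN", "BN"): (18, 2),
            ("SHRxBN", "SHR"): (2, 18),
        },
    )
    out = phasing.detect_asm(pd.DataFrame(rows))
    assert len(out) == 1 and bool(out["is_asm"].iloc[0])
    assert not out["discordant"].iloc[0]


def test_balanced_alleles_are_not_asm():
    rows = _allele_rows(
        100,
        {
            ("BNxSHR", "BN"): (10, 10),
            ("BNxSHR", "SHR"): (10, 10),
            ("SHRxBN", "BN"): (10, 10),
            ("SHRxBN", "SHR"): (10, 10),
        },
    )
    out = phasing.detect_asm(pd.DataFrame(rows))
    assert len(out) == 1 and not out["is_asm"].iloc[0]


def test_low_coverage_cell_makes_site_untested():
    rows = _allele_rows(
        100,
        {
            ("BNxSHR", "BN"): (18, 2),
            ("BNxSHR", "SHR"): (2, 18),
            ("SHRxBN", "BN"): (18, 2),
            ("SHRxBN", "SHR"): (1, 1),  # below the 5x cell filter
        },
    )
    out = phasing.detect_asm(pd.DataFrame(rows))
    assert len(out) == 0  # not tested, which is distinct from not significant


def test_asm_recovery_on_simulated_truth(truth, data):
    out = phasing.detect_asm(data.allele_pileups)
    merged = out.merge(truth.sites, on=["chrom", "pos", "strand"])
    allelic = merged[merged["theta_bn"] != merged["theta_shr"]]
    assert allelic["is_asm"].mean() > 0.8
    null = merged[(merged["theta_bn"] == merged["theta_shr"]) & ~merged["is_imprinted"]]
    assert null["is_asm"].mean() <= 0.05


def test_po_recovers_imprinted_regions_and_ignores_genotype_asm(truth, data):
    sites, regions = phasing.detect_po(data.allele_pileups)
    merged = sites.merge(truth.sites, on=["chrom", "pos", "strand"])
    imprinted = merged[merged["is_imprinted"]]
    assert imprinted["is_po"].mean() > 0.8
    # genotype-driven (ASM) differences must not appear as parent-of-origin
    genotype_only = merged[~merged["is_imprinted"]]
    assert genotype_only["is_po"].mean() <= 0.01
    assert len(regions) == truth.config.n_imprinted_regions
    expected_diff = 100 * (truth.config.theta_maternal - truth.config.theta_paternal)
    for row in regions.itertuples():
        assert row.hypermethylated_allele == "M"
        assert row.max_mean_difference == pytest.approx(expected_diff, abs=10)


def test_po_invariant_under_strain_label_swap(data):
    swapped = data.allele_pileups.copy()
    swapped["allele"] = swapped["allele"].map({"BN": "SHR", "SHR": "BN"})
    swapped["cross"] = swapped["cross"].map({"BNxSHR": "SHRxBN", "SHRxBN": "BNxSHR"})
    a_sites, a_regions = phasing.detect_po(data.allele_pileups)
    b_sites, b_regions = phasing.detect_po(swapped)
    a_po = set(map(tuple, a_sites[a_sites["is_po"]][["chrom", "pos", "strand"]].values))
    b_po = set(map(tuple, b_sites[b_sites["is_po"]][["chrom", "pos", "strand"]].values))
    assert a_po == b_po
    pd.testing.assert_frame_equal(
        a_regions[["chrom", "start", "end", "hypermethylated_allele"]],
        b_regions[["chrom", "start", "end", "hypermethylated_allele"]],
    )


def test_reciprocal_crosses_show_almost_no_differences(truth, data, parental_groups):
    samples = truth.samples
    cross_groups = {
        "BNxSHR": list(samples[samples["role"] == "F1_BNxSHR"]["sample_id"]),
        "SHRxBN": list(samples[samples["role"] == "F1_SHRxBN"]["sample_id"]),
    }
    f1 = data.pileups[data.pileups["sample_id"].isin(sum(cross_groups.values(), []))]
    cross_dmc, _ = phasing.detect_cross_dm(
        f1, cross_groups, conversion_rates=truth.conversion_rates,
        variants=truth.variants
    )
    from methmap import diffmeth

    parental_dmc, _ = diffmeth.call_dmcs_and_dmrs(
        data.pileups, parental_groups, conversion_rates=truth.conversion_rates,
        variants=truth.variants
    )
    assert cross_dmc["significant"].mean() <= 0.05
    # far fewer cross differences than parental differences on shared truth
    assert cross_dmc["significant"].sum() < parental_dmc["significant"].sum() / 10
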