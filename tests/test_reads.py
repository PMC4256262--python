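import numpy as np
import pandas as pd
import pytest

from methmap import reads, simulate
from methmap.reads import AlignedPair, AlignedRead
from methmap.types import VariantRecord


@pytest.mark.parametrize(
    "seq,mode,expected",
    [("ACGT", "C2T", "ATGT"), ("ACGT", "G2A", "ACAT")],
)
def test_convert_reference_bulk_modes(seq, mode, expected):
    assert reads.convert_reference(seq, mode) == expected


def test_convert_reference_variant_modes():
    snp = [VariantRecord("c1", 2, "C", "G", "snp")]
    assert reads.convert_reference("ACGT", "snp_mask", snp) == "ANGT"
    assert reads.convert_reference("ACGT", "allele_substitute", snp) == "AGGT"
    with pytest.raises(ValueError, match="outside"):
        reads.convert_reference("ACGT", "snp_mask", [VariantRecord("c1", 9, "C", "G", "snp")])
    with pytest.raises(ValueError, match="unknown"):
        reads.convert_reference("ACGT", "bogus")


def test_preprocess_masks_clips_and_keeps_high_quality():
    out = reads.preprocess_read_pair("CCAT", [30] * 4, "GGAT", [30] * 4)
    assert out["seq1"] == "TAT"  # C->T mask then first-base clip
    assert out["seq2"] == "AAT"  # G->A mask then first-base clip
    assert not out["empty_after_trim"]


def test_preprocess_trims_low_quality_tail():
    out = reads.preprocess_read_pair(
        "AAAATTTT", [30, 30, 30, 30, 30, 2, 2, 2], "AAAA", [30] * 4
    )
    assert out["seq1"] == "AAAT"  # clip first base, trim the Q2 tail
    out2 = reads.preprocess_read_pair("AA", [2, 2], "AAAA", [30] * 4)
    assert out2["empty_after_trim"]


def _pair(pos1=10, pos2=100, seq1="ACAC", seq2="ACAC", mapq=30, qual=30,
          conv="C2T", proper=True, dual=False, qname="p"):
    q = [qual] * len(seq1)
    return AlignedPair(
        read1=AlignedRead("c1", pos1, seq1, list(q)),
        read2=AlignedRead("c1", pos2, seq2, [qual] * len(seq2)),
        mapq=mapq,
        conv_strand=conv,
        qname=qname,
        proper_orientation=proper,
        dual_strand=dual,
    )


def test_clonal_duplicates_keep_highest_quality_then_first_seen():
    low = _pair(qual=20, qname="low")
    high = _pair(qual=35, qname="high")
    kept = reads.filter_and_clip([low, high])
    assert [p.qname for p in kept] == ["high"]
    first = _pair(qual=30, qname="first")
    second = _pair(qual=30, qname="second")
    kept = reads.filter_and_clip([first, second])
    assert [p.qname for p in kept] == ["first"]


def test_mapq_boundary_and_strand_filters():
    assert reads.filter_and_clip([_pair(mapq=19)]) == []
    assert len(reads.filter_and_clip([_pair(mapq=20)])) == 1
    assert reads.filter_and_clip([_pair(dual=True)]) == []
    assert reads.filter_and_clip([_pair(proper=False)]) == []


def test_filtering_is_idempotent():
    pairs = [_pair(qname="a"), _pair(pos1=50, pos2=120, qname="b"), _pair(mapq=5)]
    once = reads.filter_and_clip(pairs)
    twice = reads.filter_and_clip(once)
    assert [p.qname for p in once] == [p.qname for p in twice]


def test_overlap_clipping_halves_double_coverage():
    # mates overlap by 10 bp at positions 20..29
    pair = _pair(pos1=10, pos2=20, seq1="C" * 20, seq2="C" * 20)
    sites = pd.DataFrame(
        {"chrom": "c1", "pos": list(range(10, 40)), "strand": "+"}
    )
    before = reads.pileup_cytosines([pair], sites, "s")
    assert (before[(before["pos"] >= 20) & (before["pos"] < 30)]["c_count"] == 2).all()
    clipped = reads.filter_and_clip([pair])
    after = reads.pileup_cytosines(clipped, sites, "s")
    assert (after["c_count"] <= 1).all()
    assert after["c_count"].sum() == 30  # every fragment base counted once


def test_pileup_counts_by_strand():
    fwd = [
        _pair(pos1=10, pos2=100, seq1=b, seq2="AAAA")
        for b in ("CAAA", "CAAA", "CAAA", "TAAA")
    ]
    sites = pd.DataFrame({"chrom": ["c1"], "pos": [10], "strand": ["+"]})
    pile = reads.pileup_cytosines(fwd, sites, "s")
    assert (pile["c_count"].iloc[0], pile["t_count"].iloc[0]) == (3, 1)
    rev = [
        _pair(pos1=10, pos2=100, seq1=b, seq2="TTTT", conv="G2A")
        for b in ("GAAA", "GAAA", "AAAA")
    ]
    sites = pd.DataFrame({"chrom": ["c1"], "pos": [10], "strand": ["-"]})
    pile = reads.pileup_cytosines(rev, sites, "s")
    assert (pile["c_count"].iloc[0], pile["t_count"].iloc[0]) == (2, 1)


def test_simulated_pileup_matches_truth_within_binomial_bounds(truth):
    pairs = simulate.simulate_f1_reads(truth, 3000, seed=21, conversion_rate=1.0)
    sites = truth.sites[truth.sites["chrom"] == "contig1"][
        ["chrom", "pos", "strand"]
    ]
    pile = reads.pileup_cytosines(pairs, sites, "s")
    merged = pile.merge(
        truth.sites, on=["chrom", "pos", "strand"], suffixes=("", "_t")
    )
    from methmap.calling import variant_affected_sites

    affected = variant_affected_sites(merged, truth.variants)
    deep = merged[
        (merged["c_count"] + merged["t_count"] >= 20)
        # allele-balanced sites only: at allele-differential sites the
        # haplotype mixture adds variance beyond the binomial, and
        # variant-hit dyads read the SHR allele base instead of C/T
        & (merged["theta_bn"] == merged["theta_shr"])
        & ~merged["is_imprinted"]
        & ~affected
    ]
    assert len(deep) > 20
    frac = deep["c_count"] / (deep["c_count"] + deep["t_count"])
    theta = deep["theta_bn"]
    n = deep["c_count"] + deep["t_count"]
    z = (frac - theta) / np.sqrt(theta * (1 - theta) / n + 1e-12)
    assert (np.abs(z) < 4.5).mean() > 0.98


def test_sam_round_trip(tmp_path):
    sam = tmp_path / "tiny.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:contig1\tLN:1000\n"
        "r1\t99\tcontig1\t10\t60\t4M\t=\t40\t34\tACGT\tIIII\tXG:Z:CT\n"
        "r1\t147\tcontig1\t40\t60\t4M\t=\t10\t-34\tTTGA\tIIII\tXG:Z:CT\n"
    )
    pairs = reads.read_sam_pairs(sam)
    assert len(pairs) == 1
    pair = pairs[0]
    assert pair.read1.pos == 10 and pair.read1.seq == "ACGT"
    assert pair.read2.pos == 40 and pair.read2.seq == "TTGA"
    assert pair.conv_strand == "C2T"
    assert pair.mapq == 60
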