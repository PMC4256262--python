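"""Bisulfite read handling: reference conversion, read pre-processing,
post-alignment filtering and the strand-specific cytosine pileup.

Alignment itself is consumed, not performed. Reads from the bisulfite
converted forward strand align against a C-to-T converted reference
(``C2T`` pairs, "original top" strand); reads from the converted reverse
strand against a G-to-A converted reference (``G2A`` pairs). Forward-strand
CpG sites are therefore read out as C/T calls from C2T pairs and
reverse-strand sites as G/A calls from G2A pairs.

All read sequences are stored in forward reference orientation; ``pos`` is
the 1-based leftmost aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import VariantRecord


# ---------------------------------------------------------------------------
# reference conversion


def convert_reference(
    seq: str,
    mode: str,
    variants: Sequence[VariantRecord] | None = None,
) -> str:
    """In-silico conversion of a reference sequence.

    Modes: ``C2T`` (all C -> T), ``G2A`` (all G -> A), ``allele_substitute``
    (place the SHR allele at SNP positions), ``snp_mask`` (replace SNP
    positions with N). Length is preserved in every mode; indels are not
    applied by the substitution modes.
    """
    if mode == "C2T":
        return seq.replace("C", "T")
    if mode == "G2A":
        return seq.replace("G", "A")
    if mode in ("allele_substitute", "snp_mask"):
        if variants is None:
            raise ValueError(f"mode {mode!r} requires a variant table")
        chars = list(seq)
        for v in variants:
            if v.kind != "snp":
                continue
            if not (1 <= v.pos <= len(seq)):
                raise ValueError(f"variant position {v.pos} outside sequence")
            chars[v.pos - 1] = "N" if mode == "snp_mask" else v.shr_allele
        return "".join(chars)
    raise ValueError(f"unknown conversion mode {mode!r}")


# ---------------------------------------------------------------------------
# raw read pre-processing (before alignment)


def quality_trim_3prime(seq: str, qual: Sequence[int], qcut: int = 20) -> tuple[str, list[int]]:
    """BWA-style running-sum 3' quality trimming at cutoff ``qcut``.

    Trims the suffix that maximises sum(qcut - q_i); reads with all
    qualities >= qcut are returned unchanged.
    """
    s = 0
    max_s = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        s += qcut - qual[i]
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return seq[:cut], list(qual[:cut])


def preprocess_read_pair(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    qcut: int = 20,
) -> dict:
    """Pre-alignment processing of a raw read pair (as-sequenced orientation).

    i) conversion-state masking: all C of read1 -> T, all G of read2 -> A;
    ii) the first base of each read is clipped (end-repair artefact);
    iii) 3' quality trimming by the running-sum rule at ``qcut``.

    Returns a dict with the processed sequences/qualities and an
    ``empty_after_trim`` flag (empty reads are flagged, not an error).
    """
    m1 = seq1.replace("C", "T")
    m2 = seq2.replace("G", "A")
    m1, q1 = m1[1:], list(qual1[1:])
    m2, q2 = m2[1:], list(qual2[1:])
    m1, q1 = quality_trim_3prime(m1, q1, qcut)
    m2, q2 = quality_trim_3prime(m2, q2, qcut)
    return {
        "seq1": m1,
        "qual1": q1,
        "seq2": m2,
        "qual2": q2,
        "empty_after_trim": len(m1) == 0 or len(m2) == 0,
    }


# ---------------------------------------------------------------------------
# aligned pairs


@dataclass
class AlignedRead:
    chrom: str
    pos: int  # 1-based leftmost aligned base
    seq: str  # forward reference orientation
    qual: list[int]
    is_reverse: bool = False

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned base."""
        return self.pos + len(self.seq) - 1

    def base_at(self, pos: int) -> str | None:
        if self.pos <= pos <= self.end:
            return self.seq[pos - self.pos]
        return None


@dataclass
class AlignedPair:
    read1: AlignedRead
    read2: AlignedRead
    mapq: int
    conv_strand: str  # 'C2T' (original top) or 'G2A' (original bottom)
    qname: str = ""
    proper_orientation: bool = True
    dual_strand: bool = False  # mapped to both converted references
    true_haplotype: str | None = None  # simulation truth, if any

    def duplicate_key(self, mode: str = "leftmost") -> tuple:
        """Clonal-duplicate key. ``leftmost``: (chrom, leftmost pos,
        strand); ``both_mates`` additionally includes the second mate's
        5' coordinate."""
        left = min(self.read1.pos, self.read2.pos)
        if mode == "leftmost":
            return (self.read1.chrom, left, self.conv_strand)
        if mode == "both_mates":
            right = max(self.read1.end, self.read2.end)
            return (self.read1.chrom, left, right, self.conv_strand)
        raise ValueError(f"unknown duplicate-key mode {mode!r}")

    def summed_quality(self) -> int:
        return sum(self.read1.qual) + sum(self.read2.qual)


def _clip_overlap(pair: AlignedPair) -> AlignedPair:
    """Clip the 3' ends of overlapping mates so each fragment base is
    covered once, keeping the mate with the higher mean base quality in
    the overlap (ties keep read1)."""
    r1, r2 = pair.read1, pair.read2
    left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
    ov_start = right.pos
    ov_end = min(left.end, right.end)
    if ov_start > ov_end:
        return pair

    def mean_q(read: AlignedRead) -> float:
        i0 = ov_start - read.pos
        i1 = ov_end - read.pos + 1
        window = read.qual[i0:i1]
        return sum(window) / len(window) if window else 0.0

    keep_r1 = mean_q(r1) >= mean_q(r2)
    loser = r2 if keep_r1 else r1
    # remove the overlap from the losing read (its portion inside the
    # overlap window); for the left read this is its tail, for the right
    # read its head
    if loser is left:
        n = loser.end - ov_start + 1
        clipped = replace(loser, seq=loser.seq[:-n] if n else loser.seq,
                          qual=loser.qual[:-n] if n else loser.qual)
    else:
        n = ov_end - loser.pos + 1
        clipped = replace(loser, pos=loser.pos + n, seq=loser.seq[n:],
                          qual=loser.qual[n:])
    if loser is r1:
        return replace(pair, read1=clipped)
    return replace(pair, read2=clipped)


def filter_and_clip(
    pairs: Iterable[AlignedPair],
    min_mapq: int = 20,
    dup_key_mode: str = "leftmost",
) -> list[AlignedPair]:
    """Post-alignment filtering: remove clonal duplicates (keep the
    highest summed base quality, ties first-seen), MAPQ < ``min_mapq``,
    pairs mapping to both converted strands, and invalid orientations;
    then clip mate overlaps."""
    best: dict[tuple, AlignedPair] = {}
    for pair in pairs:
        if pair.mapq < min_mapq:
            continue
        if pair.dual_strand:
            continue
        if not pair.proper_orientation:
            continue
        key = pair.duplicate_key(dup_key_mode)
        incumbent = best.get(key)
        if incumbent is None or pair.summed_quality() > incumbent.summed_quality():
            best[key] = pair
    return [_clip_overlap(p) for p in best.values()]


# ---------------------------------------------------------------------------
# strand-specific cytosine pileup


def pileup_cytosines(
    pairs: Iterable[AlignedPair],
    sites: pd.DataFrame,
    sample_id: str,
) -> pd.DataFrame:
    """Count C/T base calls at strand-specific cytosine positions.

    ``sites`` needs columns chrom, pos, strand. Forward-strand sites are
    counted from C2T pairs (C = methylated call, T = converted);
    reverse-strand sites from G2A pairs, whose G/A calls (forward
    orientation) are reported as c/t. Returns a pileup table covering
    every requested site (zero counts where uncovered).
    """
    counts: dict[tuple, list[int]] = {
        (row.chrom, row.pos, row.strand): [0, 0, 0]
        for row in sites.itertuples()
    }
    for pair in pairs:
        want_strand = "+" if pair.conv_strand == "C2T" else "-"
        meth_base, unmeth_base = ("C", "T") if want_strand == "+" else ("G", "A")
        for read in (pair.read1, pair.read2):
            for pos in range(read.pos, read.end + 1):
                key = (read.chrom, pos, want_strand)
                slot = counts.get(key)
                if slot is None:
                    continue
                base = read.seq[pos - read.pos]
                if base == meth_base:
                    slot[0] += 1
                elif base == unmeth_base:
                    slot[1] += 1
                else:
                    slot[2] += 1
    rows = [
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "sample_id": sample_id,
            "c_count": c,
            "t_count": t,
            "other_count": o,
        }
        for (chrom, pos, strand), (c, t, o) in counts.items()
    ]
    return pd.DataFrame(rows).sort_values(["chrom", "pos", "strand"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# SAM-subset input (external aligner output)


def read_sam_pairs(path: str | Path) -> list[AlignedPair]:
    """Load aligned pairs from a SAM file. The converted-reference strand
    is taken from the ``XG`` tag (``CT`` or ``GA``), the convention used
    by bisulfite aligners."""
    import pysam

    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            by_name.setdefault(rec.query_name, []).append(rec)
    pairs = []
    for qname, recs in by_name.items():
        if len(recs) != 2:
            continue
        first = next(r for r in recs if r.is_read1)
        second = next(r for r in recs if r.is_read2)
        tag = first.get_tag("XG") if first.has_tag("XG") else "CT"
        reads = []
        for rec in (first, second):
            qual = list(rec.query_qualities) if rec.query_qualities is not None else [
                30
            ] * len(rec.query_sequence)
            reads.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    seq=rec.query_sequence,
                    qual=qual,
                    is_reverse=rec.is_reverse,
                )
            )
        proper = first.is_proper_pair
        pairs.append(
            AlignedPair(
                read1=reads[0],
                read2=reads[1],
                mapq=min(first.mapping_quality, second.mapping_quality),
                conv_strand="C2T" if tag == "CT" else "G2A",
                qname=qname,
                proper_orientation=proper,
            )
        )
    return pairs
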