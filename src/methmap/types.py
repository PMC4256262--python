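"""Core domain records shared across the pipeline.

Coordinates are 1-based inclusive throughout the library (the position of a
CpG site is the position of its cytosine); BED export converts to 0-based
half-open. The two strands of a CpG dyad are distinct sites: the forward
strand site sits at the C of ``CG`` and the reverse-strand site at the G
(which is a C on the reverse strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


class CpGSite(NamedTuple):
    """A strand-specific cytosine position.

    ``pos`` is the 1-based coordinate of the cytosine on the given strand
    (for '-' sites this is the G of the dyad in forward-strand coordinates).
    """

    chrom: str
    pos: int
    strand: str  # '+' or '-'

    def validate(self) -> "CpGSite":
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        return self


@dataclass(frozen=True)
class PileupRecord:
    """Per-sample C/T base-call counts at one strand-specific cytosine."""

    site: CpGSite
    sample_id: str
    c_count: int
    t_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        for name in ("c_count", "t_count", "other_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        self.site.validate()

    @property
    def coverage(self) -> int:
        return self.c_count + self.t_count + self.other_count


@dataclass(frozen=True)
class VariantRecord:
    """An inter-strain sequence variant with one allele per parental strain."""

    chrom: str
    pos: int  # 1-based
    bn_allele: str
    shr_allele: str
    kind: str  # 'snp' | 'indel'

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.bn_allele == self.shr_allele:
            raise ValueError(
                f"alleles must differ at {self.chrom}:{self.pos} "
                f"(both {self.bn_allele!r})"
            )
        if self.kind not in ("snp", "indel"):
            raise ValueError(f"kind must be 'snp' or 'indel', got {self.kind!r}")
        if self.kind == "snp" and (
            len(self.bn_allele) != 1 or len(self.shr_allele) != 1
        ):
            raise ValueError(
                f"snp at {self.chrom}:{self.pos} must have single-base alleles"
            )
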