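"""Readers and writers for the on-disk tables.

All tables are TSV with a header line. Positions on disk and in memory are
1-based; only BED export converts to 0-based half-open intervals. Floats are
written with fixed 6-decimal formatting so that a write/read round trip is
exact at the written precision; integer columns round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# column name -> required dtype kind ('i' integer, 'f' float, 's' string)
SCHEMAS: dict[str, dict[str, str]] = {
    "pileup": {
        "chrom": "s",
        "pos": "i",
        "strand": "s",
        "sample_id": "s",
        "c_count": "i",
        "t_count": "i",
        "other_count": "i",
    },
    "variant": {
        "chrom": "s",
        "pos": "i",
        "bn_allele": "s",
        "shr_allele": "s",
        "kind": "s",
    },
    "phenotype": {"strain": "s", "trait": "s", "replicate": "i", "value": "f"},
    "marker_map": {"marker": "s", "chrom": "s", "pos": "i"},
    "phased_pileup": {
        "chrom": "s",
        "pos": "i",
        "strand": "s",
        "cross": "s",
        "replicate": "i",
        "allele": "s",
        "c_count": "i",
        "t_count": "i",
    },
    "methylation": {
        "chrom": "s",
        "pos": "i",
        "strand": "s",
        "sample_id": "s",
        "c_count": "i",
        "t_count": "i",
        "m_raw": "f",
        "m_corrected": "f",
    },
}

_FLOAT_FORMAT = "%.6f"


class SchemaError(ValueError):
    """A table did not match its declared schema."""


def _check_columns(df: pd.DataFrame, kind: str) -> None:
    schema = SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"{kind} table has unexpected columns {extra}")


def _coerce(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    schema = SCHEMAS[kind]
    out = df.copy()
    for col, dkind in schema.items():
        if dkind == "i":
            numeric = pd.to_numeric(out[col], errors="coerce")
            bad = numeric.isna() | (numeric != np.floor(numeric))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"{kind} table column {col!r} row {row}: "
                    f"{df[col].iloc[row]!r} is not an integer"
                )
            out[col] = numeric.astype(np.int64)
        elif dkind == "f":
            numeric = pd.to_numeric(out[col], errors="coerce")
            if numeric.isna().any() and out[col].notna().any():
                row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
                raise SchemaError(
                    f"{kind} table column {col!r} row {row}: "
                    f"{df[col].iloc[row]!r} is not numeric"
                )
            out[col] = numeric.astype(float)
        else:
            out[col] = out[col].astype(str)
    return out


def _validate(df: pd.DataFrame, kind: str) -> None:
    if "pos" in df.columns and (df["pos"] < 1).any():
        raise SchemaError(f"{kind} table has positions < 1")
    if "strand" in df.columns:
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise SchemaError(f"{kind} table has strand values outside {{+,-}}")
    for col in ("c_count", "t_count", "other_count"):
        if col in df.columns and (df[col] < 0).any():
            raise SchemaError(f"{kind} table has negative {col}")
    if kind == "pileup":
        keys = ["chrom", "pos", "strand", "sample_id"]
        if df.duplicated(keys).any():
            dup = df[df.duplicated(keys, keep=False)].iloc[0]
            raise SchemaError(
                "duplicate (site, sample) key at "
                f"{dup['chrom']}:{dup['pos']}{dup['strand']} {dup['sample_id']}"
            )
    if kind == "variant":
        same = df["bn_allele"] == df["shr_allele"]
        if same.any():
            row = df[same].iloc[0]
            raise SchemaError(
                f"variant at {row['chrom']}:{row['pos']} has identical alleles"
            )
        bad_kind = ~df["kind"].isin(["snp", "indel"])
        if bad_kind.any():
            raise SchemaError("variant kind must be 'snp' or 'indel'")
        snps = df[df["kind"] == "snp"]
        multi = (snps["bn_allele"].str.len() != 1) | (
            snps["shr_allele"].str.len() != 1
        )
        if multi.any():
            row = snps[multi].iloc[0]
            raise SchemaError(
                f"snp at {row['chrom']}:{row['pos']} has multi-base alleles"
            )


def read_tables(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a typed table. Malformed rows raise, never drop."""
    path = Path(path)
    if kind not in SCHEMAS and kind != "genotype":
        raise ValueError(f"unknown table kind {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if kind == "genotype":
        return _read_genotype(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, kind)
    df = _coerce(df, kind)
    _validate(df, kind)
    return df


def _read_genotype(path: Path) -> pd.DataFrame:
    """RI genotype matrix: rows = strains, columns = markers, values B/S/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    for strain in df.index:
        for marker in df.columns:
            v = df.loc[strain, marker]
            if v not in ("B", "S", "NA"):
                raise SchemaError(
                    f"genotype matrix entry {v!r} at strain {strain!r}, "
                    f"marker {marker!r} is not in {{B, S, NA}}"
                )
    return df


def write_tables(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a validated table; inverse of :func:`read_tables`."""
    path = Path(path)
    if kind == "genotype":
        df.to_csv(path, sep="\t")
        return
    _check_columns(df, kind)
    df = _coerce(df, kind)
    _validate(df, kind)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_bed(
    regions: pd.DataFrame,
    path: str | Path,
    extra_columns: Iterable[str] = (),
) -> None:
    """Write regions (1-based inclusive ``start``/``end``) as 0-based
    half-open BED plus any extra columns appended after the name field."""
    extra_columns = list(extra_columns)
    with open(path, "w") as fh:
        for i, row in regions.reset_index(drop=True).iterrows():
            name = row["name"] if "name" in regions.columns else f"region_{i}"
            fields = [
                str(row["chrom"]),
                str(int(row["start"]) - 1),
                str(int(row["end"])),
                str(name),
            ]
            for col in extra_columns:
                value = row[col]
                if isinstance(value, float):
                    fields.append(_FLOAT_FORMAT % value)
                else:
                    fields.append(str(value))
            fh.write("\t".join(fields) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            elif name is not None:
                sequences[name].append(line)
    return {k: "".join(v) for k, v in sequences.items()}
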