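"""Conversion-rate estimation, conversion-corrected methylation levels,
and the coverage/variant site filters.

The relative methylation level at a cytosine is the percentage of C base
calls among C+T calls, corrected for incomplete bisulfite conversion by
subtracting the expected number of unconverted (falsely methylated-looking)
cytosines at that coverage. Each observed T call represents a converted,
hence unmethylated, molecule; with conversion rate r_s the unmethylated
molecules number t / r_s in expectation, of which a fraction (1 - r_s)
failed to convert and were read as C. The corrected level is therefore

    m = 100 * max(0, c - t * (1 - r_s) / r_s) / (c + t)

which is unbiased for 100 * theta at any methylation level theta (the
naive subtraction of (c + t) * (1 - r_s) undercalls methylated sites by
up to 100 * (1 - r_s) percentage points). F1 libraries carry an
unmethylated lambda spike-in from which r_s is read off directly; parental
libraries have no spike-in, so their r_s is predicted from their genomic
non-CpG conversion rate through an ordinary least-squares fit of
lambda-rate on non-CpG-rate across the F1 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConversionEstimate:
    sample_id: str
    r_lambda: float | None  # from spike-in (F1 samples only)
    r_noncpg: float  # genomic non-CpG conversion rate
    r_s: float  # final rate used for correction
    ok: bool  # rates > 0.97 are unflagged; lower raises a warning flag


def _rate(pileups: pd.DataFrame) -> pd.Series:
    """Conversion rate per sample: T / (C + T) over unmethylated cytosines
    (C calls are conversion failures)."""
    g = pileups.groupby("sample_id")[["c_count", "t_count"]].sum()
    cov = g["c_count"] + g["t_count"]
    if (cov == 0).any():
        zero = cov.index[cov == 0].tolist()
        raise ValueError(f"zero coverage for conversion estimation: {zero}")
    return g["t_count"] / cov


def estimate_conversion_rates(
    lambda_pileups: pd.DataFrame,
    noncpg_pileups: pd.DataFrame,
    f1_samples: list[str],
    parental_samples: list[str],
    ok_threshold: float = 0.97,
) -> dict[str, ConversionEstimate]:
    """Per-sample bisulfite conversion rates.

    F1 samples: r_s is the lambda spike-in conversion rate. Parental
    samples: r_s = a + b * r_noncpg with (a, b) fit by OLS over the F1
    points (x = non-CpG rate, y = lambda rate); predictions are clamped
    to [0, 1].
    """
    if len(f1_samples) < 2:
        raise ValueError("need at least 2 F1 samples for the regression")
    r_lambda = _rate(lambda_pileups[lambda_pileups["sample_id"].isin(f1_samples)])
    missing = set(f1_samples) - set(r_lambda.index)
    if missing:
        raise ValueError(f"no lambda coverage for F1 samples {sorted(missing)}")
    r_noncpg = _rate(noncpg_pileups)

    x = r_noncpg.reindex(f1_samples).to_numpy()
    y = r_lambda.reindex(f1_samples).to_numpy()
    slope, intercept = np.polyfit(x, y, 1)

    estimates: dict[str, ConversionEstimate] = {}
    for s in f1_samples:
        r = float(r_lambda[s])
        estimates[s] = ConversionEstimate(
            s, r, float(r_noncpg[s]), r, r > ok_threshold
        )
    for s in parental_samples:
        if s not in r_noncpg.index:
            raise ValueError(f"no non-CpG pileup for sample {s!r}")
        r = float(np.clip(intercept + slope * r_noncpg[s], 0.0, 1.0))
        estimates[s] = ConversionEstimate(
            s, None, float(r_noncpg[s]), r, r > ok_threshold
        )
    return estimates


def corrected_methylation(
    c: np.ndarray | int,
    t: np.ndarray | int,
    r_s: np.ndarray | float,
) -> np.ndarray | float:
    """Conversion-corrected percent methylation, clamped to [0, 100]."""
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    r = np.asarray(r_s, dtype=float)
    cov = c + t
    if np.any(cov == 0):
        raise ValueError("zero coverage: methylation undefined")
    if np.any(r <= 0):
        raise ValueError("conversion rate must be positive")
    m = np.clip(100.0 * (c - t * (1.0 - r) / r) / cov, 0.0, 100.0)
    return float(m) if m.ndim == 0 else m


def build_methylation_table(
    pileups: pd.DataFrame,
    conversion_rates: dict[str, float],
) -> pd.DataFrame:
    """Per-(site, sample) raw and corrected methylation percentages."""
    out = pileups[pileups["c_count"] + pileups["t_count"] > 0].copy()
    cov = out["c_count"] + out["t_count"]
    out["m_raw"] = 100.0 * out["c_count"] / cov
    r = out["sample_id"].map(conversion_rates)
    if r.isna().any():
        unknown = sorted(out.loc[r.isna(), "sample_id"].unique())
        raise ValueError(f"no conversion rate for samples {unknown}")
    out["m_corrected"] = corrected_methylation(
        out["c_count"].to_numpy(), out["t_count"].to_numpy(), r.to_numpy()
    )
    return out.drop(columns=["other_count"], errors="ignore")


def variant_affected_sites(
    sites: pd.DataFrame, variants: pd.DataFrame
) -> pd.Series:
    """Boolean mask over ``sites`` rows whose CpG dyad overlaps a SNP or
    indel footprint. The dyad of a '+' site at p is {p, p+1}; of a '-'
    site at p it is {p-1, p}. Indels occupy the span of their longer
    allele starting at their position."""
    affected: set[tuple[str, int]] = set()
    for v in variants.itertuples():
        span = max(len(v.bn_allele), len(v.shr_allele)) if v.kind == "indel" else 1
        for p in range(v.pos, v.pos + span):
            affected.add((v.chrom, p))
    dyad_first = np.where(sites["strand"] == "+", sites["pos"], sites["pos"] - 1)
    hit_first = [
        (c, int(p)) in affected for c, p in zip(sites["chrom"], dyad_first)
    ]
    hit_second = [
        (c, int(p) + 1) in affected for c, p in zip(sites["chrom"], dyad_first)
    ]
    return pd.Series(np.asarray(hit_first) | np.asarray(hit_second), index=sites.index)


def apply_site_filters(
    pileups: pd.DataFrame,
    groups: dict[str, list[str]],
    variants: pd.DataFrame | None = None,
    min_coverage: int = 5,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Sites passing the coverage filter in every group, minus sites whose
    dinucleotide is affected by sequence variation.

    A site passes for a group iff at least ``min_replicates`` of the
    group's samples have combined C+T coverage >= ``min_coverage``.
    Returns a frame with columns chrom, pos, strand.
    """
    cov = pileups.assign(cov=pileups["c_count"] + pileups["t_count"])
    passing: pd.Index | None = None
    for name, samples in groups.items():
        sub = cov[cov["sample_id"].isin(samples) & (cov["cov"] >= min_coverage)]
        reps = sub.groupby(["chrom", "pos", "strand"])["sample_id"].nunique()
        ok = reps[reps >= min_replicates].index
        passing = ok if passing is None else passing.intersection(ok)
    if passing is None:
        raise ValueError("no groups given")
    sites = pd.DataFrame(list(passing), columns=["chrom", "pos", "strand"])
    if variants is not None and len(variants) and len(sites):
        sites = sites[~variant_affected_sites(sites, variants)]
    return sites.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
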