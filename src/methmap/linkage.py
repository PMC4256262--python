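"""Single-marker meth-QTL mapping across a recombinant-inbred panel.

For a two-genotype RI panel the single-marker LOD score reduces to the
correlation form

    LOD = -(n/2) * log10(1 - r^2)

with r the Pearson correlation between the coded marker genotype (B=0,
S=1) and the trait over the n strains with complete data. Empirical
significance is by permutation of the trait across strains (genotypes
fixed), with the +1-corrected estimator p = (1 + #{perm max-LOD >=
observed}) / (n_perm + 1). A significant peak is cis when it lies within
the cis window (default 5 Mbp) of the trait's genomic location on the
same chromosome, trans otherwise; non-significant traits are NSL.

Heritability is the intraclass correlation from a one-way ANOVA across
strains, h2 = (MSB - MSW) / (MSB + (k - 1) MSW) for k replicates per
strain; the variance explained at the peak is the squared correlation of
strain means with the peak genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LinkageResult:
    trait: str
    scan: pd.DataFrame  # marker, chrom, pos, lod
    peak_marker: str
    peak_chrom: str
    peak_pos: int
    peak_lod: float
    p: float
    classification: str  # 'cis' | 'trans' | 'NSL'
    h2: float | None
    r2_cis: float
    support_interval: tuple[str, int, int] | None = None


_CODE = {"B": 0.0, "S": 1.0, "NA": np.nan}


def code_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Map B -> 0, S -> 1, NA -> NaN (strains x markers)."""
    return genotypes.apply(lambda col: col.map(_CODE)).astype(float)


def lod_from_r2(r2: np.ndarray | float, n: int) -> np.ndarray | float:
    return -(n / 2.0) * np.log10(np.clip(1.0 - np.asarray(r2, dtype=float), 1e-300, 1.0))


def _marker_lods(y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Per-marker LOD for one trait; NaN genotypes handled pairwise."""
    n, m = G.shape
    lods = np.zeros(m)
    if np.isnan(G).any():
        for j in range(m):
            mask = ~np.isnan(G[:, j])
            gj = G[mask, j]
            yj = y[mask]
            if len(yj) < 3 or gj.std() == 0 or yj.std() == 0:
                continue
            r = np.corrcoef(gj, yj)[0, 1]
            lods[j] = lod_from_r2(r**2, len(yj))
        return lods
    sd_g = G.std(axis=0)
    poly = sd_g > 0
    if y.std() == 0 or not poly.any():
        return lods
    zy = (y - y.mean()) / y.std()
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd_g[poly]
    r = zy @ Z / n
    lods[poly] = lod_from_r2(r**2, n)
    return lods


def lod_scan(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
) -> pd.DataFrame:
    """Genome scan of a strain-indexed trait. Returns a frame (marker,
    chrom, pos, lod) in map order. Monomorphic markers score 0."""
    strains = trait.dropna().index.intersection(genotypes.index)
    if len(strains) < 8:
        raise ValueError("need at least 8 strains with trait and genotype data")
    y = trait.loc[strains].to_numpy(dtype=float)
    G = code_genotypes(genotypes.loc[strains, marker_map["marker"]]).to_numpy()
    scan = marker_map.copy()
    scan["lod"] = _marker_lods(y, G)
    return scan


def permutation_pvalue(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical genome-wide p-value for the observed peak LOD."""
    if n_perm < 1000:
        warnings.warn(
            f"n_perm={n_perm} is below the 1000-permutation minimum for a "
            "stable empirical p-value",
            stacklevel=2,
        )
    strains = trait.dropna().index.intersection(genotypes.index)
    y = trait.loc[strains].to_numpy(dtype=float)
    G = code_genotypes(genotypes.loc[strains, marker_map["marker"]]).to_numpy()
    observed = _marker_lods(y, G).max()
    rng = np.random.default_rng(seed)
    n = len(y)
    if not np.isnan(G).any() and y.std() > 0:
        sd_g = G.std(axis=0)
        poly = sd_g > 0
        Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd_g[poly]
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        zy = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(
            axis=1, keepdims=True
        )
        r = zy @ Z / n
        max_lod = lod_from_r2((r**2).max(axis=1), n)
    else:
        max_lod = np.empty(n_perm)
        for i in range(n_perm):
            max_lod[i] = _marker_lods(rng.permutation(y), G).max()
    exceed = int(np.sum(max_lod >= observed))
    return (1 + exceed) / (n_perm + 1)


def classify_linkage(
    peak_chrom: str,
    peak_pos: int,
    trait_chrom: str,
    trait_pos: int,
    p: float,
    cis_window: int = 5_000_000,
    alpha: float = 0.05,
) -> str:
    """cis / trans / NSL by the peak-to-locus distance rule."""
    if p >= alpha:
        return "NSL"
    if peak_chrom == trait_chrom and abs(peak_pos - trait_pos) <= cis_window:
        return "cis"
    return "trans"


def heritability(replicates: pd.DataFrame) -> float:
    """Intraclass correlation from one-way ANOVA across strains.

    ``replicates`` has columns strain, value with k >= 2 replicates per
    strain (a balanced design is assumed; k is the mean replicate count).
    Degenerate zero-variance input returns 0.
    """
    groups = [sub["value"].to_numpy(dtype=float) for _, sub in replicates.groupby("strain")]
    if any(len(g) < 2 for g in groups):
        raise ValueError("heritability requires >= 2 replicates per strain")
    k = np.mean([len(g) for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) - 1 for g in groups)
    msb = ssb / df_b
    msw = ssw / df_w
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


def variance_explained(strain_means: pd.Series, peak_genotype: pd.Series) -> float:
    """r^2 of strain means against the coded peak-marker genotype."""
    coded = peak_genotype.map(_CODE).astype(float)
    df = pd.DataFrame({"y": strain_means, "g": coded}).dropna()
    if df["g"].std() == 0 or df["y"].std() == 0:
        return 0.0
    return float(np.corrcoef(df["y"], df["g"])[0, 1] ** 2)


def support_interval(scan: pd.DataFrame, drop: float = 2.0) -> tuple[str, int, int]:
    """Contiguous region on the peak chromosome within ``drop`` LOD of
    the peak."""
    peak = scan.loc[scan["lod"].idxmax()]
    chrom_scan = scan[scan["chrom"] == peak["chrom"]].sort_values("pos").reset_index(drop=True)
    peak_i = int(chrom_scan["lod"].idxmax())
    lo = peak_i
    while lo > 0 and chrom_scan["lod"].iloc[lo - 1] >= peak["lod"] - drop:
        lo -= 1
    hi = peak_i
    while hi < len(chrom_scan) - 1 and chrom_scan["lod"].iloc[hi + 1] >= peak["lod"] - drop:
        hi += 1
    return (peak["chrom"], int(chrom_scan["pos"].iloc[lo]), int(chrom_scan["pos"].iloc[hi]))


def map_trait(
    trait_replicates: pd.DataFrame,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    trait_chrom: str,
    trait_pos: int,
    trait_name: str = "trait",
    n_perm: int = 10_000,
    seed: int = 0,
    cis_window: int = 5_000_000,
) -> LinkageResult:
    """Full linkage workflow for one trait: strain means, genome scan,
    permutation p, cis/trans call, heritability and variance explained."""
    means = trait_replicates.groupby("strain")["value"].mean()
    scan = lod_scan(means, genotypes, marker_map)
    peak = scan.loc[scan["lod"].idxmax()]
    p = permutation_pvalue(means, genotypes, marker_map, n_perm=n_perm, seed=seed)
    classification = classify_linkage(
        peak["chrom"], int(peak["pos"]), trait_chrom, trait_pos, p, cis_window
    )
    k_ok = trait_replicates.groupby("strain").size().min() >= 2
    h2 = heritability(trait_replicates) if k_ok else None
    r2 = variance_explained(means, genotypes[peak["marker"]])
    return LinkageResult(
        trait=trait_name,
        scan=scan,
        peak_marker=peak["marker"],
        peak_chrom=peak["chrom"],
        peak_pos=int(peak["pos"]),
        peak_lod=float(peak["lod"]),
        p=p,
        classification=classification,
        h2=h2,
        r2_cis=r2,
        support_interval=support_interval(scan),
    )
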