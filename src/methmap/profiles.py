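"""Sample-level structure of methylation profiles: coverage-equalised
hierarchical clustering and principal component analysis.

To remove coverage-driven variance, each site's base calls are scaled
down to a common depth (default 5x) by hypergeometric subsampling without
replacement, which preserves the expected methylation level while keeping
integer counts. Only complete cases (sites at or above the target depth
in every included sample, dyads unaffected by sequence variation) enter
the profile matrix. Profiles are clustered by Ward's minimum-variance
method on pairwise Euclidean distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .calling import variant_affected_sites

KEY = ["chrom", "pos", "strand"]


def downsample_to_depth(
    c: np.ndarray,
    t: np.ndarray,
    target: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric draw of ``target`` base calls from c C-calls and t
    T-calls, without replacement; requires c + t >= target."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(c, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    if np.any(c + t < target):
        raise ValueError("coverage below target depth; exclude such sites upstream")
    c_sub = rng.hypergeometric(c, t, target)
    return c_sub, target - c_sub


def build_profile_matrix(
    pileups: pd.DataFrame,
    samples: list[str],
    variants: pd.DataFrame | None = None,
    target_depth: int = 5,
    seed: int = 0,
    downsample: bool = True,
) -> pd.DataFrame:
    """Sites x samples matrix of methylation percentages at equalised
    coverage. With ``downsample=False`` the analytic expectation
    (raw percentage) is used instead of the integer subsample."""
    rng = np.random.default_rng(seed)
    sub = pileups[pileups["sample_id"].isin(samples)].copy()
    sub["cov"] = sub["c_count"] + sub["t_count"]
    sub = sub[sub["cov"] >= target_depth]
    counts = sub.pivot_table(index=KEY, columns="sample_id", values="c_count")
    cov = sub.pivot_table(index=KEY, columns="sample_id", values="cov")
    complete = counts.dropna().index.intersection(cov.dropna().index)
    counts = counts.loc[complete, samples]
    cov = cov.loc[complete, samples]
    if variants is not None and len(variants) and len(complete):
        site_frame = counts.index.to_frame(index=False)
        mask = ~variant_affected_sites(site_frame, variants).to_numpy()
        counts, cov = counts[mask], cov[mask]
    if downsample:
        c = counts.to_numpy().astype(np.int64)
        t = cov.to_numpy().astype(np.int64) - c
        c_sub, _ = downsample_to_depth(c.ravel(), t.ravel(), target_depth, rng)
        m = 100.0 * c_sub.reshape(c.shape) / target_depth
    else:
        m = 100.0 * counts.to_numpy() / cov.to_numpy()
    return pd.DataFrame(m, index=counts.index, columns=samples)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def recurse(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = recurse(node.get_left())
        right = recurse(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6f},{right}:{dr:.6f})"

    return recurse(tree) + ";"


def cluster_profiles(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
) -> dict:
    """Ward clustering of sample profiles on Euclidean distances.

    Returns the linkage matrix, a newick rendering of the dendrogram,
    the full distance matrix, and — when ``groups`` is given — the mean
    within-group and between-group distances.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    samples = list(matrix.columns)
    X = matrix.to_numpy().T
    condensed = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(condensed, method="ward")
    D = pd.DataFrame(squareform(condensed), index=samples, columns=samples)
    out = {"linkage": Z, "newick": _linkage_to_newick(Z, samples), "distances": D}
    if groups:
        within = {}
        for name, members in groups.items():
            vals = [
                D.loc[a, b]
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            ]
            within[name] = float(np.mean(vals)) if vals else np.nan
        names = list(groups)
        between = {}
        for i, g1 in enumerate(names):
            for g2 in names[i + 1 :]:
                vals = [D.loc[a, b] for a in groups[g1] for b in groups[g2]]
                between[(g1, g2)] = float(np.mean(vals))
        out["within"] = within
        out["between"] = between
    return out


def pca_profiles(
    matrix: pd.DataFrame,
    scaling: str = "none",
) -> dict:
    """PCA of sample profiles (samples as observations, sites as
    variables). ``scaling``: 'none' (centering only) or 'unit_variance'.
    Variance fractions sum to 100%; each component's sign is fixed by
    forcing its largest-magnitude loading positive."""
    if scaling not in ("none", "unit_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.to_numpy().T.astype(float)  # samples x sites
    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance matrix")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    variances = S**2 / (n - 1)
    positive = variances > 1e-12 * variances.max()
    U, S, Vt = U[:, positive], S[positive], Vt[positive]
    scores = U * S
    loadings = Vt.T
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var_pct = 100.0 * variances[positive] / variances[positive].sum()
    comp = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return {
        "scores": pd.DataFrame(scores, index=matrix.columns, columns=comp),
        "loadings": pd.DataFrame(loadings, columns=comp),
        "variance_pct": var_pct,
    }
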