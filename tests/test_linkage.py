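import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmap import linkage, simulate


def test_lod_closed_form():
    assert linkage.lod_from_r2(0.5, 29) == pytest.approx(-14.5 * np.log10(0.5))
    assert linkage.lod_from_r2(0.5, 29) == pytest.approx(4.365, abs=1e-3)
    assert linkage.lod_from_r2(0.0, 29) == 0.0


def _toy_panel(n_strains=20, n_markers=6, seed=0):
    rng = np.random.default_rng(seed)
    strains = [f"RI{i}" for i in range(n_strains)]
    markers = [f"m{i}" for i in range(n_markers)]
    geno = pd.DataFrame(
        rng.choice(["B", "S"], size=(n_strains, n_markers)),
        index=strains,
        columns=markers,
    )
    geno["m0"] = "B"  # monomorphic marker
    marker_map = pd.DataFrame(
        {"marker": markers, "chrom": "chr1", "pos": np.arange(n_markers) * 2_000_000}
    )
    return geno, marker_map, strains


def test_scan_skips_monomorphic_markers_and_finds_signal():
    geno, marker_map, strains = _toy_panel()
    coded = linkage.code_genotypes(geno)
    trait = pd.Series(coded["m3"] * 10 + 50, index=strains)
    scan = linkage.lod_scan(trait, geno, marker_map)
    assert scan.loc[scan["marker"] == "m0", "lod"].iloc[0] == 0.0
    assert scan.loc[scan["lod"].idxmax(), "marker"] == "m3"


def test_lod_invariant_under_affine_trait_transform():
    geno, marker_map, strains = _toy_panel(seed=1)
    rng = np.random.default_rng(2)
    trait = pd.Series(rng.normal(size=len(strains)), index=strains)
    a = linkage.lod_scan(trait, geno, marker_map)["lod"]
    b = linkage.lod_scan(-3.0 * trait + 11.0, geno, marker_map)["lod"]
    assert a.to_numpy() == pytest.approx(b.to_numpy())


def test_scan_requires_enough_strains():
    geno, marker_map, strains = _toy_panel(n_strains=5)
    trait = pd.Series(np.arange(5.0), index=strains)
    with pytest.raises(ValueError, match="at least 8"):
        linkage.lod_scan(trait, geno, marker_map)


def test_perfect_segregation_gives_minimum_p():
    geno, marker_map, strains = _toy_panel(seed=3)
    trait = pd.Series(
        linkage.code_genotypes(geno)["m4"].to_numpy() * 5.0, index=strains
    )
    p = linkage.permutation_pvalue(trait, geno, marker_map, n_perm=1000, seed=4)
    assert p == pytest.approx(1 / 1001)


def test_permutation_p_deterministic_and_warns_below_minimum():
    geno, marker_map, strains = _toy_panel(seed=5)
    rng = np.random.default_rng(6)
    trait = pd.Series(rng.normal(size=len(strains)), index=strains)
    p1 = linkage.permutation_pvalue(trait, geno, marker_map, n_perm=1000, seed=7)
    p2 = linkage.permutation_pvalue(trait, geno, marker_map, n_perm=1000, seed=7)
    assert p1 == p2
    with pytest.warns(UserWarning, match="below the 1000"):
        linkage.permutation_pvalue(trait, geno, marker_map, n_perm=100, seed=7)


def test_null_permutation_p_is_uniform():
    geno, marker_map, strains = _toy_panel(n_strains=29, n_markers=20, seed=8)
    rng = np.random.default_rng(9)
    pvals = [
        linkage.permutation_pvalue(
            pd.Series(rng.normal(size=29), index=strains),
            geno,
            marker_map,
            n_perm=1000,
            seed=int(rng.integers(2**31)),
        )
        for _ in range(60)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


@pytest.mark.parametrize(
    "peak,trait_loc,p,expected",
    [
        (("chr1", 10_000_000), ("chr1", 13_000_000), 0.001, "cis"),
        (("chr2", 10_000_000), ("chr1", 13_000_000), 0.001, "trans"),
        (("chr1", 10_000_000), ("chr1", 16_000_000), 0.001, "trans"),
        (("chr1", 10_000_000), ("chr1", 13_000_000), 0.2, "NSL"),
    ],
)
def test_cis_trans_nsl_rule(peak, trait_loc, p, expected):
    assert linkage.classify_linkage(*peak, *trait_loc, p) == expected


def test_heritability_hand_anova():
    reps = pd.DataFrame(
        {"strain": ["a", "a", "b", "b", "c", "c"], "value": [10, 12, 20, 22, 30, 32]}
    )
    assert linkage.heritability(reps) == pytest.approx(198 / 202)


def test_heritability_degenerate_and_errors():
    flat = pd.DataFrame({"strain": ["a", "a", "b", "b"], "value": [5.0] * 4})
    assert linkage.heritability(flat) == 0.0
    single = pd.DataFrame({"strain": ["a", "b"], "value": [1.0, 2.0]})
    with pytest.raises(ValueError):
        linkage.heritability(single)


def test_heritability_recovery():
    rng = np.random.default_rng(10)
    n_strains, h2 = 30, 0.6
    strain_effect = rng.normal(0, np.sqrt(h2), n_strains)
    rows = []
    for i in range(n_strains):
        for _ in range(2):
            rows.append(
                {"strain": f"s{i}", "value": strain_effect[i] + rng.normal(0, np.sqrt(1 - h2))}
            )
    est = linkage.heritability(pd.DataFrame(rows))
    assert est == pytest.approx(0.6, abs=0.15)


def test_map_trait_full_workflow_on_panel(truth, panel):
    cis = truth.loci[truth.loci["is_cis"]].iloc[0]
    reps = panel.traits[panel.traits["locus"] == cis["locus"]]
    result = linkage.map_trait(
        reps[["strain", "replicate", "value"]],
        panel.genotypes,
        panel.marker_map,
        trait_chrom=cis["chrom"],
        trait_pos=int(cis["pos"]),
        n_perm=1000,
        seed=1,
    )
    assert result.classification == "cis"
    assert result.peak_lod > 4
    assert result.p < 0.05
    assert result.h2 is not None and result.h2 > 0.5
    # cis variance is a component of heritable variance
    assert result.r2_cis <= result.h2 + 0.1
    chrom, lo, hi = result.support_interval
    assert chrom == result.peak_chrom and lo <= result.peak_pos <= hi


def test_trans_locus_maps_to_other_chromosome(truth, panel):
    trans = truth.loci[~truth.loci["is_cis"]].iloc[0]
    reps = panel.traits[panel.traits["locus"] == trans["locus"]]
    result = linkage.map_trait(
        reps[["strain", "replicate", "value"]],
        panel.genotypes,
        panel.marker_map,
        trait_chrom=trans["chrom"],
        trait_pos=int(trans["pos"]),
        n_perm=1000,
        seed=2,
    )
    assert result.classification == "trans"
    ctrl = truth.marker_map.set_index("marker").loc[trans["controlling_marker"]]
    assert result.peak_chrom == ctrl["chrom"]
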