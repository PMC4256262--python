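from fractions import Fraction
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methmap import diffmeth, simulate


# independent oracle: exact rational enumeration via the factorial formula
@lru_cache(maxsize=None)
def _pmfs(r1, r2, c1):
    N = r1 + r2
    pref = Fraction(
        factorial(r1) * factorial(r2) * factorial(c1) * factorial(N - c1),
        factorial(N),
    )
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    return kmin, [
        pref
        / (
            factorial(k)
            * factorial(r1 - k)
            * factorial(c1 - k)
            * factorial(r2 - c1 + k)
        )
        for k in range(kmin, kmax + 1)
    ]


def fisher_oracle(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    if c1 == 0 or c1 == r1 + r2:
        return 1.0
    kmin, probs = _pmfs(r1, r2, c1)
    obs = probs[a - kmin]
    return float(sum(p for p in probs if p <= obs))


@pytest.mark.parametrize(
    "table",
    [(9, 1, 2, 8), (5, 5, 5, 5), (10, 0, 0, 10), (1, 0, 0, 1), (3, 0, 2, 7)],
)
def test_fisher_matches_enumeration_oracle(table):
    assert diffmeth.fisher_exact_two_sided(*table) == pytest.approx(
        fisher_oracle(*table), abs=1e-12
    )


def test_fisher_worked_examples():
    assert diffmeth.fisher_exact_two_sided(9, 1, 2, 8) == pytest.approx(
        0.005477494641581329, abs=1e-12
    )
    assert diffmeth.fisher_exact_two_sided(5, 5, 5, 5) == 1.0


@settings(max_examples=150, deadline=None)
@given(st.tuples(*[st.integers(0, 40)] * 4))
def test_fisher_agrees_with_scipy(table):
    a, b, c, d = table
    if a + b == 0 or c + d == 0:
        return
    ours = diffmeth.fisher_exact_two_sided(a, b, c, d)
    scipy_p = stats.fisher_exact([[a, b], [c, d]])[1]
    assert ours == pytest.approx(scipy_p, rel=1e-6, abs=1e-12)


def test_fisher_pooled_counts_and_delta():
    p, dm = diffmeth.fisher_test_pooled([(5, 0), (4, 1)], [(1, 4), (1, 4)])
    assert p == pytest.approx(fisher_oracle(9, 1, 2, 8), abs=1e-12)
    assert dm == pytest.approx(90 - 20)
    with pytest.raises(ValueError, match="zero total"):
        diffmeth.fisher_test_pooled([(0, 0)], [(1, 1)])


def test_bh_step_up_worked_example():
    q = diffmeth.bh_fdr([0.005, 0.01, 0.03, 0.04])
    assert q == pytest.approx([0.02, 0.02, 0.04, 0.04])
    assert diffmeth.bh_fdr([1, 1, 1]) == pytest.approx([1, 1, 1])
    assert diffmeth.bh_fdr([0.05]) == pytest.approx([0.05])
    with pytest.raises(ValueError):
        diffmeth.bh_fdr([])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_invariant_under_input_order(pvals):
    q1 = diffmeth.bh_fdr(pvals)
    perm = np.random.default_rng(0).permutation(len(pvals))
    q2 = diffmeth.bh_fdr(np.asarray(pvals)[perm])
    assert q1[perm] == pytest.approx(q2)
    assert np.all(q1 >= np.asarray(pvals) - 1e-12)


def test_region_clustering_gap_rule():
    sites = pd.DataFrame(
        {"chrom": "c1", "pos": [1000, 1400, 2100], "delta_m": [10.0, 20.0, -5.0]}
    )
    regions = diffmeth.cluster_sites_into_regions(sites, gap=500, value_column="delta_m")
    assert len(regions) == 2
    first = regions.iloc[0]
    assert (first["start"], first["end"], first["n_cpgs"]) == (1000, 1400, 2)
    assert not first["is_singleton"] and first["direction_consistent"]
    assert regions.iloc[1]["is_singleton"]


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.integers(1, 50_000), min_size=1, max_size=60, unique=True)
)
def test_region_membership_partitions_all_sites(positions):
    sites = pd.DataFrame({"chrom": "c1", "pos": positions})
    regions = diffmeth.cluster_sites_into_regions(sites, gap=500)
    assert regions["n_cpgs"].sum() == len(positions)
    clustered = regions[~regions["is_singleton"]]["n_cpgs"].sum()
    singletons = regions["is_singleton"].sum()
    assert clustered + singletons == len(positions)


def test_dmc_recovery_on_simulated_truth(truth, data, parental_groups):
    dmc, dmr = diffmeth.call_dmcs_and_dmrs(
        data.pileups,
        parental_groups,
        conversion_rates=truth.conversion_rates,
        variants=truth.variants,
    )
    merged = dmc.merge(truth.sites, on=["chrom", "pos", "strand"])
    true_dm = merged[merged["is_dm"]]
    recall = true_dm["significant"].mean()
    assert recall > 0.8
    hits = true_dm[true_dm["significant"]]
    # delta_m is BN - SHR, so its sign must match theta_bn - theta_shr
    direction_ok = (
        np.sign(hits["delta_m"]) == np.sign(hits["theta_bn"] - hits["theta_shr"])
    ).mean()
    assert direction_ok > 0.99
    # false positives controlled on the non-differential background
    null_sites = merged[~merged["is_dm"] & ~merged["is_imprinted"]]
    assert null_sites["significant"].mean() <= 0.05


def test_null_simulation_respects_fdr():
    cfg = simulate.SimulationConfig(
        n_cpgs=500, frac_dm=0.0, n_loci=0, n_imprinted_regions=0
    )
    truth = simulate.simulate_truth(cfg, seed=51)
    data = simulate.simulate_pileups(truth, depth=30, seed=52)
    groups = {
        "BN": [f"BN_{i}" for i in range(1, 5)],
        "SHR": [f"SHR_{i}" for i in range(1, 5)],
    }
    dmc, _ = diffmeth.call_dmcs_and_dmrs(
        data.pileups, groups, conversion_rates=truth.conversion_rates,
        variants=truth.variants
    )
    assert dmc["significant"].mean() <= 0.05


def test_overlap_enrichment_worked_example():
    universe = set(range(1000))
    a = set(range(100))
    b = set(range(60, 110))
    assert len(a & b) == 40
    fold, chi2, p = diffmeth.overlap_enrichment(a, b, universe)
    assert fold == pytest.approx(8.0)
    assert chi2 == pytest.approx(286.5497, abs=0.01)
    assert p < 1e-60


def test_overlap_enrichment_degenerate_and_null():
    u = set(range(100))
    fold, _, _ = diffmeth.overlap_enrichment(set(u), set(u), u)
    assert fold == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    u = set(range(20_000))
    a = set(rng.choice(20_000, 2000, replace=False))
    b = set(rng.choice(20_000, 2000, replace=False))
    fold, _, _ = diffmeth.overlap_enrichment(a, b, u)
    assert fold == pytest.approx(1.0, abs=0.15)
    with pytest.raises(ValueError):
        diffmeth.overlap_enrichment(a, b, set())
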