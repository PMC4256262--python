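import numpy as np
import pandas as pd
import pytest

from methmap import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(n_cpgs=400)


@pytest.fixture(scope="session")
def truth(small_config):
    return simulate.simulate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def data(truth):
    return simulate.simulate_pileups(truth, depth=30, seed=12)


@pytest.fixture(scope="session")
def panel(truth):
    return simulate.simulate_ri_panel(truth, seed=13)


@pytest.fixture(scope="session")
def parental_groups(truth):
    samples = truth.samples
    return {
        "BN": list(samples[samples["role"] == "BN"]["sample_id"]),
        "SHR": list(samples[samples["role"] == "SHR"]["sample_id"]),
    }


@pytest.fixture
def tiny_variants():
    return pd.DataFrame(
        {
            "chrom": ["contig1"] * 4,
            "pos": [100, 200, 300, 400],
            "bn_allele": ["A", "C", "G", "A"],
            "shr_allele": ["G", "T", "A", "C"],
            "kind": ["snp"] * 4,
        }
    )


def pooled_counts(pileups: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    sub = pileups[pileups["sample_id"].isin(samples)]
    return sub.groupby(["chrom", "pos", "strand"])[["c_count", "t_count"]].sum()
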