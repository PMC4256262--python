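"""Stage functions chaining the library into a file-based workflow.

Each stage reads its inputs from and writes its outputs to a working
directory of TSV/FASTA files (io module schemas), so stages can be run
individually from the command line or chained end-to-end. All stages are
deterministic given the config seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, context, diffmeth, io, linkage, phasing, profiles, qtm, simulate
from .config import RunConfig


def _wd(workdir) -> Path:
    p = Path(workdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(workdir, config: RunConfig, sim_config=None) -> None:
    wd = _wd(workdir)
    sim = sim_config or simulate.SimulationConfig()
    truth = simulate.simulate_truth(sim, config.seed)
    data = simulate.simulate_pileups(truth, depth=30, seed=config.seed + 1)
    panel = simulate.simulate_ri_panel(truth, seed=config.seed + 2)

    io.write_fasta(truth.reference, wd / "reference.fa")
    truth.sites.to_csv(wd / "truth_sites.tsv", sep="\t", index=False)
    truth.samples.to_csv(wd / "samples.tsv", sep="\t", index=False)
    truth.loci.to_csv(wd / "truth_loci.tsv", sep="\t", index=False)
    io.write_tables(truth.variants, wd / "variants.tsv", "variant")
    io.write_tables(data.pileups, wd / "pileups.tsv", "pileup")
    io.write_tables(data.lambda_pileups, wd / "lambda_pileups.tsv", "pileup")
    io.write_tables(data.noncpg_pileups, wd / "noncpg_pileups.tsv", "pileup")
    io.write_tables(data.allele_pileups, wd / "allele_pileups.tsv", "phased_pileup")
    io.write_tables(panel.genotypes, wd / "genotypes.tsv", "genotype")
    io.write_tables(panel.marker_map, wd / "marker_map.tsv", "marker_map")
    io.write_tables(panel.phenotypes, wd / "phenotypes.tsv", "phenotype")
    panel.traits.to_csv(wd / "ri_traits.tsv", sep="\t", index=False)


def _load_samples(wd: Path) -> pd.DataFrame:
    return pd.read_csv(wd / "samples.tsv", sep="\t")


def _load_conversion(wd: Path) -> dict[str, float]:
    df = pd.read_csv(wd / "conversion.tsv", sep="\t")
    return dict(zip(df["sample_id"], df["r_s"]))


def stage_call(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    samples = _load_samples(wd)
    f1 = list(samples[samples["role"].str.startswith("F1")]["sample_id"])
    parental = list(samples[~samples["role"].str.startswith("F1")]["sample_id"])
    lam = io.read_tables(wd / "lambda_pileups.tsv", "pileup")
    noncpg = io.read_tables(wd / "noncpg_pileups.tsv", "pileup")
    estimates = calling.estimate_conversion_rates(lam, noncpg, f1, parental)
    conv = pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "r_lambda": e.r_lambda if e.r_lambda is not None else np.nan,
                "r_noncpg": e.r_noncpg,
                "r_s": e.r_s,
                "ok": e.ok,
            }
            for e in estimates.values()
        ]
    )
    conv.to_csv(wd / "conversion.tsv", sep="\t", index=False)
    pileups = io.read_tables(wd / "pileups.tsv", "pileup")
    meth = calling.build_methylation_table(
        pileups, {e.sample_id: e.r_s for e in estimates.values()}
    )
    io.write_tables(meth, wd / "methylation.tsv", "methylation")


def _parental_groups(samples: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "BN": list(samples[samples["role"] == "BN"]["sample_id"]),
        "SHR": list(samples[samples["role"] == "SHR"]["sample_id"]),
    }


def stage_diff(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    samples = _load_samples(wd)
    pileups = io.read_tables(wd / "pileups.tsv", "pileup")
    variants = io.read_tables(wd / "variants.tsv", "variant")
    dmc, dmr = diffmeth.call_dmcs_and_dmrs(
        pileups,
        _parental_groups(samples),
        conversion_rates=_load_conversion(wd),
        variants=variants,
        fdr=config.fdr,
        gap=config.dmr_gap,
        min_coverage=config.min_coverage,
        min_replicates=config.min_replicates,
    )
    dmc.to_csv(wd / "dmc.tsv", sep="\t", index=False)
    dmr.to_csv(wd / "dmr.tsv", sep="\t", index=False)
    if len(dmr):
        io.write_bed(dmr, wd / "dmr.bed", extra_columns=["n_cpgs", "mean_delta_m"])


def stage_phase(workdir, config: RunConfig, n_pairs: int = 400) -> None:
    """Read-level phasing demonstration: simulate F1 read pairs from the
    written reference/variants and report phasing accuracy."""
    wd = _wd(workdir)
    sim = simulate.SimulationConfig()
    truth = simulate.simulate_truth(sim, config.seed)
    pairs = simulate.simulate_f1_reads(truth, n_pairs, seed=config.seed + 3)
    variants = io.read_tables(wd / "variants.tsv", "variant")
    rows = []
    for pair in pairs:
        call = phasing.phase_read_pair(pair, variants)
        rows.append({"qname": pair.qname, "call": call, "truth": pair.true_haplotype})
    df = pd.DataFrame(rows)
    phased = df[df["call"].isin(["BN", "SHR"])]
    stats = {
        "n_pairs": len(df),
        "n_phased": len(phased),
        "n_ambiguous": int((df["call"] == "ambiguous").sum()),
        "n_unphased": int((df["call"] == "unphased").sum()),
        "accuracy": float((phased["call"] == phased["truth"]).mean())
        if len(phased)
        else np.nan,
    }
    df.to_csv(wd / "phasing_calls.tsv", sep="\t", index=False)
    with open(wd / "phasing_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)


def stage_asm_po(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    profiles_df = io.read_tables(wd / "allele_pileups.tsv", "phased_pileup")
    asm = phasing.detect_asm(
        profiles_df,
        fdr=config.fdr,
        min_coverage=config.min_coverage,
        min_replicates=config.min_replicates,
    )
    asm.to_csv(wd / "asm.tsv", sep="\t", index=False)
    po_sites, po_regions = phasing.detect_po(
        profiles_df,
        fdr=config.fdr,
        gap=config.dmr_gap,
        min_coverage=config.min_coverage,
        min_replicates=config.min_replicates,
    )
    po_sites.to_csv(wd / "po_sites.tsv", sep="\t", index=False)
    po_regions.to_csv(wd / "po_regions.tsv", sep="\t", index=False)
    if len(po_regions):
        io.write_bed(
            po_regions,
            wd / "po_regions.bed",
            extra_columns=["n_cpgs", "max_mean_difference", "hypermethylated_allele"],
        )
    # reciprocal-cross differential methylation on unphased F1 pileups
    samples = _load_samples(wd)
    pileups = io.read_tables(wd / "pileups.tsv", "pileup")
    cross_groups = {
        "BNxSHR": list(samples[samples["role"] == "F1_BNxSHR"]["sample_id"]),
        "SHRxBN": list(samples[samples["role"] == "F1_SHRxBN"]["sample_id"]),
    }
    f1_pileups = pileups[pileups["sample_id"].isin(sum(cross_groups.values(), []))]
    variants = io.read_tables(wd / "variants.tsv", "variant")
    cross_dmc, _ = phasing.detect_cross_dm(
        f1_pileups,
        cross_groups,
        conversion_rates=_load_conversion(wd),
        variants=variants,
        fdr=config.fdr,
        min_coverage=config.min_coverage,
        min_replicates=config.min_replicates,
    )
    cross_dmc.to_csv(wd / "cross_dmc.tsv", sep="\t", index=False)


def stage_methqtl(workdir, config: RunConfig, n_perm: int = 1000) -> None:
    wd = _wd(workdir)
    genotypes = io.read_tables(wd / "genotypes.tsv", "genotype")
    marker_map = io.read_tables(wd / "marker_map.tsv", "marker_map")
    traits = pd.read_csv(wd / "ri_traits.tsv", sep="\t")
    loci = pd.read_csv(wd / "truth_loci.tsv", sep="\t")
    rows = []
    for i, locus in enumerate(loci.itertuples()):
        reps = traits[traits["locus"] == locus.locus][["strain", "replicate", "value"]]
        result = linkage.map_trait(
            reps,
            genotypes,
            marker_map,
            trait_chrom=locus.chrom,
            trait_pos=int(locus.pos),
            trait_name=locus.locus,
            n_perm=n_perm,
            seed=config.seed + 10 + i,
            cis_window=config.cis_window,
        )
        rows.append(
            {
                "trait": result.trait,
                "peak_marker": result.peak_marker,
                "peak_chrom": result.peak_chrom,
                "peak_pos": result.peak_pos,
                "lod": result.peak_lod,
                "p": result.p,
                "status": result.classification,
                "h2": result.h2,
                "r2_cis": result.r2_cis,
            }
        )
    pd.DataFrame(rows).to_csv(wd / "methqtl.tsv", sep="\t", index=False)


def stage_qtm(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    phenotypes = io.read_tables(wd / "phenotypes.tsv", "phenotype")
    traits = pd.read_csv(wd / "ri_traits.tsv", sep="\t")
    summaries = qtm.summarize_phenotypes(phenotypes)
    meth_means = (
        traits.groupby(["locus", "strain"])["value"].mean().reset_index()
    )
    result = qtm.correlate_traits(meth_means, summaries)
    result.to_csv(wd / "qtm.tsv", sep="\t", index=False)


def stage_context(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    reference = io.read_fasta(wd / "reference.fa")
    variants = io.read_tables(wd / "variants.tsv", "variant")
    dmc = pd.read_csv(wd / "dmc.tsv", sep="\t")
    sites = pd.read_csv(wd / "truth_sites.tsv", sep="\t")
    dm = dmc[dmc["significant"]]
    sets = {
        "all": sites[["chrom", "pos", "strand"]],
        "tested": dmc[["chrom", "pos", "strand"]],
        "dm": dm[["chrom", "pos", "strand"]],
    }
    stats = context.nearest_snp_stats(sets, variants, max_bp=500)
    curves = pd.DataFrame(
        {name: curve for name, curve in stats["curves"].items()},
        index=np.arange(1, 501),
    )
    curves.to_csv(wd / "snp_curves.tsv", sep="\t", index_label="bp")
    # nucleotide signatures around DM CpGs, split by direction of change
    dm_fwd = dm[dm["strand"] == "+"].copy()
    dm_fwd["delta_shr"] = -dm_fwd["delta_m"]  # delta_m is BN - SHR
    for label, sub in (
        ("hyper", dm_fwd[dm_fwd["delta_shr"] > 0]),
        ("hypo", dm_fwd[dm_fwd["delta_shr"] < 0]),
    ):
        if sub.empty:
            continue
        windows = context.extract_windows(reference, sub)
        if not windows:
            continue
        pfm, ic = context.build_pfm_ic(windows)
        pfm.to_csv(wd / f"pfm_{label}.tsv", sep="\t")
        ic.rename("ic_bits").to_csv(wd / f"ic_{label}.tsv", sep="\t", index_label="position")


def stage_cluster(workdir, config: RunConfig) -> None:
    wd = _wd(workdir)
    samples = _load_samples(wd)
    pileups = io.read_tables(wd / "pileups.tsv", "pileup")
    variants = io.read_tables(wd / "variants.tsv", "variant")
    parental = samples[samples["role"].isin(["BN", "SHR"])]
    matrix = profiles.build_profile_matrix(
        pileups,
        list(parental["sample_id"]),
        variants=variants,
        target_depth=config.min_coverage,
        seed=config.seed + 20,
    )
    groups = _parental_groups(samples)
    clust = profiles.cluster_profiles(matrix, groups)
    clust["distances"].to_csv(wd / "distances.tsv", sep="\t")
    (wd / "dendrogram.nwk").write_text(clust["newick"] + "\n")
    pca = profiles.pca_profiles(matrix)
    pca["scores"].to_csv(wd / "pca_scores.tsv", sep="\t")
    pd.Series(pca["variance_pct"], name="variance_pct").to_csv(
        wd / "pca_variance.tsv", sep="\t", index_label="component"
    )


STAGES = [
    ("simulate", stage_simulate),
    ("call", stage_call),
    ("diff", stage_diff),
    ("phase", stage_phase),
    ("asm_po", stage_asm_po),
    ("methqtl", stage_methqtl),
    ("qtm", stage_qtm),
    ("context", stage_context),
    ("cluster", stage_cluster),
]


def run_pipeline(workdir, config: RunConfig) -> None:
    """Run every stage in order on the default synthetic design."""
    for _, fn in STAGES:
        fn(workdir, config)
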