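"""Synthetic bisulfite crosses with known truth.

The generator emulates the study design this package analyses: two inbred
parental strains (BN, SHR; four biological replicates each), reciprocal F1
crosses (four replicates per cross, dam named first) with allele-resolved
methylation and imprinted regions, an unmethylated lambda-phage-like
spike-in contig, and a recombinant-inbred (RI) panel of 29 strains (two
replicates each) whose methylation loci are under cis or trans marker
control, plus one phenotype linearly coupled to a methylation locus.

Two coordinate scales coexist: sequence contigs are kilobase-scale (so
reads, pileups and sequence-context windows are cheaply simulatable) while
the RI genetic map uses megabase-scale chromosome coordinates, where the
5 Mbp cis window and the ~one-marker-per-few-Mbp map density are
meaningful. Methylation loci carry explicit map positions in the truth.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reads import AlignedPair, AlignedRead

PARENTAL_ROLES = ("BN", "SHR")
F1_ROLES = ("F1_BNxSHR", "F1_SHRxBN")
CROSSES = ("BNxSHR", "SHRxBN")


@dataclass
class SimulationConfig:
    # genome / CpG layout
    n_cpgs: int = 2000  # CpG dyads (each contributes two strand-specific sites)
    n_contigs: int = 2
    cpg_spacing: int = 60  # mean bp between dyads
    lambda_n_sites: int = 300
    n_noncpg_sites: int = 1000
    noncpg_methylation: float = 0.004
    # differential methylation truth
    frac_dm: float = 0.007
    dm_effect: float = 0.4
    dm_effect_sd: float = 0.0
    frac_dm_snp_5bp: float = 0.053
    frac_flank_bias: float = 0.8  # P(AT->GC flank | methylation up in SHR)
    # background variation
    snp_rate: float = 1 / 750
    indel_rate: float = 1 / 20000
    frac_cpg_disrupting: float = 0.01
    # imprinting
    n_imprinted_regions: int = 2
    imprinted_region_size: int = 10  # dyads per region
    theta_maternal: float = 0.95
    theta_paternal: float = 0.05
    # noise model
    conversion_low: float = 0.975
    conversion_high: float = 0.995
    base_error: float = 0.002
    # design
    n_replicates: int = 4
    # genetic map / RI panel
    n_chromosomes: int = 2
    chromosome_length: int = 100_000_000
    marker_spacing: int = 2_700_000
    recombination_rate: float = 0.1
    n_ri_strains: int = 29
    ri_replicates: int = 2
    ri_depth: int = 100
    n_loci: int = 8
    n_trans_loci: int = 1
    cpgs_per_locus: int = 5
    locus_effect: float = 0.4
    locus_noise_sd: float = 0.03
    replicate_noise_sd: float = 0.02
    # phenotype model
    phenotype_rho: float = -0.75
    phenotype_locus: int = 0
    phenotype_mean: float = 100.0
    phenotype_scale: float = 10.0

    def validate(self) -> "SimulationConfig":
        n_imprinted = self.n_imprinted_regions * self.imprinted_region_size
        if n_imprinted > self.n_cpgs:
            raise ValueError("more imprinted CpGs than CpGs")
        if self.n_loci * self.cpgs_per_locus > self.n_cpgs:
            raise ValueError("more locus CpGs than CpGs")
        if not 0 <= self.frac_dm <= 1:
            raise ValueError("frac_dm must be in [0, 1]")
        if self.n_ri_strains < 4:
            raise ValueError("need at least 4 RI strains")
        return self


@dataclass
class SimulationTruth:
    config: SimulationConfig
    reference: dict[str, str]  # includes the 'lambda' spike-in contig
    sites: pd.DataFrame  # per strand-specific CpG site truth
    variants: pd.DataFrame  # io 'variant' schema
    noncpg_sites: pd.DataFrame  # chrom, pos, strand
    conversion_rates: dict[str, float]  # sample_id -> r_s
    samples: pd.DataFrame  # sample_id, role, replicate
    marker_map: pd.DataFrame  # marker, chrom, pos (genetic-map scale)
    loci: pd.DataFrame  # methylation loci mapped in the RI panel

    def dyads(self) -> pd.DataFrame:
        """One row per CpG dyad (the forward-strand site)."""
        return self.sites[self.sites["strand"] == "+"].reset_index(drop=True)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_samples(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for role in PARENTAL_ROLES + F1_ROLES:
        for rep in range(1, config.n_replicates + 1):
            rows.append({"sample_id": f"{role}_{rep}", "role": role, "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth generation


def _base_theta(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal genome-like methylation: mostly high, a low-methylation
    fraction, and some intermediate sites."""
    kind = rng.choice(3, size=n, p=[0.8, 0.1, 0.1])
    theta = np.empty(n)
    theta[kind == 0] = rng.beta(8, 1, size=(kind == 0).sum())
    theta[kind == 1] = rng.beta(1, 12, size=(kind == 1).sum())
    theta[kind == 2] = rng.uniform(0.1, 0.9, size=(kind == 2).sum())
    return theta


def simulate_truth(config: SimulationConfig, seed: int) -> SimulationTruth:
    """Deterministic ground truth for the whole study design."""
    config.validate()
    rng = _rng(seed)

    per_contig = np.full(config.n_contigs, config.n_cpgs // config.n_contigs)
    per_contig[: config.n_cpgs % config.n_contigs] += 1

    reference: dict[str, str] = {}
    dyad_rows = []
    noncpg_rows = []
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"
        n_dyads = int(per_contig[ci])
        # spacers avoid G so the only CG dinucleotides are the planted dyads
        spacing = rng.integers(
            max(10, config.cpg_spacing // 2), config.cpg_spacing * 2, size=n_dyads + 1
        )
        chars: list[str] = []
        pos = 0
        positions = []
        for i in range(n_dyads):
            gap = int(spacing[i])
            chars.extend(rng.choice(list("ACT"), p=[0.45, 0.1, 0.45], size=gap))
            pos += gap
            chars.extend("CG")
            positions.append(pos + 1)  # 1-based position of the C
            pos += 2
        chars.extend(rng.choice(list("ACT"), p=[0.45, 0.1, 0.45], size=int(spacing[-1])))
        seq = "".join(chars)
        reference[contig] = seq
        for p in positions:
            dyad_rows.append({"chrom": contig, "pos": p})
        # non-CpG cytosines (spacer Cs) for conversion-rate estimation
        c_positions = [
            i + 1
            for i, b in enumerate(seq)
            if b == "C" and (i + 1 >= len(seq) or seq[i + 1] != "G")
        ]
        noncpg_rows.extend({"chrom": contig, "pos": p, "strand": "+"} for p in c_positions)

    dyads = pd.DataFrame(dyad_rows)
    n = len(dyads)

    noncpg = pd.DataFrame(noncpg_rows)
    if len(noncpg) > config.n_noncpg_sites:
        keep = rng.choice(len(noncpg), size=config.n_noncpg_sites, replace=False)
        noncpg = noncpg.iloc[np.sort(keep)].reset_index(drop=True)

    # lambda-like spike-in contig: fully unmethylated cytosines
    lam_chars = rng.choice(list("ACGT"), p=[0.25, 0.3, 0.2, 0.25], size=4000)
    reference["lambda"] = "".join(lam_chars)
    lam_c = [i + 1 for i, b in enumerate(reference["lambda"]) if b == "C"]
    lam_c = lam_c[: config.lambda_n_sites]

    # methylation truth
    theta_bn = _base_theta(rng, n)
    theta_shr = theta_bn.copy()
    is_dm = np.zeros(n, dtype=bool)
    n_dm = int(round(config.frac_dm * n))
    min_gap = max(10, config.cpg_spacing // 2) + 2  # min bp between dyads
    spacer = -(-550 // min_gap)  # dyads guaranteeing > 500 bp separation
    imprint_span = config.n_imprinted_regions * (
        config.imprinted_region_size + spacer
    )
    locus_budget = config.n_loci * config.cpgs_per_locus
    if imprint_span + locus_budget > n:
        raise ValueError("infeasible config: imprinted regions and RI loci "
                         "exceed the CpG count")
    # reserve the tail of the dyad list for imprinted regions and RI loci
    free = np.arange(n - imprint_span - locus_budget)
    if n_dm > len(free):
        raise ValueError("infeasible config: frac_dm too high for CpG count")
    dm_idx = rng.choice(free, size=n_dm, replace=False)
    is_dm[dm_idx] = True
    effects = np.clip(
        np.abs(rng.normal(config.dm_effect, config.dm_effect_sd, size=n_dm)), 0.05, 0.9
    )
    signs = rng.choice([-1.0, 1.0], size=n_dm)
    base = rng.uniform(0.05, 0.95 - effects)
    theta_bn[dm_idx] = np.where(signs > 0, base, base + effects)
    theta_shr[dm_idx] = theta_bn[dm_idx] + signs * effects

    # imprinted regions: consecutive dyads, methylation set by parental
    # origin; regions are separated by enough baseline dyads that the
    # 500 bp clustering rule cannot merge neighbouring planted regions
    is_imprinted = np.zeros(n, dtype=bool)
    theta_m = np.full(n, np.nan)
    theta_p = np.full(n, np.nan)
    region_id = np.full(n, -1)
    start = n - imprint_span - locus_budget
    for r in range(config.n_imprinted_regions):
        idx = np.arange(start, start + config.imprinted_region_size)
        is_imprinted[idx] = True
        theta_m[idx] = config.theta_maternal
        theta_p[idx] = config.theta_paternal
        region_id[idx] = r
        start += config.imprinted_region_size + spacer

    # RI methylation loci occupy the final dyads
    locus_id = np.full(n, -1)
    start = n - locus_budget
    for li in range(config.n_loci):
        idx = np.arange(start, start + config.cpgs_per_locus)
        locus_id[idx] = li
        start += config.cpgs_per_locus

    # variants -----------------------------------------------------------
    variant_rows = []
    dyad_pos_by_contig = {
        contig: set(sub["pos"]).union(sub["pos"] + 1)
        for contig, sub in dyads.groupby("chrom")
    }
    for contig in [f"contig{ci + 1}" for ci in range(config.n_contigs)]:
        seq = reference[contig]
        forbidden = dyad_pos_by_contig.get(contig, set())
        n_bg = rng.binomial(len(seq), config.snp_rate)
        bg_pos = rng.choice(len(seq), size=n_bg, replace=False) + 1
        for p in sorted(bg_pos):
            if p in forbidden:
                continue
            ref = seq[p - 1]
            alts = [b for b in "ACT" if b != ref]
            variant_rows.append(
                {
                    "chrom": contig,
                    "pos": int(p),
                    "bn_allele": ref,
                    "shr_allele": str(rng.choice(alts)),
                    "kind": "snp",
                }
            )
        n_indel = rng.binomial(len(seq), config.indel_rate)
        for p in sorted(rng.choice(len(seq) - 4, size=n_indel, replace=False) + 1):
            ref = seq[p - 1 : p + 2]
            variant_rows.append(
                {
                    "chrom": contig,
                    "pos": int(p),
                    "bn_allele": ref,
                    "shr_allele": ref[0],
                    "kind": "indel",
                }
            )

    # planted SNPs within +/-5 bp of a fraction of DM dyads, with the
    # flanking AT<->GC bias coupled to the direction of the SHR change
    taken = {(row["chrom"], row["pos"]) for row in variant_rows}
    n_close = int(round(config.frac_dm_snp_5bp * n_dm))
    close_idx = rng.choice(dm_idx, size=n_close, replace=False) if n_close else []
    for i in close_idx:
        contig = dyads["chrom"].iloc[i]
        c_pos = int(dyads["pos"].iloc[i])
        seq = reference[contig]
        offset = int(rng.choice([-1, 1]))  # immediately flanking base
        p = c_pos - 1 if offset == -1 else c_pos + 2
        if not (1 <= p <= len(seq)) or (contig, p) in taken or p in dyad_pos_by_contig[contig]:
            continue
        up_in_shr = theta_shr[i] > theta_bn[i]
        towards_gc = rng.random() < (
            config.frac_flank_bias if up_in_shr else 1 - config.frac_flank_bias
        )
        if towards_gc:
            bn_a, shr_a = str(rng.choice(list("AT"))), "G"
        else:
            bn_a, shr_a = "G", str(rng.choice(list("AT")))
        variant_rows.append(
            {"chrom": contig, "pos": p, "bn_allele": bn_a, "shr_allele": shr_a,
             "kind": "snp"}
        )
        taken.add((contig, p))
        # keep reference (BN haplotype) consistent with the BN allele
        reference[contig] = seq[: p - 1] + bn_a + seq[p:]

    # a few CpG-disrupting SNPs (removed by the dinucleotide filter)
    n_disrupt = int(round(config.frac_cpg_disrupting * n))
    for i in rng.choice(free, size=n_disrupt, replace=False):
        contig = dyads["chrom"].iloc[i]
        p = int(dyads["pos"].iloc[i])
        if (contig, p) in taken:
            continue
        variant_rows.append(
            {"chrom": contig, "pos": p, "bn_allele": "C", "shr_allele": "T",
             "kind": "snp"}
        )
        taken.add((contig, p))

    variants = (
        pd.DataFrame(variant_rows)
        .drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )

    # genetic map and RI locus assignment (mutates theta at locus dyads,
    # so it must precede the site-table construction)
    marker_map = _build_marker_map(config)
    loci = _assign_loci(config, rng, marker_map, dyads, theta_bn, theta_shr, locus_id, is_dm)

    # strand-specific site table (two sites per dyad, shared truth)
    def site_frame(strand: str, pos_offset: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": dyads["chrom"],
                "pos": dyads["pos"] + pos_offset,
                "strand": strand,
                "dyad": np.arange(n),
                "theta_bn": theta_bn,
                "theta_shr": theta_shr,
                "is_dm": is_dm,
                "is_imprinted": is_imprinted,
                "theta_m": theta_m,
                "theta_p": theta_p,
                "imprinted_region": region_id,
                "locus": locus_id,
            }
        )

    sites = (
        pd.concat([site_frame("+", 0), site_frame("-", 1)])
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )

    # the lambda spike-in cytosines ride along in the non-CpG site table
    lambda_sites = pd.DataFrame(
        {"chrom": "lambda", "pos": lam_c, "strand": "+", "is_lambda": True}
    )
    noncpg = pd.concat(
        [noncpg.assign(is_lambda=False), lambda_sites], ignore_index=True
    )

    samples = default_samples(config)
    conversion = {
        s: float(rng.uniform(config.conversion_low, config.conversion_high))
        for s in samples["sample_id"]
    }

    return SimulationTruth(
        config=config,
        reference=reference,
        sites=sites,
        variants=variants,
        noncpg_sites=noncpg,
        conversion_rates=conversion,
        samples=samples,
        marker_map=marker_map,
        loci=loci,
    )


def _build_marker_map(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        pos = config.marker_spacing // 2
        i = 0
        while pos < config.chromosome_length:
            rows.append({"marker": f"c{c}m{i + 1}", "chrom": f"chr{c}", "pos": pos})
            pos += config.marker_spacing
            i += 1
    return pd.DataFrame(rows)


def _assign_loci(
    config: SimulationConfig,
    rng: np.random.Generator,
    marker_map: pd.DataFrame,
    dyads: pd.DataFrame,
    theta_bn: np.ndarray,
    theta_shr: np.ndarray,
    locus_id: np.ndarray,
    is_dm: np.ndarray,
) -> pd.DataFrame:
    """Place each methylation locus on the genetic map and pick its
    controlling marker: cis loci sit next to their controlling marker,
    trans loci are controlled from a different chromosome."""
    rows = []
    n_trans = min(config.n_trans_loci, config.n_loci)
    for li in range(config.n_loci):
        is_cis = li >= n_trans
        chrom = f"chr{(li % config.n_chromosomes) + 1}"
        chrom_markers = marker_map[marker_map["chrom"] == chrom].reset_index(drop=True)
        anchor = chrom_markers.iloc[int(rng.integers(1, len(chrom_markers) - 1))]
        # keep the amplicon within half a marker spacing of its anchor so
        # the anchor is the nearest marker
        half = config.marker_spacing // 2 - 1
        pos = int(anchor["pos"] + rng.integers(-half, half))
        if is_cis:
            controlling = anchor["marker"]
        else:
            other = marker_map[marker_map["chrom"] != chrom].reset_index(drop=True)
            controlling = other["marker"].iloc[int(rng.integers(0, len(other)))]
        member = np.flatnonzero(locus_id == li)
        theta_b = float(rng.uniform(0.2, 0.55))
        sign = float(rng.choice([-1.0, 1.0]))
        theta_s = float(np.clip(theta_b + sign * config.locus_effect, 0.02, 0.98))
        # amplicon CpGs are strain-differential by construction (the study
        # selected its amplicons from parental DMRs)
        theta_bn[member] = theta_b
        theta_shr[member] = theta_s
        is_dm[member] = True
        rows.append(
            {
                "locus": f"locus{li + 1}",
                "chrom": chrom,
                "pos": pos,
                "controlling_marker": controlling,
                "is_cis": is_cis,
                "theta_b": theta_b,
                "theta_s": theta_s,
                "contig": dyads["chrom"].iloc[member[0]],
                "first_cpg": int(dyads["pos"].iloc[member[0]]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count-level simulation


def _allele_theta(row, allele: str, cross: str) -> float:
    """True methylation of one parental allele in an F1 of the given
    cross (dam named first, so in BNxSHR the BN allele is maternal)."""
    if row.is_imprinted:
        maternal = (cross == "BNxSHR" and allele == "BN") or (
            cross == "SHRxBN" and allele == "SHR"
        )
        return row.theta_m if maternal else row.theta_p
    return row.theta_bn if allele == "BN" else row.theta_shr


def _draw_counts(
    rng: np.random.Generator,
    theta: np.ndarray,
    depth: np.ndarray | int,
    r_s: float,
    error: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binomial C/T calls under the conversion-failure + base-error model:
    P(C call) = theta + (1-theta)(1-r_s), perturbed symmetrically by the
    base-error rate."""
    p_c = theta + (1 - theta) * (1 - r_s)
    p_c = p_c * (1 - error) + (1 - p_c) * error
    depth = np.broadcast_to(np.asarray(depth), p_c.shape)
    c = rng.binomial(depth, p_c)
    other = rng.binomial(depth - c, error) if error > 0 else np.zeros_like(c)
    t = depth - c - other
    return c, t, other


@dataclass
class SimulatedPileups:
    pileups: pd.DataFrame  # io 'pileup' schema; parental + unphased F1 CpG sites
    allele_pileups: pd.DataFrame  # io 'phased_pileup' schema (F1 only)
    lambda_pileups: pd.DataFrame  # io 'pileup' schema, chrom == 'lambda' (F1 only)
    noncpg_pileups: pd.DataFrame  # io 'pileup' schema (all samples)


def simulate_pileups(
    truth: SimulationTruth,
    design: pd.DataFrame | None = None,
    depth: int = 30,
    seed: int = 0,
) -> SimulatedPileups:
    """Draw strand-specific pileups for every sample in the design."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed)
    config = truth.config
    design = truth.samples if design is None else design
    known_roles = set(PARENTAL_ROLES) | set(F1_ROLES)
    bad = set(design["role"]) - known_roles
    if bad:
        raise ValueError(f"unknown sample roles: {sorted(bad)}")

    sites = truth.sites
    n = len(sites)
    pileup_frames = []
    allele_frames = []
    lambda_frames = []
    noncpg_frames = []

    theta_bn = sites["theta_bn"].to_numpy()
    theta_shr = sites["theta_shr"].to_numpy()
    is_imp = sites["is_imprinted"].to_numpy()
    theta_m = sites["theta_m"].to_numpy()
    theta_p = sites["theta_p"].to_numpy()

    for sample in design.itertuples():
        r_s = truth.conversion_rates[sample.sample_id]
        if sample.role in PARENTAL_ROLES:
            theta = theta_bn if sample.role == "BN" else theta_shr
            c, t, o = _draw_counts(rng, theta, depth, r_s, config.base_error)
            pileup_frames.append(
                pd.DataFrame(
                    {
                        "chrom": sites["chrom"],
                        "pos": sites["pos"],
                        "strand": sites["strand"],
                        "sample_id": sample.sample_id,
                        "c_count": c,
                        "t_count": t,
                        "other_count": o,
                    }
                )
            )
        else:
            cross = sample.role.removeprefix("F1_")
            d_bn = rng.binomial(depth, 0.5, size=n)
            d_shr = depth - d_bn
            out = {}
            for allele, d in (("BN", d_bn), ("SHR", d_shr)):
                if allele == "BN":
                    base = np.where(
                        is_imp,
                        np.where(cross == "BNxSHR", theta_m, theta_p),
                        theta_bn,
                    )
                else:
                    base = np.where(
                        is_imp,
                        np.where(cross == "SHRxBN", theta_m, theta_p),
                        theta_shr,
                    )
                c, t, o = _draw_counts(rng, base, d, r_s, config.base_error)
                out[allele] = (c, t, o)
                allele_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": sites["chrom"],
                            "pos": sites["pos"],
                            "strand": sites["strand"],
                            "cross": cross,
                            "replicate": sample.replicate,
                            "allele": allele,
                            "c_count": c,
                            "t_count": t,
                        }
                    )
                )
            pileup_frames.append(
                pd.DataFrame(
                    {
                        "chrom": sites["chrom"],
                        "pos": sites["pos"],
                        "strand": sites["strand"],
                        "sample_id": sample.sample_id,
                        "c_count": out["BN"][0] + out["SHR"][0],
                        "t_count": out["BN"][1] + out["SHR"][1],
                        "other_count": out["BN"][2] + out["SHR"][2],
                    }
                )
            )
            # lambda spike-in: fully unmethylated, C calls = conversion failures
            lam = truth.noncpg_sites[truth.noncpg_sites["is_lambda"]]
            c, t, o = _draw_counts(
                rng, np.zeros(len(lam)), depth, r_s, config.base_error
            )
            lambda_frames.append(
                pd.DataFrame(
                    {
                        "chrom": lam["chrom"].to_numpy(),
                        "pos": lam["pos"].to_numpy(),
                        "strand": lam["strand"].to_numpy(),
                        "sample_id": sample.sample_id,
                        "c_count": c,
                        "t_count": t,
                        "other_count": o,
                    }
                )
            )
        # genomic non-CpG cytosines (all samples)
        ncp = truth.noncpg_sites[~truth.noncpg_sites["is_lambda"]]
        c, t, o = _draw_counts(
            rng,
            np.full(len(ncp), config.noncpg_methylation),
            depth,
            r_s,
            config.base_error,
        )
        noncpg_frames.append(
            pd.DataFrame(
                {
                    "chrom": ncp["chrom"].to_numpy(),
                    "pos": ncp["pos"].to_numpy(),
                    "strand": ncp["strand"].to_numpy(),
                    "sample_id": sample.sample_id,
                    "c_count": c,
                    "t_count": t,
                    "other_count": o,
                }
            )
        )

    empty_pileup = pd.DataFrame(
        columns=["chrom", "pos", "strand", "sample_id", "c_count", "t_count", "other_count"]
    )
    empty_allele = pd.DataFrame(
        columns=["chrom", "pos", "strand", "cross", "replicate", "allele", "c_count", "t_count"]
    )
    return SimulatedPileups(
        pileups=pd.concat(pileup_frames, ignore_index=True) if pileup_frames else empty_pileup,
        allele_pileups=pd.concat(allele_frames, ignore_index=True) if allele_frames else empty_allele,
        lambda_pileups=pd.concat(lambda_frames, ignore_index=True) if lambda_frames else empty_pileup,
        noncpg_pileups=pd.concat(noncpg_frames, ignore_index=True) if noncpg_frames else empty_pileup,
    )


# ---------------------------------------------------------------------------
# read-level simulation (fixtures for the phaser)


def simulate_f1_reads(
    truth: SimulationTruth,
    n_pairs: int,
    seed: int = 0,
    cross: str = "BNxSHR",
    contig: str | None = None,
    read_length: int = 75,
    fragment_length: int = 170,
    snp_cover_fractions: tuple[float, float, float] = (0.2, 0.3, 0.5),
    conversion_rate: float | None = None,
) -> list[AlignedPair]:
    """Simulate aligned F1 read pairs carrying their true haplotype.

    ``snp_cover_fractions`` gives the target fractions of pairs covering
    0, exactly 1, and >=2 SNP positions. SNP alleles in the read sequence
    match the pair's haplotype; unmethylated cytosines on the bisulfite
    converted strand are converted with the sample conversion rate.
    Indel variants are not applied to read sequences.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = _rng(seed)
    contig = contig or "contig1"
    seq = truth.reference[contig]
    r_s = (
        conversion_rate
        if conversion_rate is not None
        else float(np.mean(list(truth.conversion_rates.values())))
    )
    snps = truth.variants[
        (truth.variants["chrom"] == contig) & (truth.variants["kind"] == "snp")
    ]
    if snps.empty:
        raise ValueError(f"no SNPs on {contig}; cannot build phasing fixtures")
    snp_pos = snps["pos"].to_numpy()
    snp_alt = dict(zip(snps["pos"], snps["shr_allele"]))

    site_theta: dict[tuple[int, str], tuple[float, float]] = {}
    for row in truth.sites[truth.sites["chrom"] == contig].itertuples():
        site_theta[(row.pos, row.strand)] = (
            _allele_theta(row, "BN", cross),
            _allele_theta(row, "SHR", cross),
        )

    # bucket fragment start positions by how many SNPs the two mates cover
    max_start = len(seq) - fragment_length
    starts = np.arange(1, max_start + 1)
    counts = np.zeros(len(starts), dtype=int)
    for p in snp_pos:
        in_mate1 = (starts <= p) & (p < starts + read_length)
        in_mate2 = (starts + fragment_length - read_length <= p) & (
            p < starts + fragment_length
        )
        counts += (in_mate1 | in_mate2).astype(int)
    buckets = [starts[counts == 0], starts[counts == 1], starts[counts >= 2]]
    fracs = np.asarray(snp_cover_fractions, dtype=float)
    fracs = fracs / fracs.sum()

    pairs: list[AlignedPair] = []
    for i in range(n_pairs):
        cat = int(rng.choice(3, p=fracs))
        while len(buckets[cat]) == 0:
            cat = (cat + 1) % 3
        start = int(rng.choice(buckets[cat]))
        hap = "BN" if rng.random() < 0.5 else "SHR"
        strand = "C2T" if rng.random() < 0.5 else "G2A"
        frag = list(seq[start - 1 : start - 1 + fragment_length])
        if hap == "SHR":
            for p in snp_pos:
                if start <= p < start + fragment_length:
                    frag[p - start] = snp_alt[p]
        # bisulfite conversion on the affected strand
        if strand == "C2T":
            target, converted = "C", "T"
        else:
            target, converted = "G", "A"
        for j, b in enumerate(frag):
            if b != target:
                continue
            pos = start + j
            key = (pos, "+" if strand == "C2T" else "-")
            theta_pair = site_theta.get(key)
            if theta_pair is not None:
                theta = theta_pair[0] if hap == "BN" else theta_pair[1]
            else:
                theta = truth.config.noncpg_methylation
            methylated = rng.random() < theta
            if not methylated and rng.random() < r_s:
                frag[j] = converted
        mate1_seq = "".join(frag[:read_length])
        mate2_start = start + fragment_length - read_length
        mate2_seq = "".join(frag[fragment_length - read_length :])
        qual = [40] * read_length
        pairs.append(
            AlignedPair(
                read1=AlignedRead(contig, start, mate1_seq, list(qual)),
                read2=AlignedRead(contig, mate2_start, mate2_seq, list(qual),
                                  is_reverse=True),
                mapq=60,
                conv_strand=strand,
                qname=f"sim_{cross}_{i}",
                true_haplotype=hap,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# RI panel simulation


@dataclass
class SimulatedRIPanel:
    genotypes: pd.DataFrame  # strains x markers, values 'B'/'S'
    marker_map: pd.DataFrame
    ri_pileups: pd.DataFrame  # io 'pileup' schema; sample_id = '<strain>_r<rep>'
    traits: pd.DataFrame  # locus, strain, replicate, value (% methylation)
    phenotypes: pd.DataFrame  # io 'phenotype' schema
    strain_theta: pd.DataFrame  # truth: locus x strain true methylation


def simulate_ri_panel(
    truth: SimulationTruth,
    seed: int = 0,
    n_strains: int | None = None,
) -> SimulatedRIPanel:
    """RI strains as marker-block mosaics of the parental haplotypes with
    cis/trans methylation control and one correlated phenotype."""
    config = truth.config
    rng = _rng(seed)
    n_strains = n_strains or config.n_ri_strains
    if n_strains < 4:
        raise ValueError("need at least 4 RI strains")
    marker_map = truth.marker_map
    strains = [f"RI{i + 1:02d}" for i in range(n_strains)]

    geno = {}
    for strain in strains:
        alleles = []
        for c in range(1, config.n_chromosomes + 1):
            chrom_markers = marker_map[marker_map["chrom"] == f"chr{c}"]
            g = rng.random() < 0.5
            for _ in range(len(chrom_markers)):
                alleles.append("B" if g else "S")
                if rng.random() < config.recombination_rate:
                    g = not g
        geno[strain] = alleles
    genotypes = pd.DataFrame.from_dict(
        geno, orient="index", columns=list(marker_map["marker"])
    )

    dyads = truth.dyads()
    trait_rows = []
    pileup_rows = []
    theta_rows = []
    for locus in truth.loci.itertuples():
        marker = locus.controlling_marker
        member_sites = truth.sites[
            (truth.sites["chrom"] == locus.contig)
            & (truth.sites["pos"] >= locus.first_cpg)
        ].head(config.cpgs_per_locus * 2)
        for strain in strains:
            allele = genotypes.loc[strain, marker]
            base = locus.theta_b if allele == "B" else locus.theta_s
            theta_strain = float(
                np.clip(base + rng.normal(0, config.locus_noise_sd), 0.0, 1.0)
            )
            theta_rows.append(
                {"locus": locus.locus, "strain": strain, "theta": theta_strain,
                 "genotype": allele}
            )
            for rep in range(1, config.ri_replicates + 1):
                theta_rep = float(
                    np.clip(
                        theta_strain + rng.normal(0, config.replicate_noise_sd),
                        0.0,
                        1.0,
                    )
                )
                c = rng.binomial(config.ri_depth, theta_rep, size=len(member_sites))
                sample = f"{strain}_r{rep}"
                for (site, ci) in zip(member_sites.itertuples(), c):
                    pileup_rows.append(
                        {
                            "chrom": site.chrom,
                            "pos": site.pos,
                            "strand": site.strand,
                            "sample_id": sample,
                            "c_count": int(ci),
                            "t_count": int(config.ri_depth - ci),
                            "other_count": 0,
                        }
                    )
                trait_rows.append(
                    {
                        "locus": locus.locus,
                        "strain": strain,
                        "replicate": rep,
                        "value": 100.0 * c.mean() / config.ri_depth,
                    }
                )

    traits = pd.DataFrame(trait_rows)
    strain_theta = pd.DataFrame(theta_rows)

    # phenotype correlated with the chosen locus's strain-mean methylation
    locus_name = truth.loci["locus"].iloc[config.phenotype_locus]
    locus_means = (
        traits[traits["locus"] == locus_name]
        .groupby("strain")["value"]
        .mean()
        .reindex(strains)
    )
    z = (locus_means - locus_means.mean()) / locus_means.std(ddof=0)
    rho = config.phenotype_rho
    noise = rng.normal(0, 1, size=n_strains)
    noise = (noise - noise.mean()) / noise.std(ddof=0)
    # orthogonalise the noise against the methylation signal so the
    # realised correlation concentrates tightly around rho
    noise = noise - np.dot(noise, z) / np.dot(z, z) * z
    noise = (noise - noise.mean()) / noise.std(ddof=0)
    y = rho * z.to_numpy() + np.sqrt(1 - rho**2) * noise
    pheno_strain = config.phenotype_mean + config.phenotype_scale * y
    pheno_rows = []
    for strain, mu in zip(strains, pheno_strain):
        for rep in range(1, config.ri_replicates + 1):
            pheno_rows.append(
                {
                    "strain": strain,
                    "trait": "pheno1",
                    "replicate": rep,
                    "value": float(mu + rng.normal(0, 0.02 * config.phenotype_scale)),
                }
            )
    phenotypes = pd.DataFrame(pheno_rows)

    return SimulatedRIPanel(
        genotypes=genotypes,
        marker_map=marker_map,
        ri_pileups=pd.DataFrame(pileup_rows),
        traits=traits,
        phenotypes=phenotypes,
        strain_theta=strain_theta,
    )
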