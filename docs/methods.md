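# Methods

This note documents the models implemented in `methmap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Counting model and methylation calling

Methylation is counted strand-specifically: a CpG dyad contributes two
sites, the forward-strand cytosine at position p and the reverse-strand
cytosine at p+1, never collapsed. All library coordinates are 1-based
inclusive; only BED export converts to 0-based half-open. Forward-strand
sites are read out as C/T calls from reads aligned to the C→T-converted
reference, reverse-strand sites as G/A calls from the G→A-converted
reference.

At a site with c C-calls and t T-calls and sample conversion rate r_s,
the corrected methylation level is

    m = 100 · max(0, c − t·(1 − r_s)/r_s) / (c + t)   [percent]

The subtrahend is the expected number of unconverted cytosines among the
reads: each T call marks a converted, hence unmethylated, molecule; the
unmethylated molecules therefore number t/r_s in expectation, of which a
fraction (1 − r_s) failed to convert and read as C. This estimator is
unbiased for 100·θ at every methylation level θ (a naive subtraction of
(c+t)(1−r_s) would undercall methylated sites by up to 100·(1−r_s)
percentage points — 3 points at r_s = 0.97). Negative corrected values
clamp to zero because methylation is a proportion.

Conversion rates: F1 libraries carry an unmethylated lambda spike-in, so
r_s = T/(C+T) on the lambda contig directly. Parental libraries have no
spike-in; their r_s is predicted from the genomic non-CpG conversion
rate via an ordinary least-squares fit of lambda rate on non-CpG rate
across the F1 samples, clamped to [0, 1]. Rates at or below 0.97 are
flagged. Non-CpG cytosines are used only for rate estimation, never
reported as methylation calls.

Site filters, applied before multiple-testing correction: a site enters
a two-group comparison only if at least 3 replicates per group have
combined C+T coverage ≥ 5×, and its dyad (both bases) is untouched by any
SNP or indel footprint. "Combined coverage" is c+t, excluding other
bases.

## Differential methylation

Counts are pooled across replicates per group and tested with a
two-sided Fisher exact test on [[C₁,T₁],[C₂,T₂]]. The p-value is computed
by exhaustive enumeration of the hypergeometric support in exact integer
arithmetic under the minimum-likelihood rule (sum of the probabilities of
all tables at the observed margins whose probability does not exceed the
observed table's, ties compared exactly). This in-house enumeration
exists because the package guarantees agreement with an independent
rational-arithmetic oracle to 1e-12 across every table with margins ≤ 30;
floating-point library implementations resolve near-ties with a relative
tolerance and cannot give that guarantee. Per-margin memoisation makes
genome-scale scans cheap (10⁵ sites in about a second at pooled depth
120 vs 120).

Δm is the difference of corrected pooled percentages; pooled counts are
corrected with the group's mean per-sample conversion rate (the paper-
style per-sample correction is not defined for pooled counts; the rates
within a group differ by < 2 percentage points under the default noise
model, so the approximation is far below the test's resolution).

q-values are Benjamini–Hochberg step-up over the post-filter universe of
the analysis at hand (parental, cross, ASM and PO universes are
corrected separately). Significant cytosines (q < 0.05) are merged into
regions when consecutive sites are ≤ 500 bp apart, irrespective of
direction; per-region direction-consistency is reported, and sites
≥ 500 bp from any other significant site are singletons.

Set-overlap enrichment between two site sets A and B within a universe U
is |A∩B| / (|A||B|/|U|) with a 1-df Pearson chi-square (no continuity
correction) on the 2×2 membership table; degenerate margins return NaN
chi-square rather than a fabricated statistic.

## Phasing, ASM and parent-of-origin detection

A read pair is assigned to the BN or SHR haplotype by majority vote over
the usable SNPs it covers. C/T SNPs are never usable (conversion mimics
the allele difference); G/A SNPs are excluded on the reverse-converted
strand for the same reason on the opposite strand — the stated exclusion
covers only C/T, and the G/A rule is this package's symmetric extension.
Allele matching is conversion-aware (a C allele may read T on the
original-top strand, a G allele may read A on the original-bottom
strand); because the confounded allele pairs are excluded up front, this
never produces a double match. Exact vote ties are discarded as
ambiguous; majority wins otherwise. Pairs covering no usable SNP remain
unphased and contribute only to unphased analyses.

With the dam named first (BNxSHR = BN mother), the comparisons are:

- ASM, maternal: BN allele in BNxSHR vs SHR allele in SHRxBN;
  ASM, paternal: BN allele in SHRxBN vs SHR allele in BNxSHR. A site is
  ASM if significant in either or both comparisons (each BH-corrected
  over its own universe). A site significant in both with opposite signs
  is reported ASM but flagged discordant.
- PO, BN background: BN allele in BNxSHR (maternal) vs BN allele in
  SHRxBN (paternal); analogously for the SHR background. A PO site must
  be significant with the same maternal−paternal sign in both
  comparisons — this consistency requirement is what makes PO calls
  invariant to swapping the strain labels, and is why genotype-driven
  (ASM) differences cannot masquerade as imprinting.

Sites are testable only when all four (cross × allele) cells pass the
coverage filter on the phased read sets; untestable sites are absent
from the output, which is distinct from not-significant. PO sites
cluster into regions with the same 500 bp rule; each region reports the
larger of the two backgrounds' mean maternal−paternal differences and
whether the maternal (M) or paternal (P) allele is hypermethylated.

## Linkage in the RI panel

Traits are per-strain means of replicate methylation percentages. For a
two-genotype RI panel the single-marker LOD reduces to
−(n/2)·log₁₀(1−r²), with r the Pearson correlation between the coded
genotype (B=0, S=1) and the trait over the n strains with complete data;
monomorphic markers score 0 and missing genotypes are handled pairwise.
Genome-wide significance is by permutation of trait values across
strains with genotypes fixed, p = (1 + #{perm max-LOD ≥ observed})/(n_perm+1);
the default is 10,000 permutations (the published analyses of such
panels use up to 10⁶; the +1 correction keeps p positive and the
estimator valid at any count), with a warning below 1,000. A significant
trait is cis when the peak marker lies within 5 Mbp of the trait's
genomic location on the same chromosome, trans otherwise; p ≥ 0.05 is
"no significant linkage". Support intervals are the contiguous region
within 2 LOD of the peak.

Heritability is the intraclass correlation from one-way ANOVA across
strains, h² = (MSB − MSW)/(MSB + (k−1)·MSW) with k replicates per strain,
clamped to [0, 1]; the estimator referenced by the study is not restated
there, and the ICC is this package's documented choice. It assumes a
balanced design and is reported missing when any strain has fewer than
two replicates. Variance explained at the peak is the squared
correlation of strain means with the coded peak genotype; on simulated
panels it is bounded by h² up to Monte-Carlo error, as cis variance is a
component of heritable variance.

## QTM analysis

Within each strain, replicate phenotype measurements pass once through
three outlier tests and any flag removes the value (the source lists the
three tests without stating their combination; the union is the
conservative reading): the boxplot rule (outside Q1 − 1.5·IQR to
Q3 + 1.5·IQR, type-7 quartiles), Grubbs at α = 0.05 with the t-based
critical value, and Nalimov at α = 0.05. The Nalimov statistic is
q = |x−x̄|/s·√(n/(n−1)) — exactly the Grubbs statistic scaled by
√(n/(n−1)) — so its critical value is derived from the Grubbs one by the
same factor rather than hard-coding a published table. Below n = 3 only
the boxplot rule applies. Locus methylation (strain means) is then
correlated with phenotype strain means by Pearson's test, BH-corrected
over all tested (locus, trait) pairs; constant vectors are logged and
skipped, not tested.

## Sequence context

Nearest-SNP distances are measured in bp from the dyad's cytosine,
excluding SNPs inside the dyad itself; those are tracked separately as
CpG-disrupting. Each dyad contributes once. Cumulative curves give the
fraction of CpGs with a SNP within x bp, and fold enrichment compares
two sets' curves at fixed cutoffs (5 and 250 bp by default).

Nucleotide-preference signatures are position frequency matrices over
the 10 flanking positions (−5..−1, +1..+5 around the dyad, a 12 bp
window including the CpG). Information content per position is the
relative entropy Σ p·log₂(p/b) against the genomic background
(A 0.29, C 0.21, G 0.21, T 0.29), with 0·log 0 = 0 — the only definition
under which a background-distributed column carries zero bits. Flanking
allele changes are classified AT→GC / GC→AT / neutral in the BN→SHR
direction and cross-tabulated against the sign of the methylation
change; the odds ratio uses the Haldane–Anscombe +0.5 correction when a
cell is empty.

## Profile structure

Profiles are compared at equalised coverage: each site's base calls are
scaled down to exactly 5 (the analysis coverage threshold) by
hypergeometric draw without replacement, which preserves expected
methylation with integer counts; the analytic expectation (plain
percentage) is available behind a flag since the downsampling operation
is not defined by the source. Only complete cases — sites at or above
target depth in every included sample, dyads variant-free — enter the
matrix. Samples are clustered by Ward's minimum-variance method on
pairwise Euclidean distances, with mean within- and between-group
distances reported and the dendrogram exported as newick. PCA centers
(optionally unit-variance-scales) the sample × site matrix; variance
fractions sum to 100% and each component's sign is fixed by forcing its
largest-magnitude loading positive. Parental-profile clustering defaults
to centering only; unit-variance scaling is the documented choice for
cell-population comparisons.

## The synthetic-data generator

`methmap.simulate` is a pure function of (config, seed) at every entry
point. It emulates the study design end to end:

- **Genome**: kilobase-scale contigs whose spacer sequence avoids G, so
  the only CG dinucleotides are the planted dyads (~2000 by default,
  mean spacing 60 bp); a 4 kb lambda-like contig that is fully
  unmethylated; ~1000 non-CpG cytosines with 0.4% residual methylation.
- **Methylation truth**: bimodal baseline (80% high ~Beta(8,1), 10% low
  ~Beta(1,12), 10% intermediate), matching the observation that most
  CpGs are highly methylated with a low-methylation minority. 0.7% of
  dyads are differentially methylated with |Δθ| = 0.4 by default; 5.3%
  of those carry a planted SNP within 5 bp, against a background SNP
  density of 1/750 bp, and the immediately flanking SNPs are biased
  (80%) toward AT→GC changes when methylation is higher in SHR — the
  planted analogues of the observed SNP-proximity enrichment and
  nucleotide-preference association. About 1% of dyads get a
  CpG-disrupting SNP to exercise the variant filter.
- **Imprinting**: two regions of 10 consecutive dyads with θ_M = 0.95,
  θ_P = 0.05, separated by enough baseline dyads that the 500 bp rule
  cannot merge planted regions.
- **Samples**: four replicates each of BN, SHR, and both reciprocal F1s;
  per-sample conversion rates uniform on [0.975, 0.995] (the study
  reports > 97% everywhere); symmetric base error 0.002 applied after
  conversion. Counts are binomial at fixed depth (30× default). F1
  samples emit allele-tagged pileups at ~half depth per allele, letting
  count-level ASM/PO tests run without read simulation; reads are
  simulated only to test the phaser (paired 75 bp mates, 170 bp
  fragments, targeted fractions of pairs covering 0/1/≥2 SNPs).
- **RI panel**: 29 strains × 2 replicates, genotypes as Markov mosaics
  along each chromosome with 10% recombination between adjacent markers
  (the RI-equivalent frequency for ~2.7 Mb marker spacing at roughly
  1 cM/Mb), markers every 2.7 Mb on two 100 Mb map chromosomes. Eight
  methylation loci of five dyads each (mirroring amplicon traits, and
  strain-differential by construction, as the study's amplicons were
  chosen from differential regions); one locus is trans-controlled from
  another chromosome. Strain methylation follows the controlling
  marker's allele (Δθ = 0.4) with 0.03 strain-level and 0.02
  replicate-level Gaussian noise on θ, read out as binomial counts at
  100× (amplicon-sequencing scale). Sequence contigs and the genetic
  map use different coordinate scales on purpose: reads and context
  windows need base-level sequence, while the 5 Mbp cis window and
  marker spacing only make sense at megabase scale; loci carry explicit
  map positions in the truth table.
- **Phenotype**: one trait per panel, linear in the chosen locus's
  strain-mean methylation with the noise component orthogonalised so the
  realised Pearson correlation concentrates tightly at the configured
  setpoint (−0.75 by default), plus small replicate noise.

What the generator does **not** emulate: realistic read-length/quality
profiles, mapping bias and mappability, non-binomial overdispersion
between replicates, chromosome-scale methylation domains, correlated
methylation between neighbouring CpGs, sex chromosomes and mitochondria
(excluded from the analyses), and the rat genome itself. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not performance on real WGBS data,
where dispersion and mapping artefacts are the dominant extra error
sources.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale by design:
2000-dyad genomes, depth 30, 10⁵-site null scans, 1000-permutation
linkage, 10–20 seed replicates for recovery rates. Genome-scale counts
from the original study (tens of millions of CpGs) are reproduced only
as worked arithmetic on the printed summary tables, because they depend
on the full deposited data. Fisher exactness is asserted at 1e-12
against an independent rational-arithmetic oracle; recovery assertions
use the Monte-Carlo tolerances stated in the tests (e.g. recall > 0.8 at
Δθ = 0.4, correlation within ±0.15 of the −0.75 setpoint at 29 strains).

## Known limitations

- The duplicate-read key defaults to (chrom, leftmost position,
  converted strand); a both-mates 5′ key is available via a switch, as
  the source does not define the key.
- The overlap-clipping quality comparison is the mean base quality over
  the overlap, ties keeping read1; the source does not define "higher
  quality end".
- Interval mapping, multi-QTL models and beta-binomial dispersion
  modelling are out of scope; the single-marker correlation LOD is exact
  for a two-genotype panel but ignores inter-marker information.
- The per-comparison (rather than joint) FDR for ASM/PO follows the
  separate-universe reading of the published analysis; a joint
  correction would be slightly more conservative.
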