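# Methods

This note documents the models, parameter choices, and numerical decisions
behind `panetsig`, and what the synthetic-data tests do and do not establish
about real data.

## Allelic-fraction mixture model

All purity/copy arithmetic derives from one mixture: a locus with `n` total
copies in tumor cells, of which `m` carry the variant, sequenced in a bulk
sample of purity `p` with `c` normal copies (c = 2 on autosomes, 1 on chrX
in males), has expected variant allelic fraction

    AF = p·m / (p·n + c·(1 − p)).

Inverting for `p` gives the purity implied by a candidate copy model,
`p = c·AF / (m + c·AF − n·AF)`; a model is infeasible when the denominator
is non-positive or the solution leaves (0, 1]. The inversion is exact (the
round trip is tested to 1e-12). Observed read support is modeled binomially
at the site depth; read counts per genomic bin are Poisson. These are the
minimal noise models consistent with sequencing count data; overdispersion
(library effects, mappability) is deliberately not modeled.

For germline-heterozygous sites the tracked allele keeps one normal-cell
copy, giving the purity-adjusted tumor allelic fraction
`AF_t = (AF_obs·(p·n + 2(1−p)) − (1−p)) / (p·n)`, clipped to [0, 1].

## Copy/zygosity calling from binned counts

Input is 500 kb bins with a read count and a heterozygous-SNP count
(`germline_het_density` expected het sites per bin, genotyped at
`snp_depth`, default 60×; a site is called heterozygous when its observed
AF lies strictly inside (0.2, 0.8)).

* **Scale.** Read counts determine copy number only up to the unknown
  reads-per-diploid-copy scale. Every per-chromosome median (and the genome
  median) proposes a scale for each candidate copy state 1–4; the proposal
  whose implied per-chromosome copy numbers land nearest the integer
  lattice wins, with residuals normalized to count space so Poisson noise
  weighs all proposals equally. A uniform genome is genuinely
  scale-ambiguous (every proposal fits), so near-ties break toward the
  interpretation closest to diploid. Proposals that call a chromosome
  haploid while its het retention is intact are penalized — a single-copy
  chromosome cannot stay heterozygous.
* **Zygosity.** Under complete tumor LOH the lost allele survives only in
  normal cells (mixture AF `(1−p)/(p·n + 2(1−p))`), so the expected het
  retention drops to a floor computable from purity and SNP depth. The
  observed/expected retention ratio is compared to the midpoint between
  that floor and 1 (the paper's input data fix no threshold; the midpoint
  is the equal-margin choice), with a narrow ±5%-of-gap band called
  `unknown`. When the floor is within 0.02 of 1 — purity too low for LOH to
  be visible — the chromosome is left unknown, and purities ≤ 0.3 flag the
  whole sample ("signal may be obscured"), mirroring the exclusion of
  low-cellularity samples.
* Resolution is whole-chromosome (one segment per chromosome), which is the
  scale of the signature; no segmentation algorithm is included.

Known limitation: for haploid losses at purity ≲ 0.5 the retention floor
sits close to the heterozygous expectation and single chromosomes can be
miscalled; cohort-level motifs (modal states across samples) are robust to
this.

## Timing and model selection

Candidate copy models enumerate 1 ≤ m ≤ n ≤ `n_max` (default 8, covering
genome-doubled CN-LOH states); when the mutation's chromosome has a copy
number call, `n` is pinned to it — the relative copy state of the mutation
constrains the model. Feasible models must imply a purity within ±0.15 of
the pathologist estimate; samples under 30% cellularity are excluded.

"Simplest" is ordered by fewest copy-number events — total copy number
nearest diploid first, then smallest n, then smallest m. A strict
smallest-n rule would prefer the haploid (1, 1) interpretation of any
clonal heterozygous mutation at moderate purity, which both contradicts the
archetypal heterozygous call (AF 0.25 at purity 0.5 → (1, 2), CCF 0.5) and
posits an extra loss event; nearest-diploid parsimony resolves this and is
configurable via the model ordering key.

When a sample carries several mutations they must share one purity: the
intersection of per-mutation implied-purity intervals (± tolerance) with
the pathologist window is computed, and each mutation takes the simplest
model consistent with its midpoint; an empty intersection falls back to
per-mutation selection with a warning.

A mutation is **early** when its tumor allelic fraction m/n reaches the CCF
cutoff (default 0.85; 0.63 is the documented relaxed cutoff for chrX genes,
where X-inactivation can substitute for LOH as the second hit) *and* it
sits on an LOH or doubled chromosome. Enrichment uses the exact binomial
test with p0 = 0.5, two-sided by the minimum-likelihood convention (sum of
all outcome probabilities ≤ that of the observed count); this convention
reproduces both published reference values (35/39 → 3.4 × 10⁻⁷; 8/11 →
0.23 = 464/2048) and is cross-checked against full outcome enumeration.
Per-gene p-values are Bonferroni-adjusted over the three MAD genes.

## Monoallelic expression

AFs are folded to max(AF, 1 − AF) before testing: monoallelic expression
pushes AFs toward either 0 or 1, and without folding bidirectional skew
cancels. The gene statistic is the mean over 1000 bootstrap resamples of a
depth-weighted z:

    z = (weighted mean folded AF − background mean) / (background sd / √n_eff),

with Kish effective sample size n_eff = (Σw)²/Σw² and the background being
the depth-weighted folded-AF distribution of all SNPs in the sample. The
null replaces the gene's SNP set with 1000 equally sized random sets, each
summarized by the *same* bootstrap-mean statistic (a symmetric statistic
avoids the calibration bias the bootstrap-mean's shrinkage would otherwise
introduce); nulls are cached per SNP count within a sample. A gene is
flagged when its mean z exceeds the null's 0.95 quantile (configurable).
Genes with fewer than two SNPs are untestable by design. Empirical
calibration on 500 null genes yields a type-I error of ~0.04–0.06 and
power 1.0 at folded AF 0.95 with 3 SNPs at 50× (recomputed by the
acceptance script).

## Parental skewing

Trio AFs are discretized (hom iff AF ≥ 0.8 or ≤ 0.2); informative sites are
maternal-homozygous and child-germline-heterozygous. "Maternal origin" of
an LOH chromosome means the **retained** homolog matches the maternal
homozygous genotype — the count tested is of retained-parent labels, and a
chromosome whose informative sites stay heterozygous in the tumor is
labeled no-LOH. The cohort test is the exact binomial at p0 = 0.5.

## Pericentromeric repression

Per-gene z-scores use the MAD− group as reference — z = (mean MAD+ − mean
MAD−)/sd MAD−, not a pooled sd — requiring ≥ 2 MAD− samples; zero-variance
genes are dropped. Genes are positioned by midpoint; midpoints inside the
acen span are dropped. Arm-level ECDF percentiles use mid-ranks for ties.
Loess is a local polynomial of degree 2 with tricube weights and span as a
fraction of points (default 0.5); with span 1 and degree 1 it reduces to
ordinary least squares (tested to 1e-8). Repression curves fit arm
percentile (default; z exposed as an option) against fractional centromere
distance separately for LOH-set and het-set chromosomes and report the
difference on a shared grid; the diagnostic window is [0, 0.025]. The
label-permutation null reruns the entire z → percentile → loess chain under
shuffled MAD labels.

With a 0.5 span, a 0.025-wide repression window is necessarily smeared: the
injected −0.8 z dip appears as a ~0.2 percentile deficit at the boundary
and leaks slightly beyond it, while the curve beyond 0.1 fractional
distance stays within ±0.05. This is a property of the smoother, not of the
biology.

## Synthetic cohort

The generator emits the study conditions every stage assumes, with
ground-truth labels always attached (tests never re-derive truth from
simulation internals):

* LOH set {1, 2, 3, 6, 8, 10, 11, 16, 21, 22}, het set {4, 5, 7, 9, 12, 13,
  14, 17, 19, 20}, chromosomes 15 and 18 variable (coin flip per sample).
* Purity U(0.4, 0.9); pathologist estimate = truth + N(0, 0.03);
  genome-doubled fraction 0.5 — doubled samples keep copy-neutral LOH
  (2, 0) and gain the het set to (4, 2).
* One truncal MAD mutation per MAD+ sample (MEN1:DAXX:ATRX at 0.5:0.3:0.2,
  ATRX hemizygous in males) with m = n, sequenced at ~200× (panel scale);
  optional passengers (`passenger_rate`, default 0) are late or
  pre-doubling events — note that (1, 4)-type models are weakly
  identifiable at 200×, an intrinsic limit, not a bug.
* Binned counts: 1000 reads and 100 het sites per diploid 500 kb bin;
  genotyping depth 60×.
* Expression: 18,000 genes (genome-wide array scale) across 28 MAD+ / 47
  MAD− samples (the scale of the larger published expression cohort), unit
  residual sd, repression −0.8 z within 0.025 fractional distance on LOH
  chromosomes of MAD+ samples only.
* Trio: 150 SNPs/chromosome at 80×, tumor purity 0.9 (high-purity exome
  setting), mother homozygous at 55% of sites.
* CGH cohort: 6 studies × 40 samples (the scale of the published
  meta-analysis), true metastasis odds ratio 4.35 between high- and low-CI
  strata (the reported effect size), baseline metastasis rate 0.25,
  band-level transcription noise 2%.

The genome is a schematic hg19 autosome skeleton: real chromosome lengths
and centromere spans, uniform synthetic band subdivision. Real analyses
load a genuine `cytoBandIdeo` file.

What passing tests show: the estimators invert the models they assume, at
the study's sample sizes and noise levels. What they do not show: behavior
under overdispersed coverage, subclonal heterogeneity, segmental (below
whole-chromosome) events, FFPE artifacts, or array normalization effects —
none of which the generator emulates.

## Meta-analysis

Per-study 2×2 tables (CI stratum × outcome) are pooled with the
Mantel–Haenszel fixed-effect odds ratio and the Robins–Breslow–Greenland
variance for the 95% CI (via statsmodels); Cochran's Q uses
inverse-variance weights on per-study log ORs with the Haldane–Anscombe 0.5
correction applied only to studies with a zero cell. No random-effects
model is provided. Profile clustering is agglomerative (average linkage by
default) on 1 − state-matched Jaccard: joint absences are uninformative,
and gains only match gains, losses only losses; conflicting gain+loss
listings for one sample/band are excluded. The high-CI cutoff (aberrant
genome fraction ≥ 0.2 of profiled length) is a configurable default; flat
profiles are mutually distant in Jaccard geometry and do not form a
cluster, which is expected.

## CENP-A peaks

Peak partitioning uses any-overlap (≥ 1 bp, half-open intervals: mere
adjacency is not overlap). RPKM apportions reads and bases across band
boundaries proportionally to overlap, making it invariant to splitting a
peak. The per-band KS D is the two-sample ECDF sup-gap of peak heights
against the genome-wide distribution (positions exposed as an alternative).
"Near the centromere" means within the periCEN flanking bands — the single
non-acen band adjacent to each acen band, whose summed length is the
`flank_size` feature; whether acrocentric p-arms enter flank-size
correlations is a flag (`exclude_acrocentric_p`, default off, i.e. they are
included).

## Determinism and configuration

Every simulation accepts a seed or numpy Generator; cohorts spawn child
seeds via `SeedSequence`, so the same seed is byte-identical. The CLI fans
one global seed out to stages by stable hashing of stage names, writes a
deterministic provenance manifest (version, seed, config hash excluding the
output path), validates its JSON outputs against minimal in-package
schemas, and logs line-delimited records with wall times and counts. All
thresholds (purity tolerance 0.15, CCF cutoffs 0.85/0.63, loess span 0.5,
1000 bootstraps, CI threshold 0.2) default to the analysis values and are
overridable via YAML config or flags.
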