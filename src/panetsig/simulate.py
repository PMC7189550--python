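"""Synthetic PANET cohort generator.

Emulates the statistical structure every downstream stage consumes, so the
full pipeline is testable without any external download:

* tumor purity and per-chromosome allele-specific copy states — MAD+ samples
  carry the signature (copy-neutral LOH on the LOH chromosome set, gains on
  the heterozygous set when genome-doubled), MAD- samples are near-diploid;
* somatic mutations whose observed allelic fractions follow the purity/copy
  mixture model with binomially sampled read support;
* 500 kb binned read counts (Poisson) and het-SNP counts (binomial thinning
  by purity on LOH bins);
* expression matrices with a configurable repression of genes within a
  narrow fractional-distance window of the centromere on LOH chromosomes;
* RNA SNP allelic fractions with a subset of monoallelically expressed genes;
* child/mother/tumor trio genotypes with a ground-truth retained parent per
  LOH chromosome;
* CGH-style binary gain/loss cytoband profiles with metastasis labels drawn
  at a configurable true odds ratio.

Ground-truth labels are always emitted alongside the data; the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import CytobandMap, hg19_skeleton
from .timing import SomaticCall, SampleMeta, expected_observed_af
from .cnstate import (BinnedCounts, Segment, SegmentProfile,
                      het_call_probability, mixture_copy_ratio)

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

#: gene -> (chromosome, representative position)
MAD_GENE_LOCI = {"MEN1": ("chr11", 64570000), "DAXX": ("chr6", 33286000),
                 "ATRX": ("chrX", 76760000)}


def _chrom_set(nums: Iterable[int]) -> frozenset[str]:
    return frozenset(f"chr{i}" for i in nums)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    The chromosome sets are the recurrent signature: LOH on 1, 2, 3, 6, 8,
    10, 11, 16, 21, 22; retained heterozygosity on 4, 5, 7, 9, 12, 13, 14,
    17, 19, 20; 15 and 18 variable.  The repression window (0.025 fractional
    distance) and depth are the analysis conditions downstream stages assume.
    """

    n_samples: int = 30
    seed: int = 0
    purity_range: tuple[float, float] = (0.4, 0.9)
    mad_positive_fraction: float = 0.6
    loh_chromosomes: frozenset[str] = _chrom_set({1, 2, 3, 6, 8, 10, 11, 16, 21, 22})
    het_chromosomes: frozenset[str] = _chrom_set({4, 5, 7, 9, 12, 13, 14, 17, 19, 20})
    variable_chromosomes: frozenset[str] = _chrom_set({15, 18})
    depth_mean: float = 200.0
    genome_doubled_fraction: float = 0.5
    mae_gene_fraction: float = 0.02
    repression_depth: float = 0.8  # z-units
    repression_width: float = 0.025  # fractional-distance units
    # binned counts
    bin_size: int = 500_000
    reads_per_bin: float = 1000.0  # diploid expectation
    germline_het_density: float = 100.0  # het SNPs per full bin
    snp_depth: int = 60  # depth at which het sites are genotyped
    # optional passenger mutations (0 = MAD truncal mutation only); late or
    # pre-doubling passengers on gained chromosomes have weakly identifiable
    # copy models at panel depth, so they are off by default
    passenger_rate: float = 0.0
    background_aberration_rate: float = 0.05  # MAD- per-chromosome aberration prob
    # expression cohort (MAD+/MAD- sample counts)
    expr_mad_pos: int = 28
    expr_mad_neg: int = 47
    n_genes: int = 18000  # genome-wide array scale
    # RNA SNPs
    rna_depth: float = 50.0
    mae_folded_af: float = 0.95
    # trio
    trio_snps_per_chrom: int = 150
    trio_purity: float = 0.9
    trio_depth: int = 80
    # CGH meta-analysis cohort
    n_studies: int = 6
    study_size: int = 40
    true_or: float = 4.35
    met_rate_low: float = 0.25
    high_ci_fraction: float = 0.5

    def __post_init__(self) -> None:
        sets = (self.loh_chromosomes, self.het_chromosomes, self.variable_chromosomes)
        if sum(len(s) for s in sets) != len(frozenset().union(*sets)):
            raise ValueError("chromosome sets must be disjoint")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class MutationTruth:
    gene: str
    chrom: str
    m: int
    n: int
    timing: str  # "early" / "late"
    af_true: float


@dataclass
class SimulatedSample:
    profile: SegmentProfile
    calls: list[SomaticCall]
    meta: SampleMeta
    purity: float
    doubled: bool
    truth: list[MutationTruth]


def simulate_sample(config: SimConfig, mad_status: str, rng=None,
                    sample_id: str = "S0",
                    genome: CytobandMap | None = None) -> SimulatedSample:
    """One synthetic sample: segment profile, somatic calls, metadata, truth.

    MAD+ samples carry the LOH signature and a truncal (early) MAD mutation
    with m = n on its LOH chromosome; genome-doubled MAD+ samples gain the
    heterozygous chromosomes (4 copies, minor 2) and double the LOH
    chromosomes (4 copies, minor 0).  MAD- samples are near-diploid.
    """
    rng = _rng(rng if rng is not None else config.seed)
    genome = genome or hg19_skeleton()
    purity = float(rng.uniform(*config.purity_range))
    doubled = bool(mad_status == "positive" and rng.random() < config.genome_doubled_fraction)
    sex = "male" if rng.random() < 0.5 else "female"

    # --- copy/zygosity states per autosome
    states: dict[str, tuple[int, int]] = {}  # chrom -> (total, minor)
    for chrom in _AUTOSOMES:
        if mad_status == "positive":
            is_loh = chrom in config.loh_chromosomes or (
                chrom in config.variable_chromosomes and rng.random() < 0.5)
            if is_loh:
                states[chrom] = (2, 0)  # copy-neutral LOH, kept through doubling
            else:
                states[chrom] = (4, 2) if doubled else (2, 1)
        else:
            if rng.random() < config.background_aberration_rate:
                states[chrom] = (1, 0) if rng.random() < 0.5 else (3, 1)
            else:
                states[chrom] = (2, 1)
    segments = [Segment(c, 0, genome.chrom_length(c), t, m) for c, (t, m) in states.items()]
    profile = SegmentProfile(sample_id, segments)

    # --- somatic mutations
    calls: list[SomaticCall] = []
    truth: list[MutationTruth] = []

    def _emit(gene, chrom, pos, m, n, normal_copies, timing):
        af_true = expected_observed_af(purity, m, n, normal_copies)
        depth = max(30, int(rng.poisson(config.depth_mean)))
        af_obs = rng.binomial(depth, af_true) / depth
        calls.append(SomaticCall(sample_id, gene, chrom, pos, af_obs, depth, total_cn=n))
        truth.append(MutationTruth(gene, chrom, m, n, timing, af_true))

    if mad_status == "positive":
        gene = str(rng.choice(["MEN1", "DAXX", "ATRX"], p=[0.5, 0.3, 0.2]))
        chrom, pos = MAD_GENE_LOCI[gene]
        if chrom == "chrX" and sex == "male":
            _emit(gene, chrom, pos, 1, 1, 1.0, "early")  # hemizygous, truncal
        elif chrom == "chrX":
            _emit(gene, chrom, pos, 2, 2, 2.0, "early")  # X-LOH in females
        else:
            t, _ = states[chrom]
            _emit(gene, chrom, pos, t, t, 2.0, "early")  # pre-LOH, pre-doubling

    n_pass = int(rng.poisson(config.passenger_rate))
    for _ in range(n_pass):
        chrom = str(rng.choice(_AUTOSOMES))
        t, minor = states[chrom]
        if minor == 0:  # LOH chromosome: passengers arise after the LOH event
            m, timing = 1, "late"
        elif t == 4:  # doubled het chromosome: pre- or post-doubling
            m, timing = (2, "early") if rng.random() < 0.5 else (1, "late")
        else:
            m, timing = 1, "late"
        pos = int(rng.integers(1_000_000, genome.chrom_length(chrom) - 1_000_000))
        _emit(f"PSG{rng.integers(1, 10_000)}", chrom, pos, m, t, 2.0, timing)

    pathologist = float(np.clip(purity + rng.normal(0, 0.03), 0.05, 1.0))
    meta = SampleMeta(sample_id, pathologist, mad_status=mad_status, sex=sex)
    return SimulatedSample(profile, calls, meta, purity, doubled, truth)


def simulate_cohort(config: SimConfig, seed: int | None = None,
                    genome: CytobandMap | None = None,
                    mad_status: str | None = None) -> list[SimulatedSample]:
    """A cohort of samples; MAD status drawn at ``mad_positive_fraction``
    unless forced via ``mad_status``."""
    genome = genome or hg19_skeleton()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(config.n_samples + 1)
    head = np.random.default_rng(children[0])
    out = []
    for i in range(config.n_samples):
        status = mad_status or ("positive" if head.random() < config.mad_positive_fraction
                                else "negative")
        out.append(simulate_sample(config, status, np.random.default_rng(children[i + 1]),
                                   sample_id=f"S{i:03d}", genome=genome))
    return out


# ---------------------------------------------------------------------------
# Binned counts
# ---------------------------------------------------------------------------

def simulate_binned_counts(profile: SegmentProfile, config: SimConfig,
                           purity: float, rng=None,
                           genome: CytobandMap | None = None) -> BinnedCounts:
    """500 kb binned read counts and het-SNP counts implied by a profile.

    Reads ~ Poisson(reads_per_bin * mixture copy ratio); het-SNP counts are
    binomially thinned by the probability that a germline-het site is still
    genotyped het given the segment's minor-allele mixture fraction.
    """
    rng = _rng(rng if rng is not None else config.seed)
    genome = genome or hg19_skeleton()
    rows = []
    for seg in profile.segments:
        length = genome.chrom_length(seg.chrom)
        edges = np.arange(0, length + config.bin_size, config.bin_size)
        edges[-1] = min(edges[-1], length)
        minor = seg.minor_cn if seg.minor_cn is not None else seg.total_cn // 2
        mix = purity * seg.total_cn + 2 * (1 - purity)
        af_het = (purity * minor + (1 - purity)) / mix
        retention = het_call_probability(af_het, config.snp_depth)
        ratio = mixture_copy_ratio(purity, seg.total_cn)
        starts, ends = edges[:-1], edges[1:]
        frac = (ends - starts) / config.bin_size
        reads = rng.poisson(config.reads_per_bin * ratio * frac)
        n_sites = rng.poisson(config.germline_het_density * frac)
        hets = rng.binomial(n_sites, retention)
        rows.append(pd.DataFrame({"chrom": seg.chrom, "start": starts.astype(int),
                                  "end": ends.astype(int), "read_count": reads,
                                  "het_snp_count": hets}))
    bins = pd.concat(rows, ignore_index=True)
    return BinnedCounts(profile.sample_id, bins, config.bin_size, config.germline_het_density)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, rng=None,
                        genome: CytobandMap | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expression matrix (genes x samples), gene coordinates, MAD labels.

    Genes within ``repression_width`` fractional distance of the centromere
    on LOH chromosomes are shifted down by ``repression_depth`` z-units in
    MAD+ samples only.
    """
    rng = _rng(rng if rng is not None else config.seed)
    genome = genome or hg19_skeleton()
    arms = [a for a in genome.arms.values() if a.has_centromere]
    lengths = np.array([a.arm_length for a in arms], float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(arms), size=config.n_genes, p=probs)
    rows = []
    for g, i in enumerate(idx):
        arm = arms[i]
        pos = int(rng.integers(arm.arm_start, arm.arm_end))
        rows.append({"gene": f"G{g:05d}", "chrom": arm.chrom,
                     "start": max(0, pos - 5000), "end": pos + 5000})
    coords = pd.DataFrame(rows)

    n_pos, n_neg = config.expr_mad_pos, config.expr_mad_neg
    samples = [f"P{i:03d}" for i in range(n_pos)] + [f"N{i:03d}" for i in range(n_neg)]
    labels = pd.Series(["positive"] * n_pos + ["negative"] * n_neg, index=samples)

    mu = rng.normal(8.0, 2.0, size=config.n_genes)
    expr = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, len(samples)))
    mid = ((coords["start"] + coords["end"]) // 2).to_numpy()
    repress = np.zeros(config.n_genes, bool)
    for g in range(config.n_genes):
        chrom = coords.at[g, "chrom"]
        if chrom in config.loh_chromosomes:
            fd = genome.fractional_distance(chrom, int(mid[g]))
            repress[g] = fd < config.repression_width
    expr[np.ix_(repress, np.arange(n_pos))] -= config.repression_depth
    return (pd.DataFrame(expr, index=coords["gene"], columns=samples), coords, labels)


# ---------------------------------------------------------------------------
# RNA SNPs (monoallelic expression)
# ---------------------------------------------------------------------------

def simulate_rna_snps(config: SimConfig, rng=None, n_genes: int = 500,
                      snps_per_gene: tuple[int, int] = (2, 6)) -> pd.DataFrame:
    """Per-gene RNA SNP allelic fractions with a subset of true-MAE genes.

    Biallelic genes draw SNP AFs as Binomial(depth, 0.5)/depth; MAE genes
    draw from a folded AF of ``mae_folded_af`` (random direction per gene).
    Columns: gene, af, depth, is_mae_truth.
    """
    rng = _rng(rng if rng is not None else config.seed)
    rows = []
    for g in range(n_genes):
        is_mae = rng.random() < config.mae_gene_fraction
        k = int(rng.integers(snps_per_gene[0], snps_per_gene[1] + 1))
        for _ in range(k):
            depth = max(10, int(rng.poisson(config.rna_depth)))
            if is_mae:
                p = config.mae_folded_af if rng.random() < 0.5 else 1 - config.mae_folded_af
            else:
                p = 0.5
            af = rng.binomial(depth, p) / depth
            rows.append({"gene": f"G{g:05d}", "af": af, "depth": depth,
                         "is_mae_truth": is_mae})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trio genotypes (parental skewing)
# ---------------------------------------------------------------------------

def simulate_trio(config: SimConfig, rng=None
                  ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Child-germline / maternal / tumor SNP AFs plus retained-parent truth.

    On each LOH chromosome one parental homolog is retained (coin flip);
    informative SNPs (maternal homozygous, child heterozygous) then show the
    tumor homozygous for the maternal allele iff the maternal homolog was
    retained.  Non-LOH chromosomes stay heterozygous in the tumor.
    """
    rng = _rng(rng if rng is not None else config.seed)
    p = config.trio_purity
    d = config.trio_depth
    truth: dict[str, str] = {}
    rows = []
    for chrom in _AUTOSOMES:
        is_loh = chrom in config.loh_chromosomes or (
            chrom in config.variable_chromosomes and rng.random() < 0.5)
        retained = None
        if is_loh:
            retained = "maternal" if rng.random() < 0.5 else "paternal"
            truth[chrom] = retained
        for i in range(config.trio_snps_per_chrom):
            maternal_hom = rng.random() < 0.55
            if maternal_hom:
                mat_alt = rng.random() < 0.5  # hom-alt vs hom-ref mother
                af_mat_true = 0.98 if mat_alt else 0.02
                # child het: maternal-derived allele from the mother, paternal opposite
                child_mat_allele_alt = mat_alt
            else:
                af_mat_true = 0.5
                child_mat_allele_alt = rng.random() < 0.5
            if is_loh:
                if retained == "maternal":
                    alt_t = 2 if child_mat_allele_alt else 0
                else:
                    alt_t = 0 if child_mat_allele_alt else 2
                af_tum_true = (p * alt_t / 2 * 2 + (1 - p) * 1) / (p * 2 + 2 * (1 - p))
            else:
                af_tum_true = 0.5
            rows.append({
                "chrom": chrom, "pos": 1_000_000 + i * 10_000,
                "af_child_germline": rng.binomial(d, 0.5) / d,
                "af_maternal": rng.binomial(d, af_mat_true) / d,
                "af_tumor": rng.binomial(d, af_tum_true) / d,
            })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# CGH cohort (meta-analysis)
# ---------------------------------------------------------------------------

def simulate_cgh_cohort(config: SimConfig, rng=None,
                        genome: CytobandMap | None = None
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Multi-study CGH-style binary gain/loss profiles with metastasis labels.

    High-CI samples carry signature-like whole-chromosome aberrations (losses
    on the LOH set, gains on the heterozygous set); low-CI samples are mostly
    flat.  Metastasis is drawn at a true odds ratio of ``true_or`` between
    the strata.  Returns ({study_id: samples x cytoband status matrix},
    labels table with ci_stratum and metastasis columns).
    """
    rng = _rng(rng if rng is not None else config.seed)
    genome = genome or hg19_skeleton()
    bands = [(c, b.name) for c in genome.chromosomes for b in genome.bands[c]
             if b.stain != "acen"]
    cols = [f"{c}:{n}" for c, n in bands]
    odds_low = config.met_rate_low / (1 - config.met_rate_low)
    odds_high = odds_low * config.true_or
    met_rate_high = odds_high / (1 + odds_high)

    profiles: dict[str, pd.DataFrame] = {}
    labels = []
    for s in range(config.n_studies):
        study = f"study{s + 1}"
        mat = np.zeros((config.study_size, len(bands)), dtype=int)
        for i in range(config.study_size):
            high = rng.random() < config.high_ci_fraction
            chrom_status: dict[str, int] = {}
            for chrom in _AUTOSOMES:
                if high and rng.random() < 0.5:
                    chrom_status[chrom] = -1 if chrom in config.loh_chromosomes else 1
                elif not high and rng.random() < 0.05:
                    chrom_status[chrom] = int(rng.choice([-1, 1]))
            for j, (chrom, _) in enumerate(bands):
                st = chrom_status.get(chrom, 0)
                if rng.random() < 0.02:  # band-level transcription noise
                    st = int(rng.choice([-1, 0, 1]))
                mat[i, j] = st
            met_rate = met_rate_high if high else config.met_rate_low
            labels.append({"study": study, "sample": f"{study}_s{i:03d}",
                           "ci_stratum": "high-CI" if high else "low-CI",
                           "metastasis": bool(rng.random() < met_rate)})
        profiles[study] = pd.DataFrame(
            mat, index=[f"{study}_s{i:03d}" for i in range(config.study_size)],
            columns=cols)
    return profiles, pd.DataFrame(labels)


def cgh_study_tables(labels: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample labels to per-study 2x2 tables (a, b, c, d).

    a = high-CI & metastatic, b = high-CI & non-metastatic,
    c = low-CI & metastatic, d = low-CI & non-metastatic.
    """
    rows = []
    for study, sub in labels.groupby("study", sort=False):
        hi = sub["ci_stratum"] == "high-CI"
        met = sub["metastasis"].astype(bool)
        rows.append({"study": study,
                     "a": int((hi & met).sum()), "b": int((hi & ~met).sum()),
                     "c": int((~hi & met).sum()), "d": int((~hi & ~met).sum())})
    return pd.DataFrame(rows)
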