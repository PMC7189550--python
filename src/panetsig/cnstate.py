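"""Per-chromosome copy/zygosity calling, cohort motifs, concordance, CI strata.

Pseudo allele-specific copy-number profiles are inferred from fixed-size
(500 kb) bins carrying a read count and a heterozygous-SNP count.  The read
count carries the total copy state through the purity mixture ratio
``(p*n_t + 2*(1-p)) / 2``; the het-SNP count carries zygosity: under complete
tumor LOH only normal-cell DNA keeps a site heterozygous, so the expected
het retention drops to a purity- and depth-dependent floor, and a chromosome
whose retention ratio falls below the midpoint between that floor and 1 is
called LOH.

Cohort-level summaries: modal-state "motifs" per chromosome, pairwise
co-occurrence/antagonism of aberrations (phi coefficient), cytoband-level
Jaccard concordance between profiles, karyotype group classification
(G1 pervasive loss / G2 near-diploid / G3 pervasive gain / G4 mixed
CN-LOH + gains), and a chromosomal-instability stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CytobandMap, normalize_chrom

LOH, HET, UNKNOWN = "LOH", "HET", "unknown"

#: AF discretization bounds: a site is called heterozygous when its observed
#: allelic fraction lies strictly between these (hom otherwise)
HET_AF_LOW, HET_AF_HIGH = 0.2, 0.8


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int | None = None
    zygosity: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.minor_cn is not None:
            if self.minor_cn > self.total_cn:
                raise ValueError("minor_cn must be <= total_cn")
            # LOH <=> minor allele fully lost
            zyg = LOH if self.minor_cn == 0 else HET
            object.__setattr__(self, "zygosity", zyg)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """Per-sample allele-specific copy-number / zygosity segments."""

    sample_id: str
    segments: list[Segment]
    warnings: list[str] = field(default_factory=list)

    @property
    def ploidy(self) -> int:
        """Modal total copy number, weighted by segment length."""
        weight: dict[int, int] = {}
        for s in self.segments:
            weight[s.total_cn] = weight.get(s.total_cn, 0) + s.length
        return max(sorted(weight), key=lambda cn: weight[cn])

    def chromosome_state(self, chrom: str) -> Segment | None:
        """Longest segment on a chromosome (whole-chromosome resolution)."""
        segs = [s for s in self.segments if s.chrom == normalize_chrom(chrom)]
        return max(segs, key=lambda s: s.length) if segs else None


@dataclass
class BinnedCounts:
    """Fixed-size genome bins with read and heterozygous-SNP counts."""

    sample_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, read_count, het_snp_count
    bin_size: int = 500_000
    germline_het_density: float = 100.0  # expected het SNPs per full bin


def het_call_probability(af: float, depth: int) -> float:
    """Probability a site with true allelic fraction ``af`` is called het.

    Het call = observed AF strictly inside (0.2, 0.8) with binomially
    sampled read support at the given depth.
    """
    k_low = int(np.floor(HET_AF_LOW * depth))  # af <= 0.2 => hom
    k_high = int(np.ceil(HET_AF_HIGH * depth))  # af >= 0.8 => hom
    return float(stats.binom.cdf(k_high - 1, depth, af) - stats.binom.cdf(k_low, depth, af))


def loh_het_retention(purity: float, total_cn: int, snp_depth: int) -> float:
    """Expected het retention under complete tumor LOH at this copy state.

    The lost allele survives only in normal cells: its mixture AF is
    ``(1-p) / (p*n_t + 2*(1-p))`` and retention is the het-call probability
    at that AF.
    """
    af_minor = (1 - purity) / (purity * total_cn + 2 * (1 - purity))
    return het_call_probability(af_minor, snp_depth)


def mixture_copy_ratio(purity: float, total_cn: float) -> float:
    """Read-depth ratio of a tumor segment relative to diploid."""
    return (purity * total_cn + 2 * (1 - purity)) / 2.0


def purity_adjusted_af(af_obs: float, purity: float, total_cn: int) -> float:
    """Allelic fraction within the tumor compartment at a germline-het site.

    Inverts the mixture ``af_obs = (p*k + (1-p)) / (p*n + 2(1-p))`` (one
    normal-cell copy of the tracked allele), clipped to [0, 1].
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if total_cn == 0:
        raise ValueError("total_cn must be nonzero")
    mix = purity * total_cn + 2 * (1 - purity)
    af_t = (af_obs * mix - (1 - purity)) / (purity * total_cn)
    return float(np.clip(af_t, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Chromosome state calling
# ---------------------------------------------------------------------------

def _estimate_diploid_reads(per_chrom_medians: np.ndarray, purity: float,
                            genome_median: float,
                            retention: np.ndarray | None = None,
                            max_state: int = 4) -> float:
    """Reads-per-bin scale of a diploid segment.

    Every per-chromosome median (and the genome median) proposes a diploid
    scale for each candidate copy state; the proposal whose implied
    chromosome copy numbers land closest to the integer lattice wins.  A
    uniform genome is scale-ambiguous (all proposals fit the lattice), so
    near-ties break toward the interpretation closest to diploid.  Proposals
    that call a chromosome haploid while its het retention is intact are
    penalized: a single-copy chromosome cannot stay heterozygous.
    """
    anchors = np.unique(np.append(per_chrom_medians, genome_median))
    proposals = sorted({float(a / mixture_copy_ratio(purity, n))
                        for a in anchors for n in range(1, max_state + 1)})
    best, best_key = None, None
    for lam in proposals:
        implied = (2 * per_chrom_medians / lam - 2 * (1 - purity)) / purity
        rounded = np.round(implied)
        if rounded.max() > max_state + 2 or rounded.min() < 0:
            continue
        # residual in relative count space, so noise weighs every proposal
        # equally and only genuine lattice misfit separates them
        ratios = np.maximum(mixture_copy_ratio(purity, np.maximum(rounded, 1)), 1e-9)
        cost = float(np.sum(np.abs(implied - rounded) * purity / (2 * ratios)))
        if retention is not None:
            cost += 0.5 * int(np.sum((rounded <= 1) & (retention > 0.95)))
        ploidy_dev = float(np.abs(rounded - 2).mean())
        key = (round(cost, 3), ploidy_dev, lam)
        if best_key is None or key < best_key:
            best, best_key = lam, key
    return best


def call_chromosome_states(binned: BinnedCounts, purity: float,
                           snp_depth: int = 60,
                           diploid_reads: float | None = None,
                           max_state: int = 6) -> SegmentProfile:
    """Call per-chromosome total copy number and zygosity from binned counts.

    Copy state: median normalized read count per chromosome, converted to a
    purity-adjusted copy number and rounded.  Zygosity: het-SNP retention
    ratio r = observed / expected; LOH when r falls below the midpoint
    between the complete-LOH retention floor and 1, HET when above, with a
    narrow unknown band around the midpoint.
    """
    if binned.germline_het_density <= 0:
        raise ValueError("germline_het_density must be positive")
    warnings: list[str] = []
    if purity <= 0.3:
        warnings.append("purity <= 0.3: signal may be obscured")

    df = binned.bins
    chroms = list(dict.fromkeys(df["chrom"]))
    med = df.groupby("chrom", sort=False)["read_count"].median()
    frac = (df["end"] - df["start"]) / binned.bin_size
    expected_hets = binned.germline_het_density * frac.groupby(df["chrom"], sort=False).sum()
    retention_ratio = (df.groupby("chrom", sort=False)["het_snp_count"].sum()
                       / expected_hets).clip(upper=1.0)
    if diploid_reads is None:
        diploid_reads = _estimate_diploid_reads(
            med.to_numpy(float), purity, float(df["read_count"].median()),
            retention_ratio.reindex(med.index).to_numpy(float))

    segments: list[Segment] = []
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        # total copy number from read depth
        implied = (2 * med[chrom] / diploid_reads - 2 * (1 - purity)) / purity
        total_cn = int(np.clip(np.round(implied), 0, max_state))
        total_cn = max(total_cn, 1)
        # zygosity from het retention
        frac_full = (sub["end"] - sub["start"]).to_numpy(float) / binned.bin_size
        expected = binned.germline_het_density * frac_full.sum()
        observed = float(sub["het_snp_count"].sum())
        r = observed / expected
        r_floor = loh_het_retention(purity, total_cn, snp_depth)
        midpoint = 0.5 * (r_floor + 1.0)
        band = 0.05 * (1.0 - r_floor)
        if 1.0 - r_floor < 0.02:
            zyg = UNKNOWN  # purity too low to separate LOH from het
        elif r < midpoint - band:
            zyg = LOH
        elif r > midpoint + band:
            zyg = HET
        else:
            zyg = UNKNOWN
        if zyg == LOH:
            minor = 0
        elif zyg == HET and total_cn >= 2:
            minor = total_cn // 2  # balanced assumption
        else:
            minor = None
        seg = Segment(chrom, int(sub["start"].min()), int(sub["end"].max()),
                      total_cn, minor_cn=minor,
                      zygosity=zyg if minor is None else UNKNOWN)
        segments.append(seg)
    return SegmentProfile(binned.sample_id, segments, warnings)


# ---------------------------------------------------------------------------
# Cohort motifs and co-occurrence
# ---------------------------------------------------------------------------

def copy_state_label(total_cn: int, baseline: int = 2) -> str:
    if total_cn < baseline:
        return "loss"
    if total_cn > baseline:
        return "gain"
    return "neutral"


@dataclass
class CohortMotif:
    """Per-chromosome modal zygosity / copy states with frequencies."""

    table: pd.DataFrame  # chrom, modal_zygosity, zygosity_freq, modal_copy, copy_freq, multimodal flags

    def recurrent(self, state: str, min_freq: float = 0.5) -> list[str]:
        t = self.table
        return list(t.loc[(t["modal_zygosity"] == state) & (t["zygosity_freq"] >= min_freq), "chrom"])


def _modal(counts: dict[str, int]) -> tuple[str, float, bool]:
    total = sum(counts.values())
    if total == 0:
        return UNKNOWN, 0.0, False
    top = max(counts.values())
    modes = sorted(k for k, v in counts.items() if v == top)
    return "/".join(modes), top / total, len(modes) > 1


def cohort_motif(profiles: list[SegmentProfile]) -> CohortMotif:
    """Most recurrent zygosity and copy state per chromosome across samples.

    Ties are reported as multi-modal ("A/B") rather than silently broken.
    """
    chroms: list[str] = []
    for p in profiles:
        for s in p.segments:
            if s.chrom not in chroms:
                chroms.append(s.chrom)
    rows = []
    for chrom in chroms:
        zyg_counts: dict[str, int] = {}
        cn_counts: dict[str, int] = {}
        for p in profiles:
            s = p.chromosome_state(chrom)
            if s is None:
                continue
            zyg_counts[s.zygosity] = zyg_counts.get(s.zygosity, 0) + 1
            lbl = copy_state_label(s.total_cn)
            cn_counts[lbl] = cn_counts.get(lbl, 0) + 1
        mz, fz, tz = _modal(zyg_counts)
        mc, fc, tc = _modal(cn_counts)
        rows.append({"chrom": chrom, "modal_zygosity": mz, "zygosity_freq": fz,
                     "zygosity_multimodal": tz, "modal_copy": mc, "copy_freq": fc,
                     "copy_multimodal": tc})
    return CohortMotif(pd.DataFrame(rows))


def _phi(a: np.ndarray, b: np.ndarray) -> float:
    """Phi coefficient between two binary vectors (0/0 contingency -> nan)."""
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def aberration_matrix(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Binary samples x (chrom, aberration) indicator matrix.

    Aberrations tracked per chromosome: LOH, copy loss, copy gain.
    """
    records = {}
    for p in profiles:
        rec = {}
        for s in p.segments:
            if s.zygosity == LOH:
                rec[f"{s.chrom}:LOH"] = 1
            lbl = copy_state_label(s.total_cn)
            if lbl != "neutral":
                rec[f"{s.chrom}:{lbl}"] = 1
        records[p.sample_id] = rec
    return pd.DataFrame.from_dict(records, orient="index").fillna(0).astype(bool)


def signature_cooccurrence(profiles: list[SegmentProfile], tau: float = 0.5,
                           min_support: int = 3,
                           method: str = "phi") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise association between chromosome-level aberrations.

    Returns (association matrix, flags).  Flags label each aberration pair
    synchronous (assoc >= +tau) or antagonistic (assoc <= -tau); support
    counts (samples carrying each aberration) are included.  ``method`` is
    "phi" (default) or "odds_ratio" (log odds ratio with Haldane correction).
    """
    mat = aberration_matrix(profiles)
    keep = [c for c in mat.columns if mat[c].sum() >= min_support]
    mat = mat[keep]
    cols = list(mat.columns)
    k = len(cols)
    assoc = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            a, b = mat[cols[i]].to_numpy(), mat[cols[j]].to_numpy()
            if method == "phi":
                assoc[i, j] = _phi(a, b)
            else:
                n11 = np.sum(a & b) + 0.5
                n10 = np.sum(a & ~b) + 0.5
                n01 = np.sum(~a & b) + 0.5
                n00 = np.sum(~a & ~b) + 0.5
                assoc[i, j] = np.log((n11 * n00) / (n10 * n01))
    amat = pd.DataFrame(assoc, index=cols, columns=cols)
    flags = []
    for i in range(k):
        for j in range(i + 1, k):
            v = assoc[i, j]
            if np.isnan(v):
                continue
            label = "synchronous" if v >= tau else "antagonistic" if v <= -tau else "independent"
            flags.append({"a": cols[i], "b": cols[j], "association": v, "flag": label,
                          "support_a": int(mat[cols[i]].sum()),
                          "support_b": int(mat[cols[j]].sum())})
    return amat, pd.DataFrame(flags)


# ---------------------------------------------------------------------------
# Concordance, karyotype groups, CI strata
# ---------------------------------------------------------------------------

def profile_band_status(profile: SegmentProfile, genome: CytobandMap) -> pd.Series:
    """Cytoband-level status vector in {loss, neutral, gain} (majority overlap)."""
    status = {}
    for chrom in genome.chromosomes:
        for band in genome.bands[chrom]:
            cover: dict[str, int] = {}
            for s in profile.segments:
                if s.chrom != chrom or s.end <= band.start or s.start >= band.end:
                    continue
                ov = min(s.end, band.end) - max(s.start, band.start)
                lbl = copy_state_label(s.total_cn)
                cover[lbl] = cover.get(lbl, 0) + ov
            lbl = max(cover, key=cover.get) if cover else "neutral"
            status[(chrom, band.name)] = lbl
    return pd.Series(status)


def jaccard_index(a: pd.Series, b: pd.Series) -> float:
    """State-matched Jaccard over aberrant cytobands; joint absences ignored.

    Intersection counts bands aberrant in both with the same direction
    (loss-with-loss, gain-with-gain); union counts bands aberrant in either.
    Both all-neutral -> 1.0 (vacuous agreement).
    """
    a, b = a.align(b, fill_value="neutral")
    ab_a = a != "neutral"
    ab_b = b != "neutral"
    union = int((ab_a | ab_b).sum())
    if union == 0:
        return 1.0
    inter = int((ab_a & ab_b & (a == b)).sum())
    return inter / union


def jaccard_concordance(profile_a: SegmentProfile, profile_b: SegmentProfile,
                        genome: CytobandMap) -> float:
    """Jaccard concordance of two profiles on cytoband-level status vectors."""
    return jaccard_index(profile_band_status(profile_a, genome),
                         profile_band_status(profile_b, genome))


def genome_state_fractions(profile: SegmentProfile) -> dict[str, float]:
    """Length fractions of the profiled genome in loss / CN-LOH / neutral-het / gain."""
    total = sum(s.length for s in profile.segments)
    frac = {"loss": 0.0, "cnloh": 0.0, "neutral_het": 0.0, "gain": 0.0, "unknown": 0.0}
    for s in profile.segments:
        lbl = copy_state_label(s.total_cn)
        if lbl == "loss":
            key = "loss"
        elif lbl == "gain":
            key = "gain"
        elif s.zygosity == LOH:
            key = "cnloh"
        elif s.zygosity == HET:
            key = "neutral_het"
        else:
            key = "unknown"
        frac[key] += s.length / total
    return frac


def classify_scarpa_group(profile: SegmentProfile) -> str:
    """Karyotype group: G1 pervasive loss, G2 near-diploid, G3 pervasive gain,
    G4 mixed CN-LOH and gains.

    Rules on genome-length fractions: G1 when loss > 50%; G3 when gains reach
    ~100% (>= 90%); G4 when CN-LOH is substantial (>= 20%), with or without
    accompanying gains; G2 otherwise (near-diploid, little LOH or loss).
    """
    f = genome_state_fractions(profile)
    if f["loss"] > 0.5:
        return "G1"
    if f["gain"] >= 0.9:
        return "G3"
    if f["cnloh"] >= 0.2:
        return "G4"
    return "G2"


def aberrant_genome_fraction(profile: SegmentProfile) -> float:
    f = genome_state_fractions(profile)
    return f["loss"] + f["gain"] + f["cnloh"]


def ci_stratum(profile: SegmentProfile, threshold: float = 0.2) -> str:
    """Chromosomal-instability stratum: high-CI iff aberrant fraction >= threshold."""
    return "high-CI" if aberrant_genome_fraction(profile) >= threshold else "low-CI"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append({"sample_id": p.sample_id, "chrom": s.chrom, "start": s.start,
                         "end": s.end, "total_cn": s.total_cn,
                         "minor_cn": s.minor_cn if s.minor_cn is not None else "",
                         "zygosity": s.zygosity})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[SegmentProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"minor_cn": "object"})
    profiles = []
    for sid, sub in df.groupby("sample_id", sort=False):
        segs = []
        for _, r in sub.iterrows():
            minor = r.get("minor_cn")
            minor = None if pd.isna(minor) or minor == "" else int(float(minor))
            segs.append(Segment(normalize_chrom(r["chrom"]), int(r["start"]), int(r["end"]),
                                int(r["total_cn"]), minor))
        profiles.append(SegmentProfile(str(sid), segs))
    return profiles


def write_binned_counts(binned: BinnedCounts, path: str | Path) -> None:
    binned.bins.to_csv(path, sep="\t", index=False)


def read_binned_counts(path: str | Path, sample_id: str, bin_size: int = 500_000,
                       germline_het_density: float = 100.0) -> BinnedCounts:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "read_count", "het_snp_count"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return BinnedCounts(sample_id, df, bin_size, germline_het_density)
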