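"""Monoallelic-expression (MAE) bootstrap test and trio parental-skewing test.

MAE test
--------
Per gene with >= 2 RNA SNPs, allelic fractions are folded to max(af, 1-af)
(monoallelic expression pushes AFs toward 0 or 1; folding makes the two
directions additive instead of cancelling) and a depth-weighted z-statistic
compares the gene's folded AFs to the sample-wide folded-AF distribution:

    z = (weighted mean - background mean) / (background sd / sqrt(n_eff))

with n_eff = (sum w)^2 / sum w^2 (Kish effective sample size) and weights
w = supporting read depth.  The gene statistic is the average z over 1000
bootstrap resamples of its SNPs; the null distribution replaces the gene's
SNP set with equally sized random SNP sets from the sample, summarized by
the same bootstrap-average statistic.  A gene is flagged MAE when its mean z
exceeds the null's upper quantile (default 0.95).

Parental skewing
----------------
Trio SNP AFs are discretized (hom iff AF >= 0.8 or <= 0.2, het otherwise).
Informative sites are maternal-homozygous and child-germline-heterozygous;
per LOH chromosome the fractions of tumor-homozygous-matching-maternal
("maternal"), tumor-homozygous-non-matching ("paternal"), and tumor-het SNPs
are reported, the chromosome is labeled by majority class (a het majority
means no LOH is visible), and a cohort-level exact binomial test compares
maternal vs paternal chromosome counts against p0 = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timing import binomial_enrichment

HOM_LOW, HOM_HIGH = 0.2, 0.8  # AF <= 0.2 or >= 0.8 is homozygous


def fold_af(af: np.ndarray) -> np.ndarray:
    return np.maximum(af, 1.0 - af)


def weighted_background(all_af: np.ndarray, all_depth: np.ndarray) -> tuple[float, float]:
    """Depth-weighted mean and sd of the sample-wide folded AF distribution."""
    x = fold_af(np.asarray(all_af, float))
    w = np.asarray(all_depth, float)
    mean = float(np.average(x, weights=w))
    var = float(np.average((x - mean) ** 2, weights=w))
    return mean, float(np.sqrt(var))


def _bootstrap_mean_z(af: np.ndarray, depth: np.ndarray, bg_mean: float,
                      bg_sd: float, n_boot: int, rng: np.random.Generator) -> float:
    """Average depth-weighted z over bootstrap resamples of one SNP set."""
    x = fold_af(np.asarray(af, float))
    w = np.asarray(depth, float)
    k = len(x)
    idx = rng.integers(0, k, size=(n_boot, k))
    xb, wb = x[idx], w[idx]
    wsum = wb.sum(axis=1)
    wm = (wb * xb).sum(axis=1) / wsum
    n_eff = wsum**2 / (wb**2).sum(axis=1)
    z = (wm - bg_mean) / (bg_sd / np.sqrt(n_eff))
    return float(z.mean())


def null_mean_z(k: int, all_af: np.ndarray, all_depth: np.ndarray,
                n_null: int = 1000, n_boot: int = 1000,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distribution of the bootstrap-mean z for random k-SNP sets."""
    rng = rng or np.random.default_rng(0)
    x = fold_af(np.asarray(all_af, float))
    w = np.asarray(all_depth, float)
    bg_mean, bg_sd = weighted_background(all_af, all_depth)
    pool = len(x)
    sets = rng.integers(0, pool, size=(n_null, k))
    # nested bootstrap, vectorized: null set i, bootstrap b, position j
    # maps to pool index sets[i, boot[i, b, j]]
    boot = rng.integers(0, k, size=(n_null, n_boot, k))
    gathered = sets[np.arange(n_null)[:, None, None], boot]
    xb = x[gathered]
    wb = w[gathered]
    wsum = wb.sum(axis=2)
    wm = (wb * xb).sum(axis=2) / wsum
    n_eff = wsum**2 / (wb**2).sum(axis=2)
    z = (wm - bg_mean) / (bg_sd / np.sqrt(n_eff))
    return z.mean(axis=1)


@dataclass
class MaeResult:
    gene: str
    n_snps: int
    mean_z: float
    null_quantile: float  # position of mean_z within the null ECDF
    mae_flag: bool


def mae_test(gene_snps: pd.DataFrame, all_snps: pd.DataFrame,
             n_boot: int = 1000, n_null: int = 1000, quantile: float = 0.95,
             seed: int = 0, null: np.ndarray | None = None) -> MaeResult:
    """Test one gene (columns af, depth) for monoallelic expression.

    ``all_snps`` is the sample-wide SNP table the background and null are
    built from.  A precomputed ``null`` array (from :func:`null_mean_z` for
    the same SNP count) may be supplied to share nulls across genes.
    """
    if len(gene_snps) < 2:
        raise ValueError("MAE test requires >= 2 SNPs in the gene")
    rng = np.random.default_rng(seed)
    bg_mean, bg_sd = weighted_background(all_snps["af"].to_numpy(),
                                         all_snps["depth"].to_numpy())
    mean_z = _bootstrap_mean_z(gene_snps["af"].to_numpy(), gene_snps["depth"].to_numpy(),
                               bg_mean, bg_sd, n_boot, rng)
    if null is None:
        null = null_mean_z(len(gene_snps), all_snps["af"].to_numpy(),
                           all_snps["depth"].to_numpy(), n_null, n_boot, rng)
    pos = float(np.mean(null < mean_z))
    cut = float(np.quantile(null, quantile))
    gene = str(gene_snps["gene"].iloc[0]) if "gene" in gene_snps else ""
    return MaeResult(gene, len(gene_snps), mean_z, pos, bool(mean_z > cut))


def mae_screen(snps: pd.DataFrame, n_boot: int = 1000, n_null: int = 1000,
               quantile: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """MAE-test every gene with >= 2 SNPs; nulls are cached per SNP count.

    ``snps`` columns: gene, af, depth.  Genes with < 2 SNPs are skipped
    (untestable by design).
    """
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    all_af = snps["af"].to_numpy()
    all_depth = snps["depth"].to_numpy()
    bg_mean, bg_sd = weighted_background(all_af, all_depth)
    rows = []
    for gene, sub in snps.groupby("gene", sort=False):
        k = len(sub)
        if k < 2:
            continue
        if k not in nulls:
            nulls[k] = null_mean_z(k, all_af, all_depth, n_null, n_boot,
                                   np.random.default_rng(seed + k))
        mean_z = _bootstrap_mean_z(sub["af"].to_numpy(), sub["depth"].to_numpy(),
                                   bg_mean, bg_sd, n_boot, rng)
        null = nulls[k]
        cut = float(np.quantile(null, quantile))
        rows.append({"gene": gene, "n_snps": k, "mean_z": mean_z,
                     "null_quantile": float(np.mean(null < mean_z)),
                     "mae_flag": bool(mean_z > cut)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parental skewing
# ---------------------------------------------------------------------------

def discretize_af(af: np.ndarray) -> np.ndarray:
    """Genotype classes from AF: 'hom_alt' (>=0.8), 'hom_ref' (<=0.2), else 'het'."""
    af = np.asarray(af, float)
    out = np.full(af.shape, "het", dtype=object)
    out[af >= HOM_HIGH] = "hom_alt"
    out[af <= HOM_LOW] = "hom_ref"
    return out


@dataclass
class ParentalSkewResult:
    per_chromosome: pd.DataFrame  # chrom, n_informative, frac_maternal/paternal/het, label
    n_maternal: int
    n_paternal: int
    binomial_p: float


def parental_skew(trio: pd.DataFrame, loh_chromosomes: set[str] | frozenset[str],
                  p0: float = 0.5) -> ParentalSkewResult:
    """Per-chromosome parental origin of retained LOH homologs plus cohort test.

    ``trio`` columns: chrom, pos, af_child_germline, af_maternal, af_tumor.
    The parent labeled is the one whose allele the tumor RETAINED.
    """
    df = trio.copy()
    df["gt_child"] = discretize_af(df["af_child_germline"])
    df["gt_mat"] = discretize_af(df["af_maternal"])
    df["gt_tum"] = discretize_af(df["af_tumor"])
    informative = df[(df["gt_mat"] != "het") & (df["gt_child"] == "het")]

    rows = []
    n_mat = n_pat = 0
    for chrom in sorted(loh_chromosomes, key=lambda c: (len(c), c)):
        sub = informative[informative["chrom"] == chrom]
        n = len(sub)
        if n == 0:
            rows.append({"chrom": chrom, "n_informative": 0, "frac_maternal": np.nan,
                         "frac_paternal": np.nan, "frac_het": np.nan, "label": "unlabeled"})
            continue
        hom = sub["gt_tum"] != "het"
        match = hom & (sub["gt_tum"] == sub["gt_mat"])
        f_mat = float(match.sum() / n)
        f_pat = float((hom & ~match).sum() / n)
        f_het = float((~hom).sum() / n)
        label = {f_mat: "maternal", f_pat: "paternal", f_het: "no-LOH"}[max(f_mat, f_pat, f_het)]
        if label == "maternal":
            n_mat += 1
        elif label == "paternal":
            n_pat += 1
        rows.append({"chrom": chrom, "n_informative": n, "frac_maternal": f_mat,
                     "frac_paternal": f_pat, "frac_het": f_het, "label": label})
    total = n_mat + n_pat
    p = binomial_enrichment(n_mat, total, p0) if total else float("nan")
    return ParentalSkewResult(pd.DataFrame(rows), n_mat, n_pat, p)
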