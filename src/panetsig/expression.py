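"""Expression-based signature inference and pericentromeric repression analysis.

Per-gene z-scores contrast MAD+ samples against the MAD- reference group
(mean and sd from MAD- only).  Genes are positioned by midpoint on their
chromosome arm, ranked into an arm-level empirical CDF percentile, and
smoothed with a loess regression (degree-2 local polynomial, tricube kernel,
span expressed as a fraction of points) against the fractional distance to
the centromere.  Repression near the centromere of LOH chromosomes appears
as a negative difference between the LOH-group and heterozygous-group loess
fits in the window [0, 0.025].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CytobandMap

REPRESSION_WINDOW = (0.0, 0.025)


# ---------------------------------------------------------------------------
# z-scores and percentiles
# ---------------------------------------------------------------------------

def gene_zscores(expr: pd.DataFrame, mad_labels: pd.Series) -> pd.Series:
    """Per-gene z of MAD+ expression against the MAD- reference.

    z = (mean over MAD+ - mean over MAD-) / sd over MAD- (ddof = 1).
    Genes with zero MAD- dispersion are dropped (NaN).  Requires >= 2 MAD-
    samples.
    """
    labels = mad_labels.reindex(expr.columns)
    pos = expr.loc[:, (labels == "positive").to_numpy()]
    neg = expr.loc[:, (labels == "negative").to_numpy()]
    if neg.shape[1] < 2:
        raise ValueError("need >= 2 MAD- samples to form the reference")
    sd = neg.std(axis=1, ddof=1)
    z = (pos.mean(axis=1) - neg.mean(axis=1)) / sd.replace(0.0, np.nan)
    return z


def arm_percentiles(z: pd.Series, arm: pd.Series) -> pd.Series:
    """Arm-level ECDF percentile of each gene's z (mid-rank for ties).

    The lowest of n distinct values gets 1/n; the highest gets 1.0; an
    all-tied arm maps every gene to the mid-rank (n+1)/(2n) ~ 0.5.
    """
    out = pd.Series(index=z.index, dtype=float)
    for _, idx in z.groupby(arm.reindex(z.index)).groups.items():
        vals = z.loc[idx]
        out.loc[idx] = vals.rank(method="average") / len(vals)
    return out


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

def loess_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
              span: float = 0.5, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with a tricube kernel.

    ``span`` is the fraction of points in each local neighborhood.  At each
    grid point the span-nearest points are tricube-weighted by scaled
    distance and a weighted polynomial of the given degree is fitted.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < degree + 1:
        raise ValueError("not enough points for the local polynomial")
    k = max(degree + 1, int(np.ceil(span * n)))
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, min(k, n) - 1)[min(k, n) - 1]
        if h == 0:
            h = max(d.max(), np.finfo(float).eps)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        deg = min(degree, max(1, np.unique(x[use]).size - 1))
        sw = np.sqrt(w[use])
        X = np.vander(x[use] - x0, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
        out[i] = beta[0]
    return out


def genomic_loess(z: pd.Series, coords: pd.DataFrame, span: float = 0.5,
                  degree: int = 2, n_grid: int = 200,
                  min_genes: int = 10) -> dict[str, pd.DataFrame]:
    """Per-chromosome loess curve of gene z-scores over genomic position.

    ``coords`` carries gene, chrom, start, end; chromosomes with fewer than
    ``min_genes`` genes are skipped.
    """
    mid = (coords["start"] + coords["end"]) / 2
    df = pd.DataFrame({"chrom": coords["chrom"].to_numpy(), "pos": mid.to_numpy(),
                       "z": z.reindex(coords["gene"]).to_numpy()})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.dropna()
        if len(sub) < min_genes:
            continue
        grid = np.linspace(sub["pos"].min(), sub["pos"].max(), n_grid)
        fit = loess_fit(sub["pos"].to_numpy(), sub["z"].to_numpy(), grid, span, degree)
        out[chrom] = pd.DataFrame({"pos": grid, "fit": fit})
    return out


# ---------------------------------------------------------------------------
# Gene records and repression curves
# ---------------------------------------------------------------------------

def gene_geometry(coords: pd.DataFrame, genome: CytobandMap) -> pd.DataFrame:
    """Arm label and fractional centromere distance per gene (midpoint rule).

    Genes whose midpoint falls inside the centromere (acen) span, or on an
    arm without a centromere boundary, are dropped.
    """
    mid = ((coords["start"] + coords["end"]) // 2).to_numpy()
    chroms = coords["chrom"].to_numpy()
    arm_lbl = np.full(len(coords), None, dtype=object)
    frac = np.full(len(coords), np.nan)
    for (chrom, arm_name), arm in genome.arms.items():
        if not arm.has_centromere:
            continue
        sel = (chroms == chrom) & (mid >= arm.arm_start) & (mid <= arm.arm_end)
        arm_lbl[sel] = f"{chrom}{arm_name}"
        frac[sel] = np.abs(mid[sel] - arm.centromere_boundary) / arm.arm_length
    out = pd.DataFrame({"gene": coords["gene"], "chrom": chroms,
                        "arm": arm_lbl, "frac_dist": frac})
    return out[out["arm"].notna()].reset_index(drop=True)


def build_gene_records(z: pd.Series, coords: pd.DataFrame, genome: CytobandMap,
                       geometry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach arm, fractional distance, and arm percentile to per-gene z.

    ``geometry`` (from :func:`gene_geometry`) can be precomputed and reused
    when only z changes, e.g. across label permutations.
    """
    rec = (geometry if geometry is not None else gene_geometry(coords, genome)).copy()
    rec["z"] = z.reindex(rec["gene"]).to_numpy()
    rec = rec.dropna(subset=["z"]).reset_index(drop=True)
    rec["arm_percentile"] = arm_percentiles(
        rec.set_index("gene")["z"], rec.set_index("gene")["arm"]).to_numpy()
    return rec


@dataclass
class RepressionCurves:
    grid: np.ndarray
    loh_fit: np.ndarray
    het_fit: np.ndarray
    basis: str

    @property
    def difference(self) -> np.ndarray:
        return self.loh_fit - self.het_fit

    def window_mean(self, lo: float = REPRESSION_WINDOW[0],
                    hi: float = REPRESSION_WINDOW[1]) -> float:
        sel = (self.grid >= lo) & (self.grid <= hi)
        return float(self.difference[sel].mean())

    @property
    def repressed_near_centromere(self) -> bool:
        """True when the LOH - het difference is negative over [0, 0.025]."""
        sel = (self.grid >= REPRESSION_WINDOW[0]) & (self.grid <= REPRESSION_WINDOW[1])
        return bool(np.all(self.difference[sel] < 0))


def repression_curves(records: pd.DataFrame, loh_set: set[str] | frozenset[str],
                      het_set: set[str] | frozenset[str], span: float = 0.5,
                      basis: str = "percentile",
                      grid: np.ndarray | None = None) -> RepressionCurves:
    """Loess fits of expression level vs fractional centromere distance.

    Separate fits for genes on LOH vs heterozygous chromosomes; ``basis`` is
    "percentile" (arm-level ECDF percentile, default) or "z".
    """
    col = {"percentile": "arm_percentile", "z": "z"}[basis]
    grid = np.linspace(0, 1, 201) if grid is None else grid
    fits = {}
    for name, chroms in (("loh", loh_set), ("het", het_set)):
        sub = records[records["chrom"].isin(chroms)]
        fits[name] = loess_fit(sub["frac_dist"].to_numpy(), sub[col].to_numpy(),
                               grid, span=span)
    return RepressionCurves(grid, fits["loh"], fits["het"], basis)


def repression_analysis(expr: pd.DataFrame, coords: pd.DataFrame,
                        mad_labels: pd.Series, genome: CytobandMap,
                        loh_set: set[str] | frozenset[str],
                        het_set: set[str] | frozenset[str],
                        span: float = 0.5, basis: str = "percentile",
                        n_perm: int = 0, seed: int = 0
                        ) -> tuple[RepressionCurves, np.ndarray]:
    """End-to-end repression pipeline, optionally with a label-permutation null.

    Returns the observed curves and, when ``n_perm`` > 0, the permutation
    null of the [0, 0.025]-window mean difference obtained by shuffling MAD
    labels and rerunning the whole z-score -> percentile -> loess chain.
    """
    geom = gene_geometry(coords, genome)
    z = gene_zscores(expr, mad_labels)
    obs = repression_curves(build_gene_records(z, coords, genome, geom),
                            loh_set, het_set, span, basis)
    null = np.empty(n_perm)
    rng = np.random.default_rng(seed)
    for i in range(n_perm):
        perm = pd.Series(rng.permutation(mad_labels.to_numpy()), index=mad_labels.index)
        zp = gene_zscores(expr, perm)
        rp = build_gene_records(zp, coords, genome, geom)
        null[i] = repression_curves(rp, loh_set, het_set, span, basis).window_mean()
    return obs, null


def infer_signature_from_zscores(records: pd.DataFrame,
                                 q: float = 0.5) -> pd.DataFrame:
    """Chromosome-level summary of expression z-scores (signature check).

    LOH chromosomes in genome-doubled MAD+ tumors sit at lower relative
    dosage than the gained heterozygous chromosomes, so chromosome-median z
    separates the two groups.  Returns chrom, median_z, inferred group by
    the cohort-median split.
    """
    med = records.groupby("chrom")["z"].median().rename("median_z").reset_index()
    cut = med["median_z"].quantile(q)
    med["inferred"] = np.where(med["median_z"] <= cut, "LOH-like", "het-like")
    return med
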