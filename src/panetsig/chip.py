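"""CENP-A ChIP peak summaries per cytoband and mis-segregation correlations.

Peaks (BED-like: chrom, start, end, height[, reads]) are partitioned between
a DAXX-depleted and a control condition by any-overlap (>= 1 bp): acquired =
depleted-only, maintained = overlapping, lost = control-only.  Per-cytoband
summaries cover peak counts, coverage, RPKM (reads per kilobase of peaks per
million mapped reads), and a two-sample Kolmogorov-Smirnov D of the band's
peak heights against the genome-wide distribution.  Chromosome-level
mis-segregation fractions are correlated with centromere/flank sizes and
CENP-A features (Pearson), and with LOH membership (point-biserial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CytobandMap, normalize_chrom

PEAK_COLUMNS = ["chrom", "start", "end", "height"]


def read_peaks(path) -> pd.DataFrame:
    """Read BED4+ peaks (chrom, start, end, height[, reads]); no header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = PEAK_COLUMNS + (["reads"] if df.shape[1] >= 5 else [])
    df = df.iloc[:, : len(names)]
    df.columns = names
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def bedgraph_to_peaks(bedgraph: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Threshold a bedGraph track (chrom, start, end, value) into peaks.

    Adjacent above-threshold intervals merge; peak height is the max value.
    """
    df = bedgraph[bedgraph["value"] >= threshold].sort_values(["chrom", "start"])
    peaks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        cur = None
        for _, r in sub.iterrows():
            if cur is not None and r["start"] <= cur[1]:
                cur[1] = max(cur[1], r["end"])
                cur[2] = max(cur[2], r["value"])
            else:
                if cur is not None:
                    peaks.append((chrom, *cur))
                cur = [r["start"], r["end"], r["value"]]
        if cur is not None:
            peaks.append((chrom, *cur))
    return pd.DataFrame(peaks, columns=PEAK_COLUMNS)


def _overlaps_any(peaks: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each peak overlap any interval in ``others`` (>=1 bp)."""
    out = np.zeros(len(peaks), dtype=bool)
    by_chrom = {c: sub.sort_values("start") for c, sub in others.groupby("chrom")}
    for i, (_, p) in enumerate(peaks.iterrows()):
        sub = by_chrom.get(p["chrom"])
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, p["end"])  # candidates start before p.end
        out[i] = bool(np.any(ends[:j] > p["start"]))
    return out


def classify_peaks(depleted: pd.DataFrame, control: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition peaks into acquired / maintained / lost under depletion.

    acquired = depleted-only, lost = control-only, maintained = peaks from
    either set that overlap the other (any-overlap rule); maintained rows
    carry a ``source`` column.
    """
    dep_hit = _overlaps_any(depleted, control)
    ctl_hit = _overlaps_any(control, depleted)
    maintained = pd.concat([
        depleted[dep_hit].assign(source="depleted"),
        control[ctl_hit].assign(source="control"),
    ], ignore_index=True)
    return {
        "acquired": depleted[~dep_hit].reset_index(drop=True),
        "maintained": maintained,
        "lost": control[~ctl_hit].reset_index(drop=True),
    }


def compare_maintained_heights(maintained: pd.DataFrame) -> tuple[float, float]:
    """Welch's t comparing maintained-peak heights between conditions."""
    dep = maintained.loc[maintained["source"] == "depleted", "height"]
    ctl = maintained.loc[maintained["source"] == "control", "height"]
    t, p = stats.ttest_ind(dep, ctl, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Per-cytoband statistics
# ---------------------------------------------------------------------------

def rpkm(peaks: pd.DataFrame, genome: CytobandMap, total_mapped_reads: float) -> pd.Series:
    """Per-cytoband RPKM: reads in band peaks / (peak kb in band * mapped/1e6).

    Peaks spanning band boundaries contribute reads and bases proportionally
    to overlap, so splitting a peak in two leaves the result unchanged.
    """
    if "reads" not in peaks:
        raise ValueError("rpkm needs a 'reads' column on peaks")
    reads_by_band: dict[tuple[str, str], float] = {}
    bp_by_band: dict[tuple[str, str], float] = {}
    for _, p in peaks.iterrows():
        length = p["end"] - p["start"]
        for band in genome.assign_to_cytoband(p["chrom"], int(p["start"]), int(p["end"])):
            ov = min(p["end"], band.end) - max(p["start"], band.start)
            key = (p["chrom"], band.name)
            reads_by_band[key] = reads_by_band.get(key, 0.0) + p["reads"] * ov / length
            bp_by_band[key] = bp_by_band.get(key, 0.0) + ov
    out = {}
    scale = total_mapped_reads / 1e6
    for key, r in reads_by_band.items():
        out[key] = r / (bp_by_band[key] / 1000.0 * scale)
    return pd.Series(out).sort_index()


def band_ks(band_values: np.ndarray, genome_values: np.ndarray) -> float:
    """Two-sample KS D: band peak-height distribution vs genome-wide."""
    if len(band_values) == 0 or len(genome_values) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(band_values, genome_values).statistic)


def cytoband_peak_stats(peaks: pd.DataFrame, genome: CytobandMap,
                        total_mapped_reads: float | None = None,
                        value: str = "height") -> pd.DataFrame:
    """Per-cytoband peak count, coverage, optional RPKM, and KS D vs genome.

    ``value`` selects the KS-tested quantity: "height" (default) or
    "position" (peak midpoints, scaled within the band's chromosome).
    """
    peaks = peaks.reset_index(drop=True).copy()
    peaks["band"] = [
        "/".join(b.name for b in genome.assign_to_cytoband(r["chrom"], int(r["start"]), int(r["end"])))
        for _, r in peaks.iterrows()
    ]
    if value == "position":
        vals_all = ((peaks["start"] + peaks["end"]) / 2).to_numpy(float)
    else:
        vals_all = peaks[value].to_numpy(float)
    rpkm_by_band = (rpkm(peaks, genome, total_mapped_reads)
                    if total_mapped_reads and "reads" in peaks else None)
    rows = []
    for (chrom, band), sub in peaks.groupby(["chrom", "band"], sort=False):
        vals = vals_all[sub.index.to_numpy()]
        rows.append({
            "chrom": chrom, "band": band, "n_peaks": len(sub),
            "coverage_bp": int((sub["end"] - sub["start"]).sum()),
            "rpkm": (float(rpkm_by_band.get((chrom, band), 0.0))
                     if rpkm_by_band is not None else np.nan),
            "ks_d": band_ks(vals, vals_all) if len(sub) else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mis-segregation correlations
# ---------------------------------------------------------------------------

def arm_feature_table(genome: CytobandMap, exclude_acrocentric_p: bool = False) -> pd.DataFrame:
    """Per-chromosome centromere size and summed periCEN flank size."""
    from .genome import ACROCENTRIC
    rows = []
    for chrom in genome.chromosomes:
        cen = flank = 0
        for arm_label in ("p", "q"):
            arm = genome.arms.get((chrom, arm_label))
            if arm is None or not arm.has_centromere:
                continue
            cen = arm.cen_size
            if exclude_acrocentric_p and arm_label == "p" and chrom in ACROCENTRIC:
                continue
            flank += arm.flank_size
        rows.append({"chrom": chrom, "cen_size": cen, "flank_size": flank})
    return pd.DataFrame(rows)


def pericen_peak_level(peaks: pd.DataFrame, genome: CytobandMap) -> pd.Series:
    """Mean peak height within the periCEN flanking bands, per chromosome."""
    levels: dict[str, list[float]] = {}
    for _, p in peaks.iterrows():
        chrom = p["chrom"]
        for arm_label in ("p", "q"):
            arm = genome.arms.get((chrom, arm_label))
            if arm is None or not arm.has_centromere:
                continue
            if arm_label == "p":
                flank_lo, flank_hi = arm.centromere_boundary - arm.flank_size, arm.centromere_boundary
            else:
                flank_lo, flank_hi = arm.centromere_boundary, arm.centromere_boundary + arm.flank_size
            if p["start"] < flank_hi and p["end"] > flank_lo:
                levels.setdefault(chrom, []).append(float(p["height"]))
    return pd.Series({c: float(np.mean(v)) for c, v in levels.items()})


def missegregation_correlations(table: pd.DataFrame,
                                features: pd.DataFrame) -> pd.DataFrame:
    """Correlate per-chromosome mis-segregation fractions with features.

    ``table`` columns: chrom, missegregation_fraction, loh_member (bool).
    ``features``: chrom plus any numeric columns (cen_size, flank_size, mean
    CENP-A level near the centromere, ...).  Continuous features use Pearson
    r; loh_member uses the point-biserial r.  Two-sided p from the t
    transform in both cases.
    """
    df = table.merge(features, on="chrom", how="inner")
    rows = []
    y = df["missegregation_fraction"].to_numpy(float)
    for col in features.columns:
        if col == "chrom":
            continue
        x = df[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"feature": col, "method": "pearson", "r": float(r),
                     "p": float(p), "n": int(ok.sum())})
    if "loh_member" in df:
        r, p = stats.pointbiserialr(df["loh_member"].astype(int), y)
        rows.append({"feature": "loh_member", "method": "point-biserial",
                     "r": float(r), "p": float(p), "n": len(df)})
    return pd.DataFrame(rows)
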