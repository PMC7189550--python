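"""CGH meta-analysis: cytoband profiles, clustering, pooled odds ratios.

Published CGH gain/loss listings are mapped to cytoband-level status vectors
in {loss, neutral, gain}; profiles are clustered hierarchically on Jaccard
distance (1 - state-matched Jaccard index, average linkage); per-study 2x2
tables of CI stratum x outcome are pooled with the Mantel-Haenszel
fixed-effect odds ratio, a Robins-Breslow-Greenland 95% CI, and Cochran's Q
for heterogeneity (Haldane 0.5 continuity correction applied only to studies
with a zero cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.contingency_tables import StratifiedTable

from .genome import CytobandMap, normalize_chrom


# ---------------------------------------------------------------------------
# CGH ingestion
# ---------------------------------------------------------------------------

def ingest_cgh(listings: pd.DataFrame, genome: CytobandMap) -> pd.DataFrame:
    """Expand gain/loss listings to a samples x cytoband status matrix.

    ``listings`` columns: sample, region, direction.  A region is a cytoband
    ("1p11"), a whole arm ("1p"), or a whole chromosome ("1"); direction is
    "gain" or "loss".  Conflicting gain+loss on the same sample/band is
    flagged by setting the band to 0 (excluded from concordance).  Status
    codes: -1 loss, 0 neutral, +1 gain.
    """
    cols = [f"{c}:{b.name}" for c in genome.chromosomes for b in genome.bands[c]
            if b.stain != "acen"]
    col_index = {c: i for i, c in enumerate(cols)}
    samples = list(dict.fromkeys(listings["sample"]))
    mat = np.zeros((len(samples), len(cols)), dtype=int)
    conflict = np.zeros_like(mat, dtype=bool)
    srow = {s: i for i, s in enumerate(samples)}
    for _, r in listings.iterrows():
        region = str(r["region"])
        value = {"gain": 1, "loss": -1}[str(r["direction"]).lower()]
        for key in _expand_region(region, genome):
            j = col_index.get(key)
            if j is None:
                continue
            i = srow[r["sample"]]
            if mat[i, j] != 0 and mat[i, j] != value:
                conflict[i, j] = True
            mat[i, j] = value
    mat[conflict] = 0
    return pd.DataFrame(mat, index=samples, columns=cols)


def _expand_region(region: str, genome: CytobandMap) -> list[str]:
    region = region.removeprefix("chr")
    num = ""
    for ch in region:
        if ch.isdigit():
            num += ch
        else:
            break
    rest = region[len(num):]
    chrom = normalize_chrom(num) if num else normalize_chrom(region)
    if chrom not in genome.bands:
        return []
    bands = [b for b in genome.bands[chrom] if b.stain != "acen"]
    if not rest:  # whole chromosome
        keep = bands
    elif rest in ("p", "q"):  # whole arm
        keep = [b for b in bands if b.name.startswith(rest)]
    else:  # single band (prefix match allows sub-band listings)
        keep = [b for b in bands if b.name == rest or b.name.startswith(rest)]
    return [f"{chrom}:{b.name}" for b in keep]


# ---------------------------------------------------------------------------
# Clustering on Jaccard distance
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - state-matched Jaccard over a samples x band status matrix.

    Intersection = bands aberrant in both with matching sign; union = bands
    aberrant in either; two all-neutral profiles get distance 0.
    """
    x = profiles.to_numpy(int)
    loss = (x == -1).astype(float)
    gain = (x == 1).astype(float)
    ab = (x != 0).astype(float)
    inter = loss @ loss.T + gain @ gain.T
    counts = ab.sum(axis=1)
    both = ab @ ab.T
    union = counts[:, None] + counts[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / union, 1.0)
    return 1.0 - j


def cluster_profiles(profiles: pd.DataFrame, k: int,
                     method: str = "average") -> pd.Series:
    """Agglomerative clustering of CGH profiles cut at k clusters."""
    d = jaccard_distance_matrix(profiles)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=profiles.index, name="cluster")


# ---------------------------------------------------------------------------
# Pooled odds ratio
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    q: float
    q_df: int
    q_p: float
    per_study: pd.DataFrame  # study, a, b, c, d, odds_ratio

    def __repr__(self) -> str:
        return (f"MetaResult(OR {self.pooled_or:.2f} "
                f"[{self.ci_low:.2f}, {self.ci_high:.2f}], "
                f"Q={self.q:.2f} df={self.q_df} p={self.q_p:.3g})")


def _study_or(a, b, c, d) -> tuple[float, float]:
    """(log OR, variance), Haldane 0.5 added only when a cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return float(log_or), float(var)


def pooled_or(studies: pd.DataFrame) -> MetaResult:
    """Mantel-Haenszel fixed-effect pooled OR with RBG CI and Cochran's Q.

    ``studies`` columns: study, a, b, c, d where the 2x2 per study is
    [[a, b], [c, d]] (rows = stratum, columns = outcome +/-).
    """
    df = studies.copy()
    nondeg = df[(df[["a", "b", "c", "d"]].sum(axis=1) > 0)
                & ((df["a"] + df["b"]) > 0) & ((df["c"] + df["d"]) > 0)]
    if nondeg.empty:
        raise ValueError("all study tables are degenerate")
    tables = np.stack([
        np.array([[r["a"], r["b"]], [r["c"], r["d"]]], float)
        for _, r in nondeg.iterrows()
    ], axis=-1)
    st = StratifiedTable(tables)
    or_mh = float(st.oddsratio_pooled)
    lo, hi = (float(v) for v in st.oddsratio_pooled_confint(alpha=0.05))

    per = []
    logs, variances = [], []
    for _, r in nondeg.iterrows():
        lor, var = _study_or(r["a"], r["b"], r["c"], r["d"])
        logs.append(lor)
        variances.append(var)
        per.append({"study": r["study"], "a": r["a"], "b": r["b"], "c": r["c"],
                    "d": r["d"], "odds_ratio": float(np.exp(lor))})
    logs = np.array(logs)
    w = 1 / np.array(variances)
    pooled_log = float(np.sum(w * logs) / np.sum(w))
    q = float(np.sum(w * (logs - pooled_log) ** 2))
    df_q = len(logs) - 1
    q_p = float(stats.chi2.sf(q, df_q)) if df_q > 0 else float("nan")
    return MetaResult(or_mh, lo, hi, q, df_q, q_p, pd.DataFrame(per))


def read_study_tables(path) -> pd.DataFrame:
    """Per-study 2x2 tables as CSV with columns study, a, b, c, d."""
    df = pd.read_csv(path)
    need = {"study", "a", "b", "c", "d"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    if (df[["a", "b", "c", "d"]] < 0).any().any():
        raise ValueError("cell counts must be non-negative")
    return df
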