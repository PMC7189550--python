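"""Molecular timing of somatic mutations relative to LOH and genome doubling.

A somatic mutation observed at allelic fraction ``af_obs`` in a tumor of
purity ``p`` carries ``m`` mutant copies out of ``n`` total copies at its
locus in the tumor compartment.  With ``c`` normal copies (2 on autosomes,
1 on chrX in males) the forward model is

    af_obs = p * m / (p * n + c * (1 - p))

which inverts to the purity a candidate (m, n) model *implies*:

    p = c * af_obs / (m + c * af_obs - n * af_obs)

Following a pathologist purity estimate with a ±0.15 tolerance, the simplest
feasible copy model is selected per mutation (ordering: fewest copy-number
events, i.e. total copy number nearest diploid, then smallest n, then m);
chromosome-level copy-number calls, when available, pin n.  The tumor allelic
fraction m/n ("cancer cell fraction" of the mutation) classifies the mutation
as early (m/n at or above a cutoff, i.e. present on all copies before LOH /
doubling) or late.  Cohort-level enrichment of early mutations is tested with
an exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MAD_GENES = frozenset({"MEN1", "ATRX", "DAXX"})

#: default CCF cutoff above which a mutation is called early
EARLY_CCF_CUTOFF = 0.85
#: relaxed cutoff used for chrX genes where LOH is not required as second hit
RELAXED_CCF_CUTOFF = 0.63
#: pathologist purity tolerance
PURITY_TOLERANCE = 0.15
#: samples below this cellularity are excluded (signal obscured)
MIN_PURITY = 0.30


# ---------------------------------------------------------------------------
# Forward / inverse allelic-fraction model
# ---------------------------------------------------------------------------

def expected_observed_af(purity: float, m: float, n: float, normal_copies: float = 2.0) -> float:
    """Expected observed allelic fraction of a somatic mutation (forward model)."""
    denom = purity * n + normal_copies * (1.0 - purity)
    if denom <= 0:
        raise ValueError("degenerate mixture: purity * n + c * (1 - purity) <= 0")
    return purity * m / denom


def implied_purity(af_obs: float, m: int, n: int, normal_copies: float = 2.0) -> float | None:
    """Purity implied by copy model (m, n) for an observed AF, or None if infeasible.

    Feasible means the solved purity lies in (0, 1].
    """
    if not (1 <= m <= n):
        raise ValueError("require 1 <= m <= n")
    denom = m + normal_copies * af_obs - n * af_obs
    if denom <= 0:
        return None
    p = normal_copies * af_obs / denom
    if p <= 0 or p > 1:
        return None
    return p


@dataclass(frozen=True)
class CopyModel:
    """Candidate (m mutant copies, n total copies) with implied purity."""

    m: int
    n: int
    implied_purity: float

    @property
    def tumor_af(self) -> float:
        """Mutation allelic fraction within tumor cells (cancer cell fraction here)."""
        return self.m / self.n

    @property
    def complexity(self) -> tuple[int, int, int]:
        """Parsimony ordering key: closest to diploid, then smallest n, then m.

        A haploid (1, 1) model implies an extra loss event, so it is *less*
        simple than the diploid states it competes with; preferring n near 2
        keeps "simplest" aligned with the fewest copy-number events.
        """
        return (abs(self.n - 2), self.n, self.m)


@dataclass
class SomaticCall:
    """One somatic mutation with observed allele support."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    af_obs: float
    depth: int
    total_cn: int | None = None  # chromosome/segment copy state, when known

    def __post_init__(self) -> None:
        if not 0 <= self.af_obs <= 1:
            raise ValueError("af_obs must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def is_mad(self) -> bool:
        return self.gene in MAD_GENES


@dataclass
class SampleMeta:
    sample_id: str
    pathologist_purity: float
    purity_tolerance: float = PURITY_TOLERANCE
    mad_status: str | None = None  # "positive" / "negative"
    cohort: str | None = None
    sex: str | None = None  # "male" / "female"; needed for chrX calls

    def __post_init__(self) -> None:
        if self.purity_tolerance < 0:
            raise ValueError("purity_tolerance must be >= 0")


@dataclass
class TimingCall:
    sample_id: str
    gene: str
    chrom: str
    model: CopyModel | None
    ccf_class: str  # "early" / "late" / "unresolved" / "excluded" / "flagged_chrx"
    cutoff: float
    is_mad: bool = False
    on_loh_or_doubled: bool = False
    warning: str | None = None

    @property
    def resolved(self) -> bool:
        return self.model is not None and self.ccf_class in ("early", "late")


def enumerate_copy_models(af_obs: float, n_max: int = 8,
                          normal_copies: float = 2.0,
                          total_cn: int | None = None) -> list[CopyModel]:
    """All feasible copy models, in parsimony order (smallest n, then m)."""
    ns = [total_cn] if total_cn is not None else range(1, n_max + 1)
    out = []
    for n in ns:
        for m in range(1, n + 1):
            p = implied_purity(af_obs, m, n, normal_copies)
            if p is not None:
                out.append(CopyModel(m, n, p))
    out.sort(key=lambda cm: cm.complexity)
    return out


def _normal_copies_for(call: SomaticCall, meta: SampleMeta) -> float | None:
    chrom = call.chrom.removeprefix("chr")
    if chrom == "X":
        if meta.sex == "male":
            return 1.0
        if meta.sex == "female":
            return 2.0
        return None  # unknown sex: flag
    return 2.0


def select_copy_model(call: SomaticCall, meta: SampleMeta, n_max: int = 8,
                      cutoff: float = EARLY_CCF_CUTOFF,
                      on_loh_or_doubled: bool = True) -> TimingCall:
    """Pick the simplest copy model consistent with pathologist purity ± tolerance.

    Samples with pathologist purity below 30% are excluded outright (low
    cellularity obscures the allelic-fraction signal).  When ``call.total_cn``
    is set, enumeration is restricted to that total copy number — the copy
    state of the mutation's chromosome constrains the model.
    """
    base = dict(sample_id=call.sample_id, gene=call.gene, chrom=call.chrom,
                cutoff=cutoff, is_mad=call.is_mad,
                on_loh_or_doubled=on_loh_or_doubled)
    if meta.pathologist_purity < MIN_PURITY:
        return TimingCall(model=None, ccf_class="excluded",
                          warning="pathologist purity < 0.30", **base)
    c = _normal_copies_for(call, meta)
    if c is None:
        return TimingCall(model=None, ccf_class="flagged_chrx",
                          warning="chrX call with unknown sex", **base)
    models = enumerate_copy_models(call.af_obs, n_max, c, call.total_cn)
    feasible = [cm for cm in models
                if abs(cm.implied_purity - meta.pathologist_purity) <= meta.purity_tolerance]
    if not feasible:
        return TimingCall(model=None, ccf_class="unresolved",
                          warning="no copy model within purity tolerance", **base)
    best = feasible[0]
    cls = "early" if best.tumor_af >= cutoff else "late"
    return TimingCall(model=best, ccf_class=cls, **base)


def select_sample_models(calls: list[SomaticCall], meta: SampleMeta,
                         n_max: int = 8, cutoff: float = EARLY_CCF_CUTOFF,
                         loh_or_doubled: dict[str, bool] | None = None) -> list[TimingCall]:
    """Joint model selection for all mutations of one sample.

    All mutations must be explainable by one tumor purity: the intersection
    of per-mutation feasible purity intervals (implied ± tolerance), further
    intersected with pathologist purity ± tolerance, must be non-empty.  When
    it is, each mutation takes the simplest model whose implied purity lies
    within tolerance of the window midpoint; otherwise selection falls back
    to per-mutation with a warning.
    """
    tol = meta.purity_tolerance
    per_call: list[TimingCall] = []
    for call in calls:
        ctx = True if loh_or_doubled is None else loh_or_doubled.get(call.chrom, False)
        per_call.append(select_copy_model(call, meta, n_max, cutoff, on_loh_or_doubled=ctx))
    resolved = [tc for tc in per_call if tc.model is not None]
    if len(resolved) < 2:
        return per_call
    lo = max(tc.model.implied_purity - tol for tc in resolved)
    hi = min(tc.model.implied_purity + tol for tc in resolved)
    lo = max(lo, meta.pathologist_purity - tol)
    hi = min(hi, meta.pathologist_purity + tol)
    if lo > hi:
        for tc in per_call:
            tc.warning = (tc.warning or "") + "|no joint purity; per-mutation fallback"
        return per_call
    p_star = 0.5 * (lo + hi)
    out: list[TimingCall] = []
    for call, tc in zip(calls, per_call):
        if tc.model is None:
            out.append(tc)
            continue
        c = _normal_copies_for(call, meta) or 2.0
        models = enumerate_copy_models(call.af_obs, n_max, c, call.total_cn)
        joint = [cm for cm in models
                 if abs(cm.implied_purity - p_star) <= tol
                 and abs(cm.implied_purity - meta.pathologist_purity) <= tol]
        if joint:
            best = joint[0]
            cls = "early" if best.tumor_af >= tc.cutoff else "late"
            out.append(TimingCall(tc.sample_id, tc.gene, tc.chrom, best, cls,
                                  tc.cutoff, tc.is_mad, tc.on_loh_or_doubled))
        else:
            out.append(tc)
    return out


# ---------------------------------------------------------------------------
# Cohort summaries and enrichment
# ---------------------------------------------------------------------------

def binomial_enrichment(k: int, n: int, p0: float = 0.5, sided: str = "two") -> float:
    """Exact binomial test by pmf summation.

    Two-sided uses the minimum-likelihood convention: the p-value is the sum
    of the probabilities of all outcomes no more likely than the observed one.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    ks = np.arange(n + 1)
    pmf = stats.binom.pmf(ks, n, p0)
    if sided == "greater":
        return float(pmf[k:].sum())
    if sided == "less":
        return float(pmf[: k + 1].sum())
    if sided == "two":
        return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-10)].sum()))
    raise ValueError(f"unknown sidedness {sided!r}")


def timing_summary(calls: list[TimingCall], cutoff: float | None = None) -> pd.DataFrame:
    """Per-MAD-gene and overall early/late counts with binomial p-values.

    A sample counts as "early" when its MAD mutation has tumor AF >= cutoff on
    an LOH or genome-doubled chromosome.  One row per gene plus an "all" row.
    """
    rows = []
    mad = [tc for tc in calls if tc.is_mad and tc.resolved]

    def _early(tc: TimingCall) -> bool:
        cut = cutoff if cutoff is not None else tc.cutoff
        return tc.model.tumor_af >= cut and tc.on_loh_or_doubled

    groups: dict[str, list[TimingCall]] = {"all": mad}
    for tc in mad:
        groups.setdefault(tc.gene, []).append(tc)
    for name, tcs in groups.items():
        n = len(tcs)
        k = sum(_early(tc) for tc in tcs)
        p = binomial_enrichment(k, n) if n else float("nan")
        rows.append({"group": name, "n_early": k, "n_total": n, "binomial_p": p})
    return pd.DataFrame(rows)


def gene_enrichment(calls: list[TimingCall], cutoff: float = EARLY_CCF_CUTOFF,
                    genes: tuple[str, ...] = ("MEN1", "ATRX", "DAXX")) -> pd.DataFrame:
    """Per-gene early enrichment, Bonferroni-adjusted over the genes tested."""
    rows = []
    for gene in genes:
        tcs = [tc for tc in calls if tc.gene == gene and tc.resolved]
        n = len(tcs)
        k = sum(tc.model.tumor_af >= cutoff and tc.on_loh_or_doubled for tc in tcs)
        p = binomial_enrichment(k, n) if n else float("nan")
        rows.append({"gene": gene, "n_early": k, "n_total": n,
                     "p_raw": p, "p_bonferroni": min(1.0, p * len(genes)) if n else float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "sample_id": ("sample_id", "sample", "tumor_sample_barcode"),
    "gene": ("gene", "hugo_symbol"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "start_position", "position"),
    "t_alt_count": ("t_alt_count", "alt_count"),
    "t_depth": ("t_depth", "depth"),
    "total_cn": ("total_cn", "tcn", "copy_number"),
}


def read_mutation_table(path: str | Path) -> list[SomaticCall]:
    """Read a tab-delimited mutation table (MAF-compatible column aliases).

    AF is taken from an ``af`` column when present, else t_alt_count/t_depth.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    cols: dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                cols[canon] = a
                break
    missing = {"sample_id", "gene", "chrom", "pos"} - cols.keys()
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    calls = []
    for _, row in df.iterrows():
        depth = int(row[cols["t_depth"]]) if "t_depth" in cols else int(row.get("depth", 0))
        if "af" in df.columns:
            af = float(row["af"])
        else:
            af = int(row[cols["t_alt_count"]]) / depth
        tcn = int(row[cols["total_cn"]]) if "total_cn" in cols and pd.notna(row[cols["total_cn"]]) else None
        calls.append(SomaticCall(str(row[cols["sample_id"]]), str(row[cols["gene"]]),
                                 str(row[cols["chrom"]]), int(row[cols["pos"]]),
                                 af, depth, total_cn=tcn))
    return calls


_TIMING_COLUMNS = ["sample_id", "gene", "chrom", "m", "n", "implied_purity",
                   "tumor_af", "ccf_class", "cutoff", "is_mad",
                   "on_loh_or_doubled", "warning"]


def timing_calls_frame(calls: list[TimingCall]) -> pd.DataFrame:
    """Flatten timing calls to a table (one row per mutation)."""
    if not calls:
        return pd.DataFrame(columns=_TIMING_COLUMNS)
    rows = []
    for tc in calls:
        rows.append({
            "sample_id": tc.sample_id, "gene": tc.gene, "chrom": tc.chrom,
            "m": tc.model.m if tc.model else None,
            "n": tc.model.n if tc.model else None,
            "implied_purity": tc.model.implied_purity if tc.model else None,
            "tumor_af": tc.model.tumor_af if tc.model else None,
            "ccf_class": tc.ccf_class, "cutoff": tc.cutoff,
            "is_mad": tc.is_mad, "on_loh_or_doubled": tc.on_loh_or_doubled,
            "warning": tc.warning,
        })
    return pd.DataFrame(rows)
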