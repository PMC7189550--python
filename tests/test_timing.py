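"""Copy-model enumeration, purity inversion, and binomial enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panetsig.timing import (SampleMeta, SomaticCall, binomial_enrichment,
                             enumerate_copy_models, expected_observed_af,
                             gene_enrichment, implied_purity,
                             read_mutation_table, select_copy_model,
                             select_sample_models, timing_summary)


# ---------------------------------------------------------------------------
# implied purity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("af, m, n, expected", [
    (0.25, 1, 2, 0.5),   # subclonal-looking het at half purity
    (0.5, 2, 2, 0.5),    # homozygous at half purity
    (0.5, 1, 2, 1.0),    # fully clonal het in a pure tumor
])
def test_implied_purity_closed_form(af, m, n, expected):
    assert implied_purity(af, m, n) == pytest.approx(expected)


def test_implied_purity_infeasible_cases():
    assert implied_purity(0.9, 1, 2) is None        # would need purity > 1
    assert implied_purity(0.6, 1, 4) is None        # denominator <= 0
    with pytest.raises(ValueError):
        implied_purity(0.5, 3, 2)


@settings(max_examples=200, deadline=None)
@given(st.floats(0.05, 1.0), st.integers(1, 8), st.integers(1, 8))
def test_implied_purity_inverts_forward_model(purity, m, n):
    """Round trip through the AF mixture model is exact to 1e-12."""
    m = min(m, n)
    af = expected_observed_af(purity, m, n)
    if af >= 1.0:
        return
    p = implied_purity(af, m, n)
    assert p == pytest.approx(purity, abs=1e-12)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _call(af, gene="MEN1", chrom="chr11", depth=200, total_cn=None):
    return SomaticCall("s", gene, chrom, 1000, af, depth, total_cn=total_cn)


def test_select_homozygous_and_heterozygous_archetypes():
    meta = SampleMeta("s", pathologist_purity=0.5)
    hom = select_copy_model(_call(0.5), meta)
    assert (hom.model.m, hom.model.n) == (2, 2)
    assert hom.model.tumor_af == 1.0 and hom.ccf_class == "early"
    het = select_copy_model(_call(0.25), meta)
    assert (het.model.m, het.model.n) == (1, 2)
    assert het.model.tumor_af == 0.5 and het.ccf_class == "late"


def test_select_unresolved_when_nothing_fits():
    meta = SampleMeta("s", pathologist_purity=0.9)
    tc = select_copy_model(_call(0.05), meta, n_max=4)
    assert tc.model is None and tc.ccf_class == "unresolved"


def test_low_cellularity_sample_excluded():
    meta = SampleMeta("s", pathologist_purity=0.25)
    tc = select_copy_model(_call(0.5), meta)
    assert tc.ccf_class == "excluded"


def test_chrx_normal_copy_handling():
    male = SampleMeta("s", 0.6, sex="male")
    # hemizygous clonal mutation: af = p / (p + (1 - p)) = 0.6 -> (1, 1)
    tc = select_copy_model(_call(0.6, gene="ATRX", chrom="chrX"), male)
    assert (tc.model.m, tc.model.n) == (1, 1) and tc.ccf_class == "early"
    unknown = SampleMeta("s", 0.6, sex=None)
    assert select_copy_model(_call(0.6, chrom="chrX"), unknown).ccf_class == "flagged_chrx"


def test_known_total_cn_constrains_enumeration():
    models = enumerate_copy_models(0.5, n_max=8, total_cn=2)
    assert all(cm.n == 2 for cm in models)


def test_joint_selection_shares_one_purity():
    meta = SampleMeta("s", pathologist_purity=0.6)
    calls = [_call(0.6, total_cn=2), _call(0.3, gene="PSG1", chrom="chr4", total_cn=2)]
    tcs = select_sample_models(calls, meta)
    assert [(t.model.m, t.model.n) for t in tcs] == [(2, 2), (1, 2)]
    assert all(abs(t.model.implied_purity - 0.6) <= 0.15 for t in tcs)


# ---------------------------------------------------------------------------
# binomial enrichment
# ---------------------------------------------------------------------------

def _enumerate_two_sided(k, n, p0=0.5):
    pk = math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
    total = 0.0
    for i in range(n + 1):
        pi = math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
        if pi <= pk * (1 + 1e-10):
            total += pi
    return min(1.0, total)


def test_binomial_reproduces_reported_values():
    # 35/39 early MAD mutations
    assert binomial_enrichment(35, 39) == pytest.approx(3.4e-7, rel=0.05)
    assert binomial_enrichment(35, 39) == pytest.approx(_enumerate_two_sided(35, 39))
    # 8/11 maternal LOH chromosomes; exact 464/2048
    assert binomial_enrichment(8, 11) == pytest.approx(464 / 2048, abs=1e-12)


def test_binomial_symmetry_and_errors():
    assert binomial_enrichment(10, 20) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        binomial_enrichment(1, 0)
    with pytest.raises(ValueError):
        binomial_enrichment(5, 4)


@settings(max_examples=150, deadline=None)
@given(st.integers(1, 20), st.data())
def test_binomial_matches_exhaustive_enumeration(n, data):
    k = data.draw(st.integers(0, n))
    assert binomial_enrichment(k, n) == pytest.approx(_enumerate_two_sided(k, n), rel=1e-9)


def test_increasing_cutoff_never_increases_early_count():
    meta = SampleMeta("s", 0.5)
    counts = []
    for cutoff in (0.5, 0.63, 0.85, 0.95):
        tcs = [select_copy_model(_call(af, gene="MEN1"), meta, cutoff=cutoff)
               for af in (0.5, 0.45, 0.25, 0.3)]
        summary = timing_summary(tcs)
        counts.append(int(summary.loc[summary["group"] == "all", "n_early"].iloc[0]))
    assert counts == sorted(counts, reverse=True)


def test_gene_enrichment_bonferroni():
    meta = SampleMeta("s", 0.5)
    tcs = [select_copy_model(_call(0.5, gene="MEN1"), meta) for _ in range(8)]
    out = gene_enrichment(tcs).set_index("gene")
    men1 = out.loc["MEN1"]
    assert men1["n_early"] == 8
    assert men1["p_bonferroni"] == pytest.approx(min(1.0, men1["p_raw"] * 3))


def test_read_mutation_table_maf_aliases(tmp_path):
    path = tmp_path / "muts.tsv"
    path.write_text(
        "Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\tt_alt_count\tt_depth\n"
        "S1\tMEN1\t11\t64570000\t50\t100\n")
    (call,) = read_mutation_table(path)
    assert (call.sample_id, call.gene, call.af_obs, call.depth) == ("S1", "MEN1", 0.5, 100)
    assert call.is_mad
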