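"""Copy/zygosity calling, motifs, concordance, karyotype groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panetsig.cnstate import (BinnedCounts, HET, LOH, Segment, SegmentProfile,
                              call_chromosome_states, ci_stratum,
                              classify_scarpa_group, cohort_motif,
                              genome_state_fractions, jaccard_concordance,
                              jaccard_index, purity_adjusted_af, read_seg,
                              signature_cooccurrence, write_seg)
from panetsig.timing import expected_observed_af


# ---------------------------------------------------------------------------
# purity-adjusted AF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("af_obs, purity, cn, expected", [
    (0.5, 1.0, 2, 0.5),    # full purity: identity
    (0.75, 0.5, 2, 1.0),   # hand-checked closed form
    (0.5, 0.3, 2, 0.5),    # balanced site is a fixed point at any purity
    (0.5, 0.7, 2, 0.5),
])
def test_purity_adjusted_af_examples(af_obs, purity, cn, expected):
    assert purity_adjusted_af(af_obs, purity, cn) == pytest.approx(expected)


def test_purity_adjusted_af_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        purity_adjusted_af(0.5, 0.5, 0)
    with pytest.raises(ValueError):
        purity_adjusted_af(0.5, 0.0, 2)


@settings(max_examples=200, deadline=None)
@given(st.floats(0.05, 1.0), st.integers(1, 6), st.integers(0, 6))
def test_purity_adjusted_af_inverts_forward_mixture(purity, total_cn, k):
    """adjust(forward(af_t)) = af_t to 1e-12 on the germline-het mixture."""
    k = min(k, total_cn)
    af_t = k / total_cn
    mix = purity * total_cn + 2 * (1 - purity)
    af_obs = (purity * k + (1 - purity)) / mix
    assert purity_adjusted_af(af_obs, purity, total_cn) == pytest.approx(af_t, abs=1e-12)


# ---------------------------------------------------------------------------
# chromosome state calling
# ---------------------------------------------------------------------------

def _noiseless_bins(states: dict[str, tuple[int, int]], purity: float,
                    density: float = 100.0, lam: float = 1000.0,
                    n_bins: int = 60, snp_depth: int = 60) -> BinnedCounts:
    from panetsig.cnstate import het_call_probability, mixture_copy_ratio
    rows = []
    for chrom, (total, minor) in states.items():
        mix = purity * total + 2 * (1 - purity)
        af_het = (purity * minor + (1 - purity)) / mix
        retention = het_call_probability(af_het, snp_depth)
        reads = lam * mixture_copy_ratio(purity, total)
        for i in range(n_bins):
            rows.append((chrom, i * 500_000, (i + 1) * 500_000,
                         int(round(reads)), int(round(density * retention))))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count", "het_snp_count"])
    return BinnedCounts("t", bins, 500_000, density)


def test_noiseless_pure_tumor_states_are_exact():
    states = {"chr1": (2, 0), "chr2": (2, 1), "chr3": (1, 0), "chr4": (3, 1)}
    binned = _noiseless_bins(states, purity=1.0)
    prof = call_chromosome_states(binned, 1.0)
    called = {s.chrom: (s.total_cn, s.zygosity) for s in prof.segments}
    assert called == {"chr1": (2, LOH), "chr2": (2, HET),
                      "chr3": (1, LOH), "chr4": (3, HET)}


def test_zero_het_chromosome_called_loh_at_full_purity():
    binned = _noiseless_bins({"chr3": (2, 0), "chr1": (2, 1)}, purity=1.0)
    prof = call_chromosome_states(binned, 1.0)
    assert prof.chromosome_state("chr3").zygosity == LOH


def test_full_retention_everywhere_called_het():
    binned = _noiseless_bins({f"chr{i}": (2, 1) for i in range(1, 6)}, purity=0.8)
    prof = call_chromosome_states(binned, 0.8)
    assert all(s.zygosity == HET for s in prof.segments)


def test_low_purity_emits_warning_flag():
    binned = _noiseless_bins({"chr1": (2, 1)}, purity=0.25)
    prof = call_chromosome_states(binned, 0.25)
    assert any("obscured" in w for w in prof.warnings)


# ---------------------------------------------------------------------------
# cohort motif
# ---------------------------------------------------------------------------

def _profile(sample_id, states):
    return SegmentProfile(sample_id, [
        Segment(c, 0, 10_000_000, t, m) for c, (t, m) in states.items()])


def test_cohort_motif_modal_and_ties():
    loh = {"chr1": (2, 0)}
    het = {"chr1": (2, 1)}
    profs = [_profile(f"s{i}", loh) for i in range(3)]
    m = cohort_motif(profs).table.iloc[0]
    assert (m["modal_zygosity"], m["zygosity_freq"]) == (LOH, 1.0)
    tie = cohort_motif([_profile("a", loh), _profile("b", loh),
                        _profile("c", het), _profile("d", het)]).table.iloc[0]
    assert tie["zygosity_multimodal"] and set(tie["modal_zygosity"].split("/")) == {HET, LOH}


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def test_cooccurrence_phi_extremes_and_independence(rng):
    profs = []
    for i in range(40):
        together = i < 20
        states = {"chr1": (2, 0) if together else (2, 1),
                  "chr2": (2, 0) if together else (2, 1),    # identical to chr1
                  "chr3": (2, 1) if together else (2, 0),    # complementary
                  "chr4": (2, 0) if rng.random() < 0.5 else (2, 1)}  # independent
        profs.append(_profile(f"s{i}", states))
    amat, flags = signature_cooccurrence(profs, min_support=3)
    assert amat.loc["chr1:LOH", "chr2:LOH"] == pytest.approx(1.0)
    assert amat.loc["chr1:LOH", "chr3:LOH"] == pytest.approx(-1.0)
    assert abs(amat.loc["chr1:LOH", "chr4:LOH"]) < 0.5  # CI contains 0 at this n
    f = flags.set_index(["a", "b"])
    assert f.loc[("chr1:LOH", "chr2:LOH"), "flag"] == "synchronous"
    assert f.loc[("chr1:LOH", "chr3:LOH"), "flag"] == "antagonistic"


# ---------------------------------------------------------------------------
# Jaccard concordance
# ---------------------------------------------------------------------------

def _brute_jaccard(a: pd.Series, b: pd.Series) -> float:
    inter = union = 0
    for band in set(a.index) | set(b.index):
        sa, sb = a.get(band, "neutral"), b.get(band, "neutral")
        if sa != "neutral" or sb != "neutral":
            union += 1
            if sa == sb:
                inter += 1
    return inter / union if union else 1.0


def test_jaccard_examples():
    a = pd.Series({1: "loss", 2: "loss", 3: "loss", 4: "neutral"})
    b = pd.Series({1: "loss", 2: "loss", 3: "neutral", 4: "neutral", 5: "loss"})
    assert jaccard_index(a, a) == 1.0
    assert jaccard_index(a, b) == pytest.approx(2 / 4)
    disjoint = pd.Series({1: "neutral", 2: "neutral", 6: "gain"})
    assert jaccard_index(a, disjoint) == 0.0


@settings(max_examples=100, deadline=None)
@given(st.lists(st.sampled_from(["loss", "neutral", "gain"]), min_size=20, max_size=20),
       st.lists(st.sampled_from(["loss", "neutral", "gain"]), min_size=20, max_size=20))
def test_jaccard_matches_brute_force_and_is_symmetric(sa, sb):
    a = pd.Series(sa, index=range(20))
    b = pd.Series(sb, index=range(20))
    assert jaccard_index(a, b) == pytest.approx(_brute_jaccard(a, b))
    assert jaccard_index(a, b) == pytest.approx(jaccard_index(b, a))


def test_jaccard_concordance_on_profiles(genome):
    sig = {c: (2, 0) for c in ["chr1", "chr2"]}
    a = _profile("a", {**sig, "chr4": (3, 1)})
    b = _profile("b", {**sig, "chr4": (3, 1)})
    c = _profile("c", {"chr5": (1, 0)})
    assert jaccard_concordance(a, b, genome) == 1.0
    assert jaccard_concordance(a, c, genome) == 0.0


# ---------------------------------------------------------------------------
# karyotype groups and CI strata
# ---------------------------------------------------------------------------

def test_scarpa_groups_from_definitions(genome):
    diploid = _profile("d", {c: (2, 1) for c in genome.chromosomes})
    assert classify_scarpa_group(diploid) == "G2"
    sizes = {c: genome.chrom_length(c) for c in genome.chromosomes}
    total = sum(sizes.values())
    losses, acc = {}, 0
    for c in sorted(sizes, key=sizes.get, reverse=True):
        losses[c] = (1, 0) if acc < 0.6 * total else (2, 1)
        acc += sizes[c] if losses[c][0] == 1 else 0
    lossy = SegmentProfile("l", [Segment(c, 0, sizes[c], t, m)
                                 for c, (t, m) in losses.items()])
    assert classify_scarpa_group(lossy) == "G1"
    gained = SegmentProfile("g", [Segment(c, 0, sizes[c], 4, 2) for c in sizes])
    assert classify_scarpa_group(gained) == "G3"
    mixed = SegmentProfile("m", [
        Segment(c, 0, sizes[c], 2, 0) if i % 2 else Segment(c, 0, sizes[c], 4, 2)
        for i, c in enumerate(sizes)])
    assert classify_scarpa_group(mixed) == "G4"


def test_ci_stratum_threshold(genome):
    sizes = {c: genome.chrom_length(c) for c in genome.chromosomes}
    flat = SegmentProfile("f", [Segment(c, 0, sizes[c], 2, 1) for c in sizes])
    assert ci_stratum(flat) == "low-CI"
    big = SegmentProfile("b", [
        Segment(c, 0, sizes[c], 2, 0 if c in ("chr1", "chr2", "chr3") else 1)
        for c in sizes])
    assert ci_stratum(big, threshold=0.2) == "high-CI"
    assert ci_stratum(big, threshold=0.5) == "low-CI"


def test_seg_round_trip(tmp_path):
    profs = [_profile("s1", {"chr1": (2, 0), "chr2": (4, 2)}),
             _profile("s2", {"chr1": (2, 1)})]
    path = tmp_path / "out.seg"
    write_seg(profs, path)
    back = read_seg(path)
    assert [(p.sample_id, [(s.chrom, s.total_cn, s.minor_cn, s.zygosity)
                           for s in p.segments]) for p in back] == \
           [(p.sample_id, [(s.chrom, s.total_cn, s.minor_cn, s.zygosity)
                           for s in p.segments]) for p in profs]
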