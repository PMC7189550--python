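"""CENP-A peak partitioning, RPKM, KS statistics, mis-segregation correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panetsig.chip import (band_ks, classify_peaks, compare_maintained_heights,
                           cytoband_peak_stats, missegregation_correlations,
                           pericen_peak_level, read_peaks, rpkm)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "height"])


def test_identical_peak_sets_all_maintained():
    p = _peaks([("chr1", 100, 200, 5.0), ("chr2", 50, 80, 3.0)])
    parts = classify_peaks(p, p.copy())
    assert parts["acquired"].empty and parts["lost"].empty
    assert len(parts["maintained"]) == 4  # both sources retained


def test_disjoint_sets_split_into_acquired_and_lost():
    dep = _peaks([("chr1", 0, 10, 1.0)])
    ctl = _peaks([("chr1", 20, 30, 1.0)])
    parts = classify_peaks(dep, ctl)
    assert len(parts["acquired"]) == 1 and len(parts["lost"]) == 1
    assert parts["maintained"].empty


def test_single_base_overlap_counts_as_maintained():
    dep = _peaks([("chr1", 0, 101, 1.0)])
    ctl = _peaks([("chr1", 100, 200, 1.0)])
    parts = classify_peaks(dep, ctl)
    assert parts["acquired"].empty and parts["lost"].empty
    # half-open adjacency is NOT an overlap
    parts2 = classify_peaks(_peaks([("chr1", 0, 100, 1.0)]), ctl)
    assert len(parts2["acquired"]) == 1


def test_partition_is_exhaustive(rng):
    dep = _peaks([("chr1", int(s), int(s) + 50, 1.0)
                  for s in rng.integers(0, 10_000, 30)])
    ctl = _peaks([("chr1", int(s), int(s) + 50, 1.0)
                  for s in rng.integers(0, 10_000, 30)])
    parts = classify_peaks(dep, ctl)
    n_dep = len(parts["acquired"]) + (parts["maintained"]["source"] == "depleted").sum()
    n_ctl = len(parts["lost"]) + (parts["maintained"]["source"] == "control").sum()
    assert (n_dep, n_ctl) == (30, 30)


def test_welch_t_on_maintained_heights():
    maintained = pd.DataFrame({
        "height": [5, 6, 7, 1, 1.5, 2.0],
        "source": ["depleted"] * 3 + ["control"] * 3})
    t, p = compare_maintained_heights(maintained)
    assert t > 0 and p < 0.05


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def test_rpkm_formula_and_scaling(genome):
    band = genome.bands["chr1"][0]
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [band.start],
                          "end": [band.start + 1000], "height": [1.0],
                          "reads": [1000]})
    out = rpkm(peaks, genome, total_mapped_reads=1e6)
    assert out.iloc[0] == pytest.approx(1000.0)
    assert rpkm(peaks, genome, 2e6).iloc[0] == pytest.approx(500.0)
    zero = rpkm(peaks.assign(reads=0), genome, 1e6)
    assert zero.iloc[0] == 0.0


def test_rpkm_invariant_to_peak_splitting(genome):
    band = genome.bands["chr2"][1]
    whole = pd.DataFrame({"chrom": ["chr2"], "start": [band.start],
                          "end": [band.start + 2000], "height": [1.0], "reads": [600]})
    halves = pd.DataFrame({
        "chrom": ["chr2", "chr2"],
        "start": [band.start, band.start + 1000],
        "end": [band.start + 1000, band.start + 2000],
        "height": [1.0, 1.0], "reads": [300, 300]})
    a = rpkm(whole, genome, 1e6)
    b = rpkm(halves, genome, 1e6)
    assert a.iloc[0] == pytest.approx(b.iloc[0])


# ---------------------------------------------------------------------------
# KS statistic
# ---------------------------------------------------------------------------

def _brute_ks(a, b):
    grid = np.concatenate([a, b])
    gaps = [abs((a <= v).mean() - (b <= v).mean()) for v in grid]
    return max(gaps)


def test_band_ks_extremes():
    same = np.array([1.0, 2.0, 3.0])
    assert band_ks(same, same) == 0.0
    assert band_ks(np.array([10.0, 11.0]), np.array([1.0, 2.0, 3.0])) == 1.0
    with pytest.raises(ValueError):
        band_ks(np.array([]), same)


def test_band_ks_hand_enumerated():
    band = np.array([1.0, 4.0, 6.0])
    genome_vals = np.array([1.0, 2.0, 3.0, 5.0, 7.0])
    assert band_ks(band, genome_vals) == pytest.approx(_brute_ks(band, genome_vals))


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=20),
       st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=20))
def test_band_ks_matches_brute_force(a, b):
    a, b = np.array(a), np.array(b)
    assert band_ks(a, b) == pytest.approx(_brute_ks(a, b), abs=1e-12)


def test_cytoband_peak_stats_schema(genome, rng):
    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": rng.integers(0, 100_000_000, 40),
        "height": rng.gamma(3, 2, 40)})
    peaks["end"] = peaks["start"] + 2000
    out = cytoband_peak_stats(peaks, genome)
    assert {"chrom", "band", "n_peaks", "coverage_bp", "ks_d"} <= set(out.columns)
    assert out["n_peaks"].sum() == 40
    assert ((out["ks_d"] >= 0) & (out["ks_d"] <= 1)).all()


# ---------------------------------------------------------------------------
# mis-segregation correlations
# ---------------------------------------------------------------------------

def test_point_biserial_zero_when_groups_match(genome):
    table = pd.DataFrame({
        "chrom": [f"chr{i}" for i in range(1, 9)],
        "missegregation_fraction": [0.1, 0.3, 0.1, 0.3, 0.1, 0.3, 0.1, 0.3],
        "loh_member": [True, True, False, False, True, True, False, False]})
    out = missegregation_correlations(table, table[["chrom"]].assign(dummy=np.arange(8.0)))
    pb = out[out["method"] == "point-biserial"].iloc[0]
    assert abs(pb["r"]) < 1e-9


def test_perfectly_linear_feature_gives_r_one():
    table = pd.DataFrame({
        "chrom": [f"chr{i}" for i in range(1, 11)],
        "missegregation_fraction": np.linspace(0.05, 0.5, 10),
        "loh_member": [True] * 5 + [False] * 5})
    feats = pd.DataFrame({"chrom": table["chrom"],
                          "cen_size": np.linspace(1e6, 5e6, 10)})
    out = missegregation_correlations(table, feats)
    assert out[out["feature"] == "cen_size"]["r"].iloc[0] == pytest.approx(1.0)


def test_injected_correlation_recovered_on_average():
    target = 0.6
    estimates = []
    for seed in range(300):
        r = np.random.default_rng(seed)
        x = r.normal(size=22)
        y = target * x + np.sqrt(1 - target**2) * r.normal(size=22)
        table = pd.DataFrame({"chrom": [f"chr{i}" for i in range(22)],
                              "missegregation_fraction": y,
                              "loh_member": [True] * 11 + [False] * 11})
        feats = pd.DataFrame({"chrom": table["chrom"], "feat": x})
        out = missegregation_correlations(table, feats)
        estimates.append(out[out["feature"] == "feat"]["r"].iloc[0])
    assert np.mean(estimates) == pytest.approx(target, abs=0.05)


def test_pericen_peak_level_only_counts_flank_peaks(genome):
    arm = genome.arms[("chr1", "q")]
    inside = (arm.centromere_boundary + 10, arm.centromere_boundary + 2010)
    outside = (arm.arm_end - 10_000, arm.arm_end - 8000)
    peaks = pd.DataFrame({"chrom": ["chr1", "chr1"],
                          "start": [inside[0], outside[0]],
                          "end": [inside[1], outside[1]],
                          "height": [7.0, 99.0]})
    levels = pericen_peak_level(peaks, genome)
    assert levels["chr1"] == pytest.approx(7.0)


def test_read_peaks_bed(tmp_path):
    path = tmp_path / "p.bed"
    path.write_text("1\t100\t200\t4.5\t33\nchr2\t5\t50\t2.0\t10\n")
    df = read_peaks(path)
    assert list(df["chrom"]) == ["chr1", "chr2"]
    assert list(df.columns) == ["chrom", "start", "end", "height", "reads"]
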