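"""Genome scan: per-SNP FST track, region delineation, haplotype
classification, frequencies, unplaced-scaffold assignment and depth masks."""

import numpy as np
import pandas as pd
import pytest

from hapblock import blockscan, popstats
from hapblock.blockscan import HaplotypeCall, RegionCall
from hapblock.iolayer import DepthTable

from conftest import make_vm, region_for_block


def _track(pos, fst, chrom="7"):
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "a": fst, "b": 0.0,
                       "c": 0.0, "fst": fst})
    # keep a + b + c proportional so ratio-of-sums is a weighted mean
    df["b"] = 1.0 - df["a"]
    return blockscan.FstTrack(df=df, genome_fst=float(np.nanmean(fst)),
                              n_defined=len(pos))


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def test_delineate_toy_cluster():
    t = _track([5, 10, 20, 40], [0.1, 0.6, 0.7, 0.9])
    regions = blockscan.delineate_regions(t, threshold=0.5, merge_gap=100)
    assert len(regions) == 1
    r = regions[0]
    assert (r.first_outlier_pos, r.last_outlier_pos) == (10, 40)
    assert r.length == 31 and r.n_outliers == 3 and r.n_snps == 3


def test_delineate_inclusive_length_printed_bounds():
    t = _track([1_511_853, 1_533_141], [0.8, 0.9])
    r = blockscan.delineate_regions(t)[0]
    assert r.length == 21_289


def test_delineate_no_outliers_empty():
    t = _track([5, 10], [0.1, 0.2])
    assert blockscan.delineate_regions(t) == []


def test_delineate_merge_gap_splits():
    t = _track([10, 20, 5000, 5010], [0.9, 0.9, 0.9, 0.9])
    assert len(blockscan.delineate_regions(t, merge_gap=100)) == 2
    assert len(blockscan.delineate_regions(t, merge_gap=10_000)) == 1


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_scan_fixed_block_and_permutation(small_bundle):
    vm, table = small_bundle.vm, small_bundle.samples
    ih, il = table.habitat_partition(vm)
    track = blockscan.persite_fst_scan(vm, ih, il)
    # permuting the group labels destroys the genome-wide signal
    rng = np.random.default_rng(0)
    allidx = rng.permutation(np.concatenate([ih, il]))
    perm = blockscan.persite_fst_scan(vm, allidx[:len(ih)], allidx[len(ih):])
    assert abs(perm.genome_fst) < 0.02 < track.genome_fst


def test_scan_background_only_matches_target():
    """Background-only dataset: genome-wide FST within ±0.005 of the 0.036
    generator target."""
    from hapblock import synthgen

    cfg = synthgen.default_config()
    cfg.blocks = []
    cfg.chrom_lengths = {"1": 1_500_000}
    cfg.coding_fraction = 0.0
    bundle = synthgen.generate(cfg, 77)
    ih, il = bundle.samples.habitat_partition(bundle.vm)
    track = blockscan.persite_fst_scan(bundle.vm, ih, il)
    assert track.genome_fst == pytest.approx(0.036, abs=0.005)
    assert blockscan.delineate_regions(track) == [] \
        or all(r.n_outliers <= 2 for r in blockscan.delineate_regions(track))


def test_scan_all_fixed_snps_theta_one():
    geno = np.array([[2, 2, 0, 0]] * 4)
    vm = make_vm(geno)
    track = blockscan.persite_fst_scan(vm, [0, 1], [2, 3])
    assert np.allclose(track.df["fst"], 1.0)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def test_histogram_single_bin():
    t = _track(np.arange(1, 11), [0.82] * 10)
    h = blockscan.fst_histogram(t)
    row = h[np.isclose(h["bin_low"], 0.80)]
    assert row["genome"].iloc[0] == 10
    assert h["genome"].sum() == 10


def test_histogram_region_stratification(scan_results, small_bundle):
    track, regions, _ = scan_results
    h = blockscan.fst_histogram(track, regions=regions)
    r7 = region_for_block(regions, small_bundle.truth.blocks[0])
    # outlier SNPs of the r7-like block concentrate in a single high bin
    col = h[r7.region_id]
    high = h[h["bin_low"] >= 0.5]
    assert col[high.index].max() > 0.5 * col[high.index].sum() > 0


def test_histogram_bad_bin_width():
    t = _track([1], [0.5])
    with pytest.raises(ValueError):
        blockscan.fst_histogram(t, bin_width=0.3)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _call(n00, n01, n11):
    return HaplotypeCall(sample_id="s", region_id="r", n00=n00, n01=n01,
                         n11=n11, n_missing=0)


@pytest.mark.parametrize("counts,expect_cls,expect_dosage", [
    ((2, 90, 8), "het", 1),
    ((0, 2, 98), "hom_alt", 2),
    ((98, 2, 0), "hom_ref", 0),
    ((40, 20, 40), "ambiguous", 0),   # majority tie -> first, flagged
    ((0, 0, 0), "ambiguous", -1),
])
def test_classify_examples(counts, expect_cls, expect_dosage):
    out = blockscan.classify_haplotypes([_call(*counts)])[0]
    assert out.cls == expect_cls
    assert out.dosage == expect_dosage
    if counts == (40, 20, 40):
        assert out.tie


def test_classify_monotone_in_n11():
    """Increasing n11 at fixed total never moves a hom_alt call away."""
    total = 100
    seen_hom = False
    for n11 in range(0, total + 1, 5):
        rest = total - n11
        out = blockscan.classify_haplotypes(
            [_call(rest // 2, rest - rest // 2, n11)])[0]
        if seen_hom:
            assert out.cls == "hom_alt"
        seen_hom = seen_hom or out.cls == "hom_alt"
    assert seen_hom


def test_haplotype_frequency_arithmetic(small_bundle):
    calls = [HaplotypeCall(sample_id=s, region_id="r", n00=0, n01=0,
                           n11=10, cls="hom_alt", dosage=d, n_missing=0)
             for s, d in zip(small_bundle.vm.sample_ids[:20],
                             [2] * 18 + [1] + [0])]
    table = small_bundle.samples
    sub = table.df[table.df["sample"].isin([c.sample_id for c in calls])]
    freqs = blockscan.haplotype_frequencies(calls, table, "habitat")
    got = freqs.set_index("group")["frequency"]
    # 18 x dosage2 + 1 + 0 over 2*20 copies
    assert got.sum() * 0 + (37 / 40) == pytest.approx(
        (freqs["frequency"] * freqs["n_samples"]).sum()
        / freqs["n_samples"].sum(), abs=1e-9)


def test_region_fst_from_dosage_equals_site_estimator():
    calls = []
    # 20 vs 19 diploids with p = (0.95, 0.10526) and het = (0.10, 0.10526)
    dosages_a = [2] * 18 + [1, 1]
    dosages_b = [0] * 16 + [1, 1, 2]
    for i, d in enumerate(dosages_a):
        calls.append(HaplotypeCall(f"a{i}", "r", 0, 0, 0, 0, "hom_alt", d))
    for i, d in enumerate(dosages_b):
        calls.append(HaplotypeCall(f"b{i}", "r", 0, 0, 0, 0, "hom_ref", d))
    ids_a = [f"a{i}" for i in range(20)]
    ids_b = [f"b{i}" for i in range(19)]
    res = blockscan.region_fst_from_dosage(calls, ids_a, ids_b)
    da = np.array(dosages_a, float)
    db = np.array(dosages_b, float)
    oracle = popstats.wc_fst_site(
        [da.sum() / (2 * 20), db.sum() / (2 * 19)],
        [(da == 1).mean(), (db == 1).mean()], [20, 19])
    assert res.theta_hat == oracle.theta_hat  # exact equality
    assert res.theta_hat == pytest.approx(0.830, abs=0.02)


def test_region_fst_extremes():
    calls = ([HaplotypeCall(f"a{i}", "r", 0, 0, 0, 0, "hom_alt", 2)
              for i in range(5)]
             + [HaplotypeCall(f"b{i}", "r", 0, 0, 0, 0, "hom_ref", 0)
                for i in range(5)])
    r = blockscan.region_fst_from_dosage(
        calls, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)])
    assert r.theta_hat == pytest.approx(1.0)
    same = [HaplotypeCall(f"x{i}", "r", 0, 0, 0, 0, "het", 1)
            for i in range(10)]
    r0 = blockscan.region_fst_from_dosage(
        same, [f"x{i}" for i in range(5)], [f"x{i}" for i in range(5, 10)])
    assert r0.theta_hat == pytest.approx(0.0, abs=1e-12)
    mono = [HaplotypeCall(f"y{i}", "r", 0, 0, 0, 0, "hom_ref", 0)
            for i in range(10)]
    with pytest.raises(ValueError):
        blockscan.region_fst_from_dosage(
            mono, [f"y{i}" for i in range(5)],
            [f"y{i}" for i in range(5, 10)])


# ---------------------------------------------------------------------------
# unplaced scaffolds
# ---------------------------------------------------------------------------

def test_assign_unplaced_mirrored_scaffold(small_bundle, scan_results):
    vm = small_bundle.vm
    track, regions, calls = scan_results
    r7 = region_for_block(regions, small_bundle.truth.blocks[0])
    ref_calls = {r7.region_id: calls[r7.region_id]}
    out = blockscan.assign_unplaced(vm, track, ref_calls, ["GroupUn1"])
    row = out.iloc[0]
    assert row["assigned"] == r7.region_id
    assert row["concordance"] == pytest.approx(1.0, abs=0.06)


def test_assign_unplaced_min_snps(small_bundle, scan_results):
    vm = small_bundle.vm
    track, regions, calls = scan_results
    r7 = region_for_block(regions, small_bundle.truth.blocks[0])
    out = blockscan.assign_unplaced(
        vm, track, {r7.region_id: calls[r7.region_id]}, ["GroupUn1"],
        min_snps=10 ** 6)
    assert out.iloc[0]["assigned"] == "unassigned"


def test_assign_unplaced_background_chrom_unassigned(small_bundle,
                                                     scan_results):
    """A background-only chromosome has (almost) no outliers and cannot be
    assigned."""
    vm = small_bundle.vm
    track, regions, calls = scan_results
    r7 = region_for_block(regions, small_bundle.truth.blocks[0])
    out = blockscan.assign_unplaced(
        vm, track, {r7.region_id: calls[r7.region_id]}, ["1"], min_snps=3)
    assert out.iloc[0]["assigned"] == "unassigned"


# ---------------------------------------------------------------------------
# depth masking
# ---------------------------------------------------------------------------

def _depth_df(vm, high, low):
    return DepthTable(pd.DataFrame({
        "chrom": [vm.chrom_ids[c] for c in vm.chrom], "pos": vm.pos,
        "depth_highland": high, "depth_lowland": low,
        "called_frac": (vm.geno != -1).mean(axis=1),
    }))


def test_depth_mask_uniform_keeps_all():
    vm = make_vm(np.zeros((10, 4)))
    d = _depth_df(vm, [9.2] * 10, [9.2] * 10)
    out, report = blockscan.depth_mask(vm, d)
    assert out.n_sites == 10 and report["retained_fraction"] == 1.0


def test_depth_mask_extreme_site_removed():
    vm = make_vm(np.zeros((10, 4)))
    high = [9.2] * 10
    high[3] = 92.0  # 10x the average
    d = _depth_df(vm, high, [9.2] * 10)
    out, report = blockscan.depth_mask(vm, d, high_frac=3.0)
    assert out.n_sites == 9 and report["n_masked_depth"] == 1


def test_depth_mask_commutes_with_scan(small_bundle):
    """Masking then scanning equals scanning then restricting to retained
    sites."""
    from hapblock import blockscan as bs

    vm, table = small_bundle.vm, small_bundle.samples
    ih, il = table.habitat_partition(vm)
    masked, _ = bs.depth_mask(vm, small_bundle.depth)
    t1 = bs.persite_fst_scan(masked, ih, il)
    t0 = bs.persite_fst_scan(vm, ih, il)
    keys = set(zip(masked.chrom.tolist(), masked.pos.tolist()))
    keep = [(c, p) in keys for c, p in zip(vm.chrom.tolist(),
                                           vm.pos.tolist())]
    sub = t0.df[keep].reset_index(drop=True)
    assert np.allclose(sub["fst"].to_numpy(), t1.df["fst"].to_numpy(),
                       equal_nan=True)


def test_depth_mask_highland_depression(small_bundle):
    """The generator depresses highland depth over block sites, so the
    highland retained fraction inside a block is lower than lowland's."""
    from hapblock.blockscan import retained_fraction_by_group

    bt = small_bundle.truth.blocks[0]
    region = RegionCall(region_id="r7", chrom=bt.chrom,
                        first_outlier_pos=bt.start,
                        last_outlier_pos=bt.end, n_snps=0, n_outliers=1,
                        region_fst=np.nan, region_fst_mean=np.nan)
    vm = small_bundle.vm
    masked, _ = blockscan.depth_mask(vm, small_bundle.depth)
    fracs = retained_fraction_by_group(vm, masked, small_bundle.depth,
                                       region)
    assert fracs["highland"] < fracs["lowland"]
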