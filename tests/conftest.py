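import numpy as np
import pytest

from hapblock import synthgen
from hapblock.iolayer import VariantMatrix


def make_vm(geno, pos=None, chrom="1", ref=None, alt=None, qual=None,
            sample_ids=None, chrom_ids=None):
    """Build a single-chromosome VariantMatrix from a dosage array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1)
    if chrom_ids is None:
        chrom_ids = [chrom]
    vm = VariantMatrix(
        chrom_ids=chrom_ids,
        chrom=np.full(n_sites, chrom_ids.index(chrom), np.int32),
        pos=np.asarray(pos, np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, "U1"),
        alt=np.asarray(alt if alt is not None else ["T"] * n_sites, "U1"),
        geno=geno,
        qual=np.asarray(qual if qual is not None else [100.0] * n_sites,
                        float),
        sample_ids=(sample_ids if sample_ids is not None
                    else [f"s{i}" for i in range(n_samples)]),
    )
    vm.validate()
    return vm


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic dataset shared across tests."""
    return synthgen.generate(synthgen.small_config(), 2024)


@pytest.fixture(scope="session")
def emitted_bundle(tmp_path_factory):
    """The same dataset written to files and its path map."""
    out = tmp_path_factory.mktemp("synth")
    paths = synthgen.emit(synthgen.small_config(), 2024, out)
    return paths


@pytest.fixture(scope="session")
def scan_results(small_bundle):
    """FST track, regions (fine granularity) and per-region classified
    haplotype calls for the shared bundle."""
    from hapblock import blockscan

    vm, table = small_bundle.vm, small_bundle.samples
    ih, il = table.habitat_partition(vm)
    track = blockscan.persite_fst_scan(vm, ih, il)
    regions = blockscan.delineate_regions(track, merge_gap=10_000)
    calls = {
        r.region_id: blockscan.classify_haplotypes(
            blockscan.genotype_composition(vm, r))
        for r in regions
    }
    return track, regions, calls


def region_for_block(regions, block_truth):
    """The delineated region with the most outliers overlapping a truth
    block (strays can form separate tiny regions)."""
    cands = [r for r in regions
             if r.chrom == block_truth.chrom
             and r.first_outlier_pos <= block_truth.end
             and r.last_outlier_pos >= block_truth.start]
    assert cands, f"no region recovered for {block_truth.block_id}"
    return max(cands, key=lambda r: r.n_outliers)
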