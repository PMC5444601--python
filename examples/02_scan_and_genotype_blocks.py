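"""Scan a synthetic panel for divergent haplotype blocks and genotype them.

Generates a 39-sample, four-population dataset with two embedded
non-recombining blocks, runs the per-SNP Weir–Cockerham FST scan between
habitat groups, delineates outlier regions and classifies every sample as
homozygous (either haplotype) or heterozygous from its genotype
composition.
"""

from hapblock import blockscan, synthgen

bundle = synthgen.generate(synthgen.small_config(), seed=7)
vm, table = bundle.vm, bundle.samples
ih, il = table.habitat_partition(vm)

track = blockscan.persite_fst_scan(vm, ih, il)
print(f"genome-wide FST (ratio of sums): {track.genome_fst:.4f}")
print(f"fraction of SNPs with FST < 0.1: {track.frac_below(0.1):.3f}")

regions = blockscan.delineate_regions(track, merge_gap=10_000)
for r in regions:
    if r.n_outliers < 20:
        continue  # stray single-SNP outliers
    calls = blockscan.classify_haplotypes(
        blockscan.genotype_composition(vm, r))
    freqs = blockscan.haplotype_frequencies(calls, table, "habitat")
    fst = blockscan.region_fst_from_dosage(
        calls, [vm.sample_ids[i] for i in ih],
        [vm.sample_ids[i] for i in il])
    fr = {row["group"]: row["frequency"] for _, row in freqs.iterrows()}
    print(f"\nregion {r.region_id}: {r.first_outlier_pos:,}-"
          f"{r.last_outlier_pos:,} ({r.length:,} bp, "
          f"{r.n_outliers} outlier SNPs)")
    print(f"  highland-haplotype frequency: highland {fr['highland']:.2f}, "
          f"lowland {fr['lowland']:.2f}")
    print(f"  region FST from block dosages: {fst.theta_hat:.3f}")

print("\nEach block behaves as one Mendelian locus: samples are cleanly "
      "homozygous or heterozygous across thousands of SNPs, and the "
      "haplotype frequencies separate the habitat groups far more strongly "
      "than any background SNP.")
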