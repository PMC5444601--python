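# hapblock

Population-genomic analysis of extended, non-recombining haplotype blocks —
the kind of megabase-scale polymorphisms (often inversions) that keep two
deeply diverged haplotypes segregating at contrasting frequencies between
environments, as seen between highland and lowland East African honey bee
populations.

Given a multi-sample VCF of biallelic SNPs, sample metadata
(locality / habitat / altitude / population), gene models, and an
outgroup-allele table, the package:

1. estimates diversity and divergence — π, Watterson's θ_w, dXY,
   per-SNP Weir–Cockerham F_ST and Reynolds F_ST distance matrices;
2. scans the genome for divergent blocks: outlier SNPs (F_ST > 0.5) are
   clustered into regions, and each sample is genotyped for the whole block
   from its genotype composition at outlier SNPs (homozygous for either
   haplotype, or heterozygous across the entire run);
3. tests whether the observed haplotype-frequency differentiation could
   arise by drift, using a coalescent clean-split null
   (`ms 78 R -I 2 40 38 -ej T 2 1 -s 1` semantics, hand-written engine);
4. dates the haplotype divergence with a molecular clock on dXY at
   non-genic sites, with window-bootstrap confidence intervals;
5. polarizes fixed differences with the outgroup, assigns each derived
   change to the haplotype branch it arose on, and compares per-branch
   non-synonymous fractions (Fisher's exact test);
6. generates fully synthetic datasets with machine-readable truth
   (`hapblock.synthgen`), so every stage above can be scored against known
   parameters.

## The statistics

With per-site alt-allele frequency *p*, observed heterozygote fraction *h*
and diploid sample sizes *n_i* per population, the Weir–Cockerham (1984)
variance components *a* (among populations), *b* (among individuals) and
*c* (within individuals) give the per-SNP estimate θ̂ = a/(a+b+c); sites
are combined as Σa / Σ(a+b+c). Nucleotide diversity uses the Nei–Li
allele-count form π = Σ 2p(1−p)·2n/(2n−1) / L, and
dXY = Σ [p_X(1−p_Y) + p_Y(1−p_X)] / L. A clean two-population split
at scaled time T (units of 4N₀ generations) implies F_ST = 1 − e^(−2T),
inverted as T = −ln(1−F_ST)/2; for F_ST = 0.036, T = 0.01833. Divergence
dates as t = dXY / (2μ) generations with μ = 5.27×10⁻⁹ /bp/generation, and
effective sizes as N_E = θ_w / (3μ) — the haplodiploid inheritance scalar
3 replaces the diploid 4.

## Worked example

`examples/` holds one short script per capability. Scanning a synthetic
panel (39 diploids, four populations, two embedded blocks) and genotyping
the blocks:

```
$ python examples/02_scan_and_genotype_blocks.py
genome-wide FST (ratio of sums): 0.3725
fraction of SNPs with FST < 0.1: 0.741

region r7.1: 100,139-219,976 (119,838 bp, 3574 outlier SNPs)
  highland-haplotype frequency: highland 1.00, lowland 0.08
  region FST from block dosages: 0.921

region r9: 120,204-259,988 (139,785 bp, 874 outlier SNPs)
  highland-haplotype frequency: highland 0.95, lowland 0.21
  region FST from block dosages: 0.712
...
```

The scan finds both embedded blocks at their true bounds; each behaves as
one Mendelian locus whose haplotype frequencies separate the habitat
groups (dosage-level F_ST 0.92 and 0.71) far beyond anything in the
background. Dating the deeper block
(`examples/03_date_haplotype_divergence.py`):

```
dXY between haplotype classes : 3.38 %/bp (95% CI 3.30-3.46)
molecular-clock split age     : 3.21 My (3.13-3.29)
generating divergence (truth) : 3.34 %/bp
```

and the coalescent null (`examples/01_null_fst_distribution.py`) shows
that under a clean split tuned to the genome-wide F_ST of 0.036, the most
extreme of 200,000 neutral loci reaches F_ST ≈ 0.6 — far below the 0.83
observed at the block — so drift alone does not produce such outliers.

## Layout

| module | contents |
|---|---|
| `hapblock.iolayer` | VCF/GFF3/TSV readers, `VariantMatrix`, filters, BED/TSV export |
| `hapblock.popstats` | π, θ_w, dXY, Weir–Cockerham and Reynolds F_ST, N_E, clock, bootstrap |
| `hapblock.blockscan` | F_ST scan, region delineation, haplotype classification, depth masks |
| `hapblock.treetools` | distance matrices, neighbor joining, windowed quartet topologies |
| `hapblock.splitsim` | coalescent join-model engine and the split null distribution |
| `hapblock.substmap` | polarization, fixed differences, coding effects, Fisher's test |
| `hapblock.synthgen` | truth-scored synthetic data generator |
| `hapblock.pipeline` | end-to-end orchestration with a reproducibility manifest |
| `hapblock.cli` | thin `hapblock` command-line entry point |

See `docs/methods.md` for the models, their assumptions and the design
choices behind the synthetic generator.
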