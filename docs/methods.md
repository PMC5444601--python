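# Methods

This note documents the statistical models implemented in `hapblock`, the
parameters that matter, the synthetic-data generator's design, and the
numerical conventions — in enough detail that every number the package
produces can be traced to a formula or an explicit simulation.

## Estimators

**Diversity.** Nucleotide diversity is the Nei–Li mean pairwise difference
in allele-count form: per site, 2p(1−p)·2n/(2n−1), summed over sites and
divided by the callable length L. The 2n/(2n−1) factor makes the per-site
term exactly the mean difference over all unordered haplotype pairs (each
diploid contributes two haplotypes); n is the per-site count of called
diploids, so missing genotypes shrink the local sample rather than the
estimate. Watterson's θ_w = S/(a_n·L) uses the harmonic number
a_n = Σ_{i<2n} 1/i of the full haplotype sample; with missing data the
sample-size correction is not localized (the panel this targets was
essentially complete after imputation). Absolute divergence
dXY = Σ [p_X(1−p_Y)+p_Y(1−p_X)]/L. All statistics are stored as per-bp
fractions and formatted as %/bp only for reporting.

**F_ST.** The Weir–Cockerham (1984) variance components a, b, c are
computed from per-population allele frequencies, observed heterozygote
fractions and diploid counts; multi-site estimates are ratio-of-sums
Σa/Σ(a+b+c). Sites monomorphic across populations (a+b+c = 0) are
undefined and excluded; sites with fewer than two called diploids in any
population are excluded (the estimators must be explicit about
missingness because no imputation is performed). Single-site estimates may
be negative. Reynolds-style coancestry for population distance matrices is
the haploid-allele-count method-of-moments ANOVA (allele copies m = 2n per
population): per locus MSP and MSG mean squares with
num = MSP − MSG, den = MSP + (m_c − 1)·MSG, combined across loci as
Σnum/Σden. On identical given frequencies this estimator's value is the
small negative bias term −1/(m_c−1), not exactly 0.

**Scalar transforms.** N_E = θ_w/(3μ) with the haplodiploid inheritance
scalar 3 (honey bee females are diploid, males haploid; θ = 3N_Eμ);
μ defaults to 5.27×10⁻⁹ /bp/generation with one-year generations. A clean
two-population split at scaled time T (4N₀-generation units) satisfies
F_ST ≈ 1−e^(−2T), inverted as T = −ln(1−F_ST)/2. Molecular-clock dating:
t = dXY/(2μ) generations. Window bootstrap CIs resample windows with
replacement (default 2,000 replicates) and take percentile bounds of the
weighted mean; weights default to callable sites per window because
unweighted means over unequal windows bias dXY.

## Genome scan and block genotyping

Per-SNP F_ST between the two habitat groups; SNPs with θ̂ > 0.5 (the
outlier threshold, configurable) are clustered per chromosome, with
adjacent outliers within `merge_gap` forming one region. Region bounds are
the first and last outlier positions; lengths are inclusive
(last − first + 1). Two granularities are emitted (default gaps 1 Mbp and
10 kbp) because physically linked sub-blocks on misassembled scaffolds may
be reported merged or separate. Region-level F_ST is reported both as the
ratio-of-sums over all SNPs inside the bounds and as the mean of defined
site estimates.

Each sample is genotyped for a whole block by counting its 0/0, 0/1 and
1/1 genotypes at the region's outlier SNPs: heterozygous if the 0/1
fraction exceeds 0.88; homozygous for either haplotype if the
corresponding fraction reaches 0.80 (the het threshold is an empirical
convention; the hom threshold is this package's choice, with an ambiguous
class and majority-rule dosage in between, ties flagged). The region is
then treated as one biallelic pseudo-locus whose per-sample genotype is
the block dosage; its single-locus Weir–Cockerham F_ST is exactly
`wc_fst_site` applied to the dosage frequencies. Unplaced scaffolds are
assigned to a candidate region when their per-sample dosage vector is
concordant with the region's (defaults: ≥ 2 outlier SNPs, concordance
≥ 0.8).

Depth masking removes sites whose group-mean read depth falls outside
[0.3×, 3.0×] of the cohort average, or with under 50% of samples
genotyped. The symmetric multiplicative band is the package's reading of
a "±30% of average depth" style filter whose literal statement is
self-contradictory; both bounds are configurable.

## Coalescent null

The null asks how extreme per-SNP F_ST can get under pure drift: two
populations (40 and 38 sampled chromosomes) that merged, looking backward,
at T = 0.01833 — the time implied by the empirical genome-wide F_ST of
0.036. The engine is a Kingman coalescent in ms time units (k lineages in
a population coalesce at total rate k(k−1) per 4N₀ generations) with
arbitrary population-join trees; exactly one mutation per locus is placed
on a branch chosen proportional to branch length (fixed-segregating-sites
semantics: the mutation-rate parameter does not affect placement and is
recorded only for provenance). Chromosomes are paired into diploids —
consecutively in haplotype-output mode, by exchangeable random assignment
otherwise; the two are distributionally identical and tested as such — and
per-locus F_ST uses the same Weir–Cockerham code path as empirical data.
Loci are independent (one SNP per locus needs no recombination).

Two summaries are reported: the ratio-of-sums combination across loci (the
standard multi-locus average, ≈ 0.0355 at the default model — this is the
quantity comparable to a genome-wide F_ST) and the mean of per-locus
estimates (≈ 0.023; single-SNP ratios are noisy and downward-shifted, so
the two differ substantially). The ratio-of-sums converges ~0.001 below
the idealized 1−e^(−2T) = 0.0363 identity (finite-sample estimator vs an
infinite-sample approximation); consistency tests allow for this. The
engine's conditional single-mutation site-frequency spectrum and its
two-population F_ST distribution are cross-validated against msprime (KS
test) in the test suite; the maximum across 10⁶ loci (seed-dependent,
typically 0.6–0.7) stays far below the dosage-level F_ST of real blocks.

## Synthetic data generator

The generator emulates the *called-genotype* level of a resequencing
panel: 39 diploids in four populations (10+10+10+9) crossing two
localities with two habitats, a weakly structured background, two embedded
blocks, an outgroup allele table, gene models with a reference sequence,
and a per-group depth table. Every random quantity derives from one seed;
the emitted file bundle is byte-reproducible.

**Background (bounded-shift model).** Ancestral derived frequencies follow
the neutral-SFS density f(p) ∝ 1/p with support matched to the sample's
resolvable frequencies, so that θ_w and π both come out at the configured
density (default 0.0082/bp). Differentiation is added as bounded shifts of
±sqrt(F·p(1−p)) per axis — localities take opposite signs, then habitats
within each locality — with F_locality = 0.030 and F_habitat = 0.041
calibrated once so the pooled highland-vs-lowland Weir–Cockerham F_ST is
≈ 0.036. The deliberate property of this model is a *thin tail*: every
SNP is weakly differentiated and essentially none crosses the 0.5 outlier
threshold (~10⁻⁵ per site), which is what real low-F_ST panels look like
(a handful of stray outliers among millions of SNPs). A clean-split
coalescent background (sharing the null engine, join times 0.048/0.0425)
is available as `bg_mode="coalescent"`, but its per-site F_ST tail is
~10-fold fatter than the data the generator is meant to emulate, which is
why it is not the default. Genotypes are Binomial(2, p) per diploid
(Hardy–Weinberg within populations); sites monomorphic in the sample are
rejected and redrawn.

**Blocks.** Each block has two founder haplotypes; every sample draws two
block haplotypes by its population's highland-haplotype frequency
(defaults 0.93 highland / 0.08 or 0.21 lowland), with no recombination, so
whole-block hom/het patterns emerge naturally. Within-block variation
decomposes into three categories:

* *founder differences* — fixed between classes, at Bernoulli density
  d_block − (θ_s·f_s + φ_h·f_h + φ_l·f_l), where the f are the exact
  (n−1)/n mean-frequency factors of each category's frequency spectrum;
* *shared polymorphism* (θ_s = 0.8·min(θ_h, θ_l)) — simulated on all
  copies jointly, segregating in both classes at correlated frequencies
  (old variation or gene flux; this is what keeps the diverse class's π
  near the genome-wide level, as real blocks show);
* *class-private mutations* (φ_c = θ_c − θ_s) — SFS ∝ 1/i within one
  class.

With this accounting, dXY measured between homozygous classes recovers
d_block without bias (verified at ±0.0003 over seeds for d_block = 0.0334
and 0.0134). The reference genome is itself a lowland-class haplotype:
categories that include lowland copies are simulated with one extra
"reference" copy, and when that copy draws the derived allele the REF/ALT
orientation flips — every haplotype still carrying the ancestral base,
including all highland copies, then scores as ALT. This reproduces the
empirical signature that highland samples are predominantly 1/1 at
outlier SNPs.

**Coding effects.** Gene models are tiled at a configured coding fraction
(default 0.20) with 1–3 exons, both strands, CDS lengths divisible by 3.
Founder changes inside CDS draw a target effect class — non-synonymous
with branch-specific probability (defaults 0.44 highland, 0.28 lowland;
the derived branch itself is highland with probability 0.57) — and may
relocate within their codon (same transcript) to a position offering that
class. Codons with no synonymous option (Met, Trp; ~3% of coding sites)
force a replacement change, so realized fractions sit ≈ 0.03·(1−target)
above target (≈ 0.47 / 0.31); the direction and the ~0.16 gap between
branches are preserved, which is what downstream tests rely on.

**Outgroup and depth.** The outgroup allele equals the true ancestral
state mutated with probability 0.069 (to a uniform different base) and is
present at 78% of sites. The depth table draws per-group depths around
9.2× (σ = 1.2) and multiplies highland depth by 0.25 at a random 30% of
block sites, emulating the mapping-depth depression of a diverged,
rearranged haplotype against a reference-like assembly.

**What the generator does not emulate.** Read-level artifacts (mapping
bias beyond the depth dip, base errors), linkage disequilibrium decay in
the background (background SNPs are exchangeable), recombination or gene
flux *within* a simulated block beyond the shared-polymorphism category,
selection dynamics, and multi-nucleotide variants. Passing the recovery
tests therefore demonstrates correctness of the estimators and of the
scan/classification logic under the assumed genotype-level model — not
robustness to alignment or calling artifacts.

## Windowed quartet topologies

Ten-kbp windows are classified by the four-point condition on pairwise
Reynolds F_ST among the four populations (negative entries floored at 0):
the pairing with the smallest intra-pair sum wins; ties, undefined pairs
or windows with fewer than 10 SNPs are unresolved. Pairings are labelled
by whether the paired populations share locality ("locality"), habitat
("environment") or neither ("mixed"). Per-chromosome enrichment of the
environment topology is a two-sided Fisher's exact test of environment vs
other resolved windows, focal chromosome vs rest. Quartet classification
via the four-point condition is equivalent to neighbor joining for four
taxa but deterministic and faster.

Neighbor joining itself (for sample trees) is the standard Saitou–Nei
agglomeration; negative branch lengths are clamped to zero with the
deficit moved to the sister branch (total edge length preserved), Q-matrix
ties resolve to the first index pair, and the output is an unrooted
newick with a final trifurcation.

## Numerical conventions and problem sizes

Coordinates are 1-based inclusive everywhere; BED export shifts only the
start. Dosages are int8 with −1 for missing. The bootstrap and all
generator draws use `numpy.random.default_rng`; the numba engine uses its
own seeded stream (seeds are kept below 2³¹).

Test and example problem sizes are chosen for desk-scale runs: the
generator's "small" genome is ~0.8 Mbp with ~40k SNPs and 120–140 kbp
blocks (the full-scale blocks are ~10× longer), multi-seed recovery
experiments use 20 seeds, and CI-coverage checks use 5 kbp windows so the
per-region window count (~28) matches what the full-scale analysis would
have at 10 kbp — percentile bootstrap coverage degrades below ~15 windows.
The null-model experiments use 10⁵–10⁶ loci (a few seconds to ~15 s
numba-compiled). The r9-like design is intrinsically marginal for a 0.5
outlier threshold: its parametric founder-site F_ST at frequencies
(0.93, 0.21) is 0.685, and in ~1–2% of seeds the realized frequencies
drift enough that the block goes undetected; the recovery tests budget
for this (≥95% of seeds fully recovered), which mirrors how such a scan
behaves on real panels.

## Known limitations

* θ_w does not localize missing data (per-site a_n would be needed for
  very patchy panels).
* The pseudo-likelihood-free classification thresholds (0.88 / 0.80) are
  conventions, not estimates; samples between them are ambiguous.
* `excess_divergence_ratio` and the distance matrices treat uncalled
  sites as identical, slightly compressing distances for patchy samples.
* The Fisher-based topology enrichment treats windows as independent,
  which real linkage violates at fine scales.
* Polarization is parsimony with a single outgroup: outgroup mutations to
  the derived allele (~2% of sites at 6.9% divergence) silently flip the
  inferred branch, slightly mixing per-branch substitution fractions.
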