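"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a called-genotype resequencing panel of four
populations (two localities x two habitats), a weakly structured genomic
background, and embedded non-recombining haplotype blocks carrying two
deeply diverged founder haplotypes at contrasting frequencies between
habitats — plus an outgroup allele table, gene models with a reference
sequence, a per-group depth table, and a machine-readable truth record
sufficient to score every downstream stage.

Model sketch
------------
* Background SNPs: by default a bounded-shift frequency model with
  locality-deep structure — differentiation is spread evenly across all
  sites so none exceeds the outlier threshold, as in real resequencing
  panels with low genome-wide FST — calibrated so the pooled
  highland-vs-lowland Weir–Cockerham FST matches the configured target
  (default 0.036).  A coalescent join-model mode sharing the null
  simulator's engine is available (``bg_mode="coalescent"``); its clean
  split has a much fatter per-site FST tail.
* Blocks: two founder haplotypes ("h" highland-enriched, "l" reference-like)
  differ at Bernoulli-placed founder sites; each sample draws two block
  haplotypes by its population's h frequency, with no recombination, so
  hom/het genotype runs emerge naturally.  Within-class variation splits
  into class-shared and class-private polymorphism; the configured
  ``d_block`` is the *target cross-class divergence*, and the founder
  density is reduced accordingly so dXY measured between homozygous
  classes recovers d_block.
* Outgroup: the truth ancestral allele mutated with probability equal to
  the outgroup divergence (default 6.9%), present at a configurable
  coverage (default 78% of sites).
* Coding effects: founder changes inside CDS choose an alt allele that is
  non-synonymous with a branch-specific probability (defaults 0.44 highland
  / 0.28 lowland), so the highland branch accumulates amino-acid changes at
  an elevated rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import splitsim, substmap
from .iolayer import (AncestralTable, DepthTable, GeneModelSet, SampleTable,
                      Transcript, VariantMatrix)

BASES = np.array(list("ACGT"))

# bounded-shift differentiation per axis, calibrated so pooled
# highland-vs-lowland WC FST ~= 0.036 at the default 20+19-diploid design
DEFAULT_F_LOCALITY = 0.030
DEFAULT_F_HABITAT = 0.041

# coalescent-mode join times with the same calibration target (the clean
# split has a much fatter per-site FST tail; see docs)
DEFAULT_T_LOCALITY = 0.048
DEFAULT_T_HABITAT = 0.0425


@dataclass
class PopulationSpec:
    label: str
    locality: str
    habitat: str
    altitude: float
    n: int


@dataclass
class BlockSpec:
    block_id: str
    chrom: str
    start: int
    end: int
    d_block: float                    # target cross-class divergence per bp
    freq_by_pop: dict                 # highland-haplotype frequency per pop
    theta_within_h: float = 0.0
    theta_within_l: float = 0.0
    highland_branch_fraction: float = 0.57
    nonsyn_fraction_h: float = 0.44
    nonsyn_fraction_l: float = 0.28
    shared_fraction: float = 0.8      # of min(theta_h, theta_l) shared
    mirror_of: str | None = None      # reuse another block's haplotype draw


@dataclass
class SynthConfig:
    chrom_lengths: dict
    populations: list
    blocks: list
    bg_theta: float = 0.0082          # per-bp Watterson target
    target_habitat_fst: float = 0.036
    bg_mode: str = "bounded"          # "bounded" | "coalescent"
    f_locality: float = DEFAULT_F_LOCALITY
    f_habitat: float = DEFAULT_F_HABITAT
    t_locality: float = DEFAULT_T_LOCALITY
    t_habitat: float = DEFAULT_T_HABITAT
    outgroup_divergence: float = 0.069
    outgroup_coverage: float = 0.78
    coding_fraction: float = 0.20
    mean_depth: float = 9.2
    depth_sd: float = 1.2
    depth_depression: float = 0.25    # highland depth multiplier at hit sites
    depth_depressed_frac: float = 0.30  # fraction of block sites hit

    def validate(self):
        for b in self.blocks:
            if b.chrom not in self.chrom_lengths:
                raise ValueError(f"block {b.block_id} on unknown chrom")
            if not (1 <= b.start <= b.end <= self.chrom_lengths[b.chrom]):
                raise ValueError(f"block {b.block_id} outside chrom bounds")
            for f in b.freq_by_pop.values():
                if not 0 <= f <= 1:
                    raise ValueError("haplotype frequencies must be in [0,1]")
        by_chrom = {}
        for b in self.blocks:
            for s, e in by_chrom.get(b.chrom, []):
                if b.start <= e and s <= b.end:
                    raise ValueError(
                        f"block {b.block_id} overlaps another block")
            by_chrom.setdefault(b.chrom, []).append((b.start, b.end))


def default_config() -> SynthConfig:
    """The study-condition dataset: 39 samples in four populations, an
    r7-like and an r9-like block, and a small unplaced scaffold mirroring
    the r7 block."""
    pops = [
        PopulationSpec("MF", "Mau", "highland", 2440, 10),
        PopulationSpec("MS", "Mau", "lowland", 1250, 10),
        PopulationSpec("MKF", "MtKenya", "highland", 2300, 10),
        PopulationSpec("MKS", "MtKenya", "lowland", 1100, 9),
    ]
    blocks = [
        BlockSpec("r7", "7", 150_001, 450_000, d_block=0.0334,
                  freq_by_pop={"MF": 0.93, "MS": 0.08, "MKF": 0.93,
                               "MKS": 0.08},
                  theta_within_h=0.0017, theta_within_l=0.0077),
        BlockSpec("r9", "9", 300_001, 700_000, d_block=0.0134,
                  freq_by_pop={"MF": 0.93, "MS": 0.21, "MKF": 0.93,
                               "MKS": 0.21},
                  theta_within_h=0.0050, theta_within_l=0.0080),
        BlockSpec("un1", "GroupUn1", 5_001, 25_000, d_block=0.0334,
                  freq_by_pop={}, theta_within_h=0.0017,
                  theta_within_l=0.0077, mirror_of="r7"),
    ]
    return SynthConfig(
        chrom_lengths={"1": 400_000, "7": 900_000, "9": 1_200_000,
                       "GroupUn1": 30_000},
        populations=pops, blocks=blocks,
    )


def small_config() -> SynthConfig:
    """A reduced genome for multi-seed experiments; same rates and design,
    smaller intervals."""
    cfg = default_config()
    cfg.chrom_lengths = {"1": 150_000, "7": 300_000, "9": 350_000,
                         "GroupUn1": 20_000}
    cfg.blocks[0] = dataclasses.replace(cfg.blocks[0], start=100_001,
                                        end=220_000)
    cfg.blocks[1] = dataclasses.replace(cfg.blocks[1], start=120_001,
                                        end=260_000)
    cfg.blocks[2] = dataclasses.replace(cfg.blocks[2], start=4_001,
                                        end=16_000)
    return cfg


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class BlockTruth:
    block_id: str
    chrom: str
    start: int
    end: int
    d_block: float
    founder_pos: np.ndarray
    founder_branch: np.ndarray
    founder_effect: np.ndarray
    hap_pairs: dict            # sample -> ("h"/"l", "h"/"l")
    freq_target: dict
    freq_realized: dict

    def dosage(self, sample: str) -> int:
        return sum(1 for h in self.hap_pairs[sample] if h == "h")

    @property
    def first_snp(self) -> int:
        return int(self.founder_pos.min()) if len(self.founder_pos) else -1

    @property
    def last_snp(self) -> int:
        return int(self.founder_pos.max()) if len(self.founder_pos) else -1


@dataclass
class Truth:
    blocks: list
    site_table: pd.DataFrame   # chrom,pos,category,block_id,branch,ancestral,effect
    t_locality: float
    t_habitat: float
    outgroup_mismatch_realized: float = float("nan")


@dataclass
class SynthBundle:
    vm: VariantMatrix
    samples: SampleTable
    genes: GeneModelSet
    reference: dict
    ancestral: AncestralTable
    depth: DepthTable
    truth: Truth


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def _sample_table(cfg: SynthConfig) -> SampleTable:
    rows = []
    for p in cfg.populations:
        for i in range(p.n):
            rows.append({
                "sample": f"{p.label}{i + 1:02d}", "locality": p.locality,
                "habitat": p.habitat, "altitude": p.altitude + 15 * i,
                "population": p.label,
            })
    return SampleTable(pd.DataFrame(rows))


def generate_gene_models(cfg: SynthConfig, rng) -> tuple:
    """Random reference sequences plus non-overlapping multi-exon gene
    models tiled at roughly the configured coding fraction, both strands."""
    reference = {}
    genes = GeneModelSet()
    for chrom, L in cfg.chrom_lengths.items():
        reference[chrom] = "".join(BASES[rng.integers(0, 4, size=L)])
        if cfg.coding_fraction <= 0:
            continue
        pos = 1
        k = 0
        while True:
            cds_len = int(rng.integers(40, 160)) * 3
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1,
                                      replace=False)) * 3 if n_exons > 1 else []
            exon_lens = np.diff(np.concatenate([[0], cuts, [cds_len]])).astype(int)
            introns = rng.integers(80, 400, size=n_exons - 1)
            span = int(exon_lens.sum() + introns.sum())
            gap_mean = span * (1.0 / cfg.coding_fraction - 1.0)
            pos += int(rng.exponential(gap_mean)) + 1
            if pos + span > L:
                break
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            segs, cur = [], pos
            for x, elen in enumerate(exon_lens):
                segs.append([cur, cur + int(elen) - 1, 0])
                cur += int(elen) + (int(introns[x]) if x < n_exons - 1 else 0)
            ordered = segs if strand == "+" else segs[::-1]
            acc = 0
            for seg in ordered:
                seg[2] = (3 - acc % 3) % 3
                acc += seg[1] - seg[0] + 1
            tid = f"t{chrom}.{k}"
            genes.add(Transcript(
                transcript_id=tid, gene_id=f"g{chrom}.{k}", chrom=chrom,
                strand=strand, segments=[tuple(s) for s in ordered],
            ))
            pos = cur
    return genes, reference


def _background_free_intervals(cfg: SynthConfig):
    out = {}
    for chrom, L in cfg.chrom_lengths.items():
        blocks = sorted((b.start, b.end) for b in cfg.blocks
                        if b.chrom == chrom)
        iv, cur = [], 1
        for s, e in blocks:
            if cur < s:
                iv.append((cur, s - 1))
            cur = e + 1
        if cur <= L:
            iv.append((cur, L))
        out[chrom] = iv
    return out


def _bounded_background_geno(cfg: SynthConfig, rng, n_sites: int) -> np.ndarray:
    """Segregating background genotypes from a bounded-shift frequency model.

    Ancestral derived frequencies follow the neutral-SFS density f(p) ∝ 1/p
    (support matched to the sample's resolvable frequencies so that expected
    pairwise diversity per segregating site matches the Watterson scaling).
    Differentiation is added as bounded, uniformly spread shifts: each axis
    moves a population's frequency by ±sqrt(F · p(1-p)) with a random sign
    per site (localities get opposite signs; habitats get opposite signs
    within each locality).  Every site is therefore weakly differentiated
    and none strongly — matching resequencing panels where genome-wide FST
    is low yet essentially no single SNP exceeds the outlier threshold —
    while the mean FST is set by F.  Genotypes are Binomial(2, p) per
    diploid; sites monomorphic in the sample are rejected and redrawn.
    """
    pops = cfg.populations
    n_hap = 2 * sum(p.n for p in pops)
    eps = 1.0 / (2.0 * n_hap)
    m_loc = np.sqrt(max(cfg.f_locality, 0.0))
    m_hab = np.sqrt(max(cfg.f_habitat, 0.0))
    out = []
    got = 0
    while got < n_sites:
        m = max(1024, int(1.3 * (n_sites - got)))
        # inverse-CDF draw from f(p) ∝ 1/p on [eps, 1 - eps]
        u = rng.random(m)
        p_anc = eps * ((1.0 - eps) / eps) ** u
        scale = np.sqrt(p_anc * (1.0 - p_anc))
        loc_freqs = {}
        localities = sorted({p.locality for p in pops})
        sign_loc = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        for li, locality in enumerate(localities):
            s = sign_loc if li == 0 else -sign_loc
            loc_freqs[locality] = np.clip(p_anc + s * m_loc * scale, 0.0, 1.0)
        cols = []
        sign_hab = {loc: np.where(rng.random(m) < 0.5, 1.0, -1.0)
                    for loc in localities}
        for p in pops:
            s = sign_hab[p.locality] * (1.0 if p.habitat == "highland" else -1.0)
            pf = loc_freqs[p.locality]
            pf = np.clip(pf + s * m_hab * np.sqrt(pf * (1.0 - pf)), 0.0, 1.0)
            cols.append(rng.binomial(2, pf[:, None],
                                     size=(m, p.n)).astype(np.int8))
        g = np.concatenate(cols, axis=1)
        tot = g.sum(axis=1)
        seg = (tot > 0) & (tot < 2 * g.shape[1])
        out.append(g[seg])
        got += int(seg.sum())
    return np.vstack(out)[:n_sites]


def _coalescent_background_geno(cfg: SynthConfig, rng, n_sites: int):
    """Background genotypes from the locality-deep / habitat-recent
    coalescent join model (shares the null-simulator engine)."""
    pops = cfg.populations
    sizes = [2 * p.n for p in pops]
    loc = {}
    for i, p in enumerate(pops):
        loc.setdefault(p.locality, []).append(i)
    localities = list(loc.values())
    if len(localities) != 2 or any(len(v) != 2 for v in localities):
        raise ValueError("background model expects 2 localities x 2 habitats")
    (a1, a2), (b1, b2) = localities
    seed = int(rng.integers(1, splitsim.MAX_SEED))
    _, _, haps, _ = splitsim.simulate_join_model(
        sizes, [cfg.t_habitat, cfg.t_habitat, cfg.t_locality],
        [a2, b2, b1], [a1, b1, a1], n_sites, seed, haplotypes=True)
    return (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)


def generate_background(cfg: SynthConfig, rng, reference):
    """Background SNPs outside block intervals.

    Site count follows the Watterson expectation S = theta * L * a_n; joint
    allele frequencies come from the bounded-shift model (default) or
    the coalescent join model (``bg_mode="coalescent"``).  The reference
    carries the ancestral allele at background sites; alt = derived.
    """
    pops = cfg.populations
    n_hap_total = 2 * sum(p.n for p in pops)
    a_n = float(np.sum(1.0 / np.arange(1, n_hap_total)))
    free = _background_free_intervals(cfg)
    chrom_pos = {}
    total_sites = 0
    for chrom, ivs in free.items():
        Lfree = sum(e - s + 1 for s, e in ivs)
        S = rng.poisson(cfg.bg_theta * Lfree * a_n)
        offsets = np.concatenate([[0], np.cumsum([e - s + 1 for s, e in ivs])])
        picks = np.sort(rng.choice(Lfree, size=min(S, Lfree), replace=False))
        pos = np.empty(len(picks), np.int64)
        for (s, _), o0, o1 in zip(ivs, offsets[:-1], offsets[1:]):
            m = (picks >= o0) & (picks < o1)
            pos[m] = s + (picks[m] - o0)
        chrom_pos[chrom] = pos
        total_sites += len(pos)

    if cfg.bg_mode == "bounded":
        geno = _bounded_background_geno(cfg, rng, total_sites)
    elif cfg.bg_mode == "coalescent":
        geno = _coalescent_background_geno(cfg, rng, total_sites)
    else:
        raise ValueError(f"unknown background mode {cfg.bg_mode!r}")

    rows = [(chrom, int(p)) for chrom, pos in chrom_pos.items() for p in pos]
    refs = np.array([reference[c][p - 1] for c, p in rows], dtype="U1")
    shift = rng.integers(1, 4, size=len(rows))
    alts = BASES[(np.searchsorted(BASES, refs) + shift) % 4]
    anc = refs.copy()  # reference carries the ancestral allele
    site_df = pd.DataFrame({
        "chrom": [c for c, _ in rows], "pos": [p for _, p in rows],
        "category": "background", "block_id": "", "branch": "",
        "ancestral": anc, "effect": "",
    })
    return site_df, refs, alts, geno


_SFS_CACHE = {}


def _sfs_counts(rng, n_copies, size):
    """Derived-allele counts from the neutral SFS P(i) ∝ 1/i, 1<=i<n."""
    if n_copies < 2 or size == 0:
        return np.zeros(size, int)
    w = _SFS_CACHE.get(n_copies)
    if w is None:
        w = (1.0 / np.arange(1, n_copies)) / np.sum(1.0 / np.arange(1, n_copies))
        _SFS_CACHE[n_copies] = w
    return rng.choice(np.arange(1, n_copies), size=size, p=w)


def _choose_alt(chrom, pos, ref, want_nonsyn, genes, reference, trees, rng):
    """Alt allele at a coding-or-not site, biased to the requested effect."""
    candidates = [b for b in "ACGT" if b != ref]
    labelled = []
    for b in candidates:
        eff, _, _ = substmap.coding_effect(chrom, pos, ref, b, genes,
                                           reference, trees)
        labelled.append((b, eff))
    nonsyn = [b for b, e in labelled if e in ("non-synonymous", "stop")]
    syn = [b for b, e in labelled if e == "synonymous"]
    other = [b for b, e in labelled if e in ("non-coding", "undetermined")]
    if other and not (nonsyn or syn):
        pool = other
    elif want_nonsyn:
        pool = nonsyn or syn or other
    else:
        pool = syn or nonsyn or other
    alt = pool[int(rng.integers(len(pool)))]
    eff = dict(labelled)[alt]
    return alt, eff


def embed_block(cfg: SynthConfig, block: BlockSpec, rng, reference, genes,
                trees, samples: SampleTable, hap_pairs=None):
    """Genotypes and truth for one non-recombining block.

    Two founder haplotypes differ at Bernoulli-placed sites (density =
    d_block minus mean within-class diversity); each sample draws two block
    haplotypes by its population's h frequency (or reuses ``hap_pairs`` for
    a mirrored block); within-class variation is added at theta_within per
    class.  Returns (site table, refs, alts, genotypes, BlockTruth).
    """
    L = block.end - block.start + 1
    meta = samples.df
    sample_ids = meta["sample"].tolist()

    if hap_pairs is None:
        hap_pairs = {}
        for sid, pop in zip(meta["sample"], meta["population"]):
            f = block.freq_by_pop[pop]
            hap_pairs[sid] = tuple(
                "h" if rng.random() < f else "l" for _ in range(2))
    dosage = np.array([sum(h == "h" for h in hap_pairs[s])
                       for s in sample_ids], np.int8)

    # Within-class variation decomposes into polymorphism shared by both
    # haplotype classes (old variation or gene flux; density theta_s) and
    # class-private mutations (phi_h, phi_l).  A cross-class pair differs at
    # a shared site with probability ~2p(1-p) and at a private site with
    # probability equal to the derived frequency, so expected cross-class
    # dXY = founder density + theta_s + phi_h + phi_l, and the founder
    # density is set so measured dXY between homozygous classes recovers
    # d_block.
    theta_s = block.shared_fraction * min(block.theta_within_h,
                                          block.theta_within_l)
    phi_h = block.theta_within_h - theta_s
    phi_l = block.theta_within_l - theta_s
    # expected cross-class contribution of a category simulated on n copies
    # is theta * (n-1)/n (mean derived frequency under the 1/i spectrum)
    n_h = sum(1 for s_ in sample_ids for hh in hap_pairs[s_] if hh == "h")
    n_l = 2 * len(sample_ids) - n_h
    def _f(n_eff):
        return (n_eff - 1) / n_eff if n_eff > 1 else 0.0
    within_contrib = (theta_s * _f(n_h + n_l + 1) + phi_h * _f(n_h)
                      + phi_l * _f(n_l + 1))
    density = block.d_block - within_contrib
    if density < 0:
        raise ValueError("d_block must be at least the within-class diversity")
    n_f = rng.binomial(L, density) if density > 0 else 0
    fpos = np.sort(rng.choice(L, size=n_f, replace=False)) + block.start
    branches = np.where(rng.random(n_f) < block.highland_branch_fraction,
                        "highland", "lowland")
    # Coding founder changes are biased to hit codon positions yielding the
    # branch-specific non-synonymous fraction: the mutation may relocate
    # within its codon (same CDS segment) to wherever the requested effect
    # class is available.
    taken = set(fpos.tolist())
    alts = np.empty(n_f, dtype="U1")
    effects = np.empty(n_f, dtype="U16")
    fpos = fpos.copy()
    for i, br in enumerate(branches):
        p = int(fpos[i])
        f_ns = (block.nonsyn_fraction_h if br == "highland"
                else block.nonsyn_fraction_l)
        want_nonsyn = rng.random() < f_ns
        opts = substmap.codon_site_options(block.chrom, p, genes, reference,
                                           trees)
        chosen = None
        if opts is not None:
            nonsyn, syn = opts
            pool = (nonsyn if want_nonsyn else syn) or \
                (syn if want_nonsyn else nonsyn)
            pool = [(q, a, e) for q, a, e in pool
                    if block.start <= q <= block.end
                    and (q == p or q not in taken)]
            if pool:
                chosen = pool[int(rng.integers(len(pool)))]
        if chosen is None:
            ref = reference[block.chrom][p - 1]
            alt, eff = _choose_alt(block.chrom, p, ref, want_nonsyn,
                                   genes, reference, trees, rng)
            chosen = (p, alt, eff)
        q, alt, eff = chosen
        if q != p:
            taken.discard(p)
            taken.add(q)
            fpos[i] = q
        alts[i] = alt
        effects[i] = eff
    order_f = np.argsort(fpos)
    fpos, branches = fpos[order_f], branches[order_f]
    alts, effects = alts[order_f], effects[order_f]
    refs = np.array([reference[block.chrom][p - 1] for p in fpos], dtype="U1")
    geno_f = np.tile(dosage, (n_f, 1))
    anc_f = np.where(branches == "highland", refs, alts)

    site_rows = [pd.DataFrame({
        "chrom": block.chrom, "pos": fpos, "category": "founder",
        "block_id": block.block_id, "branch": branches, "ancestral": anc_f,
        "effect": effects,
    })]
    geno_parts = [geno_f]
    refs_parts = [refs]
    alts_parts = [alts]

    # within-class variation: copies indexed (sample, slot)
    copies = {"h": [], "l": []}
    for si, sid in enumerate(sample_ids):
        for slot, h in enumerate(hap_pairs[sid]):
            copies[h].append(si)
    occupied = np.zeros(L, bool)
    occupied[fpos - block.start] = True

    # The reference genome is itself a lowland-class haplotype, so
    # within-lowland variation is simulated on the sampled l copies plus
    # one reference copy; when the reference copy carries the derived
    # allele, REF/ALT orientation flips and every haplotype still carrying
    # the ancestral base — including all highland copies — scores as ALT.
    # (This is why, at outlier SNPs of a real block, highland samples are
    # predominantly 1/1 rather than an even mix.)
    for cls, theta, owner_list, with_ref in (
            ("shared", theta_s, copies["h"] + copies["l"], True),
            ("h", phi_h, copies["h"], False),
            ("l", phi_l, copies["l"], True)):
        owners = np.asarray(owner_list, int)
        n_cop = len(owners)
        if n_cop < 2 or theta <= 0:
            continue
        n_eff = n_cop + (1 if with_ref else 0)
        a_n = float(np.sum(1.0 / np.arange(1, n_eff)))
        S = rng.poisson(theta * L * a_n)
        free = np.flatnonzero(~occupied)
        wpos = rng.choice(free, size=min(S, len(free)), replace=False) \
            + block.start
        wpos.sort()
        occupied[wpos - block.start] = True
        counts = _sfs_counts(rng, n_eff, len(wpos))
        gw = np.zeros((len(wpos), len(sample_ids)), np.int8)
        flipped = np.zeros(len(wpos), bool)
        for j, cnt in enumerate(counts):
            hit = rng.choice(n_eff, size=int(cnt), replace=False)
            if with_ref:
                # copy 0 is the reference haplotype
                flipped[j] = (hit == 0).any()
                hit = hit[hit > 0] - 1
            np.add.at(gw[j], owners[hit], 1)
        if flipped.any():
            # ALT is the ancestral base: every copy not carrying the derived
            # allele (all h copies, unhit l copies) contributes a dose
            gw[flipped] = 2 - gw[flipped]
        wrefs = np.array([reference[block.chrom][p - 1] for p in wpos],
                         dtype="U1")
        shift = rng.integers(1, 4, size=len(wpos))
        walts = BASES[(np.searchsorted(BASES, wrefs) + shift) % 4]
        anc_w = np.where(flipped, walts, wrefs)
        site_rows.append(pd.DataFrame({
            "chrom": block.chrom, "pos": wpos,
            "category": f"within_{cls}", "block_id": block.block_id,
            "branch": "", "ancestral": anc_w, "effect": "",
        }))
        geno_parts.append(gw)
        refs_parts.append(wrefs)
        alts_parts.append(walts)

    site_df = pd.concat(site_rows, ignore_index=True)
    geno = np.vstack(geno_parts)
    refs_all = np.concatenate(refs_parts)
    alts_all = np.concatenate(alts_parts)

    freq_real = {}
    for pop, sub in meta.groupby("population"):
        idx = sub.index.to_numpy()
        freq_real[pop] = float(dosage[idx].sum() / (2.0 * len(idx)))
    truth = BlockTruth(
        block_id=block.block_id, chrom=block.chrom, start=block.start,
        end=block.end, d_block=block.d_block, founder_pos=fpos,
        founder_branch=branches, founder_effect=effects,
        hap_pairs=hap_pairs,
        freq_target=dict(block.freq_by_pop), freq_realized=freq_real,
    )
    return site_df, refs_all, alts_all, geno, truth


def generate_outgroup(cfg: SynthConfig, rng, site_df: pd.DataFrame):
    """Outgroup alleles: the ancestral state, mutated with probability equal
    to the configured outgroup divergence, present at the configured
    coverage."""
    anc = site_df["ancestral"].to_numpy(dtype="U1")
    n = len(anc)
    present = rng.random(n) < cfg.outgroup_coverage
    mutate = rng.random(n) < cfg.outgroup_divergence
    shift = rng.integers(1, 4, size=n)
    mutated = BASES[(np.searchsorted(BASES, anc) + shift) % 4]
    og = np.where(mutate, mutated, anc)
    df = pd.DataFrame({
        "chrom": site_df["chrom"].to_numpy()[present],
        "pos": site_df["pos"].to_numpy()[present],
        "allele": og[present],
    })
    mismatch = float(mutate[present].mean()) if present.any() else float("nan")
    return AncestralTable(df), mismatch


def _depth_table(cfg: SynthConfig, rng, vm: VariantMatrix,
                 samples: SampleTable) -> DepthTable:
    n = vm.n_sites
    d_high = rng.normal(cfg.mean_depth, cfg.depth_sd, size=n).clip(min=0)
    d_low = rng.normal(cfg.mean_depth, cfg.depth_sd, size=n).clip(min=0)
    in_block = np.zeros(n, bool)
    for b in cfg.blocks:
        try:
            in_block |= vm.region_mask(b.chrom, b.start, b.end)
        except KeyError:
            continue
    hit = in_block & (rng.random(n) < cfg.depth_depressed_frac)
    d_high[hit] *= cfg.depth_depression
    called_frac = (vm.geno != -1).mean(axis=1)
    return DepthTable(pd.DataFrame({
        "chrom": [vm.chrom_ids[c] for c in vm.chrom], "pos": vm.pos,
        "depth_highland": d_high, "depth_lowland": d_low,
        "called_frac": called_frac,
    }))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def generate(cfg: SynthConfig, seed: int) -> SynthBundle:
    """Generate the full in-memory bundle for one seed (deterministic)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    samples = _sample_table(cfg)
    genes, reference = generate_gene_models(cfg, rng)
    trees = substmap._transcript_index(genes)

    site_df, refs, alts, geno = generate_background(cfg, rng, reference)
    parts = [(site_df, refs, alts, geno)]

    truths = []
    hap_store = {}
    for block in cfg.blocks:
        pairs = hap_store.get(block.mirror_of) if block.mirror_of else None
        if block.mirror_of and pairs is None:
            raise ValueError(f"mirror source {block.mirror_of} not generated")
        s, r, a, g, bt = embed_block(cfg, block, rng, reference, genes, trees,
                                     samples, hap_pairs=pairs)
        hap_store[block.block_id] = bt.hap_pairs
        parts.append((s, r, a, g))
        truths.append(bt)

    site_df = pd.concat([p[0] for p in parts], ignore_index=True)
    refs = np.concatenate([p[1] for p in parts])
    alts = np.concatenate([p[2] for p in parts])
    geno = np.vstack([p[3] for p in parts])

    chrom_ids = list(cfg.chrom_lengths.keys())
    chrom_idx = site_df["chrom"].map({c: i for i, c in enumerate(chrom_ids)})
    order = np.lexsort((site_df["pos"].to_numpy(), chrom_idx.to_numpy()))
    site_df = site_df.iloc[order].reset_index(drop=True)
    refs, alts, geno = refs[order], alts[order], geno[order]

    # drop duplicate positions (rare collisions between site categories)
    dup = site_df.duplicated(["chrom", "pos"]).to_numpy()
    if dup.any():
        keep = ~dup
        site_df = site_df[keep].reset_index(drop=True)
        refs, alts, geno = refs[keep], alts[keep], geno[keep]

    qual = rng.uniform(60.0, 2000.0, size=len(site_df))
    vm = VariantMatrix(
        chrom_ids=chrom_ids,
        chrom=site_df["chrom"].map(
            {c: i for i, c in enumerate(chrom_ids)}).to_numpy(np.int32),
        pos=site_df["pos"].to_numpy(np.int64),
        ref=refs, alt=alts, geno=geno, qual=qual,
        sample_ids=samples.sample_ids,
    )
    vm.validate()

    anc_table, mismatch = generate_outgroup(cfg, rng, site_df)
    depth = _depth_table(cfg, rng, vm, samples)
    truth = Truth(blocks=truths, site_table=site_df,
                  t_locality=cfg.t_locality, t_habitat=cfg.t_habitat,
                  outgroup_mismatch_realized=mismatch)
    return SynthBundle(vm=vm, samples=samples, genes=genes,
                       reference=reference, ancestral=anc_table, depth=depth,
                       truth=truth)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(vm: VariantMatrix, path) -> None:
    """Minimal VCF 4.2 writer (GT only) for generator output."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in vm.chrom_ids:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vm.sample_ids) + "\n")
        for i in range(vm.n_sites):
            gts = "\t".join(_GT[int(g)] for g in vm.geno[i])
            fh.write(f"{vm.chrom_ids[vm.chrom[i]]}\t{vm.pos[i]}\t.\t"
                     f"{vm.ref[i]}\t{vm.alt[i]}\t{vm.qual[i]:.1f}\t.\t.\tGT\t"
                     f"{gts}\n")


def write_gff3(genes: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in genes.transcripts.values():
            segs = sorted(tr.segments, key=lambda s: s[0])
            lo, hi = segs[0][0], max(e for _, e, _ in segs)
            fh.write(f"{tr.chrom}\tsynth\tgene\t{lo}\t{hi}\t.\t{tr.strand}\t."
                     f"\tID=gene:{tr.gene_id}\n")
            fh.write(f"{tr.chrom}\tsynth\tmRNA\t{lo}\t{hi}\t.\t{tr.strand}\t."
                     f"\tID={tr.transcript_id};Parent=gene:{tr.gene_id}\n")
            for s, e, ph in segs:
                fh.write(f"{tr.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{tr.strand}\t"
                         f"{ph}\tParent={tr.transcript_id};"
                         f"gene_id={tr.gene_id}\n")


def write_fasta(reference: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def emit(cfg: SynthConfig, seed: int, out_dir) -> dict:
    """Generate and write the full file bundle; returns the path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate(cfg, seed)
    paths = {
        "vcf": out / "synthetic.vcf",
        "meta": out / "samples.tsv",
        "gff": out / "genes.gff3",
        "fasta": out / "reference.fa",
        "ancestral": out / "ancestral.tsv",
        "depth": out / "depth.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(bundle.vm, paths["vcf"])
    bundle.samples.df.to_csv(paths["meta"], sep="\t", index=False)
    write_gff3(bundle.genes, paths["gff"])
    write_fasta(bundle.reference, paths["fasta"])
    bundle.ancestral.df.to_csv(paths["ancestral"], sep="\t", index=False)
    bundle.depth.df.to_csv(paths["depth"], sep="\t", index=False)
    bundle.truth.site_table.to_csv(paths["truth_sites"], sep="\t", index=False)
    rows = []
    for bt in bundle.truth.blocks:
        for s, pair in bt.hap_pairs.items():
            rows.append({"block_id": bt.block_id, "sample": s,
                         "hap1": pair[0], "hap2": pair[1],
                         "dosage": bt.dosage(s)})
    pd.DataFrame(rows).to_csv(paths["truth_samples"], sep="\t", index=False)
    summary = {
        "seed": seed,
        "t_locality": cfg.t_locality, "t_habitat": cfg.t_habitat,
        "outgroup_mismatch_realized": bundle.truth.outgroup_mismatch_realized,
        "blocks": [{
            "block_id": b.block_id, "chrom": b.chrom, "start": b.start,
            "end": b.end, "d_block": b.d_block,
            "first_snp": b.first_snp, "last_snp": b.last_snp,
            "n_founder": int(len(b.founder_pos)),
            "freq_target": b.freq_target, "freq_realized": b.freq_realized,
        } for b in bundle.truth.blocks],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
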