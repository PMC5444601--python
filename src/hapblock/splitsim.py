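"""Coalescent null model for FST: a clean two-population split.

Replicates the classic ``ms``-style experiment: sample chromosomes from two
populations that merge (looking backward in time) at a scaled time T, place
exactly one mutation per locus on a branch chosen proportional to branch
length, pair chromosomes into diploids, and compute per-locus Weir–Cockerham
FST.  Time is measured in ms units of 4*N0 generations, so k lineages within
a population coalesce with exponential waiting at total rate k(k-1).

The engine is a general join model (any number of populations merging along
a tree of join events); the two-population split of :class:`SplitModel` and
the four-population background of the synthetic generator are both thin
parameterizations of it.  Loci are independent (one SNP per locus needs no
within-locus recombination).  A theta parameter may be recorded for
provenance but does not affect allele placement: conditioning on a single
segregating site makes the mutation rate irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import popstats

MAX_SEED = 2 ** 31 - 1


@dataclass
class SplitModel:
    """Two-population clean-split null.

    Defaults mirror a 20 + 19 diploid sampling design (40 and 38
    chromosomes) joined at T = 0.01833 with one segregating site per locus.
    """

    n_chroms: tuple = (40, 38)
    t_join: float = 0.01833
    n_loci: int = 1_000_000
    segsites_per_locus: int = 1
    theta: float = 8.2  # recorded for provenance; unused with one fixed SNP
    seed: int = 1

    def __post_init__(self):
        if self.t_join < 0:
            raise ValueError("t_join must be >= 0")
        if any(m < 2 for m in self.n_chroms):
            raise ValueError("need >= 2 chromosomes per population")
        if self.segsites_per_locus != 1:
            raise ValueError("only one segregating site per locus is supported")


@dataclass
class SimLocus:
    derived: np.ndarray      # derived-allele count per population
    het_diploids: np.ndarray  # heterozygous diploids per population
    fst: float
    tree_length: float = float("nan")  # total branch length, 4*N0 units


# ---------------------------------------------------------------------------
# numba engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_engine(pop_sizes, jt, js, jd, n_loci, seed, want_haps):  # pragma: no cover
    np.random.seed(seed)
    K = pop_sizes.shape[0]
    N = 0
    for p in range(K):
        N += pop_sizes[p]
    max_lin = 2 * N - 1
    d_out = np.zeros((n_loci, K), np.int64)
    het_out = np.zeros((n_loci, K), np.int64)
    tlen_out = np.zeros(n_loci)
    if want_haps:
        haps = np.zeros((n_loci, N), np.int8)
    else:
        haps = np.zeros((1, 1), np.int8)
    members = np.empty((K, N), np.int64)
    kcount = np.empty(K, np.int64)
    born = np.empty(max_lin)
    blen = np.empty(max_lin)
    desc = np.empty((max_lin, K), np.int64)
    leafmask = np.zeros((max_lin, N), np.int8)
    buf = np.empty(N, np.int8)

    for locus in range(n_loci):
        li = 0
        for p in range(K):
            kcount[p] = pop_sizes[p]
            for i in range(pop_sizes[p]):
                members[p, i] = li
                born[li] = 0.0
                blen[li] = 0.0
                for q in range(K):
                    desc[li, q] = 0
                desc[li, p] = 1
                if want_haps:
                    for q in range(N):
                        leafmask[li, q] = 0
                    leafmask[li, li] = 1
                li += 1
        next_new = N
        t = 0.0
        jidx = 0
        n_alive = N
        while n_alive > 1:
            rate = 0.0
            for p in range(K):
                rate += kcount[p] * (kcount[p] - 1)
            t_join = jt[jidx] if jidx < jt.shape[0] else 1e300
            wait = np.random.exponential(1.0 / rate) if rate > 0.0 else 1e300
            if t + wait < t_join:
                t += wait
                u = np.random.random() * rate
                acc = 0.0
                psel = 0
                for p in range(K):
                    acc += kcount[p] * (kcount[p] - 1)
                    if u < acc:
                        psel = p
                        break
                kp = kcount[psel]
                ia = np.random.randint(kp)
                ib = np.random.randint(kp - 1)
                if ib >= ia:
                    ib += 1
                la = members[psel, ia]
                lb = members[psel, ib]
                blen[la] = t - born[la]
                blen[lb] = t - born[lb]
                new = next_new
                next_new += 1
                born[new] = t
                blen[new] = 0.0
                for q in range(K):
                    desc[new, q] = desc[la, q] + desc[lb, q]
                if want_haps:
                    for q in range(N):
                        leafmask[new, q] = leafmask[la, q] | leafmask[lb, q]
                if ia > ib:
                    ia, ib = ib, ia
                members[psel, ia] = new
                members[psel, ib] = members[psel, kp - 1]
                kcount[psel] = kp - 1
                n_alive -= 1
            else:
                t = t_join
                s = js[jidx]
                dpop = jd[jidx]
                for i in range(kcount[s]):
                    members[dpop, kcount[dpop] + i] = members[s, i]
                kcount[dpop] += kcount[s]
                kcount[s] = 0
                jidx += 1
        # one mutation, branch chosen proportional to length (root excluded:
        # its length is zero)
        total = 0.0
        for i in range(next_new):
            total += blen[i]
        tlen_out[locus] = total
        u = np.random.random() * total
        acc = 0.0
        chosen = next_new - 1
        for i in range(next_new):
            acc += blen[i]
            if u < acc:
                chosen = i
                break
        for q in range(K):
            d_out[locus, q] = desc[chosen, q]
        if want_haps:
            for q in range(N):
                haps[locus, q] = leafmask[chosen, q]
            # consecutive pairing of the emitted chromosomes
            off = 0
            for p in range(K):
                m = pop_sizes[p]
                nh = 0
                for i in range(0, m - 1, 2):
                    if haps[locus, off + i] + haps[locus, off + i + 1] == 1:
                        nh += 1
                het_out[locus, p] = nh
                off += m
        else:
            # exchangeable pairing: shuffle derived alleles among chromosomes
            for p in range(K):
                m = pop_sizes[p]
                d = d_out[locus, p]
                for i in range(m):
                    buf[i] = 1 if i < d else 0
                for i in range(m - 1, 0, -1):
                    j = np.random.randint(i + 1)
                    tmp = buf[i]
                    buf[i] = buf[j]
                    buf[j] = tmp
                nh = 0
                for i in range(0, m - 1, 2):
                    if buf[i] + buf[i + 1] == 1:
                        nh += 1
                het_out[locus, p] = nh
    return d_out, het_out, haps, tlen_out


def simulate_join_model(pop_sizes, join_times, join_src, join_dst,
                        n_loci: int, seed: int, haplotypes: bool = False):
    """Run the coalescent for a general tree of population joins.

    Returns (derived counts, het-diploid counts) per locus and population,
    plus the per-chromosome allele matrix when ``haplotypes`` is True
    (chromosomes ordered by population block, paired consecutively).
    """
    pop_sizes = np.asarray(pop_sizes, np.int64)
    order = np.argsort(np.asarray(join_times, float), kind="stable")
    jt = np.asarray(join_times, float)[order]
    js = np.asarray(join_src, np.int64)[order]
    jd = np.asarray(join_dst, np.int64)[order]
    if len(jt) != len(pop_sizes) - 1:
        raise ValueError("a K-population model needs K-1 join events")
    d, het, haps, tlen = _run_engine(pop_sizes, jt, js, jd, int(n_loci),
                                     int(seed) % MAX_SEED, haplotypes)
    return (d, het, haps, tlen) if haplotypes else (d, het, tlen)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def pair_into_diploids(chrom_alleles_by_pop):
    """Pair consecutive chromosomes into diploids per population.

    Input: per-population 0/1 haploid allele arrays (even length each).
    Returns a list of dicts with allele frequency, observed het fraction and
    genotype counts — the inputs the Weir–Cockerham estimator needs.
    """
    out = []
    for alleles in chrom_alleles_by_pop:
        a = np.asarray(alleles, int)
        if len(a) % 2:
            raise ValueError("odd chromosome count cannot be paired")
        g = a[0::2] + a[1::2]
        n = len(g)
        out.append({
            "freq": float(a.mean()),
            "het_frac": float((g == 1).mean()),
            "n_diploids": n,
            "genotype_counts": (int((g == 0).sum()), int((g == 1).sum()),
                                int((g == 2).sum())),
        })
    return out


def _per_locus_fst(model: SplitModel, derived, het):
    m = np.asarray(model.n_chroms, float)
    n_dip = m / 2.0
    p = derived / m
    h = het / n_dip
    a, b, c = popstats.wc_components(p, h, np.broadcast_to(n_dip, p.shape))
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta, a, denom


def simulate_locus(model: SplitModel, seed: int | None = None) -> SimLocus:
    """Simulate a single locus under the split model."""
    seed = model.seed if seed is None else seed
    d, het, tlen = simulate_join_model(
        model.n_chroms, [model.t_join], [1], [0], 1, seed)
    theta, _, _ = _per_locus_fst(model, d, het)
    return SimLocus(derived=d[0], het_diploids=het[0], fst=float(theta[0]),
                    tree_length=float(tlen[0]))


def simulate_distribution(model: SplitModel, bin_width: float = 0.01):
    """Simulate ``model.n_loci`` independent single-SNP loci and summarize
    the per-locus FST distribution.

    Returns (bin_edges, bin_counts, summary) where summary holds the mean of
    per-locus estimates, the ratio-of-sums combination, the maximum, tail
    fractions and quantiles.  Loci where the estimator is undefined are
    excluded (cannot occur with the single-mutation scheme, which always
    yields a segregating site).
    """
    d, het, _ = simulate_join_model(
        model.n_chroms, [model.t_join], [1], [0], model.n_loci, model.seed)
    theta, a, denom = _per_locus_fst(model, d, het)
    ok = np.isfinite(theta)
    theta = theta[ok]
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    counts, edges = np.histogram(theta, bins=edges)
    q = np.quantile(theta, [0.5, 0.95, 0.99, 0.999])
    summary = {
        "n_loci": int(len(theta)),
        "mean_fst": float(theta.mean()),
        "ratio_of_sums_fst": float(a[ok].sum() / denom[ok].sum()),
        "max_fst": float(theta.max()),
        "q50": float(q[0]), "q95": float(q[1]), "q99": float(q[2]),
        "q999": float(q[3]),
        "frac_ge_0.5": float((theta >= 0.5).mean()),
        "frac_ge_0.682": float((theta >= 0.682).mean()),
        "frac_ge_0.832": float((theta >= 0.832).mean()),
    }
    return edges, counts, summary
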