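"""Core population-genetic estimators and scalar transforms.

Implements the statistics the haplotype-block analysis rests on: Nei–Li
nucleotide diversity (pi) and absolute divergence (dXY), Watterson's theta,
the Weir–Cockerham (1984) FST variance-component estimator, the Reynolds
(1983) coancestry estimator for population distance matrices, haplodiploid
effective population size, relative diversity change, the clean-split
scaled-time transform, molecular-clock dating and window bootstrap CIs.

All estimators are phase-free: each diploid contributes two haplotypes
through its per-site allele counts, so unphased genotypes suffice.  Missing
genotypes are excluded per site (per-site sample size); statistics are stored
as plain per-bp fractions and formatted as %/bp only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iolayer import MISSING, VariantMatrix

DEFAULT_MU = 5.27e-9  # mutations / bp / generation, A. mellifera - A. cerana
HAPLODIPLOID_SCALAR = 3.0


@dataclass
class ClockParams:
    """Molecular-clock and effective-size parameters.

    mu : per-bp per-generation mutation rate.
    generation_years : years per generation.
    inheritance_scalar : theta = scalar * N_E * mu; 3 for haplodiploids
        (honey bees), 4 for diploids.
    """

    mu: float = DEFAULT_MU
    generation_years: float = 1.0
    inheritance_scalar: float = HAPLODIPLOID_SCALAR

    def __post_init__(self):
        if min(self.mu, self.generation_years, self.inheritance_scalar) <= 0:
            raise ValueError("clock parameters must be strictly positive")


@dataclass
class DiversityResult:
    pi: float
    theta_w: float
    n_sites: int   # callable sites (denominator)
    n_snps: int    # segregating sites


@dataclass
class FstResult:
    """Weir–Cockerham estimate with its variance components.

    a: among-population, b: among-individual-within-population,
    c: within-individual.  theta_hat = sum(a) / sum(a + b + c).
    """

    theta_hat: float
    a: float
    b: float
    c: float
    n_sites: int


# ---------------------------------------------------------------------------
# per-site allele summaries
# ---------------------------------------------------------------------------

def allele_summaries(geno: np.ndarray):
    """Per-site called-diploid count, alt-allele frequency and observed
    heterozygote fraction from a (sites x samples) dosage block."""
    called = geno != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, geno, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = np.where(called, geno == 1, False).sum(axis=1) / n
    return n, p, h


def _region_geno(vm: VariantMatrix, sample_idx, region=None):
    g = vm.geno
    if region is not None:
        chrom, start, end = region
        g = g[vm.region_mask(chrom, start, end)]
    return g[:, np.asarray(sample_idx, dtype=int)]


def harmonic_number(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


# ---------------------------------------------------------------------------
# diversity and divergence
# ---------------------------------------------------------------------------

def nucleotide_diversity(vm: VariantMatrix, sample_idx, region=None,
                         n_callable=None) -> DiversityResult:
    """Nei–Li pi and Watterson's theta over a sample set and region.

    pi is the mean pairwise per-site difference over all haplotype pairs,
    computed from allele counts with the unbiased 2n/(2n-1) pairing
    correction and a per-site called sample size.  theta_w = S / (a_n * L)
    with a_n the harmonic number of (2 n_samples - 1) and L = ``n_callable``
    (defaults to the number of SNP sites in the region, which is only
    appropriate for toy data — pass the true callable length for real use).
    """
    g = _region_geno(vm, sample_idx, region)
    n, p, _ = allele_summaries(g)
    if len(n) and (n == 0).all():
        raise ValueError("no site has a callable genotype")
    if n_callable is None:
        n_callable = len(n)
    if n_callable < (len(n)):
        raise ValueError("n_callable smaller than the number of SNPs")
    ok = n >= 1
    two_n = 2.0 * n[ok]
    with np.errstate(invalid="ignore"):
        corr = np.where(two_n > 1, two_n / (two_n - 1.0), 0.0)
    pq = 2.0 * p[ok] * (1.0 - p[ok])
    pi = float(np.sum(pq * corr)) / n_callable
    seg = ok & (p > 0) & (p < 1)
    S = int(seg.sum())
    a_n = harmonic_number(2 * len(np.atleast_1d(sample_idx)) - 1)
    theta_w = S / (a_n * n_callable) if a_n > 0 else 0.0
    return DiversityResult(pi=pi, theta_w=theta_w,
                           n_sites=int(n_callable), n_snps=S)


def dxy(vm: VariantMatrix, idx_a, idx_b, region=None, n_callable=None) -> float:
    """Mean per-site difference over cross-group haplotype pairs
    (allele-count form: sum over sites of pa(1-pb) + pb(1-pa), / L)."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty group")
    if set(idx_a.tolist()) & set(idx_b.tolist()):
        raise ValueError("groups must be disjoint")
    ga = _region_geno(vm, idx_a, region)
    gb = _region_geno(vm, idx_b, region)
    na, pa, _ = allele_summaries(ga)
    nb, pb, _ = allele_summaries(gb)
    if n_callable is None:
        n_callable = len(na)
    ok = (na >= 1) & (nb >= 1)
    d = pa[ok] * (1 - pb[ok]) + pb[ok] * (1 - pa[ok])
    return float(np.sum(d)) / n_callable if n_callable else float("nan")


def pairwise_sample_distances(vm: VariantMatrix, sample_idx, region=None,
                              n_callable=None) -> np.ndarray:
    """Per-bp dXY between every pair of samples (each diploid contributing
    its two haplotypes).  Sites where either sample is uncalled contribute 0.
    """
    g = _region_geno(vm, sample_idx, region).astype(float)
    if g.size == 0:
        raise ValueError("no callable sites in region")
    if n_callable is None:
        n_callable = g.shape[0]
    called = g != MISSING
    P = np.where(called, g / 2.0, 0.0)
    M = called.astype(float)
    # sum over sites of p_i (1 - p_j) + p_j (1 - p_i), both called
    PM = P.T @ M
    D = PM + PM.T - 2.0 * (P.T @ P)
    np.fill_diagonal(D, 0.0)
    return D / n_callable


def excess_divergence_ratio(vm: VariantMatrix, idx_a, idx_b, region=None,
                            n_callable=None) -> float:
    """Mean cross-group pairwise sample distance over mean within-group
    distance.  Returns inf (flagged) when within-group distances are all 0."""
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    if len(idx_a) < 2 and len(idx_b) < 2:
        raise ValueError("need a group of size >= 2 for the within mean")
    all_idx = np.concatenate([idx_a, idx_b])
    D = pairwise_sample_distances(vm, all_idx, region, n_callable)
    na = len(idx_a)
    cross = D[:na, na:]
    within = []
    for blk in (D[:na, :na], D[na:, na:]):
        iu = np.triu_indices_from(blk, k=1)
        within.extend(blk[iu].tolist())
    wbar = float(np.mean(within))
    xbar = float(np.mean(cross))
    if wbar == 0:
        return float("inf")
    return xbar / wbar


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def wc_components(p, h, n):
    """Weir–Cockerham (1984) variance components a, b, c.

    Parameters are per-population alt frequencies ``p``, observed
    heterozygote fractions ``h`` and diploid sample sizes ``n``; each may be
    a vector of r populations or an (n_sites, r) array.  Returns (a, b, c)
    with the same leading shape.  Sites where a + b + c == 0 are undefined
    and must be excluded from multi-site sums by the caller.
    """
    p = np.atleast_2d(np.asarray(p, float))
    h = np.atleast_2d(np.asarray(h, float))
    n = np.broadcast_to(np.atleast_2d(np.asarray(n, float)), p.shape)
    r = p.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    if (n < 1).any():
        raise ValueError("every population needs n >= 1")
    nbar = n.mean(axis=1)
    nsum = n.sum(axis=1)
    nc = (nsum - (n ** 2).sum(axis=1) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=1) / nsum
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=1) / nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        inner = (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst_site(p, h, n) -> FstResult:
    """Single-site Weir–Cockerham estimate; theta_hat is nan (undefined)
    for a site monomorphic across all populations."""
    a, b, c = wc_components(p, h, n)
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return FstResult(theta_hat=theta, a=a, b=b, c=c, n_sites=1)


def wc_fst_multi(site_results) -> FstResult:
    """Ratio-of-sums combination: theta = sum(a) / sum(a+b+c) over defined
    sites."""
    A = B = C = 0.0
    n_def = 0
    for r in site_results:
        d = r.a + r.b + r.c
        if d == 0 or not np.isfinite(d):
            continue
        A += r.a
        B += r.b
        C += r.c
        n_def += 1
    if n_def == 0:
        raise ValueError("all sites undefined")
    return FstResult(theta_hat=A / (A + B + C), a=A, b=B, c=C, n_sites=n_def)


def wc_fst_from_geno(geno_by_pop) -> FstResult:
    """Multi-site WC FST from per-population dosage blocks (sites x samples).

    Sites with fewer than 2 called diploids in any population are excluded.
    """
    stats = [allele_summaries(g) for g in geno_by_pop]
    n = np.stack([s[0] for s in stats], axis=1).astype(float)
    p = np.stack([s[1] for s in stats], axis=1)
    h = np.stack([s[2] for s in stats], axis=1)
    ok = (n >= 2).all(axis=1)
    if not ok.any():
        raise ValueError("no site with >=2 called diploids per population")
    a, b, c = wc_components(p[ok], h[ok], n[ok])
    denom = a + b + c
    use = denom != 0
    if not use.any():
        raise ValueError("all sites undefined (monomorphic)")
    return FstResult(
        theta_hat=float(a[use].sum() / denom[use].sum()),
        a=float(a[use].sum()), b=float(b[use].sum()), c=float(c[use].sum()),
        n_sites=int(use.sum()),
    )


# ---------------------------------------------------------------------------
# Reynolds coancestry FST (population distance matrices)
# ---------------------------------------------------------------------------

def reynolds_pair(p1, p2, n1, n2):
    """Per-pair Reynolds (1983) coancestry estimate combined across loci.

    Method-of-moments ANOVA on haploid allele counts (m = 2n copies per
    diploid sample): per locus, with weighted mean frequency pbar,

        MSP = sum_k m_k (p_k - pbar)^2          (between, df = 1)
        MSG = sum_k m_k p_k (1 - p_k) / sum_k (m_k - 1)
        num = MSP - MSG,  den = MSP + (m_c - 1) MSG

    combined as sum(num)/sum(den); summing over both alleles of a biallelic
    locus scales numerator and denominator equally.  Returns nan when no
    locus is defined.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    m1, m2 = 2.0 * n1, 2.0 * n2
    ok = np.isfinite(p1) & np.isfinite(p2)
    if not ok.any():
        return float("nan")
    p1, p2 = p1[ok], p2[ok]
    M = m1 + m2
    pbar = (m1 * p1 + m2 * p2) / M
    msp = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2
    msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (M - 2.0)
    mc = M - (m1 ** 2 + m2 ** 2) / M
    num = msp - msg
    den = msp + (mc - 1.0) * msg
    tot = den.sum()
    return float(num.sum() / tot) if tot != 0 else float("nan")


def reynolds_fst(freqs: np.ndarray, n_per_pop) -> np.ndarray:
    """Pairwise Reynolds FST matrix from an (n_sites, r) frequency array and
    per-population diploid counts.  Symmetric, zero diagonal; an entry is nan
    when a pair shares no defined site."""
    freqs = np.asarray(freqs, float)
    r = freqs.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    n_per_pop = np.asarray(n_per_pop, float)
    out = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = reynolds_pair(
                freqs[:, i], freqs[:, j], n_per_pop[i], n_per_pop[j]
            )
    return out


# ---------------------------------------------------------------------------
# scalar transforms
# ---------------------------------------------------------------------------

def effective_population_size(theta_w: float, clock: ClockParams) -> float:
    """N_E = theta_w / (inheritance_scalar * mu)."""
    if theta_w < 0:
        raise ValueError("theta_w must be >= 0")
    return theta_w / (clock.inheritance_scalar * clock.mu)


def delta_pi(pi_h: float, pi_l: float) -> float:
    """Relative diversity change (pi_h - pi_l) / pi_l; strongly negative
    values indicate reduced variation in the first group."""
    if pi_l <= 0:
        raise ValueError("pi_l must be > 0")
    return (pi_h - pi_l) / pi_l


def split_scaled_time(fst: float) -> float:
    """Clean-split scaled divergence time T = -ln(1 - FST) / 2 (ms units,
    4N0 generations)."""
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    return -np.log(1.0 - fst) / 2.0


def clock_date(dxy_value: float, clock: ClockParams) -> float:
    """Constant molecular clock: split age in years = dxy / (2 mu) generations
    times the generation time."""
    if dxy_value < 0:
        raise ValueError("dxy must be >= 0")
    return dxy_value / (2.0 * clock.mu) * clock.generation_years


def window_bootstrap_ci(values, weights=None, reps: int = 2000,
                        seed: int = 0, level: float = 0.95):
    """Percentile bootstrap CI for the weighted mean of per-window values.

    Windows are resampled with replacement ``reps`` times; weights default to
    equal (pass callable-site counts to weight unequal windows).
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("need at least one window")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(reps, len(values)))
    v = values[idx]
    w = weights[idx]
    means = (v * w).sum(axis=1) / w.sum(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
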