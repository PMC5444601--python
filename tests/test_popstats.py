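"""Estimator unit tests: hand-derived oracles for pi, theta_w, dXY,
Weir–Cockerham and Reynolds FST, and the scalar transforms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapblock import popstats
from hapblock.popstats import ClockParams

from conftest import make_vm


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_pi_two_haplotypes_one_diff_in_ten():
    # a single het diploid carries two haplotypes differing at 1 of 10 sites
    vm = make_vm(np.array([[1]] + [[0]] * 9))
    d = popstats.nucleotide_diversity(vm, [0], n_callable=10)
    assert d.pi == pytest.approx(0.1)


def test_theta_w_harmonic_number():
    # 2 diploids (4 haplotypes), S = 3, L = 100: S / (L * (1 + 1/2 + 1/3))
    geno = np.array([[0, 1], [1, 0], [1, 1]])
    vm = make_vm(geno)
    d = popstats.nucleotide_diversity(vm, [0, 1], n_callable=100)
    assert d.n_snps == 3
    assert d.theta_w == pytest.approx(3 / (100 * (1 + 0.5 + 1 / 3)))


def test_monomorphic_region_zero():
    vm = make_vm(np.zeros((5, 3)))
    d = popstats.nucleotide_diversity(vm, [0, 1, 2], n_callable=50)
    assert d.pi == 0 and d.theta_w == 0


def test_pi_equals_bruteforce_pair_enumeration():
    # explicit haplotypes -> dosages; pi must equal the mean difference
    # over all unordered haplotype pairs
    rng = np.random.default_rng(5)
    haps = rng.integers(0, 2, size=(10, 6))  # 6 haplotypes = 3 diploids
    geno = haps[:, 0::2] + haps[:, 1::2]
    vm = make_vm(geno)
    d = popstats.nucleotide_diversity(vm, [0, 1, 2], n_callable=10)
    pairs = list(itertools.combinations(range(6), 2))
    brute = np.mean([
        np.mean(haps[:, i] != haps[:, j]) for i, j in pairs])
    assert d.pi == pytest.approx(brute)


def test_pi_excludes_missing_per_site():
    geno = np.array([[1, -1], [0, 1]])
    vm = make_vm(geno)
    d = popstats.nucleotide_diversity(vm, [0, 1], n_callable=10)
    # site 1: n=1, p=0.5 -> 0.5*2 = 1; site 2: n=2, p=0.25 -> 0.375*(4/3)=0.5
    assert d.pi == pytest.approx((1.0 + 0.5) / 10)


# ---------------------------------------------------------------------------
# dxy
# ---------------------------------------------------------------------------

def test_dxy_fixed_difference():
    geno = np.array([[2, 2, 0, 0]] + [[0, 0, 0, 0]] * 9)
    vm = make_vm(geno)
    assert popstats.dxy(vm, [0, 1], [2, 3], n_callable=10) == pytest.approx(0.1)


def test_dxy_identical_monomorphic_groups_zero():
    vm = make_vm(np.zeros((4, 4)))
    assert popstats.dxy(vm, [0, 1], [2, 3], n_callable=4) == 0


def test_dxy_matches_bruteforce_cross_pairs():
    rng = np.random.default_rng(11)
    haps = rng.integers(0, 2, size=(20, 16))  # 8 diploids
    geno = haps[:, 0::2] + haps[:, 1::2]
    vm = make_vm(geno)
    got = popstats.dxy(vm, [0, 1, 2, 3], [4, 5, 6, 7], n_callable=20)
    ha, hb = haps[:, :8], haps[:, 8:]
    brute = np.mean([np.mean(ha[:, i] != hb[:, j])
                     for i in range(8) for j in range(8)])
    assert got == pytest.approx(brute)


def test_dxy_empty_or_overlapping_groups_error():
    vm = make_vm(np.zeros((2, 4)))
    with pytest.raises(ValueError):
        popstats.dxy(vm, [], [1], n_callable=2)
    with pytest.raises(ValueError):
        popstats.dxy(vm, [0, 1], [1, 2], n_callable=2)


# ---------------------------------------------------------------------------
# Weir–Cockerham
# ---------------------------------------------------------------------------

def _wc_oracle(p, h, n):
    """Independent transcription of the 1984 variance components."""
    p, h, n = (np.asarray(x, float) for x in (p, h, n))
    r = len(p)
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_fixed_difference_is_one():
    r = popstats.wc_fst_site([1.0, 0.0], [0.0, 0.0], [10, 10])
    assert r.theta_hat == pytest.approx(1.0)


def test_wc_hand_evaluated_components():
    r = popstats.wc_fst_site([0.5, 0.5], [0.5, 0.5], [10, 10])
    assert r.a == pytest.approx(-0.013889, abs=1e-6)
    assert r.b == pytest.approx(0.013889, abs=1e-6)
    assert r.c == pytest.approx(0.25)
    assert r.theta_hat == pytest.approx(-0.05556, abs=1e-5)


def test_wc_region_level_frequencies():
    r = popstats.wc_fst_site([0.95, 0.10526], [0.10, 0.10526], [20, 19])
    a, b, c = _wc_oracle([0.95, 0.10526], [0.10, 0.10526], [20, 19])
    assert r.theta_hat == pytest.approx(a / (a + b + c))
    assert r.theta_hat == pytest.approx(0.830, abs=5e-3)


def test_wc_monomorphic_undefined():
    r = popstats.wc_fst_site([0.0, 0.0], [0.0, 0.0], [10, 10])
    assert np.isnan(r.theta_hat)


@given(st.lists(
    st.tuples(st.floats(0, 1), st.integers(2, 30), st.integers(2, 30)),
    min_size=1, max_size=8))
@settings(deadline=None, max_examples=50)
def test_wc_multi_matches_direct_summation(sites):
    """Ratio-of-sums combination equals brute-force component sums and is
    invariant to site order."""
    results = []
    for p1, k1, k2 in sites:
        p = [p1, min(1.0, p1 * 0.5 + 0.2)]
        h = [2 * x * (1 - x) for x in p]
        results.append(popstats.wc_fst_site(p, h, [k1, k2]))
    defined = [r for r in results if np.isfinite(r.theta_hat)
               and (r.a + r.b + r.c) != 0]
    if not defined:
        with pytest.raises(ValueError):
            popstats.wc_fst_multi(results)
        return
    multi = popstats.wc_fst_multi(results)
    A = sum(r.a for r in defined)
    D = sum(r.a + r.b + r.c for r in defined)
    assert multi.theta_hat == pytest.approx(A / D)
    rev = popstats.wc_fst_multi(results[::-1])
    assert rev.theta_hat == pytest.approx(multi.theta_hat)


def test_wc_multi_single_site_identity():
    r = popstats.wc_fst_site([0.8, 0.2], [0.2, 0.3], [12, 9])
    m = popstats.wc_fst_multi([r])
    assert m.theta_hat == pytest.approx(r.theta_hat)


# ---------------------------------------------------------------------------
# Reynolds
# ---------------------------------------------------------------------------

def _reynolds_oracle(p1, p2, n1, n2):
    """Independent per-locus mean-square evaluation, combined over loci."""
    m1, m2 = 2 * n1, 2 * n2
    num = den = 0.0
    for a, b in zip(p1, p2):
        pbar = (m1 * a + m2 * b) / (m1 + m2)
        msp = m1 * (a - pbar) ** 2 + m2 * (b - pbar) ** 2
        msg = (m1 * a * (1 - a) + m2 * b * (1 - b)) / (m1 + m2 - 2)
        mc = (m1 + m2) - (m1 ** 2 + m2 ** 2) / (m1 + m2)
        num += msp - msg
        den += msp + (mc - 1) * msg
    return num / den


def test_reynolds_identical_frequencies_near_zero():
    # with identical given frequencies the estimator's expectation is the
    # small negative bias term -1/(m_c - 1)
    p = np.tile([[0.3, 0.3]], (50, 1))
    f = popstats.reynolds_fst(p, [10, 10])
    assert f[0, 1] == pytest.approx(-1 / 19)


def test_reynolds_fixed_differences_one():
    p = np.tile([[1.0, 0.0]], (20, 1))
    f = popstats.reynolds_fst(p, [10, 10])
    assert f[0, 1] == pytest.approx(1.0)


def test_reynolds_toy_matches_hand_formula():
    p1 = [0.9, 0.4, 0.1]
    p2 = [0.2, 0.5, 0.6]
    f = popstats.reynolds_fst(np.column_stack([p1, p2]), [8, 11])
    assert f[0, 1] == pytest.approx(_reynolds_oracle(p1, p2, 8, 11))
    assert f[0, 1] == f[1, 0] and f[0, 0] == 0


# ---------------------------------------------------------------------------
# scalar transforms
# ---------------------------------------------------------------------------

def test_effective_population_size():
    clock = ClockParams()
    assert popstats.effective_population_size(3 * clock.mu, clock) \
        == pytest.approx(1.0)
    assert popstats.effective_population_size(0.0082, clock) \
        == pytest.approx(518_659, rel=1e-3)


def test_effective_size_printed_value_within_half_percent():
    # whole-panel Watterson theta of 0.82 %/bp against the printed N_E
    clock = ClockParams()
    ne = popstats.effective_population_size(0.0082, clock)
    assert ne == pytest.approx(516_601, rel=5e-3)


def test_delta_pi():
    assert popstats.delta_pi(0.5, 0.5) == 0
    assert popstats.delta_pi(0.52, 0.72) == pytest.approx(-0.278, abs=5e-4)
    assert popstats.delta_pi(0.20, 0.69) == pytest.approx(-0.710, abs=5e-4)
    with pytest.raises(ValueError):
        popstats.delta_pi(0.1, 0.0)


def test_split_scaled_time():
    assert popstats.split_scaled_time(0.0) == 0
    assert popstats.split_scaled_time(0.036) == pytest.approx(0.01833,
                                                              abs=5e-6)
    assert popstats.split_scaled_time(0.5) == pytest.approx(0.34657, abs=1e-5)
    with pytest.raises(ValueError):
        popstats.split_scaled_time(1.0)


def test_clock_date_linear_and_printed_value():
    clock = ClockParams()
    assert popstats.clock_date(0.0, clock) == 0
    assert popstats.clock_date(2 * clock.mu, clock) == pytest.approx(1.0)
    assert popstats.clock_date(0.0334, clock) == pytest.approx(3.17e6,
                                                               rel=2e-3)
    # linearity in dxy
    assert popstats.clock_date(0.02, clock) == pytest.approx(
        2 * popstats.clock_date(0.01, clock))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_identical_windows_zero_width():
    lo, hi = popstats.window_bootstrap_ci([0.3] * 5, reps=200, seed=1)
    assert lo == hi == pytest.approx(0.3)


def test_bootstrap_two_window_enumeration():
    # resamples of two equal-weight windows have means {a, (a+b)/2, b} with
    # probabilities {1/4, 1/2, 1/4}; the 95% percentile interval is (a, b)
    a, b = 0.1, 0.5
    lo, hi = popstats.window_bootstrap_ci([a, b], reps=4000, seed=3)
    assert lo == pytest.approx(a) and hi == pytest.approx(b)


def test_bootstrap_weighting_shifts_mean():
    vals = [0.0, 1.0]
    lo, hi = popstats.window_bootstrap_ci(vals, weights=[1e6, 1], reps=500,
                                          seed=0, level=0.4)
    # any resample containing the heavy window has mean ~0, so both the
    # 30th and 70th percentiles sit at ~0
    assert hi < 0.01


# ---------------------------------------------------------------------------
# excess divergence
# ---------------------------------------------------------------------------

def test_excess_divergence_panmictic_near_one():
    rng = np.random.default_rng(7)
    geno = rng.integers(0, 3, size=(400, 12)).astype(np.int8)
    vm = make_vm(geno)
    ratio = popstats.excess_divergence_ratio(vm, np.arange(6),
                                             np.arange(6, 12))
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_excess_divergence_diverged_groups_flagged_inf():
    geno = np.array([[0, 0, 2, 2]] * 5)
    vm = make_vm(geno)
    assert popstats.excess_divergence_ratio(vm, [0, 1], [2, 3]) == np.inf
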