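"""Distance matrices, neighbor joining and windowed quartet topologies."""

import numpy as np
import pandas as pd
import pytest

from hapblock import treetools
from hapblock.treetools import DistanceMatrix

from conftest import make_vm


def _tip_distances(newick):
    """Pairwise tip-to-tip path lengths parsed back from newick."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for a in tips:
        for b in tips:
            if a < b:
                out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_identical_samples_zero():
    vm = make_vm(np.zeros((10, 3)))
    dm = treetools.sample_distance_matrix(vm, n_callable=10)
    assert (dm.values == 0).all()


def test_distance_one_in_ten():
    geno = np.array([[2, 0]] + [[0, 0]] * 9)
    vm = make_vm(geno)
    dm = treetools.sample_distance_matrix(vm, n_callable=10)
    assert dm.values[0, 1] == pytest.approx(0.1)


def test_distance_matches_bruteforce():
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(30, 8))
    geno = haps[:, 0::2] + haps[:, 1::2]
    vm = make_vm(geno)
    dm = treetools.sample_distance_matrix(vm, n_callable=30)
    for i in range(4):
        for j in range(i + 1, 4):
            hi = haps[:, 2 * i:2 * i + 2]
            hj = haps[:, 2 * j:2 * j + 2]
            brute = np.mean([np.mean(hi[:, a] != hj[:, b])
                             for a in range(2) for b in range(2)])
            assert dm.values[i, j] == pytest.approx(brute)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _additive_matrix(bl):
    """4-taxon tree ((A,B),(C,D)) with branch lengths dict."""
    a, b, c, d, e = bl
    D = np.zeros((4, 4))
    D[0, 1] = D[1, 0] = a + b
    D[0, 2] = D[2, 0] = a + e + c
    D[0, 3] = D[3, 0] = a + e + d
    D[1, 2] = D[2, 1] = b + e + c
    D[1, 3] = D[3, 1] = b + e + d
    D[2, 3] = D[3, 2] = c + d
    return D


def test_nj_recovers_additive_four_taxon_tree():
    bl = (0.1, 0.2, 0.3, 0.15, 0.25)
    dm = DistanceMatrix(list("ABCD"), _additive_matrix(bl))
    nwk = treetools.neighbor_joining(dm)
    tips = _tip_distances(nwk)
    # NJ reproduces the additive metric exactly
    for (x, y), want in {("A", "B"): 0.3, ("C", "D"): 0.45,
                         ("A", "C"): 0.65, ("B", "D"): 0.6}.items():
        assert tips[(x, y)] == pytest.approx(want)


def test_nj_random_additive_trees_property():
    rng = np.random.default_rng(12)
    for _ in range(20):
        bl = rng.uniform(0.05, 1.0, size=5)
        dm = DistanceMatrix(list("ABCD"), _additive_matrix(bl))
        tips = _tip_distances(treetools.neighbor_joining(dm))
        assert tips[("A", "B")] == pytest.approx(bl[0] + bl[1])
        assert tips[("C", "D")] == pytest.approx(bl[2] + bl[3])


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    nwk = treetools.neighbor_joining(DistanceMatrix(list("ABC"), D))
    tips = _tip_distances(nwk)
    assert tips[("A", "B")] == pytest.approx(0.3)
    assert tips[("A", "C")] == pytest.approx(0.5)
    assert tips[("B", "C")] == pytest.approx(0.6)


def test_nj_matches_skbio_on_additive_matrix():
    """Independent-implementation cross-check on a 6-taxon additive tree."""
    import io

    from skbio import DistanceMatrix as SkDM, TreeNode
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(9)
    # build an additive matrix from a random caterpillar tree
    n = 6
    labels = [f"t{i}" for i in range(n)]
    depths = np.cumsum(rng.uniform(0.05, 0.3, size=n))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = depths[max(i, j)] + abs(depths[i] - depths[j]) \
                    * 0.1 + 0.05 * (i != j)
    D = (D + D.T) / 2
    ours = treetools.neighbor_joining(DistanceMatrix(labels, D))
    theirs = sk_nj(SkDM(D, ids=labels))
    ours_tree = TreeNode.read(io.StringIO(ours))
    rf = ours_tree.compare_rfd(theirs)
    assert rf == 0


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        treetools.neighbor_joining(
            DistanceMatrix(["A"], np.zeros((1, 1))))
    D = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], D)


def test_nj_equal_distances_zero_internal_branch():
    D = np.ones((4, 4)) - np.eye(4)
    nwk = treetools.neighbor_joining(DistanceMatrix(list("ABCD"), D))
    tips = _tip_distances(nwk)
    for pair, v in tips.items():
        assert v == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# window topologies
# ---------------------------------------------------------------------------

def test_window_topologies_generator_truth(small_bundle):
    vm, table = small_bundle.vm, small_bundle.samples
    counts = treetools.window_topologies(vm, table)
    counts = counts.set_index("chrom")
    # background-only chromosome clusters by locality
    c1 = counts.loc["1"]
    assert c1["locality"] > c1["environment"] + c1["mixed"]
    # block windows cluster by environment on the block chromosomes
    for chrom, bt in (("7", small_bundle.truth.blocks[0]),
                      ("9", small_bundle.truth.blocks[1])):
        c = counts.loc[chrom]
        n_block_windows = (bt.end - bt.start) // 10_000
        assert c["environment"] >= 0.7 * n_block_windows
    # counts sum to the window totals
    assert (counts[["locality", "mixed", "environment", "unresolved"]]
            .sum(axis=1) == counts["n_windows"]).all()


def test_window_topologies_tie_unresolved():
    # all four populations identical -> zero distances -> tie
    geno = np.tile(np.array([[1] * 16]), (30, 1)).astype(np.int8)
    rng = np.random.default_rng(1)
    geno = rng.integers(0, 3, size=(30, 4))
    geno = np.tile(geno, (1, 4))  # four identical populations
    vm = make_vm(geno)
    df = pd.DataFrame({
        "sample": vm.sample_ids,
        "locality": ["Mau"] * 8 + ["MtKenya"] * 8,
        "habitat": (["highland"] * 4 + ["lowland"] * 4) * 2,
        "altitude": 2000,
        "population": ["MF"] * 4 + ["MS"] * 4 + ["MKF"] * 4 + ["MKS"] * 4,
    })
    from hapblock.iolayer import SampleTable

    counts = treetools.window_topologies(vm, SampleTable(df), window=100,
                                         min_snps=5)
    assert counts["unresolved"].sum() == counts["n_windows"].sum()


def test_window_topologies_needs_four_pops(small_bundle):
    from hapblock.iolayer import SampleTable

    table = small_bundle.samples
    df = table.df.copy()
    df["population"] = "X"
    with pytest.raises(ValueError):
        treetools.window_topologies(small_bundle.vm, SampleTable(df))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _enumerate_fisher(table):
    """Brute-force two-sided Fisher p by hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, col1 - row2),
                                      min(col1, row1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def test_enrichment_equal_proportions_p_one():
    counts = pd.DataFrame([
        {"chrom": "7", "locality": 10, "mixed": 10, "environment": 10,
         "unresolved": 0, "n_windows": 30},
        {"chrom": "1", "locality": 20, "mixed": 20, "environment": 20,
         "unresolved": 0, "n_windows": 60},
    ])
    odds, p = treetools.topology_enrichment(counts, "7")
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_enrichment_matches_enumeration():
    counts = pd.DataFrame([
        {"chrom": "9", "locality": 31, "mixed": 20, "environment": 49,
         "unresolved": 0, "n_windows": 100},
        {"chrom": "1", "locality": 41, "mixed": 30, "environment": 29,
         "unresolved": 0, "n_windows": 100},
    ])
    _, p = treetools.topology_enrichment(counts, "9")
    assert p == pytest.approx(_enumerate_fisher([[49, 51], [29, 71]]),
                              rel=1e-9)


def test_enrichment_block_chromosomes_minimize_p(small_bundle):
    vm, table = small_bundle.vm, small_bundle.samples
    counts = treetools.window_topologies(vm, table)
    odds = {c: treetools.topology_enrichment(counts, c)[0]
            for c in ("1", "7", "9")}
    # block chromosomes are enriched for the environment topology, the
    # background chromosome depleted
    assert odds["7"] > 1 and odds["9"] > 1 and odds["1"] < 1
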