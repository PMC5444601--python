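"""Distance matrices, neighbor-joining trees and windowed quartet topologies.

Whole-genome (or per-region) pairwise dXY between samples feeds a standard
Saitou–Nei neighbor-joining tree.  For four populations, non-overlapping
windows are classified into one of the three unrooted quartet topologies by
the four-point condition on pairwise Reynolds FST — "by locality", "mixed"
or "by environment" — and per-chromosome enrichment of the environment
topology is scored with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popstats
from .iolayer import SampleTable, VariantMatrix
from .substmap import fisher_exact_2x2

TOPOLOGY_LABELS = ("locality", "mixed", "environment")


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any() or (v < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v


def sample_distance_matrix(vm: VariantMatrix, sample_idx=None, region=None,
                           n_callable=None) -> DistanceMatrix:
    """Average pairwise genetic distance (per-bp dXY) between all samples,
    each diploid contributing its two haplotypes."""
    if sample_idx is None:
        sample_idx = np.arange(vm.n_samples)
    sample_idx = np.asarray(sample_idx, int)
    if len(sample_idx) < 2:
        raise ValueError("need at least two samples")
    D = popstats.pairwise_sample_distances(vm, sample_idx, region, n_callable)
    labels = [vm.sample_ids[i] for i in sample_idx]
    return DistanceMatrix(labels=labels, values=D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns a newick string.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch (total edge length preserved).  Ties in the Q criterion
    resolve to the lexicographically first index pair, so the output is
    deterministic.  The root is the final trifurcation (unrooted tree).
    """
    D = np.array(dm.values, float)
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    n = len(dm.labels)
    if n < 3:
        if n == 2:
            return (f"({_esc(dm.labels[0])}:{D[0, 1]:.10g},"
                    f"{_esc(dm.labels[1])}:0);")
        raise ValueError("need at least 2 taxa")
    nodes = [_esc(l) for l in dm.labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # resolve the final three nodes as a trifurcation with analytic lengths
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    return (f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},"
            f"{nodes[2]}:{lc:.10g});")


def _clamp_pair(li, lj):
    if li < 0:
        lj += -li
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, lj


def _esc(label: str) -> str:
    return str(label).replace(" ", "_").replace(",", "_").replace("(", "_") \
        .replace(")", "_").replace(":", "_").replace(";", "_")


# ---------------------------------------------------------------------------
# windowed quartet topologies
# ---------------------------------------------------------------------------

_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _pairing_label(pops, meta, pairing) -> str:
    """Semantic label for a quartet pairing given population metadata."""
    (a, b), (c, d) = pairing
    def shares(col):
        return (meta.loc[pops[a], col] == meta.loc[pops[b], col]
                and meta.loc[pops[c], col] == meta.loc[pops[d], col])
    if shares("locality"):
        return "locality"
    if shares("habitat"):
        return "environment"
    return "mixed"


def window_topologies(vm: VariantMatrix, table: SampleTable,
                      window: int = 10_000, min_snps: int = 10) -> pd.DataFrame:
    """Classify non-overlapping windows into quartet topologies.

    Per window, pairwise Reynolds FST among the four populations (negative
    entries floored at 0) is reduced by the four-point condition: the
    pairing with the smallest sum of intra-pair distances wins.  Windows
    with fewer than ``min_snps`` SNPs, an undefined pair, or a tie are
    unresolved.  Returns per-chromosome counts of the three topologies.
    """
    pops = sorted(table.df["population"].unique())
    if len(pops) != 4:
        raise ValueError("window topologies need exactly 4 populations")
    groups = table.group_indices(vm, "population")
    meta = table.df.drop_duplicates("population").set_index("population")
    labels = {pairing: _pairing_label(pops, meta, pairing)
              for pairing in _PAIRINGS}

    # per-population per-site summaries, computed once
    stats = {p: popstats.allele_summaries(vm.geno[:, groups[p]]) for p in pops}
    n_dip = {p: len(groups[p]) for p in pops}

    rows = []
    for ci, chrom in enumerate(vm.chrom_ids):
        cmask = vm.chrom == ci
        pos = vm.pos[cmask]
        if len(pos) == 0:
            continue
        counts = {k: 0 for k in TOPOLOGY_LABELS}
        counts["unresolved"] = 0
        last = int(pos.max())
        for wstart in range(1, last + 1, window):
            wmask = (pos >= wstart) & (pos <= wstart + window - 1)
            if wmask.sum() < min_snps:
                if wmask.sum() > 0:
                    counts["unresolved"] += 1
                continue
            d = np.zeros((4, 4))
            defined = True
            for x in range(4):
                for y in range(x + 1, 4):
                    px = stats[pops[x]][1][cmask][wmask]
                    py = stats[pops[y]][1][cmask][wmask]
                    val = popstats.reynolds_pair(px, py, n_dip[pops[x]],
                                                 n_dip[pops[y]])
                    if not np.isfinite(val):
                        defined = False
                    d[x, y] = d[y, x] = max(0.0, val) if np.isfinite(val) else np.nan
            if not defined:
                counts["unresolved"] += 1
                continue
            sums = []
            for pairing in _PAIRINGS:
                (a, b), (c, e) = pairing
                sums.append(d[a, b] + d[c, e])
            sums = np.asarray(sums)
            best = sums.min()
            winners = np.flatnonzero(np.isclose(sums, best))
            if len(winners) > 1:
                counts["unresolved"] += 1
            else:
                counts[labels[_PAIRINGS[winners[0]]]] += 1
        rows.append({"chrom": chrom, **counts,
                     "n_windows": sum(counts.values())})
    return pd.DataFrame(rows)


def topology_enrichment(counts: pd.DataFrame, chrom: str,
                        topology: str = "environment"):
    """Fisher's exact test (two-sided) of one topology's windows on a focal
    chromosome vs the rest of the genome, among resolved windows.

    Returns (odds_ratio, p_value).
    """
    if counts["n_windows"].sum() == 0:
        raise ValueError("no windows counted")
    focal = counts[counts["chrom"] == chrom]
    rest = counts[counts["chrom"] != chrom]
    if focal.empty:
        raise KeyError(f"chromosome {chrom!r} not in counts")
    resolved = list(TOPOLOGY_LABELS)
    a = int(focal[topology].sum())
    b = int(focal[resolved].sum().sum()) - a
    c = int(rest[topology].sum())
    d = int(rest[resolved].sum().sum()) - c
    table = [[a, b], [c, d]]
    p = fisher_exact_2x2(table)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return odds, p
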