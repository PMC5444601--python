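"""Genome scan for divergent haplotype blocks.

A per-SNP Weir–Cockerham FST track between two habitat groups, outlier-based
region delineation, genotype-composition haplotype classification, haplotype
frequencies and region-level FST, pattern-matching assignment of unplaced
scaffolds, FST histograms and depth/coverage masking.

The biology this targets: an extended non-recombining block segregating two
deeply diverged haplotypes shows a dense run of high-FST SNPs, and every
sample is either homozygous for one haplotype or heterozygous across the
whole run — so counting a sample's 0/0, 0/1 and 1/1 genotypes at the
outlier SNPs genotypes the block like a single Mendelian locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iolayer import MISSING, DepthTable, SampleTable, VariantMatrix
from . import popstats

DEFAULT_FST_THRESHOLD = 0.5
DEFAULT_MERGE_GAP = 1_000_000
DEFAULT_HET_THRESHOLD = 0.88
DEFAULT_HOM_THRESHOLD = 0.80


@dataclass
class FstTrack:
    """Per-SNP FST with Weir–Cockerham components, plus scan summary."""

    df: pd.DataFrame  # columns: chrom, pos, a, b, c, fst
    genome_fst: float  # ratio-of-sums over defined SNPs
    n_defined: int

    def frac_below(self, threshold: float) -> float:
        fst = self.df["fst"].to_numpy()
        ok = np.isfinite(fst)
        return float((fst[ok] < threshold).mean()) if ok.any() else float("nan")


@dataclass
class RegionCall:
    region_id: str
    chrom: str
    first_outlier_pos: int
    last_outlier_pos: int
    n_snps: int       # all SNPs inside [first, last]
    n_outliers: int   # SNPs with fst > threshold
    region_fst: float  # ratio-of-sums over all SNPs inside
    region_fst_mean: float  # mean of defined site estimates (alternative)
    outlier_pos: np.ndarray = field(repr=False, default=None)

    @property
    def length(self) -> int:
        """Inclusive length in bp: last - first + 1."""
        return self.last_outlier_pos - self.first_outlier_pos + 1


@dataclass
class HaplotypeCall:
    sample_id: str
    region_id: str
    n00: int
    n01: int
    n11: int
    n_missing: int
    cls: str = "unclassified"   # hom_ref | het | hom_alt | ambiguous
    dosage: int = -1            # alt-enriched haplotype copies, 0/1/2
    tie: bool = False

    @property
    def fractions(self):
        tot = self.n00 + self.n01 + self.n11
        if tot == 0:
            return (float("nan"),) * 3
        return (self.n00 / tot, self.n01 / tot, self.n11 / tot)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def persite_fst_scan(vm: VariantMatrix, idx_a, idx_b) -> FstTrack:
    """Weir–Cockerham site estimates for every SNP between two groups.

    Sites with <2 called diploids in either group get nan components and are
    excluded from the genome-wide ratio-of-sums summary.
    """
    ga = vm.geno[:, np.asarray(idx_a, int)]
    gb = vm.geno[:, np.asarray(idx_b, int)]
    na, pa, ha = popstats.allele_summaries(ga)
    nb, pb, hb = popstats.allele_summaries(gb)
    p = np.stack([pa, pb], axis=1)
    h = np.stack([ha, hb], axis=1)
    n = np.stack([na, nb], axis=1).astype(float)
    ok = (n >= 2).all(axis=1)
    a = np.full(vm.n_sites, np.nan)
    b = np.full(vm.n_sites, np.nan)
    c = np.full(vm.n_sites, np.nan)
    if ok.any():
        a[ok], b[ok], c[ok] = popstats.wc_components(p[ok], h[ok], n[ok])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    df = pd.DataFrame({
        "chrom": [vm.chrom_ids[ci] for ci in vm.chrom],
        "pos": vm.pos, "a": a, "b": b, "c": c, "fst": fst,
    })
    defined = np.isfinite(denom) & (denom != 0)
    genome = (float(a[defined].sum() / denom[defined].sum())
              if defined.any() else float("nan"))
    return FstTrack(df=df, genome_fst=genome, n_defined=int(defined.sum()))


def fst_histogram(track: FstTrack, bin_width: float = 0.05,
                  regions=None) -> pd.DataFrame:
    """SNP counts per FST bin, stratified by region and remaining genome.

    Bins partition (0, 1] left-open right-closed; the first bin additionally
    absorbs estimates <= 0 (single-site WC values may be negative).
    """
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin width must divide (0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    fst = track.df["fst"].to_numpy()
    chrom = track.df["chrom"].to_numpy()
    pos = track.df["pos"].to_numpy()
    defined = np.isfinite(fst)

    def bin_counts(mask):
        v = np.clip(fst[mask & defined], 1e-12, 1.0)
        idx = np.ceil(v / bin_width).astype(int) - 1  # left-open right-closed
        return np.bincount(idx, minlength=n_bins)

    strata = {}
    in_any = np.zeros(len(fst), bool)
    for r in (regions or []):
        m = ((chrom == r.chrom) & (pos >= r.first_outlier_pos)
             & (pos <= r.last_outlier_pos))
        strata[r.region_id] = bin_counts(m)
        in_any |= m
    strata["genome"] = bin_counts(~in_any)
    out = pd.DataFrame(strata)
    out.insert(0, "bin_low", edges[:-1])
    out.insert(1, "bin_high", edges[1:])
    return out


def delineate_regions(track: FstTrack, threshold: float = DEFAULT_FST_THRESHOLD,
                      merge_gap: int = DEFAULT_MERGE_GAP,
                      id_prefix: str = "r") -> list:
    """Cluster outlier SNPs (fst > threshold) into regions per chromosome.

    Adjacent outliers within ``merge_gap`` bp belong to one region; region
    bounds are the first and last outlier positions (inclusive length).
    ``region_fst`` is the ratio-of-sums over all SNPs inside the bounds;
    the mean of defined site estimates is reported alongside.
    """
    df = track.df
    fst = df["fst"].to_numpy()
    out = []
    for chrom in df["chrom"].unique():
        cm = (df["chrom"] == chrom).to_numpy()
        o = cm & np.isfinite(fst) & (fst > threshold)
        opos = df.loc[o, "pos"].to_numpy()
        if len(opos) == 0:
            continue
        breaks = np.where(np.diff(opos) > merge_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(opos) - 1]])
        for k, (s, e) in enumerate(zip(starts, ends)):
            first, last = int(opos[s]), int(opos[e])
            inside = cm & (df["pos"].to_numpy() >= first) \
                        & (df["pos"].to_numpy() <= last)
            a = df.loc[inside, "a"].to_numpy()
            denom = (df.loc[inside, ["a", "b", "c"]].sum(axis=1)).to_numpy()
            dmask = np.isfinite(denom) & (denom != 0)
            ros = float(a[dmask].sum() / denom[dmask].sum()) if dmask.any() else np.nan
            site_est = fst[inside]
            mean_est = float(np.nanmean(site_est)) if np.isfinite(site_est).any() else np.nan
            suffix = "" if len(starts) == 1 else f".{k + 1}"
            out.append(RegionCall(
                region_id=f"{id_prefix}{chrom}{suffix}", chrom=str(chrom),
                first_outlier_pos=first, last_outlier_pos=last,
                n_snps=int(inside.sum()), n_outliers=int(e - s + 1),
                region_fst=ros, region_fst_mean=mean_est,
                outlier_pos=opos[s:e + 1].astype(np.int64),
            ))
    return out


def regions_table(regions) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": r.region_id, "chrom": r.chrom,
        "first_outlier": r.first_outlier_pos, "last_outlier": r.last_outlier_pos,
        "length": r.length, "n_snps": r.n_snps, "n_outliers": r.n_outliers,
        "fst_ratio_of_sums": r.region_fst, "fst_mean_of_sites": r.region_fst_mean,
    } for r in regions])


# ---------------------------------------------------------------------------
# haplotype genotyping from genotype composition
# ---------------------------------------------------------------------------

def genotype_composition(vm: VariantMatrix, region: RegionCall,
                         sample_idx=None) -> list:
    """Count each sample's 0/0, 0/1 and 1/1 genotypes at the region's
    outlier SNPs."""
    if region.outlier_pos is None or len(region.outlier_pos) == 0:
        raise ValueError(f"region {region.region_id} has no outlier SNPs")
    mask = vm.region_mask(region.chrom)
    mask &= np.isin(vm.pos, region.outlier_pos)
    if sample_idx is None:
        sample_idx = np.arange(vm.n_samples)
    sample_idx = np.asarray(sample_idx, int)
    g = vm.geno[mask][:, sample_idx]
    calls = []
    for j, si in enumerate(sample_idx):
        col = g[:, j]
        calls.append(HaplotypeCall(
            sample_id=vm.sample_ids[si], region_id=region.region_id,
            n00=int((col == 0).sum()), n01=int((col == 1).sum()),
            n11=int((col == 2).sum()), n_missing=int((col == MISSING).sum()),
        ))
    return calls


def composition_percentages(calls, sample_ids_by_group: dict) -> pd.DataFrame:
    """Group-level aggregate genotype percentages with denominator
    n_outlier_snps x n_samples (missing included in the denominator)."""
    rows = []
    for group, ids in sample_ids_by_group.items():
        sub = [c for c in calls if c.sample_id in set(ids)]
        denom = sum(c.n00 + c.n01 + c.n11 + c.n_missing for c in sub)
        for key in ("n00", "n01", "n11"):
            n = sum(getattr(c, key) for c in sub)
            rows.append({"group": group, "genotype": key.replace("n", "", 1),
                         "count": n, "denominator": denom,
                         "percent": 100.0 * n / denom if denom else np.nan})
    return pd.DataFrame(rows)


def classify_haplotypes(calls, het_threshold: float = DEFAULT_HET_THRESHOLD,
                        hom_threshold: float = DEFAULT_HOM_THRESHOLD) -> list:
    """Assign each sample a haplotype class from its genotype composition.

    het if the 0/1 fraction exceeds ``het_threshold``; hom_alt / hom_ref if
    the corresponding fraction reaches ``hom_threshold``; else ambiguous,
    with dosage by majority rule (ties flagged).  Zero counted genotypes →
    ambiguous.
    """
    out = []
    for c in calls:
        f00, f01, f11 = c.fractions
        cls, dosage, tie = "ambiguous", -1, False
        if np.isnan(f01):
            pass
        elif f01 > het_threshold:
            cls, dosage = "het", 1
        elif f11 >= hom_threshold:
            cls, dosage = "hom_alt", 2
        elif f00 >= hom_threshold:
            cls, dosage = "hom_ref", 0
        else:
            counts = np.array([c.n00, c.n01, c.n11])
            best = counts.max()
            if best > 0:
                winners = np.flatnonzero(counts == best)
                dosage = int(winners[0])
                tie = len(winners) > 1
        out.append(HaplotypeCall(
            sample_id=c.sample_id, region_id=c.region_id, n00=c.n00,
            n01=c.n01, n11=c.n11, n_missing=c.n_missing, cls=cls,
            dosage=dosage, tie=tie,
        ))
    return out


def haplotype_frequencies(calls, table: SampleTable,
                          group_by: str = "population") -> pd.DataFrame:
    """Per-group frequency of the alt-enriched haplotype: sum(dosage)/(2n).

    Ambiguous samples with a majority dosage are included; samples without a
    usable dosage are excluded with a warning count.
    """
    meta = table.df.set_index("sample")
    rows = []
    usable = [c for c in calls if c.dosage >= 0]
    df = pd.DataFrame([{
        "sample": c.sample_id, "dosage": c.dosage,
        "group": meta.loc[c.sample_id, group_by],
    } for c in usable])
    for group, sub in df.groupby("group"):
        rows.append({
            "group": group, "n_samples": len(sub),
            "n_excluded": sum(1 for c in calls if c.dosage < 0
                              and meta.loc[c.sample_id, group_by] == group),
            "frequency": float(sub["dosage"].sum() / (2.0 * len(sub))),
        })
    return pd.DataFrame(rows)


def region_fst_from_dosage(calls, ids_a, ids_b) -> popstats.FstResult:
    """Treat the region as one biallelic locus (per-sample genotype = block
    dosage) and compute single-locus Weir–Cockerham FST."""
    def stats(ids):
        d = np.array([c.dosage for c in calls
                      if c.sample_id in set(ids) and c.dosage >= 0], float)
        if len(d) == 0:
            raise ValueError("no classified samples in group")
        return d.sum() / (2 * len(d)), float((d == 1).mean()), len(d)

    pa, ha, na = stats(ids_a)
    pb, hb, nb = stats(ids_b)
    res = popstats.wc_fst_site([pa, pb], [ha, hb], [na, nb])
    if not np.isfinite(res.theta_hat):
        raise ValueError("region monomorphic across groups: FST undefined")
    return res


# ---------------------------------------------------------------------------
# unplaced scaffolds
# ---------------------------------------------------------------------------

def assign_unplaced(vm: VariantMatrix, track: FstTrack, reference_calls: dict,
                    scaffolds, threshold: float = DEFAULT_FST_THRESHOLD,
                    min_snps: int = 2, min_concordance: float = 0.8,
                    het_threshold: float = DEFAULT_HET_THRESHOLD,
                    hom_threshold: float = DEFAULT_HOM_THRESHOLD) -> pd.DataFrame:
    """Assign unplaced scaffolds to candidate regions by dosage concordance.

    Each scaffold's samples are classified from the scaffold's own outlier
    SNPs; the per-sample dosage vector is compared with each candidate
    region's vector (``reference_calls``: region id -> classified calls) and
    the scaffold is assigned to the region with maximal concordance when it
    has >= ``min_snps`` outliers and concordance >= ``min_concordance``.
    """
    ref_vec = {}
    for rid, calls in reference_calls.items():
        ref_vec[rid] = {c.sample_id: c.dosage for c in calls if c.dosage >= 0}
    rows = []
    for scaf in scaffolds:
        sub = track.df[track.df["chrom"] == scaf]
        fst = sub["fst"].to_numpy()
        opos = sub.loc[np.isfinite(fst) & (fst > threshold), "pos"].to_numpy()
        region = RegionCall(
            region_id=f"scaffold:{scaf}", chrom=scaf,
            first_outlier_pos=int(opos[0]) if len(opos) else 0,
            last_outlier_pos=int(opos[-1]) if len(opos) else 0,
            n_snps=len(sub), n_outliers=len(opos), region_fst=np.nan,
            region_fst_mean=np.nan, outlier_pos=opos.astype(np.int64),
        )
        best_rid, best_conc = "unassigned", np.nan
        if len(opos) >= min_snps:
            calls = classify_haplotypes(
                genotype_composition(vm, region),
                het_threshold, hom_threshold)
            vec = {c.sample_id: c.dosage for c in calls if c.dosage >= 0}
            scored = []
            for rid, rv in ref_vec.items():
                shared = [s for s in vec if s in rv]
                if not shared:
                    continue
                conc = float(np.mean([vec[s] == rv[s] for s in shared]))
                scored.append((conc, rid))
            if scored:
                scored.sort(reverse=True)
                if scored[0][0] >= min_concordance:
                    best_conc, best_rid = scored[0]
                else:
                    best_conc = scored[0][0]
        rows.append({"scaffold": scaf, "n_outliers": len(opos),
                     "assigned": best_rid, "concordance": best_conc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# depth masking
# ---------------------------------------------------------------------------

def depth_mask(vm: VariantMatrix, depth: DepthTable, low_frac: float = 0.3,
               high_frac: float = 3.0, min_called: float = 0.5,
               strict: bool = False):
    """Mask sites with aberrant group read depth or low call rate.

    A site is removed when any group's mean depth falls outside
    [low_frac x cohort average, high_frac x cohort average] or when the
    genotyped-sample fraction is below ``min_called``.  Sites absent from
    the depth table are retained with a warning (or rejected when
    ``strict``).  Returns (filtered matrix, report dict).
    """
    d = depth.df.set_index(["chrom", "pos"])
    cols = depth.depth_columns
    cohort_avg = float(d[cols].to_numpy().mean())
    keys = list(zip((vm.chrom_ids[c] for c in vm.chrom), (int(p) for p in vm.pos)))
    present = np.array([k in d.index for k in keys])
    if strict and not present.all():
        raise ValueError("depth table does not cover all matrix sites")
    keep = np.ones(vm.n_sites, bool)
    lo, hi = low_frac * cohort_avg, high_frac * cohort_avg
    sub = d.loc[[k for k, pr in zip(keys, present) if pr]]
    depth_ok = ((sub[cols] >= lo) & (sub[cols] <= hi)).all(axis=1).to_numpy()
    called_ok = (sub["called_frac"].to_numpy() >= min_called
                 if "called_frac" in sub.columns else np.ones(len(sub), bool))
    keep[present] = depth_ok & called_ok
    report = {
        "cohort_avg_depth": cohort_avg,
        "n_masked_depth": int((~depth_ok).sum()),
        "n_masked_called": int((depth_ok & ~called_ok).sum()),
        "n_no_depth_record": int((~present).sum()),
        "retained_fraction": float(keep.mean()) if vm.n_sites else float("nan"),
    }
    return vm.take_sites(keep), report


def retained_fraction_by_group(vm_before: VariantMatrix, vm_after: VariantMatrix,
                               depth: DepthTable, region: RegionCall,
                               low_frac: float = 0.3, high_frac: float = 3.0):
    """Per-group retained fraction inside a region (masking each group's
    depth column independently), mirroring subsample-stringency checks."""
    m = vm_before.region_mask(region.chrom, region.first_outlier_pos,
                              region.last_outlier_pos)
    keys = set(zip((vm_before.chrom_ids[c] for c in vm_before.chrom[m]),
                   (int(p) for p in vm_before.pos[m])))
    d = depth.df[[k in keys for k in zip(depth.df["chrom"], depth.df["pos"])]]
    cohort_avg = float(depth.df[depth.depth_columns].to_numpy().mean())
    out = {}
    for col in depth.depth_columns:
        v = d[col].to_numpy()
        ok = (v >= low_frac * cohort_avg) & (v <= high_frac * cohort_avg)
        out[col.replace("depth_", "")] = float(ok.mean()) if len(v) else np.nan
    return out
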