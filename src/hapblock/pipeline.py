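"""End-to-end orchestration: load → filter → stats → scan → classify →
trees → null simulation → substitutions → report.

Every stage is a pure function of (inputs, config, seed); the run writes a
manifest with the seed, a config hash and package version so identical runs
are byte-reproducible.  All thresholds live in :class:`RunConfig` defaults —
never inside the computations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blockscan, iolayer, popstats, splitsim, substmap, treetools

logger = logging.getLogger("hapblock")


@dataclass
class RunConfig:
    vcf: str = ""
    metadata: str = ""
    gff: str = ""
    reference: str = ""
    ancestral: str = ""
    depth: str = ""
    out_dir: str = "hapblock_out"
    group_by: str = "habitat"
    min_qual: float = 50.0
    fst_threshold: float = 0.5
    merge_gap: int = 1_000_000
    fine_merge_gap: int = 10_000
    het_threshold: float = 0.88
    hom_threshold: float = 0.80
    window: int = 10_000
    bootstrap_reps: int = 2000
    mu: float = popstats.DEFAULT_MU
    generation_years: float = 1.0
    inheritance_scalar: float = 3.0
    sim_loci: int = 1_000_000
    sim_n_chroms: tuple = (40, 38)
    seed: int = 1

    def validate(self):
        if not (0 < self.fst_threshold < 1):
            raise ValueError("fst_threshold must be in (0,1)")
        if not (0 < self.het_threshold <= 1 and 0 < self.hom_threshold <= 1):
            raise ValueError("class thresholds must be in (0,1]")
        if self.window <= 0 or self.bootstrap_reps <= 0 or self.sim_loci < 1:
            raise ValueError("window, bootstrap_reps and sim_loci must be positive")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def clock(self) -> popstats.ClockParams:
        return popstats.ClockParams(
            mu=self.mu, generation_years=self.generation_years,
            inheritance_scalar=self.inheritance_scalar)


def report_null_position(region_fst: float, edges, counts) -> float:
    """Fraction of simulated null loci with FST >= region_fst (0 means the
    observed value was never reached in the null)."""
    edges = np.asarray(edges, float)
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty null distribution")
    # count bins whose upper edge exceeds the value, pro-rating the boundary bin
    frac = np.zeros_like(counts)
    frac[edges[1:] <= region_fst] = 0.0
    above = edges[:-1] >= region_fst
    frac[above] = 1.0
    part = (~above) & (edges[1:] > region_fst)
    width = edges[1:][part] - edges[:-1][part]
    frac[part] = (edges[1:][part] - region_fst) / width
    return float((counts * frac).sum() / total)


def _gene_body_intervals(genes) -> dict:
    """Merged transcript spans per chromosome (1-based inclusive)."""
    by_chrom = {}
    for tr in genes.transcripts.values():
        lo = min(s for s, _, _ in tr.segments)
        hi = max(e for _, e, _ in tr.segments)
        by_chrom.setdefault(tr.chrom, []).append((lo, hi))
    merged = {}
    for c, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[c] = out
    return merged


def _overlap_len(ivs, a: int, b: int) -> int:
    return sum(max(0, min(e, b) - max(s, a) + 1) for s, e in ivs)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output tables/paths.

    Emits, in order: per-population diversity; the per-SNP FST track;
    region calls at two merge granularities (TSV + BED); haplotype calls,
    group frequencies and region dosage FST; newick trees (genome and per
    region); the simulated null distribution with observed region FSTs
    positioned in it; per-region haplotype diversity / divergence / dating;
    the substitution summary; and a reproducibility manifest.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    def stage(name):
        logger.info("stage: %s", name)

    # ---- load ------------------------------------------------------------
    stage("load")
    vm, table = iolayer.load_dataset(cfg.vcf, cfg.metadata)
    vm, filter_counts = iolayer.apply_site_filters(vm, min_qual=cfg.min_qual)
    results["filter_counts"] = filter_counts
    clock = cfg.clock()

    # ---- per-population diversity ---------------------------------------
    stage("diversity")
    rows = []
    genome_len = {c: int(vm.pos[vm.chrom == i].max()) if (vm.chrom == i).any()
                  else 0 for i, c in enumerate(vm.chrom_ids)}
    n_callable = sum(genome_len.values())
    for pop, idx in table.group_indices(vm, "population").items():
        div = popstats.nucleotide_diversity(vm, idx, n_callable=n_callable)
        rows.append({
            "population": pop, "n": len(idx), "n_snps": div.n_snps,
            "pi_pct": 100 * div.pi, "theta_w_pct": 100 * div.theta_w,
            "N_E": popstats.effective_population_size(div.theta_w, clock),
        })
    div_all = popstats.nucleotide_diversity(
        vm, np.arange(vm.n_samples), n_callable=n_callable)
    rows.append({
        "population": "ALL", "n": vm.n_samples, "n_snps": div_all.n_snps,
        "pi_pct": 100 * div_all.pi, "theta_w_pct": 100 * div_all.theta_w,
        "N_E": popstats.effective_population_size(div_all.theta_w, clock),
    })
    diversity = pd.DataFrame(rows)
    iolayer.write_tables(diversity, out / "diversity.tsv")
    results["diversity"] = diversity

    # ---- scan ------------------------------------------------------------
    stage("fst_scan")
    groups = table.group_indices(vm, cfg.group_by)
    if len(groups) != 2:
        raise ValueError(f"group key {cfg.group_by!r} must define 2 groups")
    (name_a, idx_a), (name_b, idx_b) = sorted(groups.items())
    if cfg.group_by == "habitat":
        idx_a, idx_b = table.habitat_partition(vm)
        name_a, name_b = "highland", "lowland"
    track = blockscan.persite_fst_scan(vm, idx_a, idx_b)
    iolayer.write_tables(track.df, out / "fst_track.tsv")
    results["track"] = track

    stage("regions")
    regions = blockscan.delineate_regions(
        track, cfg.fst_threshold, cfg.merge_gap)
    fine = blockscan.delineate_regions(
        track, cfg.fst_threshold, cfg.fine_merge_gap, id_prefix="fine_r")
    iolayer.write_tables(blockscan.regions_table(regions),
                         out / "regions.tsv")
    iolayer.write_tables(blockscan.regions_table(fine),
                         out / "regions_fine.tsv")
    if regions:
        iolayer.regions_to_bed(regions, out / "regions.bed")
    hist = blockscan.fst_histogram(track, regions=regions)
    iolayer.write_tables(hist, out / "fst_histogram.tsv")
    results["regions"] = regions
    results["regions_fine"] = fine
    results["histogram"] = hist
    if not regions:
        logger.info("no divergent regions found; downstream region stages "
                    "skipped")

    # ---- haplotype classification ---------------------------------------
    stage("haplotypes")
    hap_tables = []
    freq_tables = []
    region_fst_rows = []
    calls_by_region = {}
    for r in regions:
        calls = blockscan.classify_haplotypes(
            blockscan.genotype_composition(vm, r),
            cfg.het_threshold, cfg.hom_threshold)
        calls_by_region[r.region_id] = calls
        for c in calls:
            f00, f01, f11 = c.fractions
            hap_tables.append({
                "region": r.region_id, "sample": c.sample_id, "n00": c.n00,
                "n01": c.n01, "n11": c.n11, "n_missing": c.n_missing,
                "f00": f00, "f01": f01, "f11": f11, "class": c.cls,
                "dosage": c.dosage, "tie": c.tie,
            })
        fr = blockscan.haplotype_frequencies(calls, table, "population")
        fr.insert(0, "region", r.region_id)
        freq_tables.append(fr)
        fr_hab = blockscan.haplotype_frequencies(calls, table, "habitat")
        fr_hab.insert(0, "region", r.region_id)
        freq_tables.append(fr_hab)
        ids_a = [vm.sample_ids[i] for i in idx_a]
        ids_b = [vm.sample_ids[i] for i in idx_b]
        try:
            dos_fst = blockscan.region_fst_from_dosage(calls, ids_a, ids_b)
            region_fst_rows.append({
                "region": r.region_id, "dosage_fst": dos_fst.theta_hat,
                "snp_fst_ratio_of_sums": r.region_fst,
            })
        except ValueError:
            pass
    if hap_tables:
        iolayer.write_tables(pd.DataFrame(hap_tables),
                             out / "haplotype_calls.tsv")
        iolayer.write_tables(pd.concat(freq_tables, ignore_index=True),
                             out / "haplotype_frequencies.tsv")
        iolayer.write_tables(pd.DataFrame(region_fst_rows),
                             out / "region_dosage_fst.tsv")
    results["haplotype_calls"] = calls_by_region
    results["region_dosage_fst"] = pd.DataFrame(region_fst_rows)

    # ---- trees -----------------------------------------------------------
    stage("trees")
    dm = treetools.sample_distance_matrix(vm, n_callable=n_callable)
    newicks = {"genome": treetools.neighbor_joining(dm)}
    for r in regions:
        reg = (r.chrom, r.first_outlier_pos, r.last_outlier_pos)
        dmr = treetools.sample_distance_matrix(vm, region=reg,
                                               n_callable=r.length)
        newicks[r.region_id] = treetools.neighbor_joining(dmr)
    with open(out / "trees.nwk", "w") as fh:
        for name, nwk in newicks.items():
            fh.write(f"# {name}\n{nwk}\n")
    results["trees"] = newicks

    # ---- null simulation -------------------------------------------------
    stage("null_simulation")
    model = splitsim.SplitModel(
        n_chroms=tuple(cfg.sim_n_chroms),
        t_join=popstats.split_scaled_time(max(track.genome_fst, 0.0)),
        n_loci=cfg.sim_loci, seed=cfg.seed)
    edges, counts, summary = splitsim.simulate_distribution(model)
    null_rows = [{"bin_low": lo, "bin_high": hi, "count": int(n)}
                 for lo, hi, n in zip(edges[:-1], edges[1:], counts) if n]
    iolayer.write_tables(pd.DataFrame(null_rows), out / "null_bins.tsv")
    for row in region_fst_rows:
        row["null_exceedance"] = report_null_position(
            row["dosage_fst"], edges, counts)
    results["null_summary"] = summary
    results["null"] = (edges, counts)
    results["region_dosage_fst"] = pd.DataFrame(region_fst_rows)

    # ---- haplotype diversity / divergence / dating -----------------------
    stage("dating")
    genes = reference = anc = None
    if cfg.gff and cfg.ancestral:
        genes, anc = iolayer.load_annotations(cfg.gff, cfg.ancestral)
    if cfg.reference:
        reference = iolayer.load_reference(cfg.reference)
    table3 = []
    for r in regions:
        calls = calls_by_region[r.region_id]
        hom_h = [c.sample_id for c in calls if c.cls == "hom_alt"]
        hom_l = [c.sample_id for c in calls if c.cls == "hom_ref"]
        if len(hom_h) < 2 or len(hom_l) < 2:
            continue
        reg = (r.chrom, r.first_outlier_pos, r.last_outlier_pos)
        # molecular-clock dXY uses presumptively neutral variants outside
        # gene bodies; both the site mask and the callable length shrink
        gene_ivs = []
        if genes is not None:
            gene_ivs = _gene_body_intervals(genes).get(r.chrom, [])
        genic_mask = np.zeros(vm.n_sites, bool)
        if gene_ivs:
            sites = np.flatnonzero(vm.region_mask(*reg))
            for i in sites:
                p = int(vm.pos[i])
                genic_mask[i] = any(s <= p <= e for s, e in gene_ivs)
        row = {"region": r.region_id}
        for label, ids in (("h", hom_h), ("l", hom_l)):
            idx = vm.sample_indices(ids)
            div = popstats.nucleotide_diversity(vm, idx, region=reg,
                                                n_callable=r.length)
            row[f"n_{label}"] = len(ids)
            row[f"pi_pct_{label}"] = 100 * div.pi
            row[f"theta_w_pct_{label}"] = 100 * div.theta_w
            row[f"N_E_{label}"] = popstats.effective_population_size(
                div.theta_w, clock)
        # dXY at non-coding sites between homozygous classes, windowed CI
        idx_h = vm.sample_indices(hom_h)
        idx_l = vm.sample_indices(hom_l)
        win_vals, win_w = [], []
        for wstart in range(r.first_outlier_pos, r.last_outlier_pos + 1,
                            cfg.window):
            wend = min(wstart + cfg.window - 1, r.last_outlier_pos)
            m = vm.region_mask(r.chrom, wstart, wend) & ~genic_mask
            L = (wend - wstart + 1) - _overlap_len(gene_ivs, wstart, wend)
            if L <= 0:
                continue
            sub = vm.take_sites(m)
            if sub.n_sites == 0:
                continue
            d = popstats.dxy(sub, idx_h, idx_l, n_callable=L)
            win_vals.append(d)
            win_w.append(L)
        if not win_vals:
            continue
        w = np.asarray(win_w, float)
        d_nc = float(np.average(win_vals, weights=w))
        lo, hi = popstats.window_bootstrap_ci(
            win_vals, weights=w, reps=cfg.bootstrap_reps, seed=cfg.seed)
        row["dxy_noncoding_pct"] = 100 * d_nc
        row["dxy_ci_low_pct"] = 100 * lo
        row["dxy_ci_high_pct"] = 100 * hi
        row["split_my"] = popstats.clock_date(d_nc, clock) / 1e6
        row["split_my_ci_low"] = popstats.clock_date(lo, clock) / 1e6
        row["split_my_ci_high"] = popstats.clock_date(hi, clock) / 1e6
        row["delta_pi"] = popstats.delta_pi(
            row["pi_pct_h"] / 100, row["pi_pct_l"] / 100)
        table3.append(row)
    table3 = pd.DataFrame(table3)
    if len(table3):
        iolayer.write_tables(table3, out / "haplotype_divergence.tsv")
    results["haplotype_divergence"] = table3

    # ---- substitutions ---------------------------------------------------
    if genes is not None and reference is not None and anc is not None:
        stage("substitutions")
        subst_rows = []
        for r in regions:
            calls = calls_by_region[r.region_id]
            hom_h = [c.sample_id for c in calls if c.cls == "hom_alt"]
            hom_l = [c.sample_id for c in calls if c.cls == "hom_ref"]
            if not hom_h or not hom_l:
                continue
            reg_mask = vm.region_mask(r.chrom, r.first_outlier_pos,
                                      r.last_outlier_pos)
            idx_h = vm.sample_indices(hom_h)
            idx_l = vm.sample_indices(hom_l)
            fixed = substmap.fixed_differences(vm, idx_h, idx_l) & reg_mask
            pol = substmap.polarize_sites(vm, anc, site_mask=fixed)
            records = substmap.substitution_records(
                vm, pol, fixed, idx_h, idx_l, genes, reference)
            summary_df, p = substmap.branch_substitution_summary(records)
            summary_df.insert(0, "region", r.region_id)
            summary_df["fisher_p"] = np.nan if p is None else p
            summary_df["highland_branch_fraction"] = \
                substmap.derived_branch_fraction(records)
            subst_rows.extend(summary_df.to_dict("records"))
            rec_df = substmap.records_table(records)
            rec_df.insert(0, "region", r.region_id)
            iolayer.write_tables(
                rec_df, out / f"substitutions_{r.region_id}.tsv")
        if subst_rows:
            subst = pd.DataFrame(subst_rows)
            iolayer.write_tables(subst, out / "substitution_summary.tsv")
            results["substitutions"] = subst

    # ---- manifest --------------------------------------------------------
    stage("manifest")
    from . import __version__

    manifest = {
        "version": __version__, "seed": cfg.seed,
        "config_hash": _config_hash(cfg), "config": asdict(cfg),
        "n_sites_input": int(vm.n_sites + filter_counts["qual"]
                             + filter_counts["blacklist"]),
        "n_sites_retained": vm.n_sites,
        "genome_fst": track.genome_fst,
        "n_regions": len(regions),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
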