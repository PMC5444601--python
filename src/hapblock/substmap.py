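"""Outgroup polarization, fixed differences and substitution effects.

Given the haplotype classes called by the block scan, this module finds the
sites fixed between the two haplotype backgrounds, polarizes them with an
outgroup allele (parsimony: the allele shared with the outgroup is
ancestral), assigns each derived change to the branch it arose on, labels
coding changes synonymous / non-synonymous / stop against GFF3 gene models
and a reference sequence, and compares per-branch non-synonymous
proportions with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iolayer import MISSING, AncestralTable, GeneModelSet, VariantMatrix

EFFECTS = ("synonymous", "non-synonymous", "stop", "non-coding", "undetermined")

_COMP = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = None


def _codon_table():
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        tbl = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            tbl[stop] = "*"
        _CODON_TABLE = tbl
    return _CODON_TABLE


@dataclass
class PolarizedSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    status: str                 # polarized | unpolarized | missing_outgroup
    ancestral: str | None = None
    derived: str | None = None


@dataclass
class SubstitutionRecord:
    chrom: str
    pos: int
    branch: str                 # highland | lowland | unpolarized
    effect: str
    gene_id: str | None = None
    multi_transcript: bool = False


# ---------------------------------------------------------------------------
# polarization and fixed differences
# ---------------------------------------------------------------------------

def polarize_sites(vm: VariantMatrix, anc: AncestralTable,
                   site_mask=None) -> list:
    """Polarize each site by the outgroup allele.

    The shared allele is ancestral and the non-shared allele derived; an
    outgroup allele equal to neither ref nor alt leaves the site
    unpolarized; a site without an outgroup record is missing_outgroup.
    """
    idx = np.flatnonzero(site_mask) if site_mask is not None \
        else np.arange(vm.n_sites)
    out = []
    for i in idx:
        chrom = vm.chrom_ids[vm.chrom[i]]
        pos = int(vm.pos[i])
        ref, alt = str(vm.ref[i]), str(vm.alt[i])
        og = anc.allele_at(chrom, pos)
        if og is None:
            out.append(PolarizedSite(chrom, pos, ref, alt, "missing_outgroup"))
        elif og == ref:
            out.append(PolarizedSite(chrom, pos, ref, alt, "polarized",
                                     ancestral=ref, derived=alt))
        elif og == alt:
            out.append(PolarizedSite(chrom, pos, ref, alt, "polarized",
                                     ancestral=alt, derived=ref))
        else:
            out.append(PolarizedSite(chrom, pos, ref, alt, "unpolarized"))
    return out


def fixed_differences(vm: VariantMatrix, idx_h, idx_l,
                      max_missing: int = 0) -> np.ndarray:
    """Site mask of fixed variants between two homozygous sample groups.

    A site qualifies when every called genotype in one group is homozygous
    for one allele and every called genotype in the other group homozygous
    for the other, with no heterozygote and at most ``max_missing`` missing
    calls per group.
    """
    idx_h = np.asarray(idx_h, int)
    idx_l = np.asarray(idx_l, int)
    if len(idx_h) == 0 or len(idx_l) == 0:
        raise ValueError("both groups must be non-empty")
    gh = vm.geno[:, idx_h]
    gl = vm.geno[:, idx_l]

    def group_state(g):
        miss = (g == MISSING).sum(axis=1)
        any_het = (g == 1).any(axis=1)
        all0 = ((g == 0) | (g == MISSING)).all(axis=1) & (miss < g.shape[1])
        all2 = ((g == 2) | (g == MISSING)).all(axis=1) & (miss < g.shape[1])
        ok = ~any_het & (miss <= max_missing)
        return ok, all0, all2

    okh, h0, h2 = group_state(gh)
    okl, l0, l2 = group_state(gl)
    return okh & okl & ((h0 & l2) | (h2 & l0))


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

def _transcript_index(genes: GeneModelSet):
    """(chrom -> IntervalTree of transcripts) for site lookup."""
    from intervaltree import IntervalTree

    trees = {}
    for tr in genes.transcripts.values():
        t = trees.setdefault(tr.chrom, IntervalTree())
        for s, e, _ in tr.segments:
            t[s:e + 1] = tr  # interval end exclusive
    return trees


def _cds_context(tr, pos: int, reference: dict):
    """(codon string, offset within codon, cds sequence index) for a genomic
    position inside a transcript's CDS, in transcript orientation."""
    seq = reference[tr.chrom]
    parts = []
    pos_in_cds = None
    acc = 0
    for s, e, _ in tr.segments:
        if tr.strand == "+":
            part = seq[s - 1:e]
            if s <= pos <= e:
                pos_in_cds = acc + (pos - s)
        else:
            part = seq[s - 1:e][::-1].translate(_COMP)
            if s <= pos <= e:
                pos_in_cds = acc + (e - pos)
        parts.append(part)
        acc += e - s + 1
    if pos_in_cds is None:
        return None
    cds = "".join(parts)
    first_phase = tr.segments[0][2]
    i = pos_in_cds - first_phase
    if i < 0:
        return None
    codon_start = first_phase + (i // 3) * 3
    codon = cds[codon_start:codon_start + 3]
    if len(codon) < 3:
        return None  # incomplete terminal codon
    return codon, i % 3, codon_start


def coding_effect(chrom: str, pos: int, ref: str, alt: str,
                  genes: GeneModelSet, reference: dict,
                  trees=None):
    """Effect of substituting alt for ref at a genomic site.

    The codon containing the site is built from the reference sequence in
    transcript orientation (reverse-complemented on minus strands); the
    effect is synonymous iff the substituted codon encodes the same amino
    acid.  Sites outside all CDS are non-coding; a site in several
    transcripts is non-synonymous if non-synonymous in any (flagged multi);
    a change creating a stop codon is labelled stop.  Returns
    (effect, gene_id, multi_flag).
    """
    if reference[chrom][pos - 1] != ref:
        raise ValueError(
            f"reference base at {chrom}:{pos} is {reference[chrom][pos - 1]},"
            f" not {ref}")
    if trees is None:
        trees = _transcript_index(genes)
    hits = trees.get(chrom).overlap(pos, pos + 1) if chrom in trees else ()
    transcripts = {iv.data.transcript_id: iv.data for iv in hits}
    if not transcripts:
        return "non-coding", None, False
    table = _codon_table()
    effects, gene_ids = [], []
    for tr in transcripts.values():
        ctx = _cds_context(tr, pos, reference)
        if ctx is None:
            effects.append("undetermined")
            gene_ids.append(tr.gene_id)
            continue
        codon, off, _ = ctx
        base_ref, base_alt = (ref, alt) if tr.strand == "+" else (
            ref.translate(_COMP), alt.translate(_COMP))
        if codon[off] != base_ref:
            raise ValueError(f"codon/reference inconsistency at {chrom}:{pos}")
        mutated = codon[:off] + base_alt + codon[off + 1:]
        aa0, aa1 = table.get(codon), table.get(mutated)
        if aa0 is None or aa1 is None:
            effects.append("undetermined")
        elif aa1 == "*" and aa0 != "*":
            effects.append("stop")
        elif aa0 == aa1:
            effects.append("synonymous")
        else:
            effects.append("non-synonymous")
        gene_ids.append(tr.gene_id)
    multi = len(transcripts) > 1
    for rank in ("stop", "non-synonymous", "synonymous", "undetermined"):
        if rank in effects:
            return rank, gene_ids[effects.index(rank)], multi
    return "undetermined", gene_ids[0], multi


def substitution_records(vm: VariantMatrix, polarized, fixed_mask,
                         idx_h, idx_l, genes: GeneModelSet,
                         reference: dict) -> list:
    """Branch-assigned, effect-labelled records for polarized fixed sites.

    The branch is highland iff the derived allele is the highland-fixed
    allele (the allele all homozygous-highland samples carry).
    """
    trees = _transcript_index(genes)
    by_site = {(p.chrom, p.pos): p for p in polarized}
    idx_h = np.asarray(idx_h, int)
    out = []
    for i in np.flatnonzero(fixed_mask):
        chrom = vm.chrom_ids[vm.chrom[i]]
        pos = int(vm.pos[i])
        ref, alt = str(vm.ref[i]), str(vm.alt[i])
        p = by_site.get((chrom, pos))
        gh = vm.geno[i, idx_h]
        gh = gh[gh != MISSING]
        highland_allele = alt if (gh == 2).all() else ref
        if p is None or p.status != "polarized":
            branch = "unpolarized"
        elif p.derived == highland_allele:
            branch = "highland"
        else:
            branch = "lowland"
        effect, gene_id, multi = coding_effect(
            chrom, pos, ref, alt, genes, reference, trees)
        out.append(SubstitutionRecord(chrom=chrom, pos=pos, branch=branch,
                                      effect=effect, gene_id=gene_id,
                                      multi_transcript=multi))
    return out


# ---------------------------------------------------------------------------
# summaries and tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table (probability-mass
    definition: sum of hypergeometric probabilities <= that of the observed
    table)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def branch_substitution_summary(records):
    """Per-branch derived-change counts and non-synonymous fractions, with a
    two-sided Fisher's exact comparison of the coding fractions.

    Returns (summary DataFrame, p_value or None).  Stop-gain changes count
    as non-synonymous for the proportion (they change the protein); the test
    is skipped when a branch has no coding records.
    """
    rows = {}
    for branch in ("highland", "lowland", "unpolarized"):
        sub = [r for r in records if r.branch == branch]
        nonsyn = sum(r.effect in ("non-synonymous", "stop") for r in sub)
        syn = sum(r.effect == "synonymous" for r in sub)
        coding = nonsyn + syn
        rows[branch] = {
            "branch": branch, "n_total": len(sub), "n_coding": coding,
            "n_nonsyn": nonsyn, "n_syn": syn,
            "nonsyn_fraction": nonsyn / coding if coding else np.nan,
        }
    df = pd.DataFrame(rows.values())
    hl, ll = rows["highland"], rows["lowland"]
    p = None
    if hl["n_coding"] > 0 and ll["n_coding"] > 0:
        p = fisher_exact_2x2([[hl["n_nonsyn"], hl["n_syn"]],
                              [ll["n_nonsyn"], ll["n_syn"]]])
    return df, p


def derived_branch_fraction(records, branch: str = "highland") -> float:
    """Fraction of polarized fixed differences assigned to a branch."""
    pol = [r for r in records if r.branch != "unpolarized"]
    if not pol:
        return float("nan")
    return sum(r.branch == branch for r in pol) / len(pol)


def records_table(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "pos": r.pos, "branch": r.branch,
        "effect": r.effect, "gene_id": r.gene_id or "",
        "multi_transcript": r.multi_transcript,
    } for r in records])


def codon_site_options(chrom: str, pos: int, genes: GeneModelSet,
                       reference: dict, trees=None):
    """Substitution options across the codon containing a coding site.

    Returns (nonsyn_options, syn_options) where each option is a
    (genomic_pos, alt_base, effect) tuple over the three positions of the
    containing codon (first covering transcript), or None for a site
    outside all CDS or with an incomplete codon.  Used by the synthetic
    generator to bias founder changes toward or away from amino-acid
    replacement.
    """
    if trees is None:
        trees = _transcript_index(genes)
    hits = trees.get(chrom).overlap(pos, pos + 1) if chrom in trees else ()
    transcripts = [iv.data for iv in hits]
    if not transcripts:
        return None
    tr = transcripts[0]
    ctx = _cds_context(tr, pos, reference)
    if ctx is None:
        return None
    _, _, codon_start = ctx
    nonsyn, syn = [], []
    for delta in range(-2, 3):
        q = pos + delta
        if not any(s <= q <= e for s, e, _ in tr.segments):
            continue
        ctx2 = _cds_context(tr, q, reference)
        if ctx2 is None or ctx2[2] != codon_start:
            continue
        ref_q = reference[chrom][q - 1]
        for alt in "ACGT":
            if alt == ref_q:
                continue
            eff, _, _ = coding_effect(chrom, q, ref_q, alt, genes,
                                      reference, trees)
            if eff in ("non-synonymous", "stop"):
                nonsyn.append((q, alt, eff))
            elif eff == "synonymous":
                syn.append((q, alt, eff))
    return nonsyn, syn
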