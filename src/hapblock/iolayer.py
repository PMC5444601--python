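"""Data model and readers/writers for the formats the pipeline touches.

The in-memory currency of the package is a :class:`VariantMatrix` (biallelic
SNP dosages) plus a :class:`SampleTable` (per-sample locality / habitat /
altitude / population metadata).  Gene models, outgroup alleles and read
depths are carried by :class:`GeneModelSet`, :class:`AncestralTable` and
:class:`DepthTable`.

Coordinate convention: every position in this package is 1-based inclusive
(the VCF convention).  The only 0-based surface is BED export, where start is
shifted down by one and end is left unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hapblock")

MISSING = -1  # genotype dosage sentinel

SAMPLE_COLUMNS = ("sample", "locality", "habitat", "altitude", "population")
HABITATS = ("highland", "lowland")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantMatrix:
    """Biallelic SNP genotypes as alt-allele dosages.

    Attributes
    ----------
    chrom_ids : list of str
        Ordered chromosome / scaffold names.
    chrom : int array (n_sites,)
        Index into ``chrom_ids`` per site.
    pos : int array (n_sites,)
        1-based positions, strictly increasing within a chromosome.
    ref, alt : single-character arrays (n_sites,)
    geno : int8 array (n_sites, n_samples)
        Alt-allele dosage 0/1/2, or -1 for missing.
    qual : float array (n_sites,)
        Per-site variant quality score.
    sample_ids : list of str
        Column order of ``geno``.
    """

    chrom_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    qual: np.ndarray
    sample_ids: list

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if self.geno.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape mismatch")
        ok = np.isin(self.geno, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2,missing}")
        for ci in range(len(self.chrom_ids)):
            p = self.pos[self.chrom == ci]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on {self.chrom_ids[ci]}"
                )
        if (self.ref == self.alt).any():
            raise ValueError("ref and alt alleles must differ")

    # -- selection helpers --------------------------------------------------

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_ids.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def region_mask(self, chrom: str, start: int | None = None,
                    end: int | None = None) -> np.ndarray:
        """Boolean site mask for a 1-based inclusive interval."""
        m = self.chrom == self.chrom_index(chrom)
        if start is not None:
            m &= self.pos >= start
        if end is not None:
            m &= self.pos <= end
        return m

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[s] for s in ids], dtype=int)

    def take_sites(self, mask_or_idx) -> "VariantMatrix":
        return VariantMatrix(
            chrom_ids=list(self.chrom_ids),
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            geno=self.geno[mask_or_idx],
            qual=self.qual[mask_or_idx],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: locality, habitat, altitude, population."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.df["sample"].duplicated().any():
            dups = self.df.loc[self.df["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        bad = set(self.df["habitat"]) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.df["sample"].tolist()

    def samples_where(self, **kw) -> list:
        m = pd.Series(True, index=self.df.index)
        for col, val in kw.items():
            m &= self.df[col] == val
        return self.df.loc[m, "sample"].tolist()

    def group_indices(self, vm: VariantMatrix, key: str) -> dict:
        """Map each level of metadata column ``key`` to sample column indices."""
        out = {}
        for level in self.df[key].unique():
            ids = self.samples_where(**{key: level})
            out[str(level)] = vm.sample_indices(ids)
        return out

    def habitat_partition(self, vm: VariantMatrix):
        g = self.group_indices(vm, "habitat")
        return g["highland"], g["lowland"]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    segments: list  # [(start, end, phase)] 1-based inclusive, 5'->3' order
    partial: bool = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.segments)


@dataclass
class GeneModelSet:
    """CDS segments grouped per transcript, ordered in transcript orientation."""

    transcripts: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.transcripts)

    def add(self, tr: Transcript) -> None:
        # flag transcripts whose phase-adjusted CDS length is not a codon multiple
        first_phase = tr.segments[0][2] if tr.segments else 0
        if (tr.cds_length - first_phase) % 3 != 0:
            tr.partial = True
        self.transcripts[tr.transcript_id] = tr

    def on_chrom(self, chrom: str) -> list:
        return [t for t in self.transcripts.values() if t.chrom == chrom]


@dataclass
class AncestralTable:
    """Outgroup allele per site (the product of a whole-genome outgroup
    alignment; at most one record per site)."""

    df: pd.DataFrame  # columns: chrom, pos, allele

    def __post_init__(self):
        need = {"chrom", "pos", "allele"}
        if not need <= set(self.df.columns):
            raise ValueError(f"ancestral table needs columns {sorted(need)}")
        if self.df.duplicated(["chrom", "pos"]).any():
            raise ValueError("ancestral table has duplicate sites")
        self._lookup = {
            (c, p): a
            for c, p, a in zip(self.df["chrom"], self.df["pos"], self.df["allele"])
        }

    def allele_at(self, chrom: str, pos: int):
        return self._lookup.get((chrom, int(pos)))

    def coverage_fraction(self, vm: VariantMatrix) -> float:
        """Fraction of matrix sites with an outgroup record."""
        n = sum(
            (vm.chrom_ids[c], int(p)) in self._lookup
            for c, p in zip(vm.chrom, vm.pos)
        )
        return n / vm.n_sites if vm.n_sites else float("nan")


@dataclass
class DepthTable:
    """Per-site read depth by group plus genotyped-sample fraction.

    ``df`` columns: chrom, pos, depth_<group>... and optionally called_frac.
    """

    df: pd.DataFrame

    def __post_init__(self):
        if not {"chrom", "pos"} <= set(self.df.columns):
            raise ValueError("depth table needs chrom and pos columns")
        depth_cols = self.depth_columns
        if not depth_cols:
            raise ValueError("depth table has no depth_* columns")
        if (self.df[depth_cols].to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def depth_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("depth_")]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_dataset(vcf_path, metadata_path):
    """Read a VCF 4.x + metadata TSV into (VariantMatrix, SampleTable).

    Only biallelic SNP records are retained; multiallelic and indel records
    are dropped with a logged count.  Sample order in the matrix follows the
    VCF header.  Raises if the VCF lacks GT fields or if the VCF header and
    the metadata disagree on sample ids.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
    table = SampleTable(meta)
    vcf_only = sorted(set(samples) - set(table.sample_ids))
    meta_only = sorted(set(table.sample_ids) - set(samples))
    if vcf_only or meta_only:
        raise ValueError(
            "sample mismatch between VCF and metadata: "
            f"in VCF only {vcf_only}, in metadata only {meta_only}"
        )
    # align metadata rows to VCF column order
    table = SampleTable(
        meta.set_index("sample").loc[samples].reset_index()
    )

    chrom_ids, chrom_lookup = [], {}
    chroms, poss, refs, alts, quals, genos = [], [], [], [], [], []
    n_dropped = 0
    saw_gt = False
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if gts is None or len(gts) != len(samples):
            raise ValueError(f"record {v.CHROM}:{v.POS} has no usable GT field")
        saw_gt = True
        if v.CHROM not in chrom_lookup:
            chrom_lookup[v.CHROM] = len(chrom_ids)
            chrom_ids.append(v.CHROM)
        chroms.append(chrom_lookup[v.CHROM])
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        g = np.asarray(gts, dtype=np.int8)
        g[g == 3] = MISSING
        genos.append(g)
    if poss and not saw_gt:
        raise ValueError("VCF has no GT fields")
    if n_dropped:
        logger.info("%d record(s) dropped (not biallelic SNPs)", n_dropped)

    vm = VariantMatrix(
        chrom_ids=chrom_ids,
        chrom=np.asarray(chroms, dtype=np.int32),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype="U1"),
        alt=np.asarray(alts, dtype="U1"),
        geno=np.vstack(genos) if genos else np.empty((0, len(samples)), np.int8),
        qual=np.asarray(quals, dtype=float),
        sample_ids=samples,
    )
    vm.n_dropped = n_dropped
    vm.validate()
    return vm, table


def apply_site_filters(vm: VariantMatrix, min_qual: float = 50.0,
                       blacklist=None):
    """Remove sites with qual <= min_qual or in a (chrom, pos) blacklist.

    Returns (filtered VariantMatrix, removal-count dict).  The blacklist is
    the package-level surface for externally derived site masks such as a
    haploid-sample heterozygosity screen.
    """
    keep = ~(vm.qual <= min_qual)
    n_qual = int((~keep).sum())
    n_black = 0
    if blacklist:
        bl = {(str(c), int(p)) for c, p in blacklist}
        in_bl = np.fromiter(
            ((vm.chrom_ids[c], int(p)) in bl for c, p in zip(vm.chrom, vm.pos)),
            dtype=bool, count=vm.n_sites,
        )
        n_black = int((keep & in_bl).sum())
        keep &= ~in_bl
    out = vm.take_sites(keep)
    counts = {"qual": n_qual, "blacklist": n_black, "retained": int(keep.sum())}
    logger.info("site filters: %s", counts)
    return out, counts


def load_annotations(gff_path, ancestral_path):
    """Read GFF3 gene models and an ancestral-allele TSV.

    CDS segments are grouped per transcript via their Parent attribute and
    ordered 5'->3' in transcript orientation (ascending coordinate on plus
    strand, descending on minus).  CDS features with unknown strand cause the
    transcript to be skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    per_tr = {}
    skipped = set()
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id or "?"]
        phase = 0
        try:
            phase = int(cds.frame)
        except (TypeError, ValueError):
            pass
        for tid in parents:
            if cds.strand not in "+-":
                skipped.add(tid)
                continue
            gene = (cds.attributes.get("gene_id") or [""])[0]
            rec = per_tr.setdefault(
                tid, {"chrom": cds.seqid, "strand": cds.strand,
                      "gene": gene, "segs": []})
            rec["segs"].append((cds.start, cds.end, phase))
    for tid in skipped:
        logger.warning("transcript %s skipped: CDS with unknown strand", tid)
        per_tr.pop(tid, None)

    genes = GeneModelSet()
    for tid, rec in per_tr.items():
        segs = sorted(rec["segs"], key=lambda s: s[0],
                      reverse=(rec["strand"] == "-"))
        genes.add(Transcript(
            transcript_id=tid, gene_id=rec["gene"] or tid,
            chrom=rec["chrom"], strand=rec["strand"], segments=segs,
        ))

    anc_df = pd.read_csv(
        ancestral_path, sep="\t", dtype={"chrom": str, "pos": int, "allele": str}
    )
    return genes, AncestralTable(anc_df)


def load_depth(path) -> DepthTable:
    return DepthTable(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def load_reference(fasta_path) -> dict:
    """Reference sequences as a {chrom: str} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tables(df: pd.DataFrame, path) -> None:
    """Write any named-column stats table as TSV with header."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=False)


def regions_to_bed(regions, path) -> None:
    """Export region calls as BED (0-based half-open).

    Internal coordinates are 1-based inclusive, so only the start shifts.
    """
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.first_outlier_pos - 1}\t{r.last_outlier_pos}"
                     f"\t{r.region_id}\n")
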