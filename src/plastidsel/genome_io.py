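"""Reading/writing FASTA, GFF3 and SNP tables, and genomic->codon mapping.

Coordinates are 1-based inclusive in all files (GFF3/VCF convention) and
0-based half-open internally.  GeneModel exons are stored in transcription
order: for a minus-strand gene the first exon is the one with the highest
genomic coordinates.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_core import GeneticCode, NUCLEOTIDES

log = logging.getLogger(__name__)


class GenomeIOError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon structure on a reference contig.

    ``exons`` are (start, end) 0-based half-open genomic intervals in
    transcription order; ``feature_class`` distinguishes protein genes (the
    only ones with codon-level behavior) from structural RNAs.
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: tuple
    feature_class: str = "protein"
    group_label: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise GenomeIOError(f"{self.gene_id}: empty/inverted exon ({s},{e})")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise GenomeIOError(f"{self.gene_id}: overlapping exons")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic single-nucleotide variant (1-based genomic position)."""

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise GenomeIOError(f"SNP at {self.contig_id}:{self.position} has ref == alt")


@dataclass(frozen=True)
class CodonAddress:
    """A genomic position expressed in reading-strand codon coordinates."""

    gene_id: str
    codon_index: int
    codon_position: int  # 0|1|2 within the codon
    cds_codon: str


@dataclass(frozen=True)
class PositionAnnotation:
    """Classification of one genomic position against one gene model."""

    location_class: str  # intergenic | intronic | exonic
    gene_id: Optional[str] = None
    strand: Optional[str] = None
    feature_class: Optional[str] = None
    codon_address: Optional[CodonAddress] = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Read FASTA into {contig_id: uppercase sequence}; U mapped to T."""
    contigs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not contigs:
        raise GenomeIOError(f"no FASTA records in {path}")
    return contigs


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 annotation


def read_annotation(path, contigs: Optional[Mapping[str, str]] = None) -> list:
    """Parse a GFF3 file into GeneModels (gene + CDS/exon features).

    CDS features are grouped under their Parent gene; minus-strand exons are
    reordered into transcription order.  Genes whose spliced CDS length is
    not divisible by 3 are excluded with a warning.  tRNA/rRNA genes carry
    their feature class but no codon arithmetic.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        children = list(db.children(gene, featuretype=("CDS", "exon")))
        cds = [c for c in children if c.featuretype == "CDS"]
        parts = cds if cds else [c for c in children if c.featuretype == "exon"]
        feature_class = gene.attributes.get("gene_biotype", ["protein"])[0]
        if feature_class in ("protein_coding", "CDS"):
            feature_class = "protein"
        if not parts:
            log.warning("gene %s has no CDS/exon children; skipped", gene.id)
            continue
        intervals = sorted((f.start - 1, f.end) for f in parts)  # to 0-based half-open
        if gene.strand == "-":
            intervals = intervals[::-1]
        if contigs is not None:
            if gene.seqid not in contigs:
                raise GenomeIOError(f"gene {gene.id}: contig {gene.seqid!r} not in FASTA")
            clen = len(contigs[gene.seqid])
            for s, e in intervals:
                if s < 0 or e > clen:
                    raise GenomeIOError(f"gene {gene.id}: interval ({s},{e}) outside contig")
        model = GeneModel(
            gene_id=gene.id,
            contig_id=gene.seqid,
            strand=gene.strand,
            exons=tuple(intervals),
            feature_class=feature_class,
        )
        if feature_class == "protein" and model.cds_length % 3:
            log.warning(
                "gene %s: CDS length %d not divisible by 3; excluded",
                gene.id, model.cds_length,
            )
            continue
        models.append(model)
    return models


def write_annotation(models: Iterable[GeneModel], path) -> None:
    """Write GeneModels as minimal GFF3 (gene + CDS features)."""
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        biotype = "protein_coding" if m.feature_class == "protein" else m.feature_class
        lines.append(
            "\t".join(
                [m.contig_id, "plastidsel", "gene", str(start + 1), str(end), ".",
                 m.strand, ".", f"ID={m.gene_id};gene_biotype={biotype}"]
            )
        )
        ftype = "CDS" if m.feature_class == "protein" else "exon"
        for i, (s, e) in enumerate(m.exons):
            phase = "0" if ftype == "CDS" else "."
            lines.append(
                "\t".join(
                    [m.contig_id, "plastidsel", ftype, str(s + 1), str(e), ".",
                     m.strand, phase, f"ID={m.gene_id}.{ftype.lower()}{i};Parent={m.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CDS extraction and position mapping

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def extract_cds(model: GeneModel, contigs: Mapping[str, str],
                code: Optional[GeneticCode] = None) -> str:
    """Splice and strand-correct the coding sequence of a gene model."""
    if model.contig_id not in contigs:
        raise GenomeIOError(f"gene {model.gene_id}: contig {model.contig_id!r} missing")
    contig = contigs[model.contig_id]
    pieces = []
    for s, e in model.exons:
        if e > len(contig):
            raise GenomeIOError(f"gene {model.gene_id}: exon ({s},{e}) beyond contig end")
        piece = contig[s:e]
        pieces.append(revcomp(piece) if model.strand == "-" else piece)
    cds = "".join(pieces)
    if code is not None and model.feature_class == "protein":
        if cds[:3] not in ("ATG", "GTG", "TTG"):
            log.warning("gene %s does not start with a start codon (%s)", model.gene_id, cds[:3])
        internal = [i // 3 for i in range(0, len(cds) - 3, 3) if code.is_stop(cds[i:i + 3])]
        if internal:
            log.warning("gene %s has internal stop codons at codons %s", model.gene_id, internal)
    return cds


def _cds_offset(model: GeneModel, pos0: int) -> Optional[int]:
    """0-based CDS offset of genomic position pos0, or None if not exonic."""
    offset = 0
    for s, e in model.exons:
        if s <= pos0 < e:
            return offset + (pos0 - s if model.strand == "+" else (e - 1) - pos0)
        offset += e - s
    return None


def map_position(
    contig_id: str,
    position: int,
    models: Sequence[GeneModel],
    contigs: Optional[Mapping[str, str]] = None,
) -> list:
    """Classify a 1-based genomic position against every overlapping gene.

    Returns one PositionAnnotation per overlapping gene copy, or a single
    intergenic annotation if no gene covers the position.  For exonic
    positions of protein genes (when ``contigs`` is given) the annotation
    carries the strand-corrected CodonAddress.
    """
    pos0 = position - 1
    hits = []
    for m in models:
        if m.contig_id != contig_id:
            continue
        lo, hi = m.span
        if not (lo <= pos0 < hi):
            continue
        offset = _cds_offset(m, pos0)
        if offset is None:
            hits.append(PositionAnnotation("intronic", m.gene_id, m.strand, m.feature_class))
            continue
        address = None
        if m.feature_class == "protein" and contigs is not None:
            cds = extract_cds(m, contigs)
            ci, cp = divmod(offset, 3)
            address = CodonAddress(m.gene_id, ci, cp, cds[3 * ci : 3 * ci + 3])
        hits.append(PositionAnnotation("exonic", m.gene_id, m.strand, m.feature_class, address))
    return hits or [PositionAnnotation("intergenic")]


# ---------------------------------------------------------------------------
# SNP tables (VCF v4.x or 4-column TSV)


def _read_vcf(path) -> tuple:
    from cyvcf2 import VCF

    records, skipped = [], 0
    for var in VCF(str(path)):
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1 \
                or var.REF not in NUCLEOTIDES or alts[0] not in NUCLEOTIDES:
            skipped += 1
            continue
        records.append(SnpRecord(var.CHROM, var.POS, var.REF, alts[0]))
    return records, skipped


def _read_tsv(path) -> tuple:
    records, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeIOError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            contig, pos, ref, alt = fields[:4]
            try:
                position = int(pos)
            except ValueError:
                raise GenomeIOError(f"{path}:{lineno}: bad position {pos!r}") from None
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or "," in alt \
                    or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                skipped += 1
                continue
            records.append(SnpRecord(contig, position, ref, alt))
    return records, skipped


def read_snp_table(path, reference: Optional[Mapping[str, str]] = None) -> list:
    """Read SNPs from VCF v4.x or a 4-column TSV (contig, pos, ref, alt).

    Indels and multiallelic records are skipped (count logged).  When a
    reference is given, each SNP's ref allele is validated against it.
    """
    text_head = Path(path).open().readline()
    if text_head.startswith("##fileformat=VCF") or str(path).endswith(".vcf"):
        records, skipped = _read_vcf(path)
    else:
        records, skipped = _read_tsv(path)
    if skipped:
        log.info("skipped %d non-SNP records in %s", skipped, path)
    if reference is not None:
        for rec in records:
            if rec.contig_id not in reference:
                raise GenomeIOError(f"SNP {rec.contig_id}:{rec.position}: unknown contig")
            actual = reference[rec.contig_id][rec.position - 1]
            if actual != rec.ref_allele:
                raise GenomeIOError(
                    f"SNP {rec.contig_id}:{rec.position}: ref allele "
                    f"{rec.ref_allele} disagrees with reference base {actual}"
                )
    return records


def write_snp_table(records: Iterable[SnpRecord], path,
                    contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write SNPs as a minimal VCF v4.2."""
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        lines.append(f"{r.contig_id}\t{r.position}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")
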