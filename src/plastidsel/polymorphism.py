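"""Within-species SNP classification and pN/pS summarization.

Each high-confidence SNP is located against the gene annotation
(intergenic / intronic / exonic) and, for exonic positions of protein
genes, classified at codon level as synonymous, nonsynonymous or nonsense
using the reading-strand alleles.  Per-gene counts are then pooled into the
configured concatenation groups; pN and pS divide the nonsynonymous and
synonymous counts by the groups' fractional site totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .codon_core import CodonSiteCounts, GeneticCode, classify_single_change
from .genome_io import (CodonAddress, GeneModel, GenomeIOError, SnpRecord,
                        complement_base, map_position)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpClassification:
    """One SNP's location class and (for coding positions) codon effect."""

    snp: SnpRecord
    location_class: str  # intergenic | intronic | exonic
    effect: str  # synonymous | nonsynonymous | nonsense | NA
    gene_id: Optional[str] = None
    codon_address: Optional[CodonAddress] = None


@dataclass(frozen=True)
class PolymorphismSummary:
    """Counts and site-normalized rates for one gene group (pN, pS, pN/pS)."""

    group_label: str
    p_n_count: int
    p_s_count: int
    nonsense_count: int
    n_sites: float
    s_sites: float

    @property
    def pN(self) -> float:
        return self.p_n_count / self.n_sites if self.n_sites > 0 else math.nan

    @property
    def pS(self) -> float:
        return self.p_s_count / self.s_sites if self.s_sites > 0 else math.nan

    @property
    def pnps(self) -> float:
        """pN/pS; NaN (inestimable) exactly when no synonymous SNP was seen."""
        if self.p_s_count == 0:
            return math.nan
        return self.pN / self.pS

    @property
    def total_snps(self) -> int:
        return self.p_n_count + self.p_s_count


def classify_snps(
    snps: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    contigs: Mapping[str, str],
    code: GeneticCode,
) -> list:
    """Classify every SNP against the annotation.

    A SNP falling in N overlapping gene copies yields N classifications.
    For minus-strand genes the ref/alt alleles are complemented before the
    codon-level call; nonsense changes (stop gains) are labeled separately.
    """
    out = []
    for snp in snps:
        if snp.contig_id not in contigs:
            raise GenomeIOError(f"SNP {snp.contig_id}:{snp.position}: unknown contig")
        actual = contigs[snp.contig_id][snp.position - 1]
        if actual != snp.ref_allele:
            raise GenomeIOError(
                f"SNP {snp.contig_id}:{snp.position}: ref allele {snp.ref_allele} "
                f"does not match reference base {actual}"
            )
        for hit in map_position(snp.contig_id, snp.position, models, contigs):
            if hit.location_class != "exonic" or hit.feature_class != "protein":
                out.append(SnpClassification(snp, hit.location_class, "NA", hit.gene_id))
                continue
            addr = hit.codon_address
            alt = snp.alt_allele
            if hit.strand == "-":
                alt = complement_base(alt)
            effect = classify_single_change(addr.cds_codon, addr.codon_position, alt, code)
            out.append(SnpClassification(snp, "exonic", effect, hit.gene_id, addr))
    return out


def tally_polymorphism(
    classifications: Sequence[SnpClassification],
    models: Sequence[GeneModel],
    grouping: Mapping[str, str],
    site_counts_per_gene: Mapping[str, CodonSiteCounts],
    excluded_genes: Sequence[str] = (),
) -> list:
    """Pool coding-SNP counts and site counts into gene groups.

    Nonsense SNPs count toward pN (they alter the protein) and are also
    reported in their own column.  Groups are the union of groups present in
    the annotation, so groups with zero SNPs still get a row.
    """
    excluded = set(excluded_genes)
    protein_genes = [m.gene_id for m in models
                     if m.feature_class == "protein" and m.gene_id not in excluded]
    missing = [g for g in protein_genes if g not in site_counts_per_gene]
    if missing:
        raise GenomeIOError(f"genes missing site counts: {missing}")

    groups: dict = {}
    for gene in protein_genes:
        label = grouping.get(gene, gene)
        agg = groups.setdefault(label, {"pn": 0, "ps": 0, "nonsense": 0,
                                        "n_sites": 0.0, "s_sites": 0.0})
        sc = site_counts_per_gene[gene]
        agg["n_sites"] += sc.n_sites
        agg["s_sites"] += sc.s_sites

    for cl in classifications:
        if cl.location_class != "exonic" or cl.gene_id in excluded or cl.effect == "NA":
            continue
        label = grouping.get(cl.gene_id, cl.gene_id)
        if label not in groups:
            continue
        if cl.effect == "synonymous":
            groups[label]["ps"] += 1
        else:  # nonsynonymous or nonsense
            groups[label]["pn"] += 1
            if cl.effect == "nonsense":
                groups[label]["nonsense"] += 1

    return [
        PolymorphismSummary(label, a["pn"], a["ps"], a["nonsense"], a["n_sites"], a["s_sites"])
        for label, a in sorted(groups.items())
    ]


def polymorphism_table(summaries: Sequence[PolymorphismSummary]) -> pd.DataFrame:
    """One row per group: counts, sites, pN, pS, pN/pS (NaN = inestimable)."""
    rows = [
        {
            "group": s.group_label,
            "Pn": s.p_n_count,
            "Ps": s.p_s_count,
            "nonsense": s.nonsense_count,
            "N_sites": s.n_sites,
            "S_sites": s.s_sites,
            "pN": s.pN,
            "pS": s.pS,
            "pN/pS": s.pnps,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
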