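"""Pairwise interspecific divergence from codon alignments (NG86 counting).

For a species pair, codon columns containing gaps or ambiguity codes (or
falling inside an explicit exclusion mask for unalignable regions) are
skipped; differences are decomposed into nonsynonymous/synonymous fractions
by pathway averaging; proportions are Jukes–Cantor corrected,
d = -(3/4)·ln(1 - (4/3)·p), applied separately to the nonsynonymous and
synonymous proportions; omega = dN/dS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .codon_core import (CodonDiffCounts, CodonSiteCounts, GeneticCode,
                         codon_site_counts, count_codon_differences,
                         normalize_codon)

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a difference proportion reaches 3/4 (JC distance undefined)."""


@dataclass
class CodonAlignment:
    """A per-gene multi-species alignment of coding sequence.

    ``mask`` lists 0-based half-open intervals of alignment columns (in
    nucleotide coordinates) excluded from every computation — the hook for
    manually curated unalignable regions.
    """

    gene_id: str
    sequences: dict
    mask: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal alignment lengths {lengths}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codon_masked(self, idx: int) -> bool:
        lo, hi = 3 * idx, 3 * idx + 3
        return any(s < hi and lo < e for s, e in self.mask)


@dataclass(frozen=True)
class PairwiseDivergence:
    """NG86 divergence summary for one species pair of one gene."""

    species_pair: tuple
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    n_codons_used: int
    dN: float
    dS: float
    omega: float  # NaN when inestimable
    zero_ds_fallback_used: bool = False

    @property
    def p_n(self) -> float:
        return self.nd / self.n_sites if self.n_sites else math.nan

    @property
    def p_s(self) -> float:
        return self.sd / self.s_sites if self.s_sites else math.nan


def jukes_cantor(p: float) -> float:
    """JC69 correction d = -(3/4)·ln(1 - (4/3)·p); errors at saturation."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def usable_codon_pairs(alignment: CodonAlignment, sp_a: str, sp_b: str):
    """Yield (codon_index, codon_a, codon_b) for comparable codon columns."""
    for sp in (sp_a, sp_b):
        if sp not in alignment.sequences:
            raise KeyError(f"{alignment.gene_id}: species {sp!r} not in alignment")
    seq_a, seq_b = alignment.sequences[sp_a], alignment.sequences[sp_b]
    for i in range(alignment.n_codons):
        if alignment.codon_masked(i):
            continue
        ca = normalize_codon(seq_a[3 * i : 3 * i + 3])
        cb = normalize_codon(seq_b[3 * i : 3 * i + 3])
        if ca is None or cb is None:  # gap or ambiguity in either sequence
            continue
        yield i, ca, cb


def extract_pairwise_snps(alignment: CodonAlignment, sp_a: str, sp_b: str) -> list:
    """Codon-level differences between two species (gapped/masked codons skipped)."""
    return [(i, ca, cb) for i, ca, cb in usable_codon_pairs(alignment, sp_a, sp_b)
            if ca != cb]


def zero_ds_fallback(nd: float, n_sites: float, s_sites: float) -> float:
    """dN/dS recomputed as if exactly one synonymous difference had occurred.

    Used when sd = 0 but nd > 0 leaves the ratio undefined; returns NaN when
    nd is also 0 (no information).
    """
    if nd <= 0:
        return math.nan
    return (nd / n_sites) / (1.0 / s_sites)


def ng86_divergence(
    alignment: CodonAlignment,
    sp_a: str,
    sp_b: str,
    code: GeneticCode,
    zero_ds_policy: str = "one_synonymous",
) -> PairwiseDivergence:
    """Counting-based dN, dS and omega for one species pair.

    Site counts are the average of the two sequences' per-codon NG86 sites
    over the comparable codons.  ``zero_ds_policy`` "one_synonymous" invokes
    the single-synonymous-substitution fallback when sd = 0 < nd (flagged);
    "na" leaves omega undefined in that case.
    """
    diffs = CodonDiffCounts(0.0, 0.0)
    sites_a = CodonSiteCounts(0.0, 0.0)
    sites_b = CodonSiteCounts(0.0, 0.0)
    used = 0
    for _, ca, cb in usable_codon_pairs(alignment, sp_a, sp_b):
        if code.is_stop(ca) or code.is_stop(cb):
            log.debug("%s: stop codon column skipped (%s/%s)", alignment.gene_id, ca, cb)
            continue
        used += 1
        sites_a = sites_a + codon_site_counts(ca, code)
        sites_b = sites_b + codon_site_counts(cb, code)
        if ca != cb:
            diffs = diffs + count_codon_differences(ca, cb, code)
    if used == 0:
        raise ValueError(f"{alignment.gene_id}: no comparable codons for {sp_a}/{sp_b}")
    n_sites = (sites_a.n_sites + sites_b.n_sites) / 2.0
    s_sites = (sites_a.s_sites + sites_b.s_sites) / 2.0
    dN = jukes_cantor(diffs.nd / n_sites)
    dS = jukes_cantor(diffs.sd / s_sites)
    fallback = False
    if dS > 0:
        omega = dN / dS
    elif diffs.nd == 0:
        omega = math.nan
    elif zero_ds_policy == "one_synonymous":
        omega = zero_ds_fallback(diffs.nd, n_sites, s_sites)
        fallback = True
    else:
        omega = math.nan
    return PairwiseDivergence(
        species_pair=(sp_a, sp_b),
        nd=diffs.nd,
        sd=diffs.sd,
        n_sites=n_sites,
        s_sites=s_sites,
        n_codons_used=used,
        dN=dN,
        dS=dS,
        omega=omega,
        zero_ds_fallback_used=fallback,
    )


def read_alignment_fasta(path, gene_id: Optional[str] = None,
                         mask: Optional[Sequence] = None) -> CodonAlignment:
    """Load a per-gene aligned FASTA into a CodonAlignment."""
    from .genome_io import read_fasta

    seqs = read_fasta(path)
    gid = gene_id or str(path)
    return CodonAlignment(gene_id=gid, sequences=seqs, mask=list(mask or []))


def read_mask_bed(path) -> list:
    """BED-style mask: 0-based half-open intervals in alignment coordinates."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            intervals.append((int(fields[1]), int(fields[2])))
    return intervals
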