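"""Genetic-code arithmetic: translation, NG86 site counting, and
pathway-averaged counting of synonymous/nonsynonymous codon differences.

The Nei–Gojobori (NG86) scheme attributes to each codon position a
synonymous fraction equal to the proportion of single-nucleotide changes at
that position that preserve the amino acid, with changes that create a stop
codon excluded from both numerator and denominator.  Differences between two
codons are decomposed by enumerating every ordering of the single-nucleotide
steps between them, discarding orderings that pass through a stop codon, and
averaging the (nonsynonymous, synonymous) step counts over the surviving
orderings with equal weight.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

from Bio.Data import CodonTable

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
STOP = "*"
#: unordered pairs related by transition (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


class CodonError(ValueError):
    """Raised for codons that violate an operation's preconditions."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table restricted to the 4-letter DNA alphabet.

    ``codon_to_aa`` maps all 64 codons to a one-letter amino acid or ``*``
    for stop.  The plastid/bacterial code (table 11) shares all 64
    assignments with the standard code (table 1); they differ only in
    permitted start codons, which play no role here.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.codon_to_aa)}")

    @classmethod
    def from_ncbi(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(table_id=table_id, codon_to_aa=mapping)

    def translate(self, codon: str) -> str:
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise CodonError(f"not an unambiguous DNA codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP))


@lru_cache(maxsize=None)
def _code_cache(table_id: int) -> GeneticCode:
    return GeneticCode.from_ncbi(table_id)


def get_code(table_id: int = 11) -> GeneticCode:
    """Shared, cached genetic-code instance."""
    return _code_cache(table_id)


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional nonsynonymous/synonymous site counts for one codon.

    For any non-stop codon ``n_sites + s_sites == 3`` exactly (stop-creating
    changes are excluded from the per-position denominators).
    """

    n_sites: float
    s_sites: float

    def __add__(self, other: "CodonSiteCounts") -> "CodonSiteCounts":
        return CodonSiteCounts(self.n_sites + other.n_sites, self.s_sites + other.s_sites)


@dataclass(frozen=True)
class CodonDiffCounts:
    """Pathway-averaged nonsynonymous (nd) / synonymous (sd) differences."""

    nd: float
    sd: float

    def __add__(self, other: "CodonDiffCounts") -> "CodonDiffCounts":
        return CodonDiffCounts(self.nd + other.nd, self.sd + other.sd)


def normalize_codon(codon: str) -> Optional[str]:
    """Uppercase and map U->T; return None if any base is not A/C/G/T."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in NUCLEOTIDES for b in c):
        return None
    return c


def translate_codon(codon: str, code: GeneticCode) -> str:
    """Translate one codon; raises CodonError on ambiguous/invalid input."""
    c = normalize_codon(codon)
    if c is None:
        raise CodonError(f"ambiguous or invalid codon: {codon!r}")
    return code.translate(c)


def _neighbor_changes(codon: str, pos: int):
    """Yield (alt_base, mutant_codon) for the 3 single-nt changes at pos."""
    for base in NUCLEOTIDES:
        if base != codon[pos]:
            yield base, codon[:pos] + base + codon[pos + 1 :]


def codon_site_counts(
    codon: str, code: GeneticCode, kappa: Optional[float] = None
) -> CodonSiteCounts:
    """NG86 fractional site counts for a single non-stop codon.

    With ``kappa`` given, each single-nucleotide change is weighted by kappa
    if it is a transition and 1 if a transversion before computing the
    per-position synonymous fraction; this brackets mutational-opportunity
    site definitions used by likelihood packages.  The default (kappa=None)
    is equal weighting, the classical NG86 rule.
    """
    c = normalize_codon(codon)
    if c is None:
        raise CodonError(f"ambiguous or invalid codon: {codon!r}")
    aa = code.translate(c)
    if aa == STOP:
        raise CodonError(f"stop codon {c} contributes no sites")
    s_total = 0.0
    for pos in range(3):
        syn_w = 0.0
        all_w = 0.0
        for base, mutant in _neighbor_changes(c, pos):
            m_aa = code.translate(mutant)
            if m_aa == STOP:
                continue  # nonsense changes excluded from both tallies
            w = 1.0
            if kappa is not None and is_transition(c[pos], base):
                w = kappa
            all_w += w
            if m_aa == aa:
                syn_w += w
        if all_w > 0:
            s_total += syn_w / all_w
    return CodonSiteCounts(n_sites=3.0 - s_total, s_sites=s_total)


def classify_single_change(ref_codon: str, pos: int, alt_base: str, code: GeneticCode) -> str:
    """Classify one single-nucleotide change: synonymous / nonsynonymous / nonsense."""
    c = normalize_codon(ref_codon)
    if c is None:
        raise CodonError(f"ambiguous or invalid codon: {ref_codon!r}")
    if pos not in (0, 1, 2):
        raise CodonError(f"codon position must be 0, 1 or 2, got {pos}")
    alt = alt_base.upper().replace("U", "T")
    if alt not in NUCLEOTIDES:
        raise CodonError(f"invalid alternate base {alt_base!r}")
    if alt == c[pos]:
        raise CodonError(f"alt base equals reference base at {c}[{pos}]: not a SNP")
    ref_aa = code.translate(c)
    if ref_aa == STOP:
        raise CodonError(f"reference codon {c} is a stop")
    mut_aa = code.translate(c[:pos] + alt + c[pos + 1 :])
    if mut_aa == STOP:
        return "nonsense"
    return "synonymous" if mut_aa == ref_aa else "nonsynonymous"


def count_codon_differences(codon_a: str, codon_b: str, code: GeneticCode) -> CodonDiffCounts:
    """NG86 pathway-averaged difference counts between two sense codons.

    All orderings of the differing positions are enumerated; orderings whose
    intermediate codons are stops are discarded; (nd, sd) is the equal-weight
    average over the rest.  If every ordering passes through a stop, all
    differing positions are counted as nonsynonymous (with a warning) so the
    positional total is preserved.
    """
    a = normalize_codon(codon_a)
    b = normalize_codon(codon_b)
    if a is None or b is None:
        raise CodonError(f"ambiguous or invalid codon pair: {codon_a!r}, {codon_b!r}")
    if code.is_stop(a) or code.is_stop(b):
        raise CodonError(f"stop codon in pair ({a}, {b})")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return CodonDiffCounts(0.0, 0.0)
    totals = []
    for order in itertools.permutations(diff_pos):
        current = a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            totals.append((nd, sd))
    if not totals:
        log.warning(
            "all mutational pathways between %s and %s pass through stops; "
            "counting %d differences as nonsynonymous",
            a, b, len(diff_pos),
        )
        return CodonDiffCounts(float(len(diff_pos)), 0.0)
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return CodonDiffCounts(nd=nd, sd=sd)


def gene_site_counts(cds: str, code: GeneticCode, kappa: Optional[float] = None) -> CodonSiteCounts:
    """Sum NG86 site counts over the codons of a coding sequence.

    Codons with ambiguity characters and terminal/internal stop codons are
    skipped with a debug log; the remaining codons' fractional sites are
    summed.
    """
    if len(cds) % 3:
        raise CodonError(f"CDS length {len(cds)} not divisible by 3")
    total = CodonSiteCounts(0.0, 0.0)
    for i in range(0, len(cds), 3):
        c = normalize_codon(cds[i : i + 3])
        if c is None:
            log.debug("skipping ambiguous codon at nt %d", i)
            continue
        if code.is_stop(c):
            continue
        total = total + codon_site_counts(c, code, kappa=kappa)
    return total
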