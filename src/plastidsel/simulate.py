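"""Synthetic study generator: 4-taxon codon alignments evolved under known
per-branch omega, plus pooled within-species SNPs under a known
polymorphism-level omega, emitted in the exact formats the pipeline reads.

Codon evolution is simulated by Gillespie (event-by-event) simulation of
the GY94 chain along each branch of the fixed topology, so the truth log
records every substitution and can be reconciled exactly against the
emitted alignments.  Intraspecific polymorphism is a weighted-rejection
"sprinkler": candidate single-nucleotide changes on the focal species'
coding sequence are proposed uniformly and accepted with relative weight 1
(synonymous) versus omega_poly (nonsynonymous), nonsense changes excluded —
a deliberate stand-in for largely population-fixed organelle variants, not
a coalescent model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .codon_core import GeneticCode, classify_single_change, get_code
from .codon_ml import INTERNAL, build_gy94_rate_matrix, _code_structure
from .config import PipelineConfig
from .divergence import CodonAlignment
from .genome_io import (GeneModel, SnpRecord, revcomp, complement_base,
                        write_annotation, write_fasta, write_snp_table)

SPECIES = ("Cam", "Tca", "Han", "Nta")

#: plastid-like AT-rich nucleotide composition used for the F3x4 root draw
DEFAULT_NT_FREQS = {"A": 0.31, "C": 0.18, "G": 0.17, "T": 0.34}

#: default branch lengths (expected substitutions per codon): short within
#: the family (Cam, Tca), longer to the two distant outgroups
DEFAULT_BRANCH_LENGTHS = {
    "Cam": 0.05, "Tca": 0.05, INTERNAL: 0.08, "Han": 0.15, "Nta": 0.20,
}


@dataclass
class SimConfig:
    """Study dimensions and true parameter values for one synthetic run.

    ``omega_div`` gives each gene's divergence-level dN/dS; a scalar per
    gene applies to every branch, or a per-branch map for branch-specific
    selection.  ``omega_poly`` is the polymorphism-level dN/dS used by the
    SNP sprinkler.  The seed fully determines every output byte.
    """

    n_genes: int = 20
    codons_per_gene: int | list = 300
    kappa: float = 2.0
    branch_lengths: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS))
    omega_div: float | list = 0.4
    omega_poly: float | list = 0.4
    snps_per_gene: int | list = 10
    n_intergenic_snps: int = 3
    genetic_code: int = 11
    seed: int = 0
    species: tuple = SPECIES
    grouping: Optional[dict] = None  # gene -> group; default: gene is its own group

    def gene_names(self) -> list:
        return [f"g{i + 1:02d}" for i in range(self.n_genes)]

    def codons_for(self, i: int) -> int:
        if isinstance(self.codons_per_gene, (list, tuple)):
            return int(self.codons_per_gene[i])
        return int(self.codons_per_gene)

    def omega_div_for(self, i: int) -> dict:
        w = self.omega_div[i] if isinstance(self.omega_div, (list, tuple)) else self.omega_div
        branches = tuple(self.species) + (INTERNAL,)
        if isinstance(w, dict):
            return {b: float(w[b]) for b in branches}
        return {b: float(w) for b in branches}

    def omega_poly_for(self, i: int) -> float:
        if isinstance(self.omega_poly, (list, tuple)):
            return float(self.omega_poly[i])
        return float(self.omega_poly)

    def snps_for(self, i: int) -> int:
        if isinstance(self.snps_per_gene, (list, tuple)):
            return int(self.snps_per_gene[i])
        return int(self.snps_per_gene)


def default_pi(code: GeneticCode, nt_freqs: dict = DEFAULT_NT_FREQS) -> np.ndarray:
    """F3x4-style sense-codon frequencies from one nucleotide composition."""
    codons = _code_structure(code.table_id)[0]
    pi = np.array([math.prod(nt_freqs[b] for b in c) for c in codons])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Gillespie simulation of one branch


def _evolve_branch(states: np.ndarray, t: float, Q: np.ndarray,
                   rng: np.random.Generator, branch: str,
                   code: GeneticCode, events: list) -> np.ndarray:
    """Evolve codon states for time t under generator Q, logging each event."""
    codons = _code_structure(code.table_id)[0]
    states = states.copy()
    exit_rates = -np.diag(Q)
    site_rates = exit_rates[states]
    total = float(site_rates.sum())
    clock = 0.0
    while total > 0:
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        site = int(rng.choice(len(states), p=site_rates / total))
        i = states[site]
        row = Q[i].copy()
        row[i] = 0.0
        j = int(rng.choice(len(row), p=row / row.sum()))
        syn = code.translate(codons[i]) == code.translate(codons[j])
        events.append({"branch": branch, "codon": site, "from": codons[i],
                       "to": codons[j], "synonymous": bool(syn)})
        states[site] = j
        total += exit_rates[j] - site_rates[site]
        site_rates[site] = exit_rates[j]
    return states


def simulate_gene_alignment(config: SimConfig, gene_index: int,
                            rng: np.random.Generator) -> tuple:
    """Simulate one gene's 4-taxon codon alignment; returns (alignment, truth).

    The root sequence is drawn from the equilibrium frequencies (first codon
    forced to ATG) at the internal node joining the two ingroup species,
    then evolved along each branch with that branch's omega.
    """
    code = get_code(config.genetic_code)
    codons, index = _code_structure(code.table_id)[:2]
    pi = default_pi(code)
    n = config.codons_for(gene_index)
    omegas = config.omega_div_for(gene_index)
    gene = config.gene_names()[gene_index]

    root = rng.choice(len(pi), size=n, p=pi)
    root[0] = index["ATG"]

    Qs = {}
    for branch, w in omegas.items():
        key = w
        if key not in Qs:
            Qs[key] = build_gy94_rate_matrix(config.kappa, w, pi, code)
    events: list = []
    sp1, sp2, sp3, sp4 = config.species
    bl = config.branch_lengths
    leaf_states = {}
    leaf_states[sp1] = _evolve_branch(root, bl[sp1], Qs[omegas[sp1]], rng, sp1, code, events)
    leaf_states[sp2] = _evolve_branch(root, bl[sp2], Qs[omegas[sp2]], rng, sp2, code, events)
    node2 = _evolve_branch(root, bl[INTERNAL], Qs[omegas[INTERNAL]], rng, INTERNAL, code, events)
    leaf_states[sp3] = _evolve_branch(node2, bl[sp3], Qs[omegas[sp3]], rng, sp3, code, events)
    leaf_states[sp4] = _evolve_branch(node2, bl[sp4], Qs[omegas[sp4]], rng, sp4, code, events)

    sequences = {sp: "".join(codons[k] for k in states)
                 for sp, states in leaf_states.items()}
    per_branch = {b: {"synonymous": 0, "nonsynonymous": 0} for b in omegas}
    for ev in events:
        key = "synonymous" if ev["synonymous"] else "nonsynonymous"
        per_branch[ev["branch"]][key] += 1
    truth = {
        "gene": gene,
        "n_codons": n,
        "omega_div": omegas,
        "kappa": config.kappa,
        "branch_lengths": dict(bl),
        "events": events,
        "event_counts": per_branch,
    }
    return CodonAlignment(gene_id=gene, sequences=sequences), truth


# ---------------------------------------------------------------------------
# polymorphism sprinkler


def simulate_polymorphism(reference_cds: str, config: SimConfig, gene_index: int,
                          rng: np.random.Generator) -> tuple:
    """Sprinkle SNPs on a coding sequence under polymorphism-level omega.

    Proposes uniform single-nucleotide changes; accepts synonymous changes
    with relative weight 1 and nonsynonymous with weight omega_poly;
    nonsense changes and repeat positions are rejected.  Returns
    (list of (cds_pos0, ref_base, alt_base, effect), truth dict).
    """
    code = get_code(config.genetic_code)
    omega_p = config.omega_poly_for(gene_index)
    target = config.snps_for(gene_index)
    n_codons = len(reference_cds) // 3
    gene = config.gene_names()[gene_index]
    max_attempts = 4000 * max(target, 1)
    accept_norm = max(1.0, omega_p)
    chosen: dict = {}
    attempts = 0
    while len(chosen) < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"gene {gene}: could not place {target} SNPs (omega_poly={omega_p}); "
                f"gene too small or omega too extreme"
            )
        codon_i = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        cds_pos = 3 * codon_i + pos
        if cds_pos in chosen:
            continue
        ref_codon = reference_cds[3 * codon_i : 3 * codon_i + 3]
        if code.is_stop(ref_codon):
            continue
        ref_base = ref_codon[pos]
        alt = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
        effect = classify_single_change(ref_codon, pos, alt, code)
        if effect == "nonsense":
            continue
        weight = 1.0 if effect == "synonymous" else omega_p
        if rng.random() >= weight / accept_norm:
            continue
        chosen[cds_pos] = (cds_pos, ref_base, alt, effect)
    snps = [chosen[k] for k in sorted(chosen)]
    truth = {
        "gene": gene,
        "omega_poly": omega_p,
        "n_synonymous": sum(1 for s in snps if s[3] == "synonymous"),
        "n_nonsynonymous": sum(1 for s in snps if s[3] == "nonsynonymous"),
    }
    return snps, truth


# ---------------------------------------------------------------------------
# genome layout and full-study emission


@dataclass
class _Placement:
    model: GeneModel
    cds_to_genomic: list  # cds position -> 0-based genomic position


def _place_genes(config: SimConfig, gene_cds: dict, rng: np.random.Generator):
    """Lay genes out on two contigs, both strands, one 2-exon gene.

    Returns (contigs, placements).  Gene 1 gets two exons split mid-codon by
    a short intron; genes alternate strands and contigs.
    """
    nt = np.array(list("ACGT"))
    freqs = np.array([DEFAULT_NT_FREQS[b] for b in "ACGT"])

    def random_dna(length: int) -> str:
        return "".join(rng.choice(nt, size=length, p=freqs))

    contig_seqs = {"ctg1": [], "ctg2": []}
    contig_len = {"ctg1": 0, "ctg2": 0}
    placements = []
    names = list(gene_cds)
    for k, gene in enumerate(names):
        cds = gene_cds[gene]
        contig = "ctg1" if k % 2 == 0 else "ctg2"
        strand = "+" if k % 4 < 2 else "-"
        spacer = random_dna(100)
        contig_seqs[contig].append(spacer)
        contig_len[contig] += len(spacer)
        start = contig_len[contig]
        if k == 0:
            # two exons split mid-codon (first exon length 7 mod 3 != 0)
            intron = random_dna(60)
            cut = 7
            genomic = cds[:cut] + intron + cds[cut:]
            exons = ((start, start + cut),
                     (start + cut + len(intron), start + len(genomic)))
            mapping = list(range(start, start + cut)) + \
                list(range(start + cut + len(intron), start + len(genomic)))
            strand = "+"
        else:
            genomic = cds if strand == "+" else revcomp(cds)
            exons = ((start, start + len(genomic)),)
            if strand == "+":
                mapping = list(range(start, start + len(genomic)))
            else:
                mapping = list(range(start + len(genomic) - 1, start - 1, -1))
        contig_seqs[contig].append(genomic)
        contig_len[contig] += len(genomic)
        model = GeneModel(gene_id=gene, contig_id=contig, strand=strand,
                          exons=exons, feature_class="protein")
        placements.append(_Placement(model=model, cds_to_genomic=mapping))
    for contig in contig_seqs:
        contig_seqs[contig].append(random_dna(100))
    contigs = {c: "".join(parts) for c, parts in contig_seqs.items()}
    return contigs, placements


def generate_study(config: SimConfig, outdir) -> dict:
    """Generate the complete synthetic study on disk.

    Emits reference.fasta, genes.gff3, snps.vcf, alignments/<gene>.fasta,
    groups.yaml, config.yaml and truth.json under ``outdir``; returns the
    truth dict.  Byte-identical for identical configs (including seed).
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    focal = config.species[0]

    alignments, truths = {}, {}
    for i, gene in enumerate(config.gene_names()):
        aln, truth = simulate_gene_alignment(config, i, rng)
        alignments[gene] = aln
        truths[gene] = truth

    gene_cds = {g: alignments[g].sequences[focal] for g in alignments}
    contigs, placements = _place_genes(config, gene_cds, rng)

    snp_records = []
    for i, placement in enumerate(placements):
        gene = placement.model.gene_id
        cds_snps, poly_truth = simulate_polymorphism(gene_cds[gene], config, i, rng)
        truths[gene]["polymorphism"] = poly_truth
        truths[gene]["placement"] = {
            "contig": placement.model.contig_id,
            "strand": placement.model.strand,
            "exons": [list(e) for e in placement.model.exons],
        }
        for cds_pos, ref_base, alt_base, _effect in cds_snps:
            gpos0 = placement.cds_to_genomic[cds_pos]
            ref_g, alt_g = ref_base, alt_base
            if placement.model.strand == "-":
                ref_g, alt_g = complement_base(ref_base), complement_base(alt_base)
            snp_records.append(SnpRecord(placement.model.contig_id, gpos0 + 1, ref_g, alt_g))

    # a few intergenic SNPs in the leading spacer of each contig
    for k in range(config.n_intergenic_snps):
        contig = "ctg1" if k % 2 == 0 else "ctg2"
        pos0 = int(rng.integers(0, 100))
        ref = contigs[contig][pos0]
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        snp_records.append(SnpRecord(contig, pos0 + 1, ref, alt))

    snp_records.sort(key=lambda r: (r.contig_id, r.position))

    models = [p.model for p in placements]
    grouping = config.grouping or {g: g for g in gene_cds}

    write_fasta(contigs, outdir / "reference.fasta")
    write_annotation(models, outdir / "genes.gff3")
    write_snp_table(snp_records, outdir / "snps.vcf",
                    contig_lengths={c: len(s) for c, s in contigs.items()})
    for gene, aln in alignments.items():
        write_fasta(aln.sequences, outdir / "alignments" / f"{gene}.fasta")
    (outdir / "groups.yaml").write_text(yaml.safe_dump(grouping, sort_keys=True))
    PipelineConfig(genetic_code=config.genetic_code, gene_groups=dict(grouping),
                   seed=config.seed).to_yaml(outdir / "config.yaml")
    truth = {
        "seed": config.seed,
        "species": list(config.species),
        "genes": truths,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
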