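import json
from pathlib import Path

import numpy as np
import pytest

from plastidsel.codon_core import get_code
from plastidsel.codon_ml import INTERNAL
from plastidsel.divergence import ng86_divergence
from plastidsel.genome_io import read_annotation, read_fasta, read_snp_table, extract_cds
from plastidsel.polymorphism import classify_snps
from plastidsel.simulate import (SimConfig, generate_study,
                                 simulate_gene_alignment, simulate_polymorphism)

CODE = get_code(11)


def _study_bytes(outdir):
    return {p.relative_to(outdir): p.read_bytes()
            for p in sorted(Path(outdir).rglob("*")) if p.is_file()}


def test_generate_study_is_byte_deterministic(tmp_path):
    cfg = SimConfig(n_genes=4, codons_per_gene=120, snps_per_gene=5, seed=9)
    generate_study(cfg, tmp_path / "a")
    generate_study(cfg, tmp_path / "b")
    a, b = _study_bytes(tmp_path / "a"), _study_bytes(tmp_path / "b")
    assert list(a) == list(b)
    assert all(a[k] == b[k] for k in a)


def test_zero_branch_lengths_give_identical_sequences():
    cfg = SimConfig(n_genes=1, codons_per_gene=100, seed=3,
                    branch_lengths={b: 0.0 for b in
                                    ("Cam", "Tca", "Han", "Nta", INTERNAL)})
    aln, truth = simulate_gene_alignment(cfg, 0, np.random.default_rng(3))
    assert len(set(aln.sequences.values())) == 1
    assert truth["events"] == []


def test_omega_zero_yields_no_nonsynonymous_events():
    cfg = SimConfig(n_genes=1, codons_per_gene=400, omega_div=0.0, seed=4)
    aln, truth = simulate_gene_alignment(cfg, 0, np.random.default_rng(4))
    assert truth["events"], "expect some substitutions at these branch lengths"
    assert all(ev["synonymous"] for ev in truth["events"])


def test_no_internal_stops_in_emitted_sequences():
    cfg = SimConfig(n_genes=2, codons_per_gene=300, omega_div=2.0, seed=6)
    for i in range(2):
        aln, _ = simulate_gene_alignment(cfg, i, np.random.default_rng(6 + i))
        for seq in aln.sequences.values():
            assert all(not CODE.is_stop(seq[j:j + 3]) for j in range(0, len(seq), 3))


def test_event_log_reconciles_with_sequences():
    """With every branch but the focal one at length zero, replaying the
    event log on the sister sequence must reproduce the focal sequence."""
    bl = {b: 0.0 for b in ("Cam", "Tca", "Han", "Nta", INTERNAL)}
    bl["Cam"] = 0.08
    cfg = SimConfig(n_genes=1, codons_per_gene=500, branch_lengths=bl, seed=12)
    aln, truth = simulate_gene_alignment(cfg, 0, np.random.default_rng(12))
    seq = list(aln.sequences["Tca"])  # equals the root here
    for ev in truth["events"]:
        assert ev["branch"] == "Cam"
        i = ev["codon"]
        assert "".join(seq[3 * i:3 * i + 3]) == ev["from"]
        seq[3 * i:3 * i + 3] = ev["to"]
    assert "".join(seq) == aln.sequences["Cam"]


def test_realized_omega_near_one_for_neutral_long_branch():
    """omega=1 on a long branch: realized (Nd/N)/(Sd/S) from NG86 counting
    of the emitted pair falls in the sampling band around 1."""
    bl = {b: 0.0 for b in ("Cam", "Tca", "Han", "Nta", INTERNAL)}
    bl["Cam"] = 0.15
    cfg = SimConfig(n_genes=1, codons_per_gene=10_000, omega_div=1.0,
                    branch_lengths=bl, seed=17)
    aln, _ = simulate_gene_alignment(cfg, 0, np.random.default_rng(17))
    div = ng86_divergence(aln, "Cam", "Tca", CODE)
    assert 0.8 <= div.omega <= 1.25


def test_polymorphism_sprinkler_effects():
    rng = np.random.default_rng(1)
    cds = "ATG" + "GCTAAATTTGGGCCC" * 40
    cfg = SimConfig(n_genes=1, omega_poly=0.0, snps_per_gene=15, seed=1)
    snps, truth = simulate_polymorphism(cds, cfg, 0, rng)
    assert len(snps) == 15
    assert truth["n_nonsynonymous"] == 0
    assert all(effect == "synonymous" for *_, effect in snps)
    # determinism
    snps2, _ = simulate_polymorphism(cds, cfg, 0, np.random.default_rng(1))
    assert snps2 == snps
    # unreachable target errors out
    with pytest.raises(RuntimeError, match="could not place"):
        simulate_polymorphism("ATGGCT", cfg, 0, rng)


def test_generated_study_reads_back_clean_and_matches_truth(small_study):
    outdir, cfg, truth = small_study
    contigs = read_fasta(outdir / "reference.fasta")
    models = read_annotation(outdir / "genes.gff3", contigs)
    snps = read_snp_table(outdir / "snps.vcf", reference=contigs)
    assert len(models) == cfg.n_genes
    assert {m.strand for m in models} == {"+", "-"}
    assert len({m.contig_id for m in models}) == 2
    assert any(len(m.exons) == 2 for m in models)
    # reference CDS equals the focal species' alignment sequence
    for m in models:
        assert extract_cds(m, contigs) == \
            read_fasta(outdir / "alignments" / f"{m.gene_id}.fasta")["Cam"]
    # classification of the emitted VCF reproduces the truth counts per
    # gene, which exercises minus-strand allele complementation
    classifications = classify_snps(snps, models, contigs, CODE)
    by_gene = {}
    for cl in classifications:
        if cl.location_class == "exonic":
            by_gene.setdefault(cl.gene_id, []).append(cl.effect)
    truth_json = json.loads((outdir / "truth.json").read_text())
    for gene, info in truth_json["genes"].items():
        effects = by_gene[gene]
        assert effects.count("synonymous") == info["polymorphism"]["n_synonymous"]
        assert effects.count("nonsynonymous") == info["polymorphism"]["n_nonsynonymous"]
    n_intergenic = sum(cl.location_class == "intergenic" for cl in classifications)
    assert n_intergenic == cfg.n_intergenic_snps
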