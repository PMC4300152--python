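#!/usr/bin/env python
"""Classify the study's pooled within-species SNPs against the annotation
and tally per-gene pN, pS and pN/pS.

Reads results/study/, writes results/polymorphism.tsv, and prints the
location-class breakdown plus the per-gene table.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from plastidsel.codon_core import gene_site_counts, get_code
from plastidsel.config import PipelineConfig
from plastidsel.genome_io import extract_cds, read_annotation, read_fasta, read_snp_table
from plastidsel.polymorphism import classify_snps, polymorphism_table, tally_polymorphism

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    cfg = PipelineConfig.from_yaml(study / "config.yaml")
    code = get_code(cfg.genetic_code)
    contigs = read_fasta(study / "reference.fasta")
    models = read_annotation(study / "genes.gff3", contigs)
    snps = read_snp_table(study / "snps.vcf", reference=contigs)

    classifications = classify_snps(snps, models, contigs, code)
    print(f"{len(snps)} SNPs classified:",
          dict(Counter(c.location_class for c in classifications)))
    print("coding effects:",
          dict(Counter(c.effect for c in classifications if c.effect != "NA")))

    grouping = {m.gene_id: cfg.group_of(m.gene_id) for m in models}
    sites = {m.gene_id: gene_site_counts(extract_cds(m, contigs), code)
             for m in models}
    rows = tally_polymorphism(classifications, models, grouping, sites)
    table = polymorphism_table(rows)
    out = ROOT / "results" / "polymorphism.tsv"
    table.to_csv(out, sep="\t", index=False)
    pd.set_option("display.width", 120)
    print(table.round(4).to_string(index=False))
    print(f"written to {out}")


if __name__ == "__main__":
    main()
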