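# plastidsel

Selection analysis for plastid protein-coding genes: interspecific
divergence (dN/dS) versus intraspecific polymorphism (pN/pS).

Several angiosperm lineages — the Campanulaceae prominently among them —
carry structurally unstable plastid genomes in which a recurring set of
genes (*ycf1*, *ycf2*, *clpP*, ribosomal protein genes) shows elevated
nonsynonymous substitution rates. Whether the mechanisms behind this
acceleration continue to act *within* species can be asked by comparing
each gene's divergence-level ratio dN/dS (from a multi-species comparison)
with its polymorphism-level ratio pN/pS (from segregating SNPs in a pooled
within-species sample): a cross-gene correlation of the two indicates the
same gene-specific selective regimes operating on both timescales, and
McDonald–Kreitman tests ask whether divergence carries an excess of
nonsynonymous change over what polymorphism predicts.

This package implements that comparison end to end for a four-taxon
design (a focal species, a within-family sister, and two distant
outgroups, as in *Campanulastrum americanum* / *Trachelium caeruleum* /
*Helianthus annuus* / *Nicotiana tabacum*):

- **codon_core** — genetic-code arithmetic: Nei–Gojobori (NG86) fractional
  site counting per codon (N + S = 3, stop-creating changes excluded) and
  pathway-averaged synonymous/nonsynonymous decomposition of codon
  differences.
- **genome_io** — FASTA / GFF3 / VCF (and TSV) reading and writing,
  strand-aware genomic-to-codon coordinate mapping.
- **polymorphism** — SNP classification (intergenic / intronic / exonic;
  synonymous / nonsynonymous / nonsense) and per-gene-group pN = Pn/N,
  pS = Ps/S, pN/pS.
- **divergence** — pairwise NG86 counting over codon alignments with
  Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p), explicit masks for
  unalignable regions, and the one-synonymous-substitution fallback for
  genes with dS = 0.
- **codon_ml** — Goldman–Yang (GY94) codon-model likelihood on the fixed
  unrooted topology ((focal, sister), outgroup₁, outgroup₂) with one ω per
  branch, F3×4 codon frequencies, Felsenstein pruning over 61 states, and
  the ω = 1 likelihood-ratio test (χ², 1 df) with Bonferroni correction.
- **selection_stats** — Fisher's exact 2×2 test (probability-mass
  two-sided rule), MK tables with neutrality index NI = (Pn/Ps)/(Dn/Ds)
  and α = 1 − NI, the cross-gene Pearson correlation of log dN/dS vs
  log pN/pS with a ≥3-SNP filter, and Table-style summaries.
- **simulate** — a synthetic-study generator: Gillespie simulation of the
  GY94 chain along each branch (with a complete event log for exact
  reconciliation) plus a weighted-rejection SNP sprinkler with its own
  polymorphism-level ω, emitted in the exact input formats the pipeline
  reads, with truth files.
- **published** — the published per-gene summary values for the
  *C. americanum* plastid study, used as reference inputs for the summary
  arithmetic.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth:

```bash
python analysis/01_generate_study.py --seed 1   # 20 genes, gene-wise true omega
python analysis/02_polymorphism.py              # classify SNPs, pN/pS per gene
python analysis/03_divergence.py                # NG86 dN/dS vs each outgroup
python analysis/04_codon_ml.py                  # GY94 fits + omega=1 LRTs
python analysis/05_selection_tests.py           # MK tests + log-ratio correlation
python analysis/06_published_summary.py         # published-table arithmetic
```

Step 05 prints (seed 1):

```
log-ratio correlation over 20 genes: r=0.891 (r^2=0.795), p=1.3e-07
no MK test significant before Bonferroni correction
```

— the strong positive correlation is the expected signature when each
gene's divergence-level and polymorphism-level ω are equal (here both were
drawn log-uniform on [0.05, 3]), and the MK tests are correctly null
because divergence and polymorphism were generated under the same ω per
gene. Step 04 shows the likelihood route per gene, e.g.

```
g02: omega_hat=4.980 (true 2.449), kappa=2.17; LRT omega=1: stat=7.59, p=0.00586, p_bonf=0.0996
g03: omega_hat=0.086 (true 0.090), kappa=1.92
```

Step 06 recomputes the published summary arithmetic:

```
mean dN/dS (excluding clpP): 0.431
mean pN/pS (estimable rows): 0.518
total coding length: 62853 bp
groups passing the correlation filter (n=11): atp, ndh, pet, psb, rbcl, rpl, rpo, rps, matK, ycf1, ycf2
```

The same stages are available as a CLI (`plastidsel generate-study`,
`classify-snps`, `divergence`, `fit-ml`, `run-all`, `correlate`); `run-all`
emits a report directory with the summary table, per-outgroup MK tests,
correlation and LRT JSON, and a run manifest with input digests.

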