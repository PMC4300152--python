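# Methods

## The quantities being estimated

For each protein gene (or concatenation of functionally related genes) the
pipeline produces two ratios. The divergence-level ratio ω = dN/dS
compares nonsynonymous and synonymous substitution rates between species;
the polymorphism-level ratio pN/pS is its within-species analog computed
from segregating SNPs. Under purifying selection both sit well below 1;
relaxed or positive selection pushes them up. The headline analysis is the
cross-gene Pearson correlation of ln(dN/dS) against ln(pN/pS), restricted
to groups with at least three SNPs and with both ratios strictly positive
(log-transformable); a strong positive correlation indicates the same
gene-specific selective regimes acting on both timescales.
McDonald–Kreitman tests then contrast each group's fixed differences
(Dn : Ds, against each outgroup separately) with its polymorphisms
(Pn : Ps) in a 2×2 Fisher's exact test.

## Counting route (NG86)

Site counts follow Nei–Gojobori: at each codon position the synonymous
fraction is the proportion of the single-nucleotide changes at that
position that preserve the amino acid, with changes creating a stop codon
excluded from numerator and denominator, so every sense codon contributes
exactly 3 sites split between N and S. An optional κ-weighted variant
weights each change by the transition/transversion ratio before forming
the fraction; it is exposed because likelihood packages define sites by
mutational opportunity, and the two options bracket that behavior. Neither
variant claims bit-compatibility with any particular ML implementation.

Differences between two codons are decomposed by enumerating all k!
orderings of the k differing positions, discarding orderings that pass
through a stop codon, and averaging (nd, sd) with equal weights over the
survivors. If every ordering is blocked by a stop (impossible under the
standard code, possible in principle), all differing positions are counted
as nonsynonymous and a warning is emitted — a deterministic fallback that
preserves the positional total.

Pairwise divergence skips codon columns containing a gap or ambiguity code
in either sequence and any column inside an explicit mask (the hook for
manually curated unalignable regions; the package does not try to detect
them). Proportions p = nd/N and sd/S are corrected with the Jukes–Cantor
transform d = −(3/4)·ln(1 − (4/3)·p), applied separately to the
nonsynonymous and synonymous proportions; p ≥ 3/4 raises a saturation
error rather than returning a number. Site counts for a pair are the
average of the two sequences' per-codon site counts. When a group's
pooled synonymous difference count is zero but nonsynonymous differences
exist, the ratio is recomputed as if exactly one synonymous substitution
had occurred and the row is flagged (`zero_ds_policy: one_synonymous`,
the default; `na` leaves it undefined). Concatenation groups pool raw
nd/sd and site counts over member genes before ratios are formed, which
is how a concatenated alignment would behave.

Polymorphism counting is presence/absence: pooled-sample allele
frequencies are ignored, several SNPs in one codon are classified
independently against the reference codon (no phasing), and nonsense SNPs
count toward Pn (they change the protein) while also being reported in a
separate column. Intronic and intergenic SNPs are classified and reported
but excluded from pN/pS. pN/pS is reported as inestimable (NaN) exactly
when Ps = 0.

## Likelihood route (GY94)

The Goldman–Yang model is a 61-state reversible Markov chain over sense
codons with rate q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous] for
single-nucleotide changes and 0 otherwise, each branch's generator
rescaled to one expected substitution per codon at equilibrium. Branch
lengths are therefore expected substitutions per codon everywhere
(simulator and fitter share this scaling; recovery tests depend on it).
Codon frequencies are F3×4 — products of position-specific nucleotide
frequencies renormalized over sense codons — estimated once from the
alignment with a pseudocount of 0.5 per nucleotide per position to guard
structural zeros on short genes, and held fixed during optimization.

The topology is fixed and unrooted, ((focal, sister), outgroup₁,
outgroup₂), with five branches each carrying its own ω. Likelihood is
computed by Felsenstein pruning rooted (arbitrarily, by reversibility) at
the node joining the ingroup pair, over site patterns compressed with
counts; codon columns with a gap, ambiguity or stop in any taxon are
dropped listwise. Transition matrices come from eigendecomposition in the
π^{1/2}-symmetrized basis, which reversibility guarantees has a real
spectrum.

Fitting maximizes the log-likelihood with L-BFGS-B over log-transformed
parameters: five branch lengths (initialized by the closed-form additive
solution from the six pairwise JC-corrected distances, floored at 5e-3),
κ (initial 2), and one ω per free branch (initial 0.4). Bounds are
t ∈ [1e-6, 20], κ ∈ [0.01, 100], ω ∈ [1e-6, 100]; the convergence
tolerance on the objective is 1e-8. The fit is deterministic for given
inputs. ω estimates can legitimately hit the upper bound when a short
branch happens to carry no synonymous events (the likelihood analog of
the zero-dS situation in counting).

The ω = 1 test on a named branch refits with that branch's ω pinned at 1,
starting from the free optimum; the statistic 2·(lnL_free − lnL_1) is
referred to χ²(1). If the constrained fit ever exceeds the free one
beyond numerical slack, the free model is refit from the constrained
solution before the statistic is formed. Bonferroni factors are config
keys: 17 for the per-group LRT family and 51 for the MK family (17 groups
× 3 outgroups), multiplied onto p and capped at 1.

## Statistics

Fisher's exact two-sided p uses the probability-mass ordering — the sum
of hypergeometric probabilities of all tables sharing the observed
margins whose probability does not exceed the observed table's, with a
relative tie slack of 1e-12 — computed with exact integer combinatorics.
A zero margin returns p = 1 (degenerate table, flagged). The neutrality
index NI = (Pn/Ps)/(Dn/Ds) and α = 1 − NI are NaN whenever Ps, Dn or Ds
is zero. The log-ratio correlation uses natural logs (Pearson r is
invariant to the base) with a two-sided p from t with n − 2 df, and
errors out below n = 3. Summary-table means are unweighted arithmetic
means over estimable entries, with groups whose dN/dS rests on the
zero-dS fallback excluded from the dN/dS mean (matching how the published
"All Genes" row treats clpP).

## Synthetic data: what it emulates and what it does not

The generator emulates the study design, not the biology of any
particular genome. Divergence is simulated gene by gene as Gillespie
(event-by-event) realizations of the GY94 chain along each branch of the
fixed topology — chosen over endpoint sampling from exp(Qt) so the truth
log contains every substitution and tests can reconcile emitted
alignments against the event log exactly. The root sequence is drawn from
an F3×4 equilibrium built on an AT-rich, plastid-like composition
(A 0.31, C 0.18, G 0.17, T 0.34), with the first codon forced to ATG.
Polymorphism is a weighted-rejection sprinkler on the focal species'
coding sequence: uniform single-nucleotide proposals accepted with
relative weight 1 (synonymous) vs ω_poly (nonsynonymous), nonsense
rejected. This deliberately models organelle variants that are largely
fixed between diverged populations as unlinked presence/absence variants;
it is not a coalescent and carries no frequency spectrum, linkage, or
sequencing-error structure. Passing recovery tests therefore show the
estimators are correct for count-based signals of the study's design —
they say nothing about robustness to alignment error, heteroplasmy
mixtures, or homopolymer artifacts in real reads.

Default study dimensions: 20 genes of 300 codons (the analysis scripts
use 500), branch lengths {focal 0.05, sister 0.05, internal 0.08,
outgroups 0.15/0.20} substitutions per codon — short within the family,
longer to the distant outgroups — κ = 2, and 10–12 SNPs per gene,
comparable to the per-group SNP counts in the published table. Genome
layout places genes on two contigs and both strands with one intron-split
gene, so coordinate mapping and strand complementation are exercised by
construction. Every output is byte-deterministic in the seed.

Simulation scales used by the test suite and acceptance script are sized
for a single CPU: 5,000 codons for single-gene ω recovery, 500-codon
genes for the 20-gene rank-correlation and end-to-end correlation
studies, and 200 replicate 1,000-codon genes for the LRT type-I
calibration.

## Known limitations

- Site-homogeneous ω per branch only; no site-class models, so genes with
  a few positively selected codons against a conserved background are
  summarized by their average ω.
- The counting and likelihood routes are both reported but are different
  estimators; they agree in rank, not digit-for-digit, and neither claims
  bit-compatibility with PAML's site definitions or gap handling.
- MK counts from the counting route are rounded pathway-averaged
  fractions; with very few differences the rounding matters.
- The published per-gene values embedded for summary arithmetic are the
  printed (3-decimal) numbers; means recomputed from them can differ from
  the originally printed means by one unit in the last place (0.431 vs
  0.430 for the dN/dS mean).
- Alignment masks are caller-provided; the package does not detect
  unalignable regions.
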