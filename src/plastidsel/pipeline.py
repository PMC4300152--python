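"""End-to-end orchestration: classify -> tally -> diverge -> (fit) -> test
-> correlate -> report, with a reproducible run manifest.

Divergence-side counts for a concatenation group are pooled at the level
of raw NG86 difference/site counts over member genes before ratios are
formed, mirroring how concatenated alignments behave.  The Table-2-style
dN/dS column is the focal-vs-sister pairwise estimate by default, or the
fitted terminal-branch omega when the likelihood stage is enabled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .codon_core import gene_site_counts, get_code
from .codon_ml import fit_branch_model, lrt_omega_equals_one
from .config import PipelineConfig
from .divergence import (CodonAlignment, ng86_divergence, read_alignment_fasta,
                         zero_ds_fallback)
from .genome_io import extract_cds, read_annotation, read_fasta, read_snp_table
from .polymorphism import classify_snps, polymorphism_table, tally_polymorphism
from .selection_stats import (SelectionSummary, correlate_log_ratios, mk_test,
                              summarize_table)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    version: str
    seed: int
    started: float
    finished: float = 0.0


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class StudyInputs:
    reference: Path
    annotation: Path
    snps: Path
    alignments_dir: Path

    @classmethod
    def from_study_dir(cls, study_dir) -> "StudyInputs":
        d = Path(study_dir)
        return cls(d / "reference.fasta", d / "genes.gff3", d / "snps.vcf",
                   d / "alignments")

    def check(self) -> None:
        for p in (self.reference, self.annotation, self.snps, self.alignments_dir):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing pipeline input: {p}")


def run_pipeline(
    inputs: StudyInputs,
    config: PipelineConfig,
    outdir,
    fit_ml: bool = False,
) -> dict:
    """Run the full analysis and write the report directory.

    Per-gene failures (unreadable alignment, saturated distances) are
    flagged in the output rather than aborting the run.  Returns a dict
    with the in-memory results.
    """
    inputs.check()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    code = get_code(config.genetic_code)
    focal, sister = config.focal_species, config.sister_species
    species = (focal, sister) + tuple(
        s for s in config.outgroup_species if s not in (focal, sister))

    contigs = read_fasta(inputs.reference)
    models = read_annotation(inputs.annotation, contigs)
    snps = read_snp_table(inputs.snps, reference=contigs)

    protein = [m for m in models if m.feature_class == "protein"
               and m.gene_id not in config.excluded_genes]
    grouping = {m.gene_id: config.group_of(m.gene_id) for m in protein}
    site_counts = {m.gene_id: gene_site_counts(extract_cds(m, contigs), code)
                   for m in protein}

    # --- polymorphism ---
    classifications = classify_snps(snps, models, contigs, code)
    poly = tally_polymorphism(classifications, models, grouping, site_counts,
                              excluded_genes=config.excluded_genes)
    poly_by_group = {p.group_label: p for p in poly}

    # --- divergence: pool NG86 counts over member genes per group ---
    flags: dict = {}
    pair_counts: dict = {}  # (group, other_sp) -> dict of summed counts
    for m in protein:
        path = Path(inputs.alignments_dir) / f"{m.gene_id}.fasta"
        if not path.exists():
            flags.setdefault(m.gene_id, []).append("missing alignment")
            continue
        try:
            aln = read_alignment_fasta(path, gene_id=m.gene_id)
            for other in [sister] + [s for s in config.outgroup_species if s != sister]:
                div = ng86_divergence(aln, focal, other, code,
                                      zero_ds_policy="na")
                key = (grouping[m.gene_id], other)
                agg = pair_counts.setdefault(
                    key, {"nd": 0.0, "sd": 0.0, "n_sites": 0.0, "s_sites": 0.0})
                agg["nd"] += div.nd
                agg["sd"] += div.sd
                agg["n_sites"] += div.n_sites
                agg["s_sites"] += div.s_sites
        except Exception as exc:  # noqa: BLE001 - per-gene isolation is the contract
            log.warning("gene %s failed divergence stage: %s", m.gene_id, exc)
            flags.setdefault(m.gene_id, []).append(f"divergence failed: {exc}")

    from .divergence import jukes_cantor

    def group_omega(group: str, other: str):
        agg = pair_counts.get((group, other))
        if agg is None:
            return math.nan, math.nan, math.nan, False
        dN = jukes_cantor(agg["nd"] / agg["n_sites"])
        dS = jukes_cantor(agg["sd"] / agg["s_sites"])
        if dS > 0:
            return dN, dS, dN / dS, False
        if agg["nd"] == 0:
            return dN, dS, math.nan, False
        if config.zero_ds_policy == "one_synonymous":
            return dN, dS, zero_ds_fallback(agg["nd"], agg["n_sites"], agg["s_sites"]), True
        return dN, dS, math.nan, False

    # --- likelihood fits / LRTs (optional, desk-scale) ---
    lrt_rows = []
    ml_omega: dict = {}
    if fit_ml:
        genes_by_group: dict = {}
        for m in protein:
            genes_by_group.setdefault(grouping[m.gene_id], []).append(m.gene_id)
        for group, genes in sorted(genes_by_group.items()):
            seqs = {sp: "" for sp in species}
            for g in genes:
                path = Path(inputs.alignments_dir) / f"{g}.fasta"
                if not path.exists():
                    continue
                aln = read_alignment_fasta(path, gene_id=g)
                for sp in species:
                    seqs[sp] += aln.sequences[sp]
            if not seqs[focal]:
                continue
            concat = CodonAlignment(gene_id=group, sequences=seqs)
            try:
                fit = fit_branch_model(concat, species, code)
                ml_omega[group] = fit.params.omega[focal]
                if fit.params.omega[focal] > 1.0:
                    lrt = lrt_omega_equals_one(
                        concat, species, focal, code,
                        bonferroni_factor=config.bonferroni_factor_divergence,
                        free_fit=fit)
                    lrt_rows.append(dataclasses.asdict(lrt) | {"group": group})
            except Exception as exc:  # noqa: BLE001
                log.warning("group %s failed ML stage: %s", group, exc)
                flags.setdefault(group, []).append(f"ml failed: {exc}")

    # --- summaries (Table-2-style) ---
    group_lengths: dict = {}
    for m in protein:
        group_lengths[grouping[m.gene_id]] = \
            group_lengths.get(grouping[m.gene_id], 0) + m.cds_length

    summaries = []
    for group in sorted({grouping[m.gene_id] for m in protein}):
        _, _, omega, fallback = group_omega(group, sister)
        if fit_ml and group in ml_omega:
            omega = ml_omega[group]
        p = poly_by_group.get(group)
        summaries.append(SelectionSummary(
            group_label=group,
            length=group_lengths.get(group, 0),
            n_poly=p.total_snps if p else 0,
            dnds=omega,
            pnps=p.pnps if p else math.nan,
            dnds_fallback=fallback,
        ))

    fallback_groups = [s.group_label for s in summaries if s.dnds_fallback]
    table = summarize_table(summaries, mean_exclusions_dnds=fallback_groups)

    # --- MK tests per group x outgroup ---
    mk_rows = []
    for group in sorted({grouping[m.gene_id] for m in protein}):
        p = poly_by_group.get(group)
        if p is None:
            continue
        for other in config.outgroup_species:
            agg = pair_counts.get((group, other))
            if agg is None:
                continue
            mk = mk_test(group, other, int(round(agg["nd"])), int(round(agg["sd"])),
                         p.p_n_count, p.p_s_count,
                         bonferroni_factor=config.bonferroni_factor_mk)
            mk_rows.append(dataclasses.asdict(mk))

    # --- correlation ---
    try:
        correlation = correlate_log_ratios(summaries, min_snps=config.min_snps)
    except ValueError as exc:
        correlation = {"error": str(exc)}

    # --- report ---
    table.to_csv(outdir / "summary_table.tsv", sep="\t", index=False)
    polymorphism_table(poly).to_csv(outdir / "polymorphism.tsv", sep="\t", index=False)
    pd.DataFrame(mk_rows).to_csv(outdir / "mk_tests.tsv", sep="\t", index=False)
    (outdir / "correlation.json").write_text(json.dumps(correlation, indent=1))
    (outdir / "lrt.json").write_text(json.dumps(lrt_rows, indent=1))
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_digests={
            "reference": _digest(inputs.reference),
            "annotation": _digest(inputs.annotation),
            "snps": _digest(inputs.snps),
        },
        version=__version__,
        seed=config.seed,
        started=started,
        finished=time.time(),
    )
    (outdir / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    if flags:
        (outdir / "flags.json").write_text(json.dumps(flags, indent=1))

    return {
        "summaries": summaries,
        "table": table,
        "polymorphism": poly,
        "mk": mk_rows,
        "correlation": correlation,
        "lrt": lrt_rows,
        "flags": flags,
    }
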