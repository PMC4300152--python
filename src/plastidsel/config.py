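"""Pipeline configuration: YAML-backed settings shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import yaml

#: gene-name prefixes grouped into concatenations by default (ATP synthase,
#: NADH dehydrogenase, cytochrome b6f, photosystems I/II, ribosomal proteins,
#: RNA polymerase); all other protein genes are analyzed individually.
DEFAULT_GROUP_PREFIXES = ("atp", "ndh", "pet", "psa", "psb", "rpl", "rps", "rpo")


def group_for_gene(gene_id: str, explicit: Optional[Mapping[str, str]] = None) -> str:
    """Concatenation label for a gene: explicit mapping, else prefix rule."""
    if explicit and gene_id in explicit:
        return explicit[gene_id]
    low = gene_id.lower()
    for prefix in DEFAULT_GROUP_PREFIXES:
        if low.startswith(prefix):
            return prefix
    return gene_id


@dataclass
class PipelineConfig:
    """Settings for a full divergence + polymorphism run.

    ``bonferroni_factor_divergence`` multiplies the per-branch LRT p-values
    (one test per gene/concatenation); ``bonferroni_factor_mk`` multiplies
    the McDonald-Kreitman p-values (genes x outgroups).  ``zero_ds_policy``
    controls the dN/dS fallback when no synonymous difference is observed:
    "one_synonymous" recomputes the ratio as if a single synonymous change
    had occurred; "na" leaves the ratio undefined.
    """

    genetic_code: int = 11
    gene_groups: dict = field(default_factory=dict)
    excluded_genes: tuple = ()
    min_snps: int = 3
    bonferroni_factor_divergence: int = 17
    bonferroni_factor_mk: int = 51
    zero_ds_policy: str = "one_synonymous"
    seed: int = 0
    focal_species: str = "Cam"
    sister_species: str = "Tca"
    outgroup_species: tuple = ("Tca", "Han", "Nta")

    def group_of(self, gene_id: str) -> str:
        return group_for_gene(gene_id, self.gene_groups)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("excluded_genes", "outgroup_species"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["excluded_genes"] = list(self.excluded_genes)
        data["outgroup_species"] = list(self.outgroup_species)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
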