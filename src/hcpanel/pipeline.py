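"""End-to-end orchestration: QC -> consequence -> filter cascade ->
pathogenicity -> cohort summary.

Every variant that enters the pipeline leaves it exactly once: either as a
deleterious call or with one machine-readable exclusion reason
(conservation of records).  The stage results are returned both as typed
records and as a flat :class:`pandas.DataFrame` suitable for report files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml

from . import io as hio
from .errors import ConfigError
from .filtering import FilterState, FilterTrace, apply_cascade, qc_filter, FILTER_CLASSES
from .hgvs import ConsequenceClass, HgvsChange, classify_consequence, parse_hgvs
from .pathogenicity import Basis, PathogenicityCall, call_pathogenicity
from .summary import (
    CohortSummary,
    DeleteriousRecord,
    build_carrier_reports,
    summarize,
    syndrome_crosstab,
)
from .types import AnnotatedVariant, CurationEntry, GenePanelEntry, Genotype, SyndromeFlags

log = logging.getLogger("hcpanel.pipeline")

__all__ = ["Thresholds", "VariantOutcome", "PipelineResult", "run_variants", "run_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the pipeline, with the study defaults."""

    maf_max: float = 0.01
    qual_min: float = 20.0
    neighbor_min: int = 5
    depth_min: int = 4
    splice_window: int = 2
    msi_low_fraction: float = 0.30
    ihc_loss_delta: int = 2
    qc_indels: bool = False  # QC thresholds were defined for SNV calls

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "Thresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown threshold keys {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class VariantOutcome:
    """Everything the pipeline decided about one input variant."""

    variant: AnnotatedVariant
    change: Optional[HgvsChange]
    consequence: ConsequenceClass
    trace: FilterTrace
    call: Optional[PathogenicityCall]

    @property
    def deleterious(self) -> bool:
        return self.call is not None and self.call.deleterious

    @property
    def exclusion_reason(self) -> Optional[str]:
        if self.trace.final_state is FilterState.EXCLUDED:
            return f"filter:{self.trace.exclusion_reason}"
        if self.call is not None and not self.call.deleterious:
            return f"pathogenicity:{self.call.reason}"
        if self.trace.final_state is FilterState.RETAINED_NEEDS_CURATION:
            return "curation_pending"
        return None


def _is_snv(variant: AnnotatedVariant) -> bool:
    return len(variant.call.ref_allele) == 1 and len(variant.call.alt_allele) == 1 and \
        variant.call.ref_allele != "-" and variant.call.alt_allele != "-"


def run_variants(
    variants: List[AnnotatedVariant],
    panel: Mapping[str, GenePanelEntry],
    curation: Mapping[tuple, CurationEntry],
    thresholds: Thresholds = Thresholds(),
) -> List[VariantOutcome]:
    """Run QC, consequence classification, the filter cascade and the
    pathogenicity rules over a list of annotated variants."""
    # first pass: parse + classify, and count filter-class candidates per
    # (sample, gene) so the cascade can recognize compound heterozygosity
    parsed: List[tuple] = []
    candidates: Dict[tuple, int] = {}
    for variant in variants:
        if variant.gene not in panel:
            raise ConfigError(f"gene {variant.gene} absent from the panel file")
        try:
            change = parse_hgvs(variant.cdna_hgvs, variant.protein_hgvs)
            consequence = classify_consequence(change, thresholds.splice_window)
        except Exception:
            change, consequence = None, ConsequenceClass.OTHER
        parsed.append((variant, change, consequence))
        if consequence in FILTER_CLASSES:
            key = (variant.sample_id, variant.gene)
            candidates[key] = candidates.get(key, 0) + 1

    outcomes: List[VariantOutcome] = []
    for variant, change, consequence in parsed:
        if thresholds.qc_indels or _is_snv(variant):
            qc_pass = qc_filter(
                variant.call,
                thresholds.qual_min,
                thresholds.neighbor_min,
                thresholds.depth_min,
            )
        else:
            qc_pass = True  # indel calls bypass the SNV quality filter
        entry = curation.get((variant.gene, variant.cdna_hgvs))
        trace = apply_cascade(
            variant,
            consequence,
            panel[variant.gene],
            maf_max=thresholds.maf_max,
            curation=entry,
            change=change,
            splice_window=thresholds.splice_window,
            same_gene_candidates=candidates.get((variant.sample_id, variant.gene), 0),
            qc_pass=qc_pass,
        )
        call = None
        if trace.final_state is FilterState.RETAINED:
            call = call_pathogenicity(variant, consequence, variant.predictions, entry)
        outcome = VariantOutcome(variant, change, consequence, trace, call)
        if not outcome.deleterious:
            log.info(
                "excluded %s: %s", variant.variant_id, outcome.exclusion_reason
            )
        outcomes.append(outcome)
    return outcomes


def outcomes_frame(outcomes: List[VariantOutcome]) -> pd.DataFrame:
    """Flatten pipeline outcomes into one row per input variant."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "variant_id": o.variant.variant_id,
                "sample": o.variant.sample_id,
                "gene": o.variant.gene,
                "cdna": o.variant.cdna_hgvs,
                "protein": o.variant.protein_hgvs,
                "consequence": o.consequence.value,
                "qc_pass": o.trace.qc_pass,
                "criterion_region": o.trace.criterion_region,
                "criterion_class": o.trace.criterion_class,
                "criterion_frequency": o.trace.criterion_frequency,
                "criterion_inheritance": o.trace.criterion_inheritance,
                "recessive_flagged": o.trace.recessive_flagged,
                "filter_state": o.trace.final_state.value,
                "deleterious": o.deleterious,
                "basis": o.call.basis.value if o.call else "",
                "exclusion_reason": o.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows)


def deleterious_records(outcomes: List[VariantOutcome]) -> List[DeleteriousRecord]:
    return [
        DeleteriousRecord(
            sample_id=o.variant.sample_id,
            gene=o.variant.gene,
            consequence=o.consequence,
            variant_id=o.variant.variant_id,
        )
        for o in outcomes
        if o.deleterious
    ]


@dataclass
class PipelineResult:
    outcomes: List[VariantOutcome]
    summary: CohortSummary
    crosstab: Dict[str, Dict[str, int]]
    reports: list

    @property
    def frame(self) -> pd.DataFrame:
        return outcomes_frame(self.outcomes)


def run_pipeline(config_path) -> PipelineResult:
    """Run the full pipeline from a declarative YAML configuration.

    The config names the variant table(s), panel, curation and flags files,
    threshold overrides and the cohort size; see the README for the schema.
    """
    config_path = Path(config_path)
    with open(config_path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    for key in ("variants", "panel", "curation"):
        if key not in config:
            raise ConfigError(f"pipeline config must name '{key}'")

    base = config_path.parent

    def _resolve(name):
        p = Path(name)
        return p if p.is_absolute() else base / p

    variant_paths = config["variants"]
    if isinstance(variant_paths, str):
        variant_paths = [variant_paths]
    variants: List[AnnotatedVariant] = []
    for path in variant_paths:
        variants.extend(hio.read_variant_table(_resolve(path)))

    panel = hio.read_gene_panel(_resolve(config["panel"]))
    curation = hio.read_curation(_resolve(config["curation"]))
    flags: Dict[str, SyndromeFlags] = {}
    if config.get("flags"):
        flags = hio.read_syndrome_flags(_resolve(config["flags"]))
    thresholds = Thresholds.from_mapping(config.get("thresholds", {}))
    n_probands = int(config.get("n_probands", 0))

    outcomes = run_variants(variants, panel, curation, thresholds)
    records = deleterious_records(outcomes)
    summary = summarize(records, panel, flags, n_probands or len(
        {v.sample_id for v in variants}
    ))
    reports = build_carrier_reports(records, panel, flags)
    crosstab = syndrome_crosstab(reports)

    out_dir = config.get("out_dir")
    if out_dir:
        out = _resolve(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outcomes_frame(outcomes).to_csv(out / "variant_outcomes.tsv", sep="\t", index=False)
        with open(out / "summary.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(summary_dict(summary, crosstab), fh, sort_keys=True)
    return PipelineResult(outcomes=outcomes, summary=summary, crosstab=crosstab,
                          reports=reports)


def summary_dict(summary: CohortSummary, crosstab=None) -> dict:
    doc = {
        "n_probands": summary.n_probands,
        "n_carriers": summary.n_carriers,
        "n_variants": summary.n_variants,
        "n_genes": summary.n_genes,
        "multi_gene_carriers": summary.multi_gene_carriers,
        "per_class_variant_counts": {
            k.value: v for k, v in sorted(summary.per_class_variant_counts.items())
        },
        "per_category_variant_counts": {
            k.value: v for k, v in sorted(summary.per_category_variant_counts.items())
        },
        "per_category_carrier_counts": {
            k.value: v for k, v in sorted(summary.per_category_carrier_counts.items())
        },
        "fractions": {
            name: {"percent": pct, "numerator": num, "denominator": den}
            for name, (pct, num, den) in sorted(summary.fraction_tables.items())
        },
    }
    if crosstab is not None:
        doc["syndrome_crosstab"] = crosstab
    return doc
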