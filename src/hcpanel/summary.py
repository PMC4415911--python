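"""Cohort-level aggregation of per-proband deleterious calls.

Produces the headline numbers of a panel-screening study: variant, gene and
carrier counts, per-gene-category breakdowns, multi-gene carriers, the
syndrome-criteria cross-tabulation and an onset-age comparison.

Percentages are rounded half-up to one decimal place (the convention of the
clinical-genetics literature this pipeline mirrors), with numerator and
denominator reported alongside every fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .errors import InputError
from .hgvs import ConsequenceClass
from .types import GeneCategory, GenePanelEntry, SyndromeFlags

__all__ = [
    "DeleteriousRecord",
    "CarrierReport",
    "CohortSummary",
    "percent",
    "summarize",
    "category_gene_breakdown",
    "syndrome_crosstab",
    "onset_age_ttest",
]


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (18/99 -> 18.2)."""
    if denominator <= 0:
        raise InputError("percentage denominator must be positive")
    if numerator > denominator:
        raise InputError(f"numerator {numerator} exceeds denominator {denominator}")
    value = Decimal(numerator * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DeleteriousRecord:
    """Minimal view of one deleterious call used for aggregation."""

    sample_id: str
    gene: str
    consequence: ConsequenceClass
    variant_id: str = ""


@dataclass
class CarrierReport:
    """All deleterious calls of one proband plus family-level context."""

    sample_id: str
    calls: List[DeleteriousRecord]
    genes: frozenset
    categories: frozenset
    syndrome_flags: SyndromeFlags = field(default_factory=SyndromeFlags)
    age_dx: Optional[int] = None

    @property
    def multi_gene(self) -> bool:
        return len(self.genes) >= 2


@dataclass
class CohortSummary:
    n_probands: int
    n_carriers: int
    n_variants: int
    n_genes: int
    per_category_variant_counts: Dict[GeneCategory, int]
    per_category_carrier_counts: Dict[GeneCategory, int]
    per_class_variant_counts: Dict[ConsequenceClass, int]
    multi_gene_carriers: int
    fraction_tables: Dict[str, Tuple[float, int, int]]


def _panel_lookup(panel: Mapping[str, GenePanelEntry], gene: str) -> GenePanelEntry:
    try:
        return panel[gene]
    except KeyError:
        raise InputError(f"gene {gene} absent from the panel file") from None


def build_carrier_reports(
    calls: Iterable[DeleteriousRecord],
    panel: Mapping[str, GenePanelEntry],
    flags: Optional[Mapping[str, SyndromeFlags]] = None,
) -> List[CarrierReport]:
    by_sample: Dict[str, List[DeleteriousRecord]] = {}
    for call in calls:
        by_sample.setdefault(call.sample_id, []).append(call)
    reports = []
    for sample_id in sorted(by_sample):
        sample_calls = by_sample[sample_id]
        genes = frozenset(c.gene for c in sample_calls)
        categories = frozenset(_panel_lookup(panel, g).category for g in genes)
        fl = (flags or {}).get(sample_id, SyndromeFlags())
        reports.append(
            CarrierReport(
                sample_id=sample_id,
                calls=sample_calls,
                genes=genes,
                categories=categories,
                syndrome_flags=fl,
            )
        )
    return reports


def summarize(
    calls: Sequence[DeleteriousRecord],
    panel: Mapping[str, GenePanelEntry],
    flags: Optional[Mapping[str, SyndromeFlags]] = None,
    n_probands: int = 0,
    n_hbocs_families: Optional[int] = None,
) -> CohortSummary:
    """Aggregate deleterious calls into cohort-level counts and fractions.

    ``flags`` maps family/sample id to syndrome flags; when it covers the
    whole cohort, ``n_hbocs_families`` is derived from it, otherwise it may
    be supplied directly.  A carrier contributes to every gene-category
    count it belongs to; multi-gene carriers are counted once.
    """
    reports = build_carrier_reports(calls, panel, flags)
    n_carriers = len(reports)
    if n_probands and n_probands < n_carriers:
        raise InputError(
            f"n_probands ({n_probands}) below the number of carriers ({n_carriers})"
        )

    per_class: Dict[ConsequenceClass, int] = {}
    per_cat_variants: Dict[GeneCategory, int] = {}
    genes_seen = set()
    n_variants = 0
    for call in calls:
        n_variants += 1
        genes_seen.add(call.gene)
        per_class[call.consequence] = per_class.get(call.consequence, 0) + 1
        cat = _panel_lookup(panel, call.gene).category
        per_cat_variants[cat] = per_cat_variants.get(cat, 0) + 1

    per_cat_carriers: Dict[GeneCategory, int] = {}
    for report in reports:
        for cat in report.categories:
            per_cat_carriers[cat] = per_cat_carriers.get(cat, 0) + 1

    multi = sum(1 for r in reports if r.multi_gene)

    fractions: Dict[str, Tuple[float, int, int]] = {}
    brca_carriers = per_cat_carriers.get(GeneCategory.BRCA, 0)
    if n_probands:
        fractions["carriers_of_cohort"] = (
            percent(n_carriers, n_probands), n_carriers, n_probands,
        )
        fractions["brca_carriers_of_cohort"] = (
            percent(brca_carriers, n_probands), brca_carriers, n_probands,
        )
    if n_carriers:
        fractions["multi_gene_of_carriers"] = (
            percent(multi, n_carriers), multi, n_carriers,
        )
    if n_hbocs_families is None and flags:
        n_hbocs_families = sum(1 for f in flags.values() if f.hbocs)
    if n_hbocs_families:
        fractions["brca_carriers_of_hbocs_families"] = (
            percent(brca_carriers, n_hbocs_families), brca_carriers, n_hbocs_families,
        )
    breakdown = category_gene_breakdown(calls, panel)
    non_brca = breakdown["non_brca_total"]
    if non_brca:
        fa = breakdown.get(GeneCategory.FA, 0)
        fractions["fa_genes_of_non_brca_genes"] = (percent(fa, non_brca), fa, non_brca)

    return CohortSummary(
        n_probands=n_probands,
        n_carriers=n_carriers,
        n_variants=n_variants,
        n_genes=len(genes_seen),
        per_category_variant_counts=per_cat_variants,
        per_category_carrier_counts=per_cat_carriers,
        per_class_variant_counts=per_class,
        multi_gene_carriers=multi,
        fraction_tables=fractions,
    )


def category_gene_breakdown(
    calls: Iterable[DeleteriousRecord],
    panel: Mapping[str, GenePanelEntry],
) -> Dict:
    """Distinct mutated genes per category, plus the non-BRCA gene total."""
    genes = {call.gene for call in calls}
    counts: Dict = {}
    for gene in genes:
        cat = _panel_lookup(panel, gene).category
        counts[cat] = counts.get(cat, 0) + 1
    counts["non_brca_total"] = sum(
        v for k, v in counts.items() if isinstance(k, GeneCategory) and k is not GeneCategory.BRCA
    )
    return counts


#: gene-group -> (categories forming the group, flag attribute checked)
SYNDROME_GROUPS = {
    "BRCA1/2": (frozenset({GeneCategory.BRCA}), "hbocs"),
    "TP53": (frozenset({GeneCategory.TP53}), "lfs"),
    "MMR": (frozenset({GeneCategory.MMR}), "ls"),
}


def syndrome_crosstab(reports: Sequence[CarrierReport]) -> Dict[str, Dict[str, int]]:
    """Carriers per gene group, split by whether the family fulfils the
    matching hereditary-cancer-syndrome criteria."""
    table: Dict[str, Dict[str, int]] = {}
    for group, (categories, flag_attr) in SYNDROME_GROUPS.items():
        fulfilling = not_fulfilling = 0
        for report in reports:
            if not (report.categories & categories):
                continue
            if getattr(report.syndrome_flags, flag_attr):
                fulfilling += 1
            else:
                not_fulfilling += 1
        table[group] = {
            "carriers": fulfilling + not_fulfilling,
            "fulfilling": fulfilling,
            "not_fulfilling": not_fulfilling,
        }
    return table


def onset_age_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "pooled",
) -> Tuple[float, float]:
    """Two-sample t-test on onset ages; two-sided P.

    ``variant`` selects the classical pooled-variance test (default) or the
    Welch unequal-variance test.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("each onset-age group needs at least two values")
    if variant not in ("pooled", "welch"):
        raise InputError(f"unknown t-test variant {variant!r}")
    import numpy as np

    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    # degenerate 0/0 case (identical constant groups): no evidence of any
    # difference, reported as t = 0, P = 1 rather than NaN
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    result = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(result.statistic), float(result.pvalue)
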