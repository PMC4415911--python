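"""QC pre-filter and the four-criterion candidate filter cascade.

A variant is followed up only when every criterion holds:

i.   region    — exonic, or within the splice window of an exon/intron
                 boundary;
ii.  class     — an indel, a nonsense or missense substitution, or a splice
                 change;
iii. frequency — not present in the population reference panel at a minor
                 allele frequency above ``maf_max`` (absent counts as rare);
iv.  inheritance — the genotype is compatible with the gene's mode of
                 inheritance.

For a recessively acting gene, a heterozygous call passes criterion iv only
as part of a compound-heterozygous pair, or when it is a single *strong*
candidate — a protein-truncating stop or a canonical splice-site change —
in which case it is retained pending manual curation: a matching curation
entry (database or literature evidence) resolves it to fully retained.

All four criteria are evaluated unconditionally (no short-circuiting), so
the retained set is independent of evaluation order; the order only decides
which violated criterion is named first in the exclusion reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigError
from .hgvs import ConsequenceClass, HgvsChange, parse_hgvs
from .types import (
    AnnotatedVariant,
    CurationEntry,
    Evidence,
    GenePanelEntry,
    Genotype,
    Inheritance,
    RawCallRecord,
    Region,
)

__all__ = ["FilterState", "FilterTrace", "qc_filter", "apply_cascade",
           "CRITERION_ORDER", "FILTER_CLASSES"]

#: Consequence classes accepted by criterion ii.
FILTER_CLASSES = frozenset(
    {
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.NONFRAMESHIFT_INDEL,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.MISSENSE,
        ConsequenceClass.SPLICING,
    }
)

CRITERION_ORDER = ("region", "class", "frequency", "inheritance")


class FilterState(str, enum.Enum):
    RETAINED = "retained"
    RETAINED_NEEDS_CURATION = "retained_needs_curation"
    EXCLUDED = "excluded"


@dataclass
class FilterTrace:
    """Full audit record of one variant's passage through the cascade."""

    variant_id: str
    qc_pass: bool
    criterion_region: bool
    criterion_class: bool
    criterion_frequency: bool
    criterion_inheritance: bool
    recessive_flagged: bool
    final_state: FilterState
    exclusion_reason: Optional[str] = None

    @property
    def retained(self) -> bool:
        return self.final_state is not FilterState.EXCLUDED


def qc_filter(
    record: RawCallRecord,
    qual_min: float = 20.0,
    neighbor_min: int = 5,
    depth_min: int = 4,
) -> bool:
    """Post-calling quality filter: call quality, distance to the nearest
    neighbouring call, and read depth must all reach their thresholds."""
    if qual_min < 0 or neighbor_min < 0 or depth_min < 0:
        raise ValueError("QC thresholds must be non-negative")
    return (
        record.quality >= qual_min
        and record.neighbor_distance >= neighbor_min
        and record.depth >= depth_min
    )


def _strong_candidate(consequence: ConsequenceClass, change: Optional[HgvsChange]) -> bool:
    """A single heterozygous allele in a recessive gene is worth follow-up
    only when it is unambiguously disruptive: a splice-site change, or any
    change whose protein annotation is a stop (nonsense substitutions and
    truncating indels alike)."""
    if consequence is ConsequenceClass.SPLICING:
        return True
    if consequence is ConsequenceClass.NONSENSE:
        return True
    if change is not None and change.protein_terminates:
        return True
    if change is not None and change.frameshift_tagged:
        # a frameshift is as disruptive as a stop; kept under the same clause
        return True
    return False


def apply_cascade(
    variant: AnnotatedVariant,
    consequence: ConsequenceClass,
    panel: GenePanelEntry,
    maf_max: float = 0.01,
    curation: Optional[CurationEntry] = None,
    *,
    change: Optional[HgvsChange] = None,
    splice_window: int = 2,
    same_gene_candidates: int = 1,
    qc_pass: bool = True,
    criterion_order: Sequence[str] = CRITERION_ORDER,
) -> FilterTrace:
    """Evaluate the four-criterion cascade for one variant.

    ``same_gene_candidates`` is the number of filter-class variants this
    sample carries in the same gene (including this one); a value >= 2 in a
    recessive gene constitutes compound heterozygosity.  ``change`` is the
    parsed HGVS pair (parsed on demand when omitted).
    """
    if panel.gene != variant.gene:
        raise ConfigError(
            f"panel entry for {panel.gene} applied to a {variant.gene} variant"
        )
    if set(criterion_order) != set(CRITERION_ORDER):
        raise ValueError(f"criterion_order must permute {CRITERION_ORDER}")

    if change is None:
        try:
            change = parse_hgvs(variant.cdna_hgvs, variant.protein_hgvs)
        except Exception:
            change = None

    # -- criterion i: region -------------------------------------------------
    if variant.region is Region.EXONIC:
        c_region = True
    elif change is not None and change.intron_offset is not None:
        c_region = abs(change.intron_offset) <= splice_window
    else:
        # labelled splicing/intronic but no resolvable offset: outside window
        c_region = variant.region is Region.SPLICING and consequence is ConsequenceClass.SPLICING

    # -- criterion ii: consequence class ------------------------------------
    c_class = consequence in FILTER_CLASSES

    # -- criterion iii: population frequency ---------------------------------
    c_freq = variant.maf_1000g is None or variant.maf_1000g <= maf_max

    # -- criterion iv: inheritance -------------------------------------------
    recessive_flagged = False
    if panel.inheritance is Inheritance.RECESSIVE:
        if variant.call.genotype is Genotype.HOM:
            c_inherit = True
        elif same_gene_candidates >= 2:
            c_inherit = True  # compound heterozygosity
        elif _strong_candidate(consequence, change):
            c_inherit = True
            recessive_flagged = True
        else:
            c_inherit = False
    else:
        # dominant (or unknown) inheritance: any germline genotype qualifies
        c_inherit = True

    flags = {
        "region": c_region,
        "class": c_class,
        "frequency": c_freq,
        "inheritance": c_inherit,
    }

    if qc_pass and all(flags.values()):
        if recessive_flagged:
            curated = curation is not None and curation.evidence is not Evidence.NONE
            state = FilterState.RETAINED if curated else FilterState.RETAINED_NEEDS_CURATION
        else:
            state = FilterState.RETAINED
        reason = None
    else:
        state = FilterState.EXCLUDED
        if not qc_pass:
            reason = "qc"
        else:
            reason = next(name for name in criterion_order if not flags[name])

    return FilterTrace(
        variant_id=variant.variant_id,
        qc_pass=qc_pass,
        criterion_region=c_region,
        criterion_class=c_class,
        criterion_frequency=c_freq,
        criterion_inheritance=c_inherit,
        recessive_flagged=recessive_flagged,
        final_state=state,
        exclusion_reason=reason,
    )
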