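"""Final deleteriousness calls.

Protein-truncating classes (frameshift and in-frame indels, nonsense,
splice-site changes) are considered pathogenic outright.  A missense change
must pass a two-feature in-silico rule — at least one missense predictor
(SIFT / PolyPhen-2) calls it damaging AND at least one conservation scorer
(PhyloP / LRT) calls the site conserved — and additionally carry curation
evidence (a locus-specific database entry or a published report) before it
is called deleterious.  Prediction columns that annotators attach to
non-missense variants are ignored: the in-silico rule is scoped to the
missense class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import InputError
from .hgvs import ConsequenceClass, TRUNCATING_CLASSES
from .types import (
    AnnotatedVariant,
    ConservationCall,
    CurationEntry,
    Evidence,
    PolyphenCall,
    PredictionProfile,
    SiftCall,
)

__all__ = ["Basis", "PathogenicityCall", "missense_insilico", "call_pathogenicity"]

#: PolyPhen-2 categories read as "damaging".  "possibly damaging" is
#: included by default (conservative reading); override via the
#: ``polyphen_damaging`` argument if a stricter mapping is wanted.
POLYPHEN_DAMAGING_DEFAULT = frozenset(
    {
        PolyphenCall.DAMAGING,
        PolyphenCall.PROBABLY_DAMAGING,
        PolyphenCall.POSSIBLY_DAMAGING,
    }
)


class Basis(str, enum.Enum):
    TRUNCATING_CLASS = "truncating_class"
    MISSENSE_INSILICO_PLUS_CURATION = "missense_insilico_plus_curation"
    NOT_DELETERIOUS = "not_deleterious"


@dataclass
class PathogenicityCall:
    variant_id: str
    deleterious: bool
    basis: Basis
    feature_prediction: Optional[bool] = None
    feature_conservation: Optional[bool] = None
    reason: Optional[str] = None  # why a non-deleterious call failed


def missense_insilico(
    profile: PredictionProfile,
    polyphen_damaging: frozenset = POLYPHEN_DAMAGING_DEFAULT,
) -> tuple[bool, bool, bool]:
    """Evaluate the two-feature rule on a missense prediction profile.

    Returns ``(feature_prediction, feature_conservation, damaging)`` where
    each feature is an OR over its two tools and ``damaging`` requires both
    features.  An absent tool call counts as not-damaging / not-conserved,
    but each feature needs at least one tool with a call.
    """
    if profile.sift is SiftCall.ABSENT and profile.polyphen is PolyphenCall.ABSENT:
        raise InputError("missense rule needs at least one missense predictor call")
    if profile.phylop is ConservationCall.ABSENT and profile.lrt is ConservationCall.ABSENT:
        raise InputError("missense rule needs at least one conservation call")
    feature_prediction = (
        profile.sift is SiftCall.DAMAGING or profile.polyphen in polyphen_damaging
    )
    feature_conservation = (
        profile.phylop is ConservationCall.CONSERVED
        or profile.lrt is ConservationCall.CONSERVED
    )
    return feature_prediction, feature_conservation, feature_prediction and feature_conservation


def call_pathogenicity(
    variant: AnnotatedVariant,
    consequence: ConsequenceClass,
    profile: Optional[PredictionProfile] = None,
    curation: Optional[CurationEntry] = None,
) -> PathogenicityCall:
    """Assign the final deleteriousness call to a filter-retained variant."""
    if consequence in TRUNCATING_CLASSES:
        return PathogenicityCall(
            variant_id=variant.variant_id,
            deleterious=True,
            basis=Basis.TRUNCATING_CLASS,
        )

    if consequence is ConsequenceClass.MISSENSE:
        if profile is None:
            profile = variant.predictions
        if profile is None or profile.empty:
            raise InputError(
                f"missense variant {variant.variant_id} has no prediction profile"
            )
        pred, cons, damaging = missense_insilico(profile)
        curated = curation is not None and curation.evidence is not Evidence.NONE
        if damaging and curated:
            return PathogenicityCall(
                variant_id=variant.variant_id,
                deleterious=True,
                basis=Basis.MISSENSE_INSILICO_PLUS_CURATION,
                feature_prediction=pred,
                feature_conservation=cons,
            )
        reason = "missense_rule" if not damaging else "curation"
        return PathogenicityCall(
            variant_id=variant.variant_id,
            deleterious=False,
            basis=Basis.NOT_DELETERIOUS,
            feature_prediction=pred,
            feature_conservation=cons,
            reason=reason,
        )

    return PathogenicityCall(
        variant_id=variant.variant_id,
        deleterious=False,
        basis=Basis.NOT_DELETERIOUS,
        reason=f"class:{consequence.value}",
    )
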