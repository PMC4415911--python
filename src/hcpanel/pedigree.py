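"""Pedigrees: study eligibility, lineage partitioning and segregation scoring.

Eligibility follows the study's three enrolment rules for a breast-cancer
proband:

* age at diagnosis <= 35 with at least one other blood relative with any
  cancer;
* 35 < age <= 50 with at least two blood relatives with cancer in the same
  lineage;
* age > 50 with at least three blood relatives with cancer in the same
  lineage.

Segregation is reported as "x/y": carriers among family members tested for
the variant (the proband included).  Segregation is *complete* when every
tested affected member carries the variant — an unaffected tested
non-carrier does not break completeness (it is the expected genotype for an
unaffected relative); a tested affected non-carrier does.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .errors import InputError, StructuralError

__all__ = [
    "CarrierStatus",
    "Lineage",
    "Individual",
    "Pedigree",
    "SegregationResult",
    "check_eligibility",
    "score_segregation",
]


class CarrierStatus(str, enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    UNTESTED = "untested"


class Lineage(str, enum.Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    NUCLEAR = "nuclear"


@dataclass
class Individual:
    id: str
    family_id: str
    sex: str = "unknown"  # female | male | unknown
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    relation: str = ""
    affected: bool = False
    cancer_types: List[str] = field(default_factory=list)
    ages_dx: List[int] = field(default_factory=list)
    is_proband: bool = False
    lineage: Optional[Lineage] = None
    genotype_for: Dict[str, CarrierStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.affected and not self.cancer_types:
            raise InputError(f"affected individual {self.id} lists no cancer type")
        if self.ages_dx and not self.affected:
            raise InputError(f"unaffected individual {self.id} has a diagnosis age")

    @property
    def age_dx(self) -> Optional[int]:
        """First diagnosis age (bilateral/metachronous cases store several)."""
        return self.ages_dx[0] if self.ages_dx else None


@dataclass
class Pedigree:
    family_id: str
    members: List[Individual]
    proband_id: str

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if len(ids) != len(self.members):
            raise StructuralError(f"family {self.family_id}: duplicate member ids")
        if self.proband_id not in ids:
            raise StructuralError(
                f"family {self.family_id}: proband {self.proband_id} not a member"
            )
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise StructuralError(
                        f"family {self.family_id}: member {m.id} names unknown "
                        f"parent {parent}"
                    )
        self._assign_lineages()

    def __len__(self) -> int:
        return len(self.members)

    @property
    def proband(self) -> Individual:
        return next(m for m in self.members if m.id == self.proband_id)

    def member(self, member_id: str) -> Individual:
        try:
            return next(m for m in self.members if m.id == member_id)
        except StopIteration:
            raise StructuralError(
                f"family {self.family_id}: no member {member_id}"
            ) from None

    # -- lineage partition ---------------------------------------------------
    def _assign_lineages(self) -> None:
        """Partition non-proband members into paternal/maternal/nuclear.

        Explicit ``lineage`` values from the input win; the rest are derived
        by connectivity: anyone reachable from the proband's father without
        passing through the proband is paternal, the mother's side maternal,
        and the proband's siblings, children and spouses-of-children nuclear.
        Members connected through neither parent default to nuclear.
        """
        by_id = {m.id: m for m in self.members}
        proband = self.proband

        children: Dict[str, List[str]] = {m.id: [] for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent in children:
                    children[parent].append(m.id)

        def side(root: Optional[str], blocked: Optional[str]) -> set:
            # walk the family graph from one parent, never through the
            # proband or the other parent (so siblings, reachable from both
            # parents, surface on both sides and resolve to nuclear)
            if root is None or root not in by_id:
                return set()
            seen, stack = set(), [root]
            while stack:
                cur = stack.pop()
                if cur in seen or cur == proband.id or cur == blocked:
                    continue
                seen.add(cur)
                node = by_id[cur]
                neighbours = [node.father_id, node.mother_id] + children[cur]
                stack.extend(n for n in neighbours if n and n not in seen)
            return seen

        paternal = side(proband.father_id, proband.mother_id)
        maternal = side(proband.mother_id, proband.father_id)
        for m in self.members:
            if m.id == proband.id or m.lineage is not None:
                continue
            in_p, in_m = m.id in paternal, m.id in maternal
            if in_p and not in_m:
                m.lineage = Lineage.PATERNAL
            elif in_m and not in_p:
                m.lineage = Lineage.MATERNAL
            else:
                # parents and siblings sit in both sets; own descendants in
                # neither: all belong to the proband's nuclear family
                m.lineage = Lineage.NUCLEAR

    # -- phenotype counts ----------------------------------------------------
    def affected_relatives(self) -> int:
        return sum(1 for m in self.members if m.affected and m.id != self.proband_id)

    def same_lineage_affected(self) -> int:
        """Largest number of affected relatives attributable to one lineage.

        Nuclear-family relatives share both parental bloodlines, so they
        count toward either side.
        """
        counts = {Lineage.PATERNAL: 0, Lineage.MATERNAL: 0}
        nuclear = 0
        for m in self.members:
            if m.id == self.proband_id or not m.affected:
                continue
            if m.lineage is Lineage.NUCLEAR or m.lineage is None:
                nuclear += 1
            else:
                counts[m.lineage] += 1
        return max(counts.values()) + nuclear if counts else nuclear


@dataclass
class SegregationResult:
    variant_id: str
    positive: int
    tested: int
    display: str
    completeness: str  # complete | incomplete | unavailable

    def __post_init__(self) -> None:
        if not 0 <= self.positive <= self.tested:
            raise InputError(
                f"segregation {self.positive}/{self.tested} out of range"
            )


def check_eligibility(
    proband_age: int,
    relatives_with_cancer: int,
    same_lineage_count: int,
) -> bool:
    """Apply the three age-stratified family-history enrolment rules."""
    if relatives_with_cancer < 0 or same_lineage_count < 0:
        raise InputError("relative counts must be non-negative")
    if proband_age <= 35:
        return relatives_with_cancer >= 1
    if proband_age <= 50:
        return same_lineage_count >= 2
    return same_lineage_count >= 3


def pedigree_eligible(pedigree: Pedigree) -> bool:
    """Convenience wrapper deriving the counts from the pedigree itself."""
    age = pedigree.proband.age_dx
    if age is None:
        raise InputError(
            f"family {pedigree.family_id}: proband has no diagnosis age"
        )
    return check_eligibility(
        age, pedigree.affected_relatives(), pedigree.same_lineage_affected()
    )


def score_segregation(pedigree: Pedigree, variant_id: str) -> SegregationResult:
    """Count carriers among tested members and judge completeness."""
    tested = [
        m
        for m in pedigree.members
        if m.genotype_for.get(variant_id, CarrierStatus.UNTESTED)
        is not CarrierStatus.UNTESTED
    ]
    if not any(variant_id in m.genotype_for for m in pedigree.members):
        raise InputError(
            f"variant {variant_id} unknown to every member of family "
            f"{pedigree.family_id}"
        )
    if not tested:
        return SegregationResult(variant_id, 0, 0, "U/A", "unavailable")

    positive = sum(
        1 for m in tested if m.genotype_for[variant_id] is CarrierStatus.CARRIER
    )
    affected_tested = [m for m in tested if m.affected]
    complete = all(
        m.genotype_for[variant_id] is CarrierStatus.CARRIER for m in affected_tested
    )
    return SegregationResult(
        variant_id,
        positive,
        len(tested),
        f"{positive}/{len(tested)}",
        "complete" if complete else "incomplete",
    )
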