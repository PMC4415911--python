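"""Shared domain types for the hereditary-cancer panel pipeline.

Every record that crosses a module boundary is one of the dataclasses
defined here.  Validation is performed eagerly in ``__post_init__`` so that
malformed records fail at construction, not deep inside a pipeline stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class Region(str, enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    OTHER = "other"


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"


class GeneCategory(str, enum.Enum):
    BRCA = "BRCA"
    TP53 = "TP53"
    MMR = "MMR"
    CDH1 = "CDH1"
    FA = "FA"
    OTHER = "OTHER"


class Evidence(str, enum.Enum):
    DATABASE = "database"
    LITERATURE = "literature"
    NONE = "none"


class SiftCall(str, enum.Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class PolyphenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    DAMAGING = "damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class ConservationCall(str, enum.Enum):
    CONSERVED = "conserved"
    NOT_CONSERVED = "not_conserved"
    ABSENT = "absent"


@dataclass(frozen=True)
class RawCallRecord:
    """A single variant call with the quality metrics the QC filter consumes."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: Genotype = Genotype.HET
    quality: float = 0.0
    neighbor_distance: int = 0
    depth: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be 1-based positive, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise InputError(
                f"ref and alt alleles are identical ({self.ref_allele!r}) "
                f"at {self.chrom}:{self.pos}"
            )
        if self.quality < 0 or self.neighbor_distance < 0 or self.depth < 0:
            raise InputError("quality metrics must be non-negative")


@dataclass(frozen=True)
class PredictionProfile:
    """Categorical in-silico tool calls feeding the two-feature missense rule.

    The two missense predictors (SIFT, PolyPhen-2) act at the amino-acid
    level; the two conservation scorers (PhyloP, LRT) act at the nucleotide
    level.  ``absent`` means the tool returned no call for the site.
    """

    sift: SiftCall = SiftCall.ABSENT
    polyphen: PolyphenCall = PolyphenCall.ABSENT
    phylop: ConservationCall = ConservationCall.ABSENT
    lrt: ConservationCall = ConservationCall.ABSENT

    @property
    def empty(self) -> bool:
        return (
            self.sift is SiftCall.ABSENT
            and self.polyphen is PolyphenCall.ABSENT
            and self.phylop is ConservationCall.ABSENT
            and self.lrt is ConservationCall.ABSENT
        )


@dataclass
class AnnotatedVariant:
    """One annotated germline variant call for one sample.

    Coordinates are 1-based inclusive [start, end]; a VCF reader converts at
    the boundary.  ``maf_1000g = None`` means the variant is absent from the
    population reference panel and is distinct from an observed frequency of
    zero; both satisfy the rarity criterion.
    """

    call: RawCallRecord
    sample_id: str
    gene: str
    transcript: str
    cdna_hgvs: str
    protein_hgvs: str
    region: Region
    start: int
    end: int
    maf_1000g: Optional[float] = None
    predictions: Optional[PredictionProfile] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"start > end ({self.start} > {self.end}) for {self.variant_id}"
            )
        if self.maf_1000g is not None and not 0.0 <= self.maf_1000g <= 1.0:
            raise InputError(
                f"MAF must lie in [0, 1], got {self.maf_1000g} for {self.variant_id}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.sample_id}:{self.gene}:{self.cdna_hgvs}"


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    inheritance: Inheritance
    category: GeneCategory


@dataclass(frozen=True)
class CurationEntry:
    """One manually curated variant: a locus-specific database hit or a
    published report supporting pathogenicity."""

    gene: str
    cdna_hgvs: str
    evidence: Evidence
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.evidence is Evidence.NONE and self.source_label:
            raise InputError(
                f"curation entry {self.gene} {self.cdna_hgvs}: evidence 'none' "
                "cannot carry a source label"
            )


@dataclass(frozen=True)
class IhcPair:
    """Paired normal/tumor immunohistochemistry staining scores (0..3+)."""

    normal_score: int
    tumor_score: int
    change: str  # marked_loss | reduced | stable | increased


@dataclass
class SyndromeFlags:
    """Which NCCN-style hereditary-cancer-syndrome criteria a family meets."""

    hbocs: bool = False
    lfs: bool = False
    ls: bool = False
    source: str = "input_flag"
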