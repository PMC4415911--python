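"""Parsing of cDNA/protein HGVS descriptions and consequence classification.

The pipeline never consults a reference sequence: everything it needs is
carried by the variant nomenclature itself, as emitted by the annotation
step upstream.  The parser therefore covers the HGVS dialect found in
annotated panel tables — substitutions, deletions, duplications,
insertions, deletion-insertions, and intronic offsets — not the full HGVS
grammar.

Classification priority
-----------------------
1.  A protein-level frameshift annotation (``fs``) wins outright, even when
    the cDNA change touches a splice site (e.g. a deletion spanning an
    acceptor that is annotated ``p.A1823Gfs*9`` is a frameshift, not a
    splice variant).
2.  Otherwise a change whose nearest position lies within the splice window
    of an exon/intron boundary is ``splicing``.
3.  Otherwise indels: frame-disrupting length (not a multiple of 3) means
    ``frameshift_indel``.  A single-base deletion or duplication whose first
    shifted codon happens to be a stop is annotated by HGVS as a bare
    ``p.X#*``; mechanistically it is still a frameshift and is classified as
    such.  A duplication whose protein annotation is a plain residue
    insertion (rather than a clean ``dup``) is treated as frame-disrupting,
    mirroring the behaviour of coordinate-based annotators on ambiguous
    duplication junctions.  Remaining in-frame indels are
    ``nonframeshift_indel``.
4.  Substitutions: a stop gain is ``nonsense``, an amino-acid exchange is
    ``missense``, an unchanged protein is ``synonymous``.
5.  Anything else falls through to ``other``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

from .errors import ParseError

__all__ = [
    "CdnaKind",
    "ProteinKind",
    "ConsequenceClass",
    "HgvsChange",
    "parse_hgvs",
    "classify_consequence",
]


class CdnaKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class ProteinKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    STOP_GAIN = "stop_gain"  # bare p.X#* at the changed residue
    FRAMESHIFT = "frameshift"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    SYNONYMOUS = "synonymous"
    UNKNOWN = "unknown"  # p.? or absent


class ConsequenceClass(str, enum.Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes the candidate filter accepts and the pathogenicity stage treats
#: as protein-truncating (missense is filter-accepted but handled by the
#: in-silico rule instead).
TRUNCATING_CLASSES = frozenset(
    {
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.NONFRAMESHIFT_INDEL,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.SPLICING,
    }
)


@dataclass(frozen=True)
class HgvsChange:
    """A parsed cDNA + protein HGVS pair."""

    raw_cdna: str
    raw_protein: str
    cdna_kind: CdnaKind
    protein_kind: ProteinKind
    intron_offset: Optional[int] = None
    indel_length: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    @property
    def protein_terminates(self) -> bool:
        """True when the protein change is a bare stop at the changed residue."""
        return self.protein_kind is ProteinKind.STOP_GAIN

    @property
    def frameshift_tagged(self) -> bool:
        return self.protein_kind is ProteinKind.FRAMESHIFT

    @property
    def is_indel(self) -> bool:
        return self.cdna_kind is not CdnaKind.SUBSTITUTION


# -- cDNA position grammar ---------------------------------------------------
# An exonic coordinate with an optional intronic offset: 850-2, 194+2, 5468-1
_POS = r"(?:[-*]?\d+)(?:[+-]\d+)?"
_POS_RE = re.compile(r"^([-*]?\d+)([+-]\d+)?$")

_SUB_RE = re.compile(rf"^c\.({_POS})([ACGTN])>([ACGTN])$")
_RANGE = rf"({_POS})(?:_({_POS}))?"
_DEL_RE = re.compile(rf"^c\.{_RANGE}del([ACGTN]+|\d+)?$")
_DUP_RE = re.compile(rf"^c\.{_RANGE}dup([ACGTN]+|\d+)?$")
_INS_RE = re.compile(rf"^c\.{_RANGE}ins([ACGTN]+|\d+)$")
_DELINS_RE = re.compile(rf"^c\.{_RANGE}delins([ACGTN]+|\d+)$")

_AA = r"(?:[A-Z])"
_P_FS_RE = re.compile(rf"^p\.{_AA}\d+{_AA}?fs(?:\*\d+|\*\?)?$")
_P_STOP_RE = re.compile(rf"^p\.({_AA})(\d+)\*$")
_P_SUB_RE = re.compile(rf"^p\.({_AA})(\d+)({_AA})$")
_P_DEL_RE = re.compile(rf"^p\.{_AA}\d+(?:_{_AA}\d+)?del$")
_P_DUP_RE = re.compile(rf"^p\.{_AA}\d+(?:_{_AA}\d+)?dup$")
_P_INS_RE = re.compile(rf"^p\.{_AA}\d+_{_AA}\d+ins{_AA}+$")


def _parse_pos(token: str) -> tuple[int, Optional[int]]:
    """Split '850-2' into (850, -2); plain '850' gives (850, None)."""
    m = _POS_RE.match(token)
    if m is None:
        raise ParseError(f"unsupported cDNA position {token!r}")
    base = int(m.group(1).lstrip("*"))
    offset = int(m.group(2)) if m.group(2) else None
    return base, offset


def _span_length(start: str, end: Optional[str], suffix: Optional[str]) -> int:
    """Length of the affected reference span of a del/dup range.

    The explicit base string or count after the keyword is authoritative
    (it is the only unambiguous source when an endpoint is intronic, e.g.
    ``c.5468-1_5474del8``); otherwise the length is the coordinate span.
    """
    if suffix:
        if suffix.isdigit():
            return int(suffix)
        return len(suffix)
    s_base, s_off = _parse_pos(start)
    if end is None:
        return 1
    e_base, e_off = _parse_pos(end)
    if s_off is None and e_off is None:
        return e_base - s_base + 1
    raise ParseError(
        f"cannot derive span length across an intronic boundary "
        f"({start}_{end}) without an explicit base count"
    )


def _offset_of(start: str, end: Optional[str]) -> Optional[int]:
    """Smallest-magnitude intronic offset among the change's endpoints."""
    offsets = []
    for token in (start, end):
        if token is None:
            continue
        _, off = _parse_pos(token)
        if off is not None:
            offsets.append(off)
    if not offsets:
        return None
    return min(offsets, key=abs)


def _parse_protein(protein: str) -> tuple[ProteinKind, Optional[str], Optional[str]]:
    p = protein.strip()
    if p in ("", "p.?", "?", "-", "."):
        return ProteinKind.UNKNOWN, None, None
    if p in ("p.=", "p.(=)"):
        return ProteinKind.SYNONYMOUS, None, None
    if _P_FS_RE.match(p):
        return ProteinKind.FRAMESHIFT, None, None
    m = _P_STOP_RE.match(p)
    if m:
        return ProteinKind.STOP_GAIN, m.group(1), "*"
    m = _P_SUB_RE.match(p)
    if m:
        ref, alt = m.group(1), m.group(3)
        if ref == alt:
            return ProteinKind.SYNONYMOUS, ref, alt
        return ProteinKind.SUBSTITUTION, ref, alt
    if _P_DEL_RE.match(p):
        return ProteinKind.DELETION, None, None
    if _P_DUP_RE.match(p):
        return ProteinKind.DUPLICATION, None, None
    if _P_INS_RE.match(p):
        return ProteinKind.INSERTION, None, None
    raise ParseError(f"unsupported protein HGVS {p!r}")


def parse_hgvs(cdna: str, protein: str = "") -> HgvsChange:
    """Parse a cDNA/protein HGVS pair into an :class:`HgvsChange`.

    Raises :class:`~hcpanel.errors.ParseError` for forms outside the
    supported dialect, echoing the offending token.
    """
    c = cdna.strip()
    if not c.startswith("c."):
        raise ParseError(f"cDNA description must start with 'c.': {c!r}")
    p_kind, ref_aa, alt_aa = _parse_protein(protein)

    m = _SUB_RE.match(c)
    if m:
        _, offset = _parse_pos(m.group(1))
        if m.group(2) == m.group(3) and p_kind is ProteinKind.UNKNOWN:
            p_kind = ProteinKind.SYNONYMOUS
        return HgvsChange(c, protein, CdnaKind.SUBSTITUTION, p_kind,
                          intron_offset=offset, ref_aa=ref_aa, alt_aa=alt_aa)

    for regex, kind in (
        (_DELINS_RE, CdnaKind.DELINS),  # delins must precede del
        (_DEL_RE, CdnaKind.DELETION),
        (_DUP_RE, CdnaKind.DUPLICATION),
        (_INS_RE, CdnaKind.INSERTION),
    ):
        m = regex.match(c)
        if m is None:
            continue
        start, end, suffix = m.group(1), m.group(2), m.group(3)
        if kind is CdnaKind.INSERTION:
            # inserted bases, not the flanking coordinates, define the length
            length = int(suffix) if suffix.isdigit() else len(suffix)
        elif kind is CdnaKind.DELINS:
            # the replaced reference span governs (net length change is
            # reflected in the protein annotation instead)
            length = _span_length(start, end, None)
        else:
            length = _span_length(start, end, suffix)
        if length <= 0:
            raise ParseError(f"non-positive indel length in {c!r}")
        return HgvsChange(c, protein, kind, p_kind,
                          intron_offset=_offset_of(start, end),
                          indel_length=length, ref_aa=ref_aa, alt_aa=alt_aa)

    raise ParseError(f"unsupported cDNA HGVS {c!r}")


def classify_consequence(change: HgvsChange, splice_window: int = 2) -> ConsequenceClass:
    """Assign exactly one consequence class to a parsed change.

    ``splice_window`` is the maximum |intronic offset| (bases from the
    nearest exon/intron boundary) still counted as a splice-site change; the
    default of 2 covers the canonical donor/acceptor dinucleotides on both
    sides.
    """
    if splice_window < 1:
        raise ValueError("splice_window must be a positive integer")

    if change.frameshift_tagged:
        return ConsequenceClass.FRAMESHIFT_INDEL
    if change.intron_offset is not None and abs(change.intron_offset) <= splice_window:
        return ConsequenceClass.SPLICING

    if change.is_indel:
        assert change.indel_length is not None
        if change.indel_length % 3 != 0:
            return ConsequenceClass.FRAMESHIFT_INDEL
        if (
            change.cdna_kind is CdnaKind.DUPLICATION
            and change.protein_kind is ProteinKind.INSERTION
        ):
            # in-frame-length duplication whose protein annotation is a plain
            # insertion, i.e. the duplicated copy does not read as a tandem
            # peptide duplication: treated as frame-disrupting (see module
            # docstring)
            return ConsequenceClass.FRAMESHIFT_INDEL
        return ConsequenceClass.NONFRAMESHIFT_INDEL

    # substitutions
    if change.protein_kind is ProteinKind.STOP_GAIN:
        return ConsequenceClass.NONSENSE
    if change.protein_kind is ProteinKind.SUBSTITUTION:
        return ConsequenceClass.MISSENSE
    if change.protein_kind is ProteinKind.SYNONYMOUS:
        return ConsequenceClass.SYNONYMOUS
    return ConsequenceClass.OTHER
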