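"""HGVS parsing and consequence classification."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcpanel.errors import ParseError
from hcpanel.hgvs import (
    CdnaKind,
    ConsequenceClass,
    classify_consequence,
    parse_hgvs,
)


@pytest.mark.parametrize(
    "cdna, protein, kind, offset, length, fs, stop",
    [
        ("c.850-2A>G", "p.?", CdnaKind.SUBSTITUTION, -2, None, False, False),
        ("c.194+2T>C", "p.?", CdnaKind.SUBSTITUTION, +2, None, False, False),
        ("c.1189_1191delTAT", "p.I397del", CdnaKind.DELETION, None, 3, False, False),
        ("c.754delC", "p.R252Vfs*46", CdnaKind.DELETION, None, 1, True, False),
        ("c.162_179del18", "p.A57_A62del", CdnaKind.DELETION, None, 18, False, False),
        ("c.5468-1_5474del8", "p.A1823Gfs*9", CdnaKind.DELETION, -1, 8, True, False),
        ("c.8956_8957insAA", "p.I2986Kfs*3", CdnaKind.INSERTION, None, 2, True, False),
        ("c.1050_1051delinsTCT", "p.Q350Hfs*11", CdnaKind.DELINS, None, 2, True, False),
        ("c.320dupA", "p.Y107*", CdnaKind.DUPLICATION, None, 1, False, True),
        ("c.1214C>G", "p.S405*", CdnaKind.SUBSTITUTION, None, None, False, True),
        ("c.7007G>A", "p.R2336H", CdnaKind.SUBSTITUTION, None, None, False, False),
    ],
)
def test_parse_supported_forms(cdna, protein, kind, offset, length, fs, stop):
    change = parse_hgvs(cdna, protein)
    assert change.cdna_kind is kind
    assert change.intron_offset == offset
    assert change.indel_length == length
    assert change.frameshift_tagged is fs
    assert change.protein_terminates is stop


@pytest.mark.parametrize(
    "cdna, protein",
    [
        ("g.12345A>T", "p.?"),            # wrong coordinate system
        ("c.notavariant", "p.?"),
        ("c.100A>T", "p.gibberish!"),
        ("c.100_99del", "p.?"),           # zero/negative span handled upstream
    ],
)
def test_parse_rejects_unsupported_forms(cdna, protein):
    with pytest.raises(ParseError):
        parse_hgvs(cdna, protein)


@pytest.mark.parametrize(
    "cdna, protein, expected",
    [
        ("c.194+2T>C", "p.?", ConsequenceClass.SPLICING),
        ("c.850-2A>G", "p.?", ConsequenceClass.SPLICING),
        ("c.1214C>G", "p.S405*", ConsequenceClass.NONSENSE),
        ("c.7007G>A", "p.R2336H", ConsequenceClass.MISSENSE),
        ("c.100A>G", "p.K34K", ConsequenceClass.SYNONYMOUS),
        ("c.100A>A", "p.=", ConsequenceClass.SYNONYMOUS),
        ("c.1189_1191delTAT", "p.I397del", ConsequenceClass.NONFRAMESHIFT_INDEL),
        ("c.754delC", "p.R252Vfs*46", ConsequenceClass.FRAMESHIFT_INDEL),
        # deletion spanning the splice acceptor but annotated as a protein
        # frameshift: the protein-level evidence wins over the offset
        ("c.5468-1_5474del8", "p.A1823Gfs*9", ConsequenceClass.FRAMESHIFT_INDEL),
        # 1-bp indels whose first shifted codon is a stop are frameshifts,
        # not nonsense (the stop arises from the shifted reading frame)
        ("c.320dupA", "p.Y107*", ConsequenceClass.FRAMESHIFT_INDEL),
        ("c.2305delG", "p.V769*", ConsequenceClass.FRAMESHIFT_INDEL),
        ("c.300-40A>G", "p.?", ConsequenceClass.OTHER),  # deep intronic
    ],
)
def test_classify_consequence(cdna, protein, expected):
    assert classify_consequence(parse_hgvs(cdna, protein)) is expected


def test_splice_window_is_configurable():
    change = parse_hgvs("c.300-4A>G", "p.?")
    assert classify_consequence(change, splice_window=2) is ConsequenceClass.OTHER
    assert classify_consequence(change, splice_window=5) is ConsequenceClass.SPLICING


def test_study_fixture_partition(study_variants):
    """The 42 deleterious study variants partition into 22 frameshift,
    5 in-frame indel, 8 nonsense, 5 missense and 2 splice changes."""
    counts = Counter(
        classify_consequence(parse_hgvs(v.cdna_hgvs, v.protein_hgvs)).value
        for v in study_variants
    )
    assert counts == {
        "frameshift_indel": 22,
        "nonframeshift_indel": 5,
        "nonsense": 8,
        "missense": 5,
        "splicing": 2,
    }


@settings(derandomize=True, max_examples=200)
@given(
    pos=st.integers(min_value=10, max_value=5000),
    length=st.integers(min_value=1, max_value=30),
    dup=st.booleans(),
)
def test_indel_frame_rule_matches_length_oracle(pos, length, dup):
    """For plain indels (no protein annotation), frameshift status is
    exactly 'length not divisible by 3'."""
    keyword = "dup" if dup else "del"
    if length == 1:
        cdna = f"c.{pos}{keyword}A"
    else:
        cdna = f"c.{pos}_{pos + length - 1}{keyword}{'A' * length}"
    cls = classify_consequence(parse_hgvs(cdna, "p.?"))
    if length % 3 != 0:
        assert cls is ConsequenceClass.FRAMESHIFT_INDEL
    else:
        assert cls is ConsequenceClass.NONFRAMESHIFT_INDEL


@settings(derandomize=True, max_examples=100)
@given(st.integers(min_value=10, max_value=5000), st.integers(min_value=1, max_value=2),
       st.booleans())
def test_canonical_offsets_always_splice(pos, offset, donor):
    sign = "+" if donor else "-"
    cls = classify_consequence(parse_hgvs(f"c.{pos}{sign}{offset}A>G", "p.?"))
    assert cls is ConsequenceClass.SPLICING
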