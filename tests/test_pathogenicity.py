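"""Two-feature missense rule and final deleteriousness calls."""

import itertools

import pytest

from hcpanel.errors import InputError
from hcpanel.hgvs import ConsequenceClass
from hcpanel.pathogenicity import Basis, call_pathogenicity, missense_insilico
from hcpanel.types import (
    AnnotatedVariant,
    ConservationCall,
    CurationEntry,
    Evidence,
    Genotype,
    PolyphenCall,
    PredictionProfile,
    RawCallRecord,
    Region,
    SiftCall,
)

D, B = SiftCall.DAMAGING, SiftCall.BENIGN
PD, PB = PolyphenCall.PROBABLY_DAMAGING, PolyphenCall.BENIGN
C, NC = ConservationCall.CONSERVED, ConservationCall.NOT_CONSERVED
CURATED = CurationEntry("G", "c.1A>G", Evidence.DATABASE, "db")


def _variant(cdna="c.523C>G", protein="p.R175G", predictions=None):
    return AnnotatedVariant(
        call=RawCallRecord("17", 7578407, "C", "G", Genotype.HET, 99, 10, 50),
        sample_id="83",
        gene="TP53",
        transcript="NM_000546",
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        region=Region.EXONIC,
        start=7578407,
        end=7578407,
        maf_1000g=0.0,
        predictions=predictions,
    )


@pytest.mark.parametrize(
    "sift, polyphen, phylop, lrt, pred, cons",
    [
        (D, B, C, NC, True, True),     # either tool per feature suffices
        (D, PD, NC, C, True, True),
        (D, PD, C, C, True, True),
        (B, PB, NC, NC, False, False),
        (B, PD, C, NC, True, True),
        (D, B, NC, NC, True, False),   # prediction without conservation
        (B, PB, C, C, False, True),    # conservation without prediction
    ],
)
def test_missense_rule_truth_table(sift, polyphen, phylop, lrt, pred, cons):
    got_pred, got_cons, damaging = missense_insilico(
        PredictionProfile(sift, polyphen, phylop, lrt)
    )
    assert (got_pred, got_cons) == (pred, cons)
    assert damaging is (pred and cons)


def test_missense_rule_requires_one_tool_per_feature():
    with pytest.raises(InputError):
        missense_insilico(PredictionProfile(SiftCall.ABSENT, PolyphenCall.ABSENT, C, C))
    with pytest.raises(InputError):
        missense_insilico(
            PredictionProfile(D, PD, ConservationCall.ABSENT, ConservationCall.ABSENT)
        )
    # absent on one side of a feature is tolerated
    _, _, damaging = missense_insilico(
        PredictionProfile(D, PolyphenCall.ABSENT, C, ConservationCall.ABSENT)
    )
    assert damaging


def test_upgrading_a_tool_call_never_flips_damaging_off():
    """Monotonicity: promoting any single tool from benign/not-conserved to
    damaging/conserved can only keep or gain the damaging call."""
    upgrades = {
        "sift": (B, D),
        "polyphen": (PB, PD),
        "phylop": (NC, C),
        "lrt": (NC, C),
    }
    for base in itertools.product((B, D), (PB, PD), (NC, C), (NC, C)):
        profile = PredictionProfile(*base)
        _, _, before = missense_insilico(profile)
        for field, (lo, hi) in upgrades.items():
            if getattr(profile, field) is lo:
                upgraded = PredictionProfile(
                    **{**{f: getattr(profile, f) for f in upgrades}, field: hi}
                )
                _, _, after = missense_insilico(upgraded)
                assert after or not before


@pytest.mark.parametrize(
    "consequence",
    [
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.NONFRAMESHIFT_INDEL,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.SPLICING,
    ],
)
def test_truncating_classes_are_deleterious_without_predictions(consequence):
    call = call_pathogenicity(_variant(), consequence)
    assert call.deleterious and call.basis is Basis.TRUNCATING_CLASS
    assert call.feature_prediction is None


def test_predictions_are_ignored_for_nonsense():
    """A stop-gain carrying prediction columns is still decided by its
    class, even when a tool says benign."""
    v = _variant(cdna="c.5699C>G", protein="p.S1900*",
                 predictions=PredictionProfile(D, B, C, NC))
    call = call_pathogenicity(v, ConsequenceClass.NONSENSE)
    assert call.basis is Basis.TRUNCATING_CLASS


def test_missense_needs_rule_and_curation():
    damaging = PredictionProfile(D, PD, C, C)
    v = _variant(predictions=damaging)
    call = call_pathogenicity(v, ConsequenceClass.MISSENSE, curation=CURATED)
    assert call.deleterious
    assert call.basis is Basis.MISSENSE_INSILICO_PLUS_CURATION
    assert call.feature_prediction and call.feature_conservation

    call = call_pathogenicity(v, ConsequenceClass.MISSENSE, curation=None)
    assert not call.deleterious and call.reason == "curation"

    benign = PredictionProfile(B, PB, NC, NC)
    call = call_pathogenicity(
        _variant(predictions=benign), ConsequenceClass.MISSENSE, curation=CURATED
    )
    assert not call.deleterious and call.reason == "missense_rule"


def test_missense_without_profile_is_an_error():
    with pytest.raises(InputError):
        call_pathogenicity(_variant(), ConsequenceClass.MISSENSE, curation=CURATED)


def test_fixture_missense_all_pass_with_both_features(
    study_variants, study_curation, merged_panel
):
    """The five study missense variants all carry at least one damaging
    prediction and one conserved call, and all have curation evidence."""
    from hcpanel.hgvs import classify_consequence, parse_hgvs

    n_missense = 0
    for v in study_variants:
        cls = classify_consequence(parse_hgvs(v.cdna_hgvs, v.protein_hgvs))
        if cls is not ConsequenceClass.MISSENSE:
            continue
        n_missense += 1
        entry = study_curation[(v.gene, v.cdna_hgvs)]
        call = call_pathogenicity(v, cls, v.predictions, entry)
        assert call.deleterious
        assert call.feature_prediction and call.feature_conservation
    assert n_missense == 5
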