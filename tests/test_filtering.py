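"""QC filter and the four-criterion candidate cascade."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcpanel.filtering import (
    CRITERION_ORDER,
    FilterState,
    apply_cascade,
    qc_filter,
)
from hcpanel.hgvs import ConsequenceClass, classify_consequence, parse_hgvs
from hcpanel.pipeline import Thresholds, run_variants
from hcpanel.types import (
    AnnotatedVariant,
    CurationEntry,
    Evidence,
    GenePanelEntry,
    GeneCategory,
    Genotype,
    Inheritance,
    PredictionProfile,
    RawCallRecord,
    Region,
    SiftCall,
    ConservationCall,
)


def _record(qual=99.0, nd=10, depth=50, genotype=Genotype.HET):
    return RawCallRecord("1", 1000, "A", "G", genotype, qual, nd, depth)


def _variant(gene="BRCA2", cdna="c.7007G>A", protein="p.R2336H",
             region=Region.EXONIC, maf=0.0, genotype=Genotype.HET,
             predictions=None, sample="S1"):
    return AnnotatedVariant(
        call=_record(genotype=genotype),
        sample_id=sample,
        gene=gene,
        transcript="NM_000059",
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        region=region,
        start=1000,
        end=1000,
        maf_1000g=maf,
        predictions=predictions,
    )


DOMINANT = GenePanelEntry("BRCA2", Inheritance.DOMINANT, GeneCategory.BRCA)
RECESSIVE = GenePanelEntry("MUTYH", Inheritance.RECESSIVE, GeneCategory.OTHER)


@pytest.mark.parametrize(
    "qual, nd, depth, expected",
    [
        (20.0, 5, 4, True),    # all three exactly at threshold
        (19.9, 5, 4, False),
        (20.0, 4, 4, False),
        (20.0, 5, 3, False),
        (60.0, 0, 100, False),  # one criterion alone fails the call
        (100.0, 50, 200, True),
    ],
)
def test_qc_filter_thresholds(qual, nd, depth, expected):
    assert qc_filter(_record(qual, nd, depth)) is expected


def _classified(variant):
    change = parse_hgvs(variant.cdna_hgvs, variant.protein_hgvs)
    return change, classify_consequence(change)


def test_dominant_rare_missense_is_retained():
    v = _variant()
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, DOMINANT, change=change)
    assert trace.final_state is FilterState.RETAINED
    assert trace.exclusion_reason is None


def test_common_variant_excluded_by_frequency():
    v = _variant(maf=0.05)
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, DOMINANT, change=change)
    assert trace.final_state is FilterState.EXCLUDED
    assert trace.exclusion_reason == "frequency"


def test_maf_absent_and_zero_both_pass_frequency():
    for maf in (None, 0.0):
        v = _variant(maf=maf)
        change, cls = _classified(v)
        assert apply_cascade(v, cls, DOMINANT, change=change).criterion_frequency


def test_synonymous_excluded_by_class():
    v = _variant(cdna="c.99A>G", protein="p.K33K")
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, DOMINANT, change=change)
    assert trace.exclusion_reason == "class"


def test_deep_intronic_excluded_by_region():
    v = _variant(cdna="c.90-50_90-48delTTT", protein="p.?", region=Region.INTRONIC)
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, DOMINANT, change=change)
    assert trace.exclusion_reason == "region"


def test_recessive_het_missense_excluded_by_inheritance():
    v = _variant(gene="MUTYH")
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, RECESSIVE, change=change)
    assert trace.exclusion_reason == "inheritance"
    assert not trace.recessive_flagged


def test_recessive_hom_passes_inheritance():
    v = _variant(gene="MUTYH", genotype=Genotype.HOM)
    change, cls = _classified(v)
    assert apply_cascade(v, cls, RECESSIVE, change=change).retained


def test_recessive_compound_het_passes_inheritance():
    v = _variant(gene="MUTYH")
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, RECESSIVE, change=change, same_gene_candidates=2)
    assert trace.retained and not trace.recessive_flagged


def test_recessive_het_strong_candidate_needs_curation():
    """A lone heterozygous splice variant in a recessive gene is retained
    pending curation; matching evidence resolves it to fully retained."""
    v = _variant(gene="MUTYH", cdna="c.850-2A>G", protein="p.?",
                 region=Region.SPLICING, maf=0.002)
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, RECESSIVE, change=change)
    assert trace.final_state is FilterState.RETAINED_NEEDS_CURATION
    assert trace.recessive_flagged

    entry = CurationEntry("MUTYH", "c.850-2A>G", Evidence.LITERATURE, "report")
    trace = apply_cascade(v, cls, RECESSIVE, change=change, curation=entry)
    assert trace.final_state is FilterState.RETAINED


def test_qc_failure_dominates():
    v = _variant()
    change, cls = _classified(v)
    trace = apply_cascade(v, cls, DOMINANT, change=change, qc_pass=False)
    assert trace.exclusion_reason == "qc"


def test_retained_set_is_order_independent():
    """Permuting criterion evaluation order never changes what is retained,
    only which violated criterion is named first."""
    cases = [
        _variant(),
        _variant(maf=0.05),
        _variant(cdna="c.99A>G", protein="p.K33K"),
        _variant(cdna="c.90-50_90-48delTTT", protein="p.?", region=Region.INTRONIC),
        _variant(gene="MUTYH"),
        # violates several criteria at once
        _variant(cdna="c.90-50_90-48delTTT", protein="p.?",
                 region=Region.INTRONIC, maf=0.3),
    ]
    panels = {"BRCA2": DOMINANT, "MUTYH": RECESSIVE}
    baseline = None
    for order in itertools.permutations(CRITERION_ORDER):
        states = []
        for v in cases:
            change, cls = _classified(v)
            trace = apply_cascade(v, cls, panels[v.gene], change=change,
                                  criterion_order=order)
            states.append(trace.retained)
        if baseline is None:
            baseline = states
        assert states == baseline


@settings(derandomize=True, max_examples=60)
@given(
    maf=st.one_of(st.none(), st.floats(min_value=0, max_value=0.5)),
    thresholds=st.tuples(
        st.floats(min_value=0, max_value=0.1), st.floats(min_value=0, max_value=0.1)
    ),
)
def test_lowering_maf_max_never_adds_retained(maf, thresholds):
    lo, hi = min(thresholds), max(thresholds)
    v = _variant(maf=maf)
    change, cls = _classified(v)
    at_lo = apply_cascade(v, cls, DOMINANT, maf_max=lo, change=change).retained
    at_hi = apply_cascade(v, cls, DOMINANT, maf_max=hi, change=change).retained
    assert not (at_lo and not at_hi)  # retained at lo implies retained at hi


def test_fixture_all_retained_and_distractors_all_excluded(
    study_variants, merged_panel, study_curation, distractors
):
    dvars, expected, dcur = distractors
    curation = {**study_curation, **dcur}
    outcomes = run_variants(study_variants + dvars, merged_panel, curation)
    by_id = {o.variant.variant_id: o for o in outcomes}
    # conservation of records: every input appears exactly once
    assert len(outcomes) == len(study_variants) + len(dvars)
    for v in study_variants:
        assert by_id[v.variant_id].deleterious
    want = {
        "region": "filter:region",
        "class": "filter:class",
        "frequency": "filter:frequency",
        "inheritance": "filter:inheritance",
        "missense_rule": "pathogenicity:missense_rule",
        "curation": "pathogenicity:curation",
    }
    for v in dvars:
        outcome = by_id[v.variant_id]
        assert not outcome.deleterious
        assert outcome.exclusion_reason == want[expected[v.variant_id]]
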