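"""Synthetic-cohort generator: determinism, truth-label recovery, marker
rate structure, and on-disk round trip."""

import math

import pytest

from hcpanel import io as hio
from hcpanel.errors import ConfigError
from hcpanel.msi import DEFAULT_PANEL_MEMBERSHIP, MarkerCall, PanelStatus, classify_msi
from hcpanel.pedigree import pedigree_eligible
from hcpanel.pipeline import run_variants
from hcpanel.simulate import (
    SimulationConfig,
    generate,
    generate_marker_profiles,
    make_distractors,
    write_cohort,
)


def _small_config(seed, **overrides):
    defaults = dict(seed=seed, n_families=5, background_variants_per_sample=30)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _recovery(cohort):
    outcomes = run_variants(cohort.variants, cohort.panel, cohort.curation)
    tp = fp = fn = tn = 0
    for o in outcomes:
        if cohort.truth_labels[o.variant.variant_id] == "spiked_pathogenic":
            tp += o.deleterious
            fn += not o.deleterious
        else:
            fp += o.deleterious
            tn += not o.deleterious
    return tp / (tp + fn), tn / (tn + fp), fp


def test_same_seed_reproduces_cohort_field_for_field():
    a, b = generate(_small_config(7)), generate(_small_config(7))
    assert [v.variant_id for v in a.variants] == [v.variant_id for v in b.variants]
    assert all(
        (x.maf_1000g, x.cdna_hgvs, x.call.quality) == (y.maf_1000g, y.cdna_hgvs, y.call.quality)
        for x, y in zip(a.variants, b.variants)
    )
    assert a.truth_labels == b.truth_labels
    for pa, pb in zip(a.marker_profiles, b.marker_profiles):
        assert pa.calls == pb.calls
    c = generate(_small_config(8))
    assert [v.variant_id for v in a.variants] != [v.variant_id for v in c.variants]


def test_pipeline_recovers_spikes_exactly():
    """Under the default construction the filter + pathogenicity chain
    separates spiked pathogenic variants from background perfectly."""
    config = _small_config(3)
    cohort = generate(config)
    n_spiked = sum(
        1 for label in cohort.truth_labels.values() if label == "spiked_pathogenic"
    )
    assert n_spiked == sum(count for *_, count in config.spike_plan)
    sens, spec, _ = _recovery(cohort)
    assert (sens, spec) == (1.0, 1.0)


def test_adversarial_background_degrades_specificity_by_construction():
    cohort = generate(_small_config(3, n_adversarial=4))
    _, _, fp = _recovery(cohort)
    assert fp == 4


def test_synonymous_only_background_retains_nothing():
    config = _small_config(
        5, p_common=0.0, fraction_synonymous=1.0, fraction_deep_intronic=0.0,
        spike_plan=(),
    )
    cohort = generate(config)
    outcomes = run_variants(cohort.variants, cohort.panel, cohort.curation)
    assert not any(o.trace.retained for o in outcomes)


def test_infeasible_recessive_spike_is_a_config_error():
    with pytest.raises(ConfigError, match="recessive"):
        SimulationConfig(seed=1, spike_plan=(("MUTYH", "missense", "het", 1),))
    with pytest.raises(ConfigError, match="fraction|\\[0, 1\\]"):
        SimulationConfig(seed=1, p_common=1.5)


def test_pedigrees_satisfy_enrolment_rules():
    cohort = generate(_small_config(9, n_families=12))
    assert len(cohort.pedigrees) == 12
    assert all(pedigree_eligible(p) for p in cohort.pedigrees)


def test_marker_rates_recovered_within_three_standard_errors():
    config = SimulationConfig(
        seed=21,
        marker_instability_rates={
            "deficient": {"nci_mono": 0.0, "nci_di": 0.25, "extra_di": 0.25,
                          "emast": 0.5},
            "proficient": {"nci_mono": 0.0, "nci_di": 0.0, "extra_di": 0.0,
                           "emast": 0.0},
        },
    )
    profiles, truth = generate_marker_profiles(config, n_deficient=1000, n_proficient=10)
    deficient = [p for p in profiles if truth[p.sample_label] == "deficient"]
    for panel_class, rate in (("nci_di", 0.25), ("emast", 0.5)):
        markers = [m for m, c in DEFAULT_PANEL_MEMBERSHIP.items() if c == panel_class]
        n = len(deficient) * len(markers)
        observed = sum(
            p.calls[m] is MarkerCall.UNSTABLE for p in deficient for m in markers
        ) / n
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < 3 * se
    # all-zero rates give uniformly stable profiles
    proficient = [p for p in profiles if truth[p.sample_label] == "proficient"]
    for p in proficient:
        status = classify_msi(p)
        assert status.nci_plus_d_status is PanelStatus.MSS and not status.emast_positive


def test_deficient_profiles_show_more_instability_than_proficient():
    cohort = generate(_small_config(13, n_families=20))
    rates = {"deficient": [], "proficient": []}
    for profile in cohort.marker_profiles:
        status = classify_msi(profile)
        signal = (status.nci_plus_d_status is not PanelStatus.MSS) or status.emast_positive
        rates[cohort.marker_truth[profile.sample_label]].append(signal)
    assert sum(rates["deficient"]) / len(rates["deficient"]) > sum(
        rates["proficient"]
    ) / len(rates["proficient"])


def test_all_emast_rates_one_gives_emast_positive_everywhere():
    config = SimulationConfig(
        seed=2,
        marker_instability_rates={
            "deficient": {"nci_mono": 0.0, "nci_di": 0.0, "extra_di": 0.0, "emast": 1.0},
            "proficient": {"nci_mono": 0.0, "nci_di": 0.0, "extra_di": 0.0, "emast": 0.0},
        },
    )
    profiles, truth = generate_marker_profiles(config, 20, 1)
    for p in profiles:
        if truth[p.sample_label] == "deficient":
            assert classify_msi(p).emast_positive


def test_cohort_round_trips_through_disk(tmp_path):
    cohort = generate(_small_config(17, n_families=3, background_variants_per_sample=10))
    write_cohort(cohort, tmp_path)
    again = hio.read_variant_table(tmp_path / "variants.tsv")
    assert [v.variant_id for v in again] == [v.variant_id for v in cohort.variants]
    panel = hio.read_gene_panel(tmp_path / "panel.yaml")
    assert panel.keys() == cohort.panel.keys()
    ped = hio.read_pedigree(tmp_path / "SIM001.ped")
    assert ped.proband.id == "P"
    # double write is byte-identical (reproducibility of reports)
    second = tmp_path / "again"
    write_cohort(generate(_small_config(17, n_families=3,
                                        background_variants_per_sample=10)), second)
    assert (tmp_path / "variants.tsv").read_bytes() == (second / "variants.tsv").read_bytes()


def test_distractors_cycle_all_six_modes():
    variants, expected, curation = make_distractors(12, seed=4)
    assert len(variants) == 12
    assert sorted(set(expected.values())) == [
        "class", "curation", "frequency", "inheritance", "missense_rule", "region",
    ]
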