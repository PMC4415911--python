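"""Synthetic cohorts for end-to-end testing of every pipeline stage.

The generator emulates the *input structure* the pipeline assumes — it is
not a population-genetic simulator.  Each synthetic family gets:

* a pedigree satisfying the age-stratified enrolment rules, with a
  configurable number of affected relatives;
* a per-sample annotated variant table made of *background* variants, each
  constructed to violate at least one filter criterion (or to fail the
  missense in-silico rule), and *spiked* pathogenic variants of requested
  consequence classes that satisfy every criterion by construction;
* truth labels per variant id, so filter + pathogenicity recovery can be
  scored exactly.

Marker-panel profiles are drawn separately, conditioned on mismatch-repair
(MMR) status: MMR-deficient samples draw elevated instability at the
dinucleotide and tetranucleotide (EMAST) markers and near-zero instability
at the mononucleotide markers, emulating the instability signature of
MSH3 loss; proficient samples draw near-zero rates everywhere.

Determinism: every family consumes its own pseudo-random stream spawned
from ``(seed, family_index)``, so regenerating a subset of families
reproduces them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .hgvs import ConsequenceClass
from .msi import ALL_MARKERS, DEFAULT_PANEL_MEMBERSHIP, MarkerCall, MarkerPanelProfile
from .pedigree import CarrierStatus, Individual, Lineage, Pedigree
from .types import (
    AnnotatedVariant,
    ConservationCall,
    CurationEntry,
    Evidence,
    GeneCategory,
    GenePanelEntry,
    Genotype,
    Inheritance,
    PolyphenCall,
    PredictionProfile,
    RawCallRecord,
    Region,
    SiftCall,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate",
    "generate_marker_profiles",
    "make_distractors",
    "simulated_panel",
    "write_cohort",
]

#: Genes available to the simulator, beyond the study panel: plausible
#: hereditary-cancer panel members with dominant inheritance, plus three
#: recessive genes for inheritance-criterion tests.
SIM_DOMINANT_GENES = (
    "BRCA1", "BRCA2", "TP53", "PALB2", "ATM", "CHEK2", "BARD1", "BRIP1",
    "RAD51C", "MSH3", "MLH1", "CDH1", "STK11", "PTEN", "NBN",
)
SIM_RECESSIVE_GENES = ("MUTYH", "WRN", "CYP17A1")

_CATEGORY = {
    "BRCA1": GeneCategory.BRCA, "BRCA2": GeneCategory.BRCA,
    "TP53": GeneCategory.TP53, "MLH1": GeneCategory.MMR,
    "MSH3": GeneCategory.MMR, "CDH1": GeneCategory.CDH1,
    "PALB2": GeneCategory.FA, "RAD51C": GeneCategory.FA,
}

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"

DEFAULT_SPIKE_PLAN: Tuple[Tuple[str, str, str, int], ...] = (
    ("BRCA1", "frameshift_indel", "het", 3),
    ("BRCA2", "nonsense", "het", 3),
    ("TP53", "missense", "het", 2),
    ("MSH3", "nonframeshift_indel", "het", 2),
    ("PALB2", "splicing", "het", 2),
    ("MUTYH", "splicing", "het", 1),
)

DEFAULT_MARKER_RATES: Mapping[str, Mapping[str, float]] = {
    "deficient": {"nci_mono": 0.01, "nci_di": 0.15, "extra_di": 0.25, "emast": 0.5},
    "proficient": {"nci_mono": 0.005, "nci_di": 0.01, "extra_di": 0.01, "emast": 0.02},
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_families: int = 10
    background_variants_per_sample: int = 50
    # background MAF mixture: mass p_common drawn uniform(0.01, 0.5]
    # (criterion-iii violators), the rest uniform[0, 0.01]
    p_common: float = 0.7
    fraction_synonymous: float = 0.4
    fraction_deep_intronic: float = 0.3
    spike_plan: Tuple[Tuple[str, str, str, int], ...] = DEFAULT_SPIKE_PLAN
    relatives_affected_range: Tuple[int, int] = (1, 4)
    n_adversarial: int = 0  # curated damaging background missense (known FPs)
    marker_instability_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MARKER_RATES
    )

    def __post_init__(self) -> None:
        for name in ("p_common", "fraction_synonymous", "fraction_deep_intronic"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.fraction_synonymous + self.fraction_deep_intronic > 1.0:
            raise ConfigError("rare-background fractions must sum to <= 1")
        if self.n_families < 0 or self.background_variants_per_sample < 0:
            raise ConfigError("counts must be non-negative")
        for gene, cls, zygosity, count in self.spike_plan:
            if count < 0:
                raise ConfigError(f"negative spike count for {gene}")
            ConsequenceClass(cls)
            if gene in SIM_RECESSIVE_GENES and zygosity == "het" and cls not in (
                "nonsense", "splicing", "frameshift_indel"
            ):
                raise ConfigError(
                    f"infeasible spike: heterozygous {cls} in recessive gene "
                    f"{gene} can never satisfy the inheritance criterion"
                )
            if gene not in SIM_DOMINANT_GENES + SIM_RECESSIVE_GENES:
                raise ConfigError(f"unknown simulated gene {gene}")


@dataclass
class SyntheticCohort:
    pedigrees: List[Pedigree]
    variants: List[AnnotatedVariant]
    truth_labels: Dict[str, str]  # variant_id -> spiked_pathogenic | background
    curation: Dict[tuple, CurationEntry]
    panel: Dict[str, GenePanelEntry]
    marker_profiles: List[MarkerPanelProfile] = field(default_factory=list)
    marker_truth: Dict[str, str] = field(default_factory=dict)


def simulated_panel() -> Dict[str, GenePanelEntry]:
    panel = {}
    for gene in SIM_DOMINANT_GENES:
        panel[gene] = GenePanelEntry(
            gene, Inheritance.DOMINANT, _CATEGORY.get(gene, GeneCategory.OTHER)
        )
    for gene in SIM_RECESSIVE_GENES:
        panel[gene] = GenePanelEntry(gene, Inheritance.RECESSIVE, GeneCategory.OTHER)
    return panel


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, family_index)))


def _codon_pos(rng) -> int:
    # exonic cDNA position, kept on a codon-friendly scale
    return int(rng.integers(3, 3000))


def _damaging_profile() -> PredictionProfile:
    return PredictionProfile(
        sift=SiftCall.DAMAGING,
        polyphen=PolyphenCall.PROBABLY_DAMAGING,
        phylop=ConservationCall.CONSERVED,
        lrt=ConservationCall.CONSERVED,
    )


def _benign_profile() -> PredictionProfile:
    return PredictionProfile(
        sift=SiftCall.BENIGN,
        polyphen=PolyphenCall.BENIGN,
        phylop=ConservationCall.NOT_CONSERVED,
        lrt=ConservationCall.NOT_CONSERVED,
    )


def _base_call(rng, chrom: str, pos: int, genotype=Genotype.HET,
               ref: str = "A", alt: str = "G") -> RawCallRecord:
    return RawCallRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        genotype=genotype,
        quality=float(rng.integers(40, 100)),
        neighbor_distance=int(rng.integers(6, 30)),
        depth=int(rng.integers(10, 120)),
    )


def _hgvs_for_class(rng, cls: ConsequenceClass) -> Tuple[str, str, Region]:
    """Grammatical HGVS templates per consequence class; coordinates are
    arbitrary but internally consistent."""
    pos = _codon_pos(rng)
    codon = pos // 3 + 1
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    aa_ref, aa_alt = rng.choice(list(_AA), size=2, replace=False)
    if cls is ConsequenceClass.MISSENSE:
        return f"c.{pos}{ref}>{alt}", f"p.{aa_ref}{codon}{aa_alt}", Region.EXONIC
    if cls is ConsequenceClass.NONSENSE:
        return f"c.{pos}{ref}>{alt}", f"p.{aa_ref}{codon}*", Region.EXONIC
    if cls is ConsequenceClass.SYNONYMOUS:
        return f"c.{pos}{ref}>{alt}", f"p.{aa_ref}{codon}{aa_ref}", Region.EXONIC
    if cls is ConsequenceClass.SPLICING:
        offset = int(rng.integers(1, 3))  # within the canonical +-2 window
        sign = "+" if rng.random() < 0.5 else "-"
        return f"c.{pos}{sign}{offset}{ref}>{alt}", "p.?", Region.SPLICING
    if cls is ConsequenceClass.FRAMESHIFT_INDEL:
        length = int(rng.choice([1, 2, 4, 5]))
        if length == 1:
            bases = "".join(rng.choice(list(_BASES), size=1))
            cdna = f"c.{pos}del{bases}"
        else:
            bases = "".join(rng.choice(list(_BASES), size=length))
            cdna = f"c.{pos}_{pos + length - 1}del{bases}"
        stop = int(rng.integers(2, 60))
        return cdna, f"p.{aa_ref}{codon}{aa_alt}fs*{stop}", Region.EXONIC
    if cls is ConsequenceClass.NONFRAMESHIFT_INDEL:
        length = int(rng.choice([3, 6, 9]))
        bases = "".join(rng.choice(list(_BASES), size=length))
        cdna = f"c.{pos}_{pos + length - 1}del{bases}"
        end_codon = codon + length // 3 - 1
        if length == 3:
            protein = f"p.{aa_ref}{codon}del"
        else:
            protein = f"p.{aa_ref}{codon}_{aa_alt}{end_codon}del"
        return cdna, protein, Region.EXONIC
    raise ConfigError(f"no HGVS template for class {cls}")


def _spike_variant(rng, sample_id: str, gene: str, cls: ConsequenceClass,
                   zygosity: str, index: int) -> AnnotatedVariant:
    cdna, protein, region = _hgvs_for_class(rng, cls)
    pos = 1_000_000 + index * 1000 + int(rng.integers(0, 999))
    genotype = Genotype.HOM if zygosity == "hom" else Genotype.HET
    call = _base_call(rng, chrom="1", pos=pos, genotype=genotype)
    return AnnotatedVariant(
        call=call,
        sample_id=sample_id,
        gene=gene,
        transcript=f"NM_9{index:05d}",
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        region=region,
        start=pos,
        end=pos + ((len(cdna) % 3)),
        maf_1000g=None if rng.random() < 0.5 else 0.0,
        predictions=_damaging_profile() if cls is ConsequenceClass.MISSENSE else None,
    )


def _background_variant(rng, config: SimulationConfig, sample_id: str,
                        index: int, adversarial: bool = False) -> Tuple[AnnotatedVariant, str]:
    """One background variant; returns (variant, violation tag)."""
    gene = str(rng.choice(SIM_DOMINANT_GENES))
    pos = 2_000_000 + index * 1000 + int(rng.integers(0, 999))

    if adversarial:
        cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
        maf: Optional[float] = None
        profile = _damaging_profile()
        tag = "adversarial_curated_missense"
    elif rng.random() < config.p_common:
        cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
        maf = float(rng.uniform(0.0100001, 0.5))
        profile = _damaging_profile() if rng.random() < 0.3 else _benign_profile()
        tag = "common"
    else:
        maf = float(rng.uniform(0.0, 0.01))
        mode = rng.random()
        if mode < config.fraction_synonymous:
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.SYNONYMOUS)
            profile = None
            tag = "synonymous"
        elif mode < config.fraction_synonymous + config.fraction_deep_intronic:
            base = _codon_pos(rng)
            offset = int(rng.integers(10, 80))
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            cdna, protein, region = (
                f"c.{base}-{offset}{ref}>{alt}", "p.?", Region.INTRONIC,
            )
            profile = None
            tag = "deep_intronic"
        else:
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
            profile = _benign_profile()
            tag = "benign_missense"

    call = _base_call(rng, chrom="2", pos=pos)
    return (
        AnnotatedVariant(
            call=call,
            sample_id=sample_id,
            gene=gene,
            transcript=f"NM_8{index:05d}",
            cdna_hgvs=cdna,
            protein_hgvs=protein,
            region=region,
            start=pos,
            end=pos,
            maf_1000g=maf,
            predictions=profile,
        ),
        tag,
    )


_CANCERS = ("breast", "ovary", "colon", "stomach", "lung", "lymphoma")


def _simulate_pedigree(rng, family_id: str) -> Pedigree:
    """A three-generation family satisfying one of the enrolment rules,
    with margin (the affected-relative count exceeds the bound by one
    where the structure allows it)."""
    scenario = int(rng.integers(0, 3))
    if scenario == 0:
        proband_age, n_affected = int(rng.integers(25, 36)), int(rng.integers(1, 4))
    elif scenario == 1:
        proband_age, n_affected = int(rng.integers(36, 51)), int(rng.integers(2, 5))
    else:
        proband_age, n_affected = int(rng.integers(51, 66)), int(rng.integers(3, 5))

    members = [
        Individual(id="GF", family_id=family_id, sex="male"),
        Individual(id="GM", family_id=family_id, sex="female"),
        Individual(id="F", family_id=family_id, sex="male"),
        Individual(id="M", family_id=family_id, sex="female",
                   father_id="GF", mother_id="GM"),
    ]
    # maternal aunts/uncles provide the same-lineage affected relatives
    for i in range(max(n_affected, 2)):
        sex = "female" if rng.random() < 0.7 else "male"
        members.append(
            Individual(id=f"R{i + 1}", family_id=family_id, sex=sex,
                       father_id="GF", mother_id="GM")
        )
    proband = Individual(
        id="P", family_id=family_id, sex="female", father_id="F", mother_id="M",
        affected=True, cancer_types=["breast"], ages_dx=[proband_age],
        is_proband=True,
    )
    members.append(proband)

    # mark affected relatives (mother first, then aunts/uncles)
    pool = [m for m in members if m.id not in ("P", "F", "GF")]
    for member in pool[:n_affected]:
        member.affected = True
        member.cancer_types = [str(rng.choice(_CANCERS))]
        member.ages_dx = [int(rng.integers(30, 80))]

    return Pedigree(family_id=family_id, members=members, proband_id="P")


def generate(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    panel = simulated_panel()
    pedigrees: List[Pedigree] = []
    variants: List[AnnotatedVariant] = []
    truth: Dict[str, str] = {}
    curation: Dict[tuple, CurationEntry] = {}

    # distribute spikes round-robin over families
    spikes: List[Tuple[str, ConsequenceClass, str]] = []
    for gene, cls, zygosity, count in config.spike_plan:
        spikes.extend([(gene, ConsequenceClass(cls), zygosity)] * count)

    adversarial_left = config.n_adversarial
    for fam_idx in range(config.n_families):
        rng = _family_rng(config.seed, fam_idx)
        family_id = f"SIM{fam_idx + 1:03d}"
        pedigree = _simulate_pedigree(rng, family_id)
        pedigrees.append(pedigree)
        sample_id = f"{family_id}-P"

        for b_idx in range(config.background_variants_per_sample):
            adversarial = adversarial_left > 0 and b_idx == 0
            variant, tag = _background_variant(
                rng, config, sample_id, fam_idx * 10_000 + b_idx, adversarial
            )
            if adversarial:
                adversarial_left -= 1
                curation[(variant.gene, variant.cdna_hgvs)] = CurationEntry(
                    gene=variant.gene, cdna_hgvs=variant.cdna_hgvs,
                    evidence=Evidence.LITERATURE, source_label="synthetic adversarial",
                )
            variants.append(variant)
            truth[variant.variant_id] = "background"

        for s_idx, (gene, cls, zygosity) in enumerate(spikes):
            if s_idx % config.n_families != fam_idx:
                continue
            variant = _spike_variant(rng, sample_id, gene, cls, zygosity,
                                     fam_idx * 100 + s_idx)
            variants.append(variant)
            truth[variant.variant_id] = "spiked_pathogenic"
            needs_curation = cls is ConsequenceClass.MISSENSE or (
                panel[gene].inheritance is Inheritance.RECESSIVE and zygosity == "het"
            )
            if needs_curation:
                curation[(variant.gene, variant.cdna_hgvs)] = CurationEntry(
                    gene=variant.gene, cdna_hgvs=variant.cdna_hgvs,
                    evidence=Evidence.LITERATURE, source_label="synthetic truth",
                )
            # proband carries the spike; tested relatives mostly co-segregate
            key = f"{gene}:{variant.cdna_hgvs}"
            for member in pedigree.members:
                if member.id == "P":
                    member.genotype_for[key] = CarrierStatus.CARRIER
                elif member.affected:
                    member.genotype_for[key] = (
                        CarrierStatus.CARRIER
                        if rng.random() < 0.85
                        else CarrierStatus.NON_CARRIER
                    )

    profiles, marker_truth = generate_marker_profiles(
        config,
        n_deficient=max(1, config.n_families // 2),
        n_proficient=max(1, config.n_families - config.n_families // 2),
    )
    return SyntheticCohort(
        pedigrees=pedigrees,
        variants=variants,
        truth_labels=truth,
        curation=curation,
        panel=panel,
        marker_profiles=profiles,
        marker_truth=marker_truth,
    )


def generate_marker_profiles(
    config: SimulationConfig,
    n_deficient: int,
    n_proficient: int,
) -> Tuple[List[MarkerPanelProfile], Dict[str, str]]:
    """Draw per-marker stability calls conditioned on MMR status."""
    for status, rates in config.marker_instability_rates.items():
        for name, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"marker rate {status}.{name}={rate} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 77_777)))
    profiles: List[MarkerPanelProfile] = []
    truth: Dict[str, str] = {}
    plan = [("deficient", n_deficient), ("proficient", n_proficient)]
    for status, count in plan:
        rates = config.marker_instability_rates[status]
        for i in range(count):
            label = f"{status}-{i + 1}"
            calls = {}
            for marker in ALL_MARKERS:
                rate = rates.get(DEFAULT_PANEL_MEMBERSHIP[marker], 0.0)
                calls[marker] = (
                    MarkerCall.UNSTABLE if rng.random() < rate else MarkerCall.STABLE
                )
            profiles.append(MarkerPanelProfile(sample_label=label, calls=calls))
            truth[label] = status
    return profiles, truth


# -- deterministic distractor suite ------------------------------------------

def make_distractors(n: int = 60, seed: int = 0) -> Tuple[List[AnnotatedVariant], Dict[str, str], Dict[tuple, CurationEntry]]:
    """Variants that each violate exactly one candidate-filter criterion or
    one pathogenicity rule, cycling through the six violation modes:

    ``region`` (deep-intronic in-frame indel), ``class`` (exonic
    synonymous), ``frequency`` (curated damaging missense at MAF > 0.01),
    ``inheritance`` (heterozygous curated damaging missense in a recessive
    gene), ``missense_rule`` (rare curated missense with benign
    predictions) and ``curation`` (rare damaging missense without curation
    evidence).  Returns (variants, expected-reason map, curation entries).
    """
    rng = np.random.default_rng(seed)
    variants: List[AnnotatedVariant] = []
    expected: Dict[str, str] = {}
    curation: Dict[tuple, CurationEntry] = {}
    modes = ("region", "class", "frequency", "inheritance", "missense_rule", "curation")

    for i in range(n):
        mode = modes[i % len(modes)]
        sample_id = f"DIS{i + 1:03d}"
        pos = 3_000_000 + i * 997
        gene = "MUTYH" if mode == "inheritance" else str(
            rng.choice(("ATM", "CHEK2", "BARD1", "BRIP1", "STK11"))
        )
        curated = True
        maf: Optional[float] = float(rng.uniform(0.0, 0.009))
        profile: Optional[PredictionProfile] = _damaging_profile()
        region = Region.EXONIC

        if mode == "region":
            base = _codon_pos(rng)
            offset = int(rng.integers(12, 60))
            cdna = f"c.{base}-{offset}_{base}-{offset - 2}delTTT"
            protein = "p.?"
            region, profile = Region.INTRONIC, None
        elif mode == "class":
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.SYNONYMOUS)
            profile = None
        elif mode == "frequency":
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
            maf = float(rng.uniform(0.02, 0.4))
        elif mode == "inheritance":
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
        elif mode == "missense_rule":
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
            profile = _benign_profile()
        else:  # curation
            cdna, protein, region = _hgvs_for_class(rng, ConsequenceClass.MISSENSE)
            curated = False

        variant = AnnotatedVariant(
            call=_base_call(rng, chrom="3", pos=pos),
            sample_id=sample_id,
            gene=gene,
            transcript=f"NM_7{i:05d}",
            cdna_hgvs=cdna,
            protein_hgvs=protein,
            region=region,
            start=pos,
            end=pos,
            maf_1000g=maf,
            predictions=profile,
        )
        variants.append(variant)
        expected[variant.variant_id] = mode
        if curated and mode != "class" and mode != "region":
            curation[(gene, cdna)] = CurationEntry(
                gene=gene, cdna_hgvs=cdna,
                evidence=Evidence.DATABASE, source_label="synthetic distractor",
            )
    return variants, expected, curation


def distractor_panel() -> Dict[str, GenePanelEntry]:
    """Panel entries covering the distractor genes plus the study panel."""
    panel = simulated_panel()
    for gene in ("ATM", "CHEK2", "BARD1", "BRIP1", "STK11"):
        panel.setdefault(
            gene, GenePanelEntry(gene, Inheritance.DOMINANT, GeneCategory.OTHER)
        )
    return panel


# -- cohort persistence -------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort as the pipeline's on-disk input formats: a merged
    variant TSV, one PED + genotype file per family, a marker CSV, the
    truth labels and the generated curation table."""
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_variant_table(cohort.variants, out / "variants.tsv")

    with open(out / "truth_labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("VariantID\tLabel\n")
        for vid, label in sorted(cohort.truth_labels.items()):
            fh.write(f"{vid}\t{label}\n")

    with open(out / "curation.tsv", "w", encoding="utf-8") as fh:
        fh.write("Gene\tcDNA\tEvidence\tSource\n")
        for (gene, cdna), entry in sorted(cohort.curation.items()):
            fh.write(f"{gene}\t{cdna}\t{entry.evidence.value}\t{entry.source_label}\n")

    with open(out / "panel.yaml", "w", encoding="utf-8") as fh:
        fh.write("genes:\n")
        for gene, entry in sorted(cohort.panel.items()):
            fh.write(
                f"  {gene}: {{inheritance: {entry.inheritance.value}, "
                f"category: {entry.category.value}}}\n"
            )

    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    for pedigree in cohort.pedigrees:
        with open(out / f"{pedigree.family_id}.ped", "w", encoding="utf-8") as fh:
            for m in pedigree.members:
                fh.write(
                    " ".join(
                        [
                            pedigree.family_id,
                            m.id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            "2" if m.affected else "1",
                            ";".join(m.cancer_types) or "0",
                            ",".join(str(a) for a in m.ages_dx) or "0",
                            "1" if m.is_proband else "0",
                        ]
                    )
                    + "\n"
                )
        rows = [
            (pedigree.family_id, m.id, vid, status.value)
            for m in pedigree.members
            for vid, status in sorted(m.genotype_for.items())
        ]
        if rows:
            with open(out / f"{pedigree.family_id}_genotypes.tsv", "w",
                      encoding="utf-8") as fh:
                fh.write("Family\tIndividual\tVariant\tStatus\n")
                for row in rows:
                    fh.write("\t".join(row) + "\n")

    if cohort.marker_profiles:
        with open(out / "markers.csv", "w", encoding="utf-8") as fh:
            fh.write("Family,Patient,Site," + ",".join(ALL_MARKERS) + "\n")
            symbol = {MarkerCall.UNSTABLE: "+", MarkerCall.STABLE: "-",
                      MarkerCall.FAILED: "x"}
            for profile in cohort.marker_profiles:
                calls = ",".join(symbol[profile.calls[m]] for m in ALL_MARKERS)
                fh.write(f"{profile.sample_label},tumor,na,{calls}\n")
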