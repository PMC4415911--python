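"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Variant table: UTF-8 TSV with columns ``Sample Gene Transcript cDNA
  Protein Chrom Start End Region MAF_1000G SIFT PolyPhen2 PhyloP LRT
  Genotype Qual NeighborDist Depth``.  Coordinates are 1-based inclusive.
  An empty / "." / "-" MAF field is *absent* (not zero).  Prediction calls
  use the annotation shorthand D / B / PD / PoD / C / NC, "-" for no call.
* Minimal VCF reader (``dialect="vcf_lite"``): CHROM/POS/REF/ALT/QUAL plus
  INFO keys carrying the same annotations.
* Pedigree: PED-style whitespace-separated columns ``Family Individual
  Father Mother Sex Phenotype CancerTypes AgeDx Proband [Lineage]`` with
  "0" for missing; cancer types ";"-separated, diagnosis ages ","-separated.
* Marker calls: CSV, one row per sample x tissue, one column per marker,
  "+" unstable / "-" stable / "x" failed, optional ``IHC_Normal``/
  ``IHC_Tumor`` columns with 0..3+ staining scores.
* Gene panel: YAML mapping gene -> inheritance + category.
* Curation evidence: TSV ``Gene cDNA Evidence Source``.
* Syndrome flags: TSV ``Family HBOCS LFS LS`` with 0/1 values.
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import pandas as pd
import yaml

from .errors import FormatError, StructuralError
from .hgvs import CdnaKind, parse_hgvs
from .msi import MarkerCall, MarkerPanelProfile, ALL_MARKERS
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
    SyndromeFlags,
)

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "Sample", "Gene", "Transcript", "cDNA", "Protein", "Chrom", "Start",
    "End", "Region", "MAF_1000G", "SIFT", "PolyPhen2", "PhyloP", "LRT",
    "Genotype", "Qual", "NeighborDist", "Depth",
]

_SIFT_IN = {"D": SiftCall.DAMAGING, "B": SiftCall.BENIGN}
_POLYPHEN_IN = {
    "PD": PolyphenCall.PROBABLY_DAMAGING,
    "PoD": PolyphenCall.POSSIBLY_DAMAGING,
    "D": PolyphenCall.DAMAGING,
    "B": PolyphenCall.BENIGN,
}
_CONS_IN = {"C": ConservationCall.CONSERVED, "NC": ConservationCall.NOT_CONSERVED}
_SIFT_OUT = {v: k for k, v in _SIFT_IN.items()}
_POLYPHEN_OUT = {v: k for k, v in _POLYPHEN_IN.items()}
_CONS_OUT = {v: k for k, v in _CONS_IN.items()}
_MISSING = {"", "-", ".", "—", "nan", "None"}


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    text = str(value).strip()
    # table exports sometimes bold empty cells as "**-**"
    while text.startswith("**") and text.endswith("**") and len(text) > 4:
        text = text[2:-2]
    return text


def _parse_maf(raw, line_no: int) -> Optional[float]:
    text = _clean(raw)
    if text in _MISSING:
        return None
    try:
        value = float(text)
    except ValueError:
        raise FormatError(f"line {line_no}: unparseable MAF field {raw!r}") from None
    return value


def _parse_predictions(row, line_no: int) -> Optional[PredictionProfile]:
    sift = _clean(row.get("SIFT"))
    poly = _clean(row.get("PolyPhen2"))
    phylop = _clean(row.get("PhyloP"))
    lrt = _clean(row.get("LRT"))
    if all(v in _MISSING for v in (sift, poly, phylop, lrt)):
        return None
    try:
        return PredictionProfile(
            sift=_SIFT_IN.get(sift, SiftCall.ABSENT) if sift not in _MISSING else SiftCall.ABSENT,
            polyphen=_POLYPHEN_IN.get(poly, PolyphenCall.ABSENT) if poly not in _MISSING else PolyphenCall.ABSENT,
            phylop=_CONS_IN.get(phylop, ConservationCall.ABSENT) if phylop not in _MISSING else ConservationCall.ABSENT,
            lrt=_CONS_IN.get(lrt, ConservationCall.ABSENT) if lrt not in _MISSING else ConservationCall.ABSENT,
        )
    except KeyError as exc:  # pragma: no cover - mapping .get never raises
        raise FormatError(f"line {line_no}: bad prediction call {exc}") from None


def _alleles_from_cdna(cdna: str, protein: str) -> tuple:
    """Placeholder ref/alt alleles derived from the cDNA description (the
    table dialect does not carry explicit allele columns)."""
    try:
        change = parse_hgvs(cdna, protein)
    except Exception:
        return "N", "V"
    if change.cdna_kind is CdnaKind.SUBSTITUTION:
        ref, alt = change.raw_cdna[-3], change.raw_cdna[-1]
        return ref, alt
    length = change.indel_length or 1
    if change.cdna_kind is CdnaKind.DELETION:
        return "N" * length, "-"
    if change.cdna_kind is CdnaKind.DELINS:
        return "N" * length, "I" * length
    return "-", "N" * length  # dup / ins


def read_variant_table(path: PathLike, dialect: str = "tsv") -> List[AnnotatedVariant]:
    """Read an annotated variant table; rows are returned in file order."""
    if dialect == "vcf_lite":
        return _read_vcf_lite(path)
    if dialect != "tsv":
        raise FormatError(f"unknown variant-table dialect {dialect!r}")

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: variant table is missing required column(s) {missing}"
        )
    variants: List[AnnotatedVariant] = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            ref, alt = _alleles_from_cdna(row["cDNA"], row["Protein"])
            call = RawCallRecord(
                chrom=_clean(row["Chrom"]),
                pos=int(row["Start"]),
                ref_allele=ref,
                alt_allele=alt,
                genotype=Genotype(_clean(row["Genotype"]).lower() or "unknown"),
                quality=float(row["Qual"]),
                neighbor_distance=int(row["NeighborDist"]),
                depth=int(row["Depth"]),
            )
            variants.append(
                AnnotatedVariant(
                    call=call,
                    sample_id=_clean(row["Sample"]),
                    gene=_clean(row["Gene"]),
                    transcript=_clean(row["Transcript"]),
                    cdna_hgvs=_clean(row["cDNA"]),
                    protein_hgvs=_clean(row["Protein"]),
                    region=Region(_clean(row["Region"]).lower()),
                    start=int(row["Start"]),
                    end=int(row["End"]),
                    maf_1000g=_parse_maf(row["MAF_1000G"], line_no),
                    predictions=_parse_predictions(row, line_no),
                )
            )
        except FormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return variants


def write_variant_table(variants: List[AnnotatedVariant], path: PathLike) -> None:
    rows = []
    for v in variants:
        p = v.predictions
        rows.append(
            {
                "Sample": v.sample_id,
                "Gene": v.gene,
                "Transcript": v.transcript,
                "cDNA": v.cdna_hgvs,
                "Protein": v.protein_hgvs,
                "Chrom": v.call.chrom,
                "Start": v.start,
                "End": v.end,
                "Region": v.region.value,
                "MAF_1000G": "-" if v.maf_1000g is None else repr(v.maf_1000g),
                "SIFT": _SIFT_OUT.get(p.sift, "-") if p else "-",
                "PolyPhen2": _POLYPHEN_OUT.get(p.polyphen, "-") if p else "-",
                "PhyloP": _CONS_OUT.get(p.phylop, "-") if p else "-",
                "LRT": _CONS_OUT.get(p.lrt, "-") if p else "-",
                "Genotype": v.call.genotype.value,
                "Qual": v.call.quality,
                "NeighborDist": v.call.neighbor_distance,
                "Depth": v.call.depth,
            }
        )
    frame = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def _read_vcf_lite(path: PathLike) -> List[AnnotatedVariant]:
    """Minimal VCF ingestion via cyvcf2; INFO keys carry the annotations.

    VCF positions for indels include the anchor base; the annotation INFO
    keys START/END carry the 1-based inclusive affected span used by the
    table dialect.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - present in this stack
        raise FormatError("vcf_lite dialect requires cyvcf2") from exc

    variants: List[AnnotatedVariant] = []
    for record in VCF(str(path)):
        info = dict(record.INFO)
        get = lambda key, default="": str(info.get(key, default))
        maf_raw = info.get("MAF1KG")
        row = {
            "SIFT": get("SIFT", "-"),
            "PolyPhen2": get("POLYPHEN", "-"),
            "PhyloP": get("PHYLOP", "-"),
            "LRT": get("LRT", "-"),
        }
        call = RawCallRecord(
            chrom=record.CHROM,
            pos=record.POS,
            ref_allele=record.REF,
            alt_allele=record.ALT[0] if record.ALT else "N",
            genotype=Genotype(get("GT", "unknown")),
            quality=record.QUAL or 0.0,
            neighbor_distance=int(info.get("NEIGHBOR", 0)),
            depth=int(info.get("DP", 0)),
        )
        variants.append(
            AnnotatedVariant(
                call=call,
                sample_id=get("SAMPLE"),
                gene=get("GENE"),
                transcript=get("TRANSCRIPT"),
                cdna_hgvs=get("CDNA"),
                protein_hgvs=get("PROTEIN"),
                region=Region(get("REGION", "other")),
                start=int(info.get("START", record.POS)),
                end=int(info.get("END", record.POS)),
                maf_1000g=None if maf_raw is None else float(maf_raw),
                predictions=_parse_predictions(row, 0),
            )
        )
    return variants


# -- gene panel ---------------------------------------------------------------

def read_gene_panel(path: PathLike) -> Dict[str, GenePanelEntry]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "genes" not in doc:
        raise FormatError(f"{path}: panel file must contain a 'genes' mapping")
    panel = {}
    for gene, spec in doc["genes"].items():
        try:
            panel[gene] = GenePanelEntry(
                gene=gene,
                inheritance=Inheritance(spec.get("inheritance", "unknown")),
                category=GeneCategory(spec.get("category", "OTHER")),
            )
        except (ValueError, AttributeError) as exc:
            raise FormatError(f"{path}: bad panel entry for {gene}: {exc}") from exc
    return panel


# -- curation evidence --------------------------------------------------------

def read_curation(path: PathLike) -> Dict[tuple, CurationEntry]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Gene", "cDNA", "Evidence"):
        if col not in frame.columns:
            raise FormatError(f"{path}: curation file is missing column {col}")
    entries = {}
    for _, row in frame.iterrows():
        entry = CurationEntry(
            gene=row["Gene"],
            cdna_hgvs=row["cDNA"],
            evidence=Evidence(row["Evidence"]),
            source_label=_clean(row.get("Source", "")),
        )
        entries[(entry.gene, entry.cdna_hgvs)] = entry
    return entries


# -- syndrome flags -----------------------------------------------------------

def read_syndrome_flags(path: PathLike) -> Dict[str, SyndromeFlags]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Family", "HBOCS", "LFS", "LS"):
        if col not in frame.columns:
            raise FormatError(f"{path}: flags file is missing column {col}")
    flags = {}
    for _, row in frame.iterrows():
        flags[row["Family"]] = SyndromeFlags(
            hbocs=row["HBOCS"].strip() == "1",
            lfs=row["LFS"].strip() == "1",
            ls=row["LS"].strip() == "1",
            source="input_flag",
        )
    return flags


# -- marker calls -------------------------------------------------------------

_MARKER_IN = {"+": MarkerCall.UNSTABLE, "-": MarkerCall.STABLE, "x": MarkerCall.FAILED}


def read_marker_calls(path: PathLike) -> List[dict]:
    """Read per-sample marker stability calls (and optional IHC scores).

    Returns a list of dicts with keys ``profile`` (:class:`MarkerPanelProfile`),
    ``family``, ``patient``, ``site`` and, when present, ``ihc_normal`` /
    ``ihc_tumor`` (integers).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    marker_cols = [c for c in frame.columns if c in ALL_MARKERS]
    if not marker_cols:
        raise FormatError(f"{path}: no recognized marker columns found")
    out = []
    for idx, row in frame.iterrows():
        calls = {}
        for marker in marker_cols:
            token = _clean(row[marker])
            if token not in _MARKER_IN:
                raise FormatError(
                    f"{path} line {idx + 2}: bad call {row[marker]!r} for {marker}"
                )
            calls[marker] = _MARKER_IN[token]
        family = _clean(row.get("Family", ""))
        patient = _clean(row.get("Patient", ""))
        site = _clean(row.get("Site", ""))
        record = {
            "family": family,
            "patient": patient,
            "site": site,
            "profile": MarkerPanelProfile(
                sample_label=f"{family}:{patient}:{site}".strip(":"), calls=calls
            ),
        }
        for key, col in (("ihc_normal", "IHC_Normal"), ("ihc_tumor", "IHC_Tumor")):
            raw = _clean(row.get(col, ""))
            if raw:
                record[key] = int(raw.rstrip("+"))
        out.append(record)
    return out


# -- pedigrees ----------------------------------------------------------------

_SEX = {"1": "male", "2": "female", "0": "unknown"}


def read_pedigree(path: PathLike) -> Pedigree:
    """Read one family from a PED-style file (see module docstring)."""
    members: List[Individual] = []
    family_ids = set()
    probands = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw_line in fh:
            line = raw_line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 9:
                raise FormatError(
                    f"{path}: pedigree row needs >= 9 columns, got {len(fields)}: "
                    f"{line!r}"
                )
            (family, ind, father, mother, sex, pheno, cancers, ages, proband
             ) = fields[:9]
            lineage = fields[9] if len(fields) > 9 and fields[9] != "0" else None
            family_ids.add(family)
            affected = pheno == "2"
            member = Individual(
                id=ind,
                family_id=family,
                sex=_SEX.get(sex, "unknown"),
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                affected=affected,
                cancer_types=[] if cancers == "0" else cancers.split(";"),
                ages_dx=[] if ages == "0" else [int(a) for a in ages.split(",")],
                is_proband=proband == "1",
                lineage=Lineage(lineage) if lineage else None,
            )
            if member.is_proband:
                probands.append(member.id)
            members.append(member)
    if not members:
        raise FormatError(f"{path}: empty pedigree file")
    if len(family_ids) > 1:
        raise StructuralError(f"{path}: multiple family ids {sorted(family_ids)}")
    if len(probands) != 1:
        raise StructuralError(
            f"{path}: expected exactly one proband, found {len(probands)}"
        )
    return Pedigree(family_id=family_ids.pop(), members=members, proband_id=probands[0])


def read_genotypes(path: PathLike, pedigree: Pedigree) -> None:
    """Attach carrier statuses from a TSV ``Family Individual Variant Status``
    onto the pedigree members, in place."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Family", "Individual", "Variant", "Status"):
        if col not in frame.columns:
            raise FormatError(f"{path}: genotype file is missing column {col}")
    for _, row in frame.iterrows():
        if row["Family"] != pedigree.family_id:
            continue
        member = pedigree.member(row["Individual"])
        member.genotype_for[row["Variant"]] = CarrierStatus(row["Status"])
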