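"""Loaders for the packaged study fixtures.

The package ships, as plain-text data files, the study's published result
tables re-encoded in the pipeline's input formats:

* ``deleterious_variants.tsv`` — the 42 deleterious germline variants of
  the 34 mutation-carrying probands (HGVS, coordinates, population
  frequency, prediction calls);
* ``gene_panel.yaml`` — inheritance mode and category of the 21 mutated
  genes;
* ``curation.tsv`` — locus-specific database / literature evidence for the
  previously reported variants;
* ``syndrome_flags_synthetic.tsv`` — per-family HBOCS/LFS/LS criteria
  flags.  Carrier families carry their published flags; the remaining
  families are synthetic fill-ins chosen only to reproduce the published
  cohort totals (88 HBOCS, 11 LFS, 15 LS of 99 families);
* ``msh3_markers.csv`` — the 8 paired-tissue marker-panel rows (MSI/EMAST
  calls plus IHC scores) of the MSH3-mutation families;
* ``family22.ped`` / ``family49.ped`` and their genotype tables —
  synthetic pedigree reconstructions consistent with the published
  segregation counts;
* ``proband_ages.tsv`` — age at diagnosis per carrier proband (bilateral
  cases keep both ages).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List

import pandas as pd

from . import io as hio
from .pedigree import Pedigree

N_PROBANDS = 99  # enrolled study cohort size

__all__ = [
    "N_PROBANDS",
    "fixture_path",
    "load_variants",
    "load_panel",
    "load_curation",
    "load_flags",
    "load_marker_records",
    "load_family",
    "load_proband_ages",
]


def fixture_path(name: str) -> Path:
    with resources.as_file(resources.files("hcpanel") / "data" / name) as path:
        return Path(path)


def load_variants():
    return hio.read_variant_table(fixture_path("deleterious_variants.tsv"))


def load_panel():
    return hio.read_gene_panel(fixture_path("gene_panel.yaml"))


def load_curation():
    return hio.read_curation(fixture_path("curation.tsv"))


def load_flags():
    return hio.read_syndrome_flags(fixture_path("syndrome_flags_synthetic.tsv"))


def load_marker_records() -> List[dict]:
    return hio.read_marker_calls(fixture_path("msh3_markers.csv"))


def load_family(family_id: str) -> Pedigree:
    ped = hio.read_pedigree(fixture_path(f"family{family_id}.ped"))
    hio.read_genotypes(fixture_path(f"family{family_id}_genotypes.tsv"), ped)
    return ped


def load_proband_ages() -> Dict[str, List[int]]:
    frame = pd.read_csv(fixture_path("proband_ages.tsv"), sep="\t", dtype=str)
    return {
        row["Sample"]: [int(a) for a in row["AgeDx"].split(",")]
        for _, row in frame.iterrows()
    }
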