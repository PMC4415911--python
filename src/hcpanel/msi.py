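"""Microsatellite-instability (MSI) and EMAST status calling, plus IHC
expression-change scoring.

Marker panels
-------------
* NCI consensus panel: two mononucleotide repeats (BAT25, BAT26) and three
  dinucleotide repeats (D2S123, D5S346, D17S250).
* Two additional dinucleotide markers: D18S64, D18S69 — together with the
  NCI five they form the extended "NCI+D" panel.
* Seven tetranucleotide (EMAST) markers: MYCL1, D20S82, D20S85, L17835,
  D8S321, D9S242, D19S394.

Status rule (per panel, failed markers dropped from both numerator and
denominator): zero unstable markers is MSS; at least one unstable marker
with an unstable fraction below ``low_fraction`` (default 0.30) is MSI-L;
an unstable fraction at or above ``low_fraction`` is MSI-H.  EMAST is
positive when at least one tetranucleotide marker is unstable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Mapping

from .errors import InputError
from .types import IhcPair

__all__ = [
    "NCI_MONO_MARKERS",
    "NCI_DI_MARKERS",
    "EXTRA_DI_MARKERS",
    "EMAST_MARKERS",
    "MarkerCall",
    "MarkerPanelProfile",
    "MsiStatus",
    "classify_msi",
    "score_ihc",
]

NCI_MONO_MARKERS = ("BAT25", "BAT26")
NCI_DI_MARKERS = ("D2S123", "D5S346", "D17S250")
NCI_MARKERS = NCI_MONO_MARKERS + NCI_DI_MARKERS
EXTRA_DI_MARKERS = ("D18S64", "D18S69")
NCI_D_MARKERS = NCI_MARKERS + EXTRA_DI_MARKERS
EMAST_MARKERS = ("MYCL1", "D20S82", "D20S85", "L17835", "D8S321", "D9S242", "D19S394")

ALL_MARKERS = NCI_D_MARKERS + EMAST_MARKERS

DEFAULT_PANEL_MEMBERSHIP: Dict[str, str] = {
    **{m: "nci_mono" for m in NCI_MONO_MARKERS},
    **{m: "nci_di" for m in NCI_DI_MARKERS},
    **{m: "extra_di" for m in EXTRA_DI_MARKERS},
    **{m: "emast" for m in EMAST_MARKERS},
}


class MarkerCall(str, enum.Enum):
    UNSTABLE = "unstable"
    STABLE = "stable"
    FAILED = "failed"


class PanelStatus(str, enum.Enum):
    MSS = "MSS"
    MSI_L = "MSI_L"
    MSI_H = "MSI_H"


@dataclass
class MarkerPanelProfile:
    """Per-marker stability calls for one sample x tissue."""

    sample_label: str
    calls: Dict[str, MarkerCall]
    panel_membership: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_MEMBERSHIP)
    )

    def informative(self, markers) -> list:
        """Markers from the given set that were assayed and did not fail."""
        return [
            m
            for m in markers
            if self.calls.get(m, MarkerCall.FAILED) is not MarkerCall.FAILED
        ]

    def unstable(self, markers) -> list:
        return [m for m in markers if self.calls.get(m) is MarkerCall.UNSTABLE]


@dataclass
class MsiStatus:
    sample_label: str
    nci_status: PanelStatus
    nci_plus_d_status: PanelStatus
    emast_positive: bool
    unstable_fraction_nci: float
    unstable_fraction_nci_d: float


def _panel_status(profile: MarkerPanelProfile, markers, low_fraction: float):
    informative = profile.informative(markers)
    if not informative:
        raise InputError(
            f"{profile.sample_label}: no informative markers left in panel "
            f"{markers}"
        )
    n_unstable = len(profile.unstable(informative))
    fraction = n_unstable / len(informative)
    if n_unstable == 0:
        return PanelStatus.MSS, fraction
    if fraction < low_fraction:
        return PanelStatus.MSI_L, fraction
    return PanelStatus.MSI_H, fraction


def classify_msi(profile: MarkerPanelProfile, low_fraction: float = 0.30) -> MsiStatus:
    """Call MSI status on the NCI panel and the extended NCI+D panel, and
    EMAST positivity on the tetranucleotide panel."""
    if not 0.0 < low_fraction <= 1.0:
        raise InputError(f"low_fraction must lie in (0, 1], got {low_fraction}")
    nci_status, frac_nci = _panel_status(profile, NCI_MARKERS, low_fraction)
    nci_d_status, frac_nci_d = _panel_status(profile, NCI_D_MARKERS, low_fraction)
    emast_informative = profile.informative(EMAST_MARKERS)
    emast_positive = len(profile.unstable(emast_informative)) >= 1
    return MsiStatus(
        sample_label=profile.sample_label,
        nci_status=nci_status,
        nci_plus_d_status=nci_d_status,
        emast_positive=emast_positive,
        unstable_fraction_nci=frac_nci,
        unstable_fraction_nci_d=frac_nci_d,
    )


def score_ihc(normal: int, tumor: int, loss_delta: int = 2) -> IhcPair:
    """Categorize the change between paired normal/tumor staining scores.

    ``marked_loss`` requires a drop of at least ``loss_delta`` intensity
    steps (default 2, e.g. 2+ in normal down to 0 in tumor).
    """
    for score in (normal, tumor):
        if score not in (0, 1, 2, 3):
            raise InputError(f"IHC scores are 0..3, got {score}")
    delta = normal - tumor
    if delta >= loss_delta:
        change = "marked_loss"
    elif delta >= 1:
        change = "reduced"
    elif delta == 0:
        change = "stable"
    else:
        change = "increased"
    return IhcPair(normal_score=normal, tumor_score=tumor, change=change)
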