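"""Consensus clinical-impression adjudication and neoplastic binarization.

Sites with an initial clinical impression of *normal* are categorized
``Normal`` without observer review.  For initially-abnormal sites, three
expert observers each assign a category; the consensus is the category at
least two observers agree on, and sites where all three disagree are
excluded from analysis.  For binary classification, ``Cancer`` and
``HighRisk`` are neoplastic, ``Normal`` and ``LowRisk`` non-neoplastic.

Melanosis — benign dark pigmentation that absorbs both the excitation and
the emitted fluorescence — mimics the fluorescence loss of neoplasia, so
melanosis-flagged sites are excluded before algorithm development by
default.  Oral submucous fibrosis (OSF) preserves fluorescence and is
retained among the non-neoplastic sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple

from .datamodel import ClinicalCategory, SiteRecord, ValidationError


class BinaryLabel(str, Enum):
    NEOPLASTIC = "neoplastic"
    NON_NEOPLASTIC = "non_neoplastic"


class ConsensusStatus(str, Enum):
    ASSIGNED = "assigned"
    EXCLUDED = "excluded"


class Agreement(str, Enum):
    UNANIMOUS = "unanimous"
    TWO_OF_THREE = "two_of_three"
    INITIAL_NORMAL = "initial_normal"


@dataclass(frozen=True)
class ConsensusResult:
    status: ConsensusStatus
    category: Optional[ClinicalCategory] = None
    agreement: Optional[Agreement] = None

    def __post_init__(self) -> None:
        if self.status is ConsensusStatus.EXCLUDED and self.category is not None:
            raise ValidationError("excluded sites carry no consensus category")
        if self.status is ConsensusStatus.ASSIGNED and self.category is None:
            raise ValidationError("assigned sites require a consensus category")
        if (
            self.agreement is Agreement.INITIAL_NORMAL
            and self.category is not ClinicalCategory.NORMAL
        ):
            raise ValidationError("initially-normal sites are categorized Normal")


def adjudicate(record: SiteRecord) -> ConsensusResult:
    """Apply the consensus protocol to one site.

    Initially-normal sites are assigned ``Normal`` without review.  For
    abnormal sites the majority of the three observer impressions is the
    consensus; a three-way disagreement excludes the site.
    """
    if record.initial_impression == "normal":
        return ConsensusResult(
            ConsensusStatus.ASSIGNED, ClinicalCategory.NORMAL, Agreement.INITIAL_NORMAL
        )
    if len(record.observer_impressions) != 3:
        raise ValidationError(
            f"site {record.site_id}: abnormal sites require 3 observer impressions"
        )
    counts = Counter(record.observer_impressions)
    category, top = counts.most_common(1)[0]
    if top == 3:
        return ConsensusResult(ConsensusStatus.ASSIGNED, category, Agreement.UNANIMOUS)
    if top == 2:
        return ConsensusResult(ConsensusStatus.ASSIGNED, category, Agreement.TWO_OF_THREE)
    return ConsensusResult(ConsensusStatus.EXCLUDED)


def binarize(category: ClinicalCategory) -> BinaryLabel:
    """Cancer/HighRisk -> neoplastic; Normal/LowRisk -> non-neoplastic."""
    if category in (ClinicalCategory.CANCER, ClinicalCategory.HIGH_RISK):
        return BinaryLabel.NEOPLASTIC
    return BinaryLabel.NON_NEOPLASTIC


def filter_for_algorithm(
    items: Sequence[Tuple[SiteRecord, ConsensusResult]],
    include_melanosis: bool = False,
) -> List[Tuple[SiteRecord, ConsensusResult]]:
    """Drop consensus-excluded sites and (by default) melanosis sites.

    OSF sites are retained and labelled by their consensus category.
    ``include_melanosis=True`` keeps melanosis sites, which reproduces the
    confounding effect of pigment-induced fluorescence loss.
    """
    kept = []
    for record, consensus in items:
        if consensus.status is ConsensusStatus.EXCLUDED:
            continue
        if record.melanosis_visible and not include_melanosis:
            continue
        kept.append((record, consensus))
    return kept
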