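"""Shared vocabulary: tiers, frameworks, response codes, WHO standards.

All enums are string-valued so that they serialize naturally to the CSV
and YAML interchange formats used throughout the pipeline.
"""

from __future__ import annotations

import enum


class Tier(str, enum.Enum):
    """Facility tier. Scoring is always stratified by tier: hospitals are
    assessed against an expanded item list (comprehensive emergency
    obstetric and newborn care), health centres/clinics against the basic
    list, and scores are comparable only within a tier."""

    HOSPITAL = "hospital"
    HEALTH_CENTRE_CLINIC = "health_centre_clinic"


class ManagingAuthority(str, enum.Enum):
    GOVERNMENT = "government"
    PRIVATE = "private"


class Framework(str, enum.Enum):
    """Item-selection framework behind an index."""

    SARA = "SARA"
    DHS = "DHS"
    WHO_STANDARDS = "WHO_standards"


class WhoStandard(str, enum.Enum):
    """The five WHO quality-of-care standards a WHO-framework item maps to
    (three provision-of-care standards, two cross-cutting)."""

    PROVISION_EVIDENCE_BASED = "provision_evidence_based"
    INFORMATION_SYSTEMS = "information_systems"
    REFERRAL_SYSTEMS = "referral_systems"
    HUMAN_RESOURCES = "human_resources"
    PHYSICAL_RESOURCES = "physical_resources"


class Response(str, enum.Enum):
    """Raw per-item facility response before 0/1 coding."""

    YES = "yes"
    NO = "no"
    DONT_KNOW = "dont_know"
    MISSING = "missing"
    NOT_APPLICABLE = "not_applicable"


class TierApplicability(str, enum.Enum):
    BOTH = "both"
    HOSPITAL_ONLY = "hospital_only"
    HEALTH_CENTRE_ONLY = "health_centre_only"

    def applies_to(self, tier: Tier) -> bool:
        if self is TierApplicability.BOTH:
            return True
        if self is TierApplicability.HOSPITAL_ONLY:
            return tier is Tier.HOSPITAL
        return tier is Tier.HEALTH_CENTRE_CLINIC


class AggregationMethod(str, enum.Enum):
    """The three aggregation rules used to collapse binary items into a
    composite score in [0, 1]."""

    SIMPLE = "simple"
    WEIGHTED = "weighted"
    PCA = "pca"


class MatrixPurpose(str, enum.Enum):
    """Coding purpose for a response matrix.

    ``additive``: not-applicable cells are masked out and the score
    denominator shrinks. ``pca``: not-applicable cells are coded 0 so the
    matrix is dense for correlation-based aggregation.
    """

    ADDITIVE = "additive"
    PCA = "pca"
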