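"""End-to-end glue: score all nine indices for a tier, frame results,
and run the comparison battery. Used by the CLI, the analysis drivers
and the acceptance checks so they all exercise the same code path."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .comparison import ComparisonReport, compare_all
from .core import AggregationMethod, Framework, MatrixPurpose, Tier
from .item_analysis import availability
from .registry import ItemRegistry, load_index_spec
from .scoring import (PcaModel, ReadinessScore, fit_pca, score_domain_weighted,
                      score_pca, score_simple)
from .survey_io import FacilityRecord, ResponseMatrix, code_responses

ALL_FRAMEWORKS = tuple(Framework)
ALL_METHODS = tuple(AggregationMethod)

ScoresByIndex = dict[tuple[Framework, AggregationMethod], list[ReadinessScore]]


def split_by_tier(records: Sequence[FacilityRecord]) -> dict[Tier, list[FacilityRecord]]:
    out: dict[Tier, list[FacilityRecord]] = {}
    for rec in records:
        out.setdefault(rec.tier, []).append(rec)
    return out


def score_tier(records: Sequence[FacilityRecord], registry: ItemRegistry,
               tier: Tier,
               frameworks: Sequence[Framework] = ALL_FRAMEWORKS,
               methods: Sequence[AggregationMethod] = ALL_METHODS,
               ) -> tuple[ScoresByIndex, dict[Framework, ResponseMatrix],
                          dict[Framework, PcaModel]]:
    """Score one tier's records under every requested (framework, method).

    Returns the scores, the additive matrices (for item diagnostics),
    and the fitted PCA models. PCA is fitted per tier, so its scores
    are cohort-relative.
    """
    scores: ScoresByIndex = {}
    additive: dict[Framework, ResponseMatrix] = {}
    models: dict[Framework, PcaModel] = {}
    for fw in frameworks:
        spec = load_index_spec(fw, tier, registry)
        add = code_responses(records, spec, MatrixPurpose.ADDITIVE)
        additive[fw] = add
        for method in methods:
            if method is AggregationMethod.SIMPLE:
                scores[(fw, method)] = score_simple(add, index_name=fw)
            elif method is AggregationMethod.WEIGHTED:
                scores[(fw, method)] = score_domain_weighted(
                    add, spec.domains,
                    excluded_domains=spec.excluded_domains_for_weighting,
                    index_name=fw)
            else:
                pca_matrix = code_responses(records, spec, MatrixPurpose.PCA)
                model = fit_pca(pca_matrix, on_degenerate="drop")
                models[fw] = model
                scores[(fw, method)] = score_pca(pca_matrix, model, index_name=fw)
    return scores, additive, models


def scores_frame(scores: ScoresByIndex, tier: Tier) -> pd.DataFrame:
    """Long-format score table: one row per facility x index x method,
    with one column per domain score where the method produces them."""
    rows = []
    for (fw, method), lst in scores.items():
        for s in lst:
            row = {
                "facility_id": s.facility_id, "tier": tier.value,
                "framework": Framework(fw).value,
                "method": AggregationMethod(method).value,
                "score": s.score, "n_applicable": s.n_applicable,
            }
            if s.domain_scores:
                for dom, val in s.domain_scores.items():
                    row[f"domain:{dom}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


def volumes_of(records: Sequence[FacilityRecord]) -> dict[str, Optional[float]]:
    return {r.facility_id: (None if r.monthly_delivery_volume is None
                            else float(r.monthly_delivery_volume))
            for r in records}


def compare_tier(records: Sequence[FacilityRecord], registry: ItemRegistry,
                 tier: Tier,
                 frameworks: Sequence[Framework] = ALL_FRAMEWORKS,
                 methods: Sequence[AggregationMethod] = ALL_METHODS,
                 rare_threshold: float = 0.40,
                 wide_threshold: float = 0.90,
                 ) -> tuple[ComparisonReport, ScoresByIndex]:
    """Full comparison battery for one tier."""
    scores, additive, _ = score_tier(records, registry, tier, frameworks, methods)
    avail = {fw: availability(mx) for fw, mx in additive.items()}
    report = compare_all(scores, volumes_of(records), avail, tier,
                         rare_threshold=rare_threshold,
                         wide_threshold=wide_threshold)
    return report, scores
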