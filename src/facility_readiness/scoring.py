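"""The three aggregation rules that turn binary item matrices into
composite readiness scores in [0, 1].

* simple addition — available items divided by possible items, equal
  item weights, denominator adjusted for not-applicable cells;
* domain-weighted addition — mean of per-domain availability fractions,
  equal domain weights, with configured domains (and domains left empty
  by not-applicable masking) excluded from the composite;
* principal components — eigendecomposition of the item correlation
  matrix; the first component is extracted, oriented so that higher
  means readier, and min–max rescaled to [0, 1] over the scored cohort.

PCA scores are therefore cohort-relative: by construction at least one
facility scores exactly 0 and one exactly 1 within a tier, and scores
are not comparable across separately fitted cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import AggregationMethod, Framework, MatrixPurpose, Tier
from .errors import (DegenerateItemError, InsufficientDataError, RescaleError,
                     UndefinedScoreError)
from .survey_io import ResponseMatrix


@dataclass
class ReadinessScore:
    """One facility's composite score for one (index, method) pair."""

    facility_id: str
    index_name: Framework
    method: AggregationMethod
    score: float
    n_applicable: int
    domain_scores: Optional[dict[str, float]] = None
    tier: Optional[Tier] = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.score <= 1 + 1e-12:
            raise ValueError(f"score out of [0,1]: {self.score}")


@dataclass
class PcaModel:
    """First-principal-component scoring model for one binary item set."""

    item_ids: list[str]
    loadings: np.ndarray            # first eigenvector of the correlation matrix
    eigenvalues: np.ndarray         # nonincreasing
    variance_explained_first: float
    item_means: np.ndarray
    item_sds: np.ndarray
    score_min: float = field(default=np.nan)
    score_max: float = field(default=np.nan)

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if (np.diff(ev) > 1e-10).any():
            raise ValueError("eigenvalues must be nonincreasing")
        if (ev < -1e-10).any():
            raise ValueError("negative eigenvalue beyond tolerance")


def _require_additive(matrix: ResponseMatrix) -> None:
    if matrix.purpose is not MatrixPurpose.ADDITIVE:
        raise ValueError("additive-purpose matrix required")


def score_simple(matrix: ResponseMatrix,
                 index_name: Framework | None = None) -> list[ReadinessScore]:
    """Simple addition: available / possible, over applicable items."""
    _require_additive(matrix)
    counts = matrix.applicable.sum(axis=1)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise UndefinedScoreError(
            "facilities with no applicable items: "
            f"{[matrix.facility_ids[i] for i in empty]}")
    scores = matrix.values.sum(axis=1) / counts
    return [ReadinessScore(facility_id=fid, index_name=index_name,
                           method=AggregationMethod.SIMPLE, score=float(s),
                           n_applicable=int(k), tier=matrix.tier)
            for fid, s, k in zip(matrix.facility_ids, scores, counts)]


def score_domain_weighted(matrix: ResponseMatrix,
                          partition: Mapping[str, Sequence[str]],
                          excluded_domains: frozenset[str] | set[str] = frozenset(),
                          index_name: Framework | None = None,
                          ) -> list[ReadinessScore]:
    """Domain-weighted addition: mean of per-domain availability fractions.

    Domain scores are reported for every domain with at least one
    applicable item; the composite averages the non-excluded, non-empty
    domains with equal weight.
    """
    _require_additive(matrix)
    covered = [iid for members in partition.values() for iid in members]
    if sorted(covered) != sorted(matrix.item_ids):
        raise ValueError("partition does not cover the matrix items exactly")
    col = {iid: j for j, iid in enumerate(matrix.item_ids)}
    out: list[ReadinessScore] = []
    dom_cols = {dom: [col[iid] for iid in members]
                for dom, members in partition.items()}
    for i, fid in enumerate(matrix.facility_ids):
        domain_scores: dict[str, float] = {}
        contributing: list[float] = []
        n_applicable = 0
        for dom, cols in dom_cols.items():
            app = matrix.applicable[i, cols]
            k = int(app.sum())
            if k == 0:
                continue  # entirely not-applicable domain: dropped
            ds = float(matrix.values[i, cols].sum() / k)
            domain_scores[dom] = ds
            n_applicable += k
            if dom not in excluded_domains:
                contributing.append(ds)
        if not contributing:
            raise UndefinedScoreError(
                f"facility {fid!r}: no non-excluded domain with applicable items")
        out.append(ReadinessScore(
            facility_id=fid, index_name=index_name,
            method=AggregationMethod.WEIGHTED,
            score=float(np.mean(contributing)), n_applicable=n_applicable,
            domain_scores=domain_scores, tier=matrix.tier))
    return out


def fit_pca(matrix: ResponseMatrix, on_degenerate: str = "error") -> PcaModel:
    """Eigendecomposition of the item correlation (phi) matrix.

    The first eigenvector is oriented so its loading sum is positive
    (higher score = more ready). ``on_degenerate``: ``"error"`` refuses
    zero-variance items, ``"drop"`` removes them with a warning.
    """
    if matrix.purpose is not MatrixPurpose.PCA:
        raise ValueError("pca-purpose matrix required")
    X = matrix.values.astype(float)
    if X.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 facilities")
    sds = X.std(axis=0, ddof=1)
    item_ids = list(matrix.item_ids)
    dead = [item_ids[j] for j in np.flatnonzero(sds == 0)]
    if dead:
        if on_degenerate == "drop":
            warnings.warn(f"dropping zero-variance items from PCA: {dead}",
                          stacklevel=2)
            keep = np.flatnonzero(sds > 0)
            X = X[:, keep]
            sds = sds[keep]
            item_ids = [item_ids[j] for j in keep]
        else:
            raise DegenerateItemError(dead)
    if X.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 non-degenerate items")
    means = X.mean(axis=0)
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    first = eigvecs[:, order[0]]
    if first.sum() < 0 or (first.sum() == 0 and first[np.argmax(np.abs(first))] < 0):
        first = -first
    model = PcaModel(
        item_ids=item_ids, loadings=first, eigenvalues=eigvals,
        variance_explained_first=float(eigvals[0] / len(item_ids)),
        item_means=means, item_sds=sds)
    raw = _raw_projection(X, model)
    model.score_min = float(raw.min())
    model.score_max = float(raw.max())
    return model


def _raw_projection(X: np.ndarray, model: PcaModel) -> np.ndarray:
    Z = (X - model.item_means) / model.item_sds
    return Z @ model.loadings


def score_pca(matrix: ResponseMatrix, model: PcaModel,
              index_name: Framework | None = None) -> list[ReadinessScore]:
    """Project onto the first component and min–max rescale over the cohort."""
    if matrix.purpose is not MatrixPurpose.PCA:
        raise ValueError("pca-purpose matrix required")
    if list(matrix.item_ids) != list(model.item_ids):
        # model may have dropped degenerate items; align by id
        col = {iid: j for j, iid in enumerate(matrix.item_ids)}
        try:
            X = matrix.values.astype(float)[:, [col[iid] for iid in model.item_ids]]
        except KeyError as exc:
            raise ValueError(f"matrix lacks model item {exc}") from exc
    else:
        X = matrix.values.astype(float)
    raw = _raw_projection(X, model)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise RescaleError("all facilities project to the same raw score")
    rescaled = (raw - lo) / (hi - lo)
    n_app = matrix.applicable.sum(axis=1)
    return [ReadinessScore(facility_id=fid, index_name=index_name,
                           method=AggregationMethod.PCA, score=float(s),
                           n_applicable=int(k), tier=matrix.tier)
            for fid, s, k in zip(matrix.facility_ids, rescaled, n_app)]


def scores_as_array(scores: Sequence[ReadinessScore]) -> np.ndarray:
    return np.array([s.score for s in scores], dtype=float)
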