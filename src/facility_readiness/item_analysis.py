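"""Per-item diagnostics and the item-selection procedure.

The WHO-standards item selection starts from a candidate pool, drops
items that are nearly universally available (>97%, strictly) because
they cannot differentiate facilities, then characterises the survivors
with a two-parameter logistic (2PL) item response model per readiness
domain:

    P(y_ij = 1 | theta_i) = 1 / (1 + exp(-a_j (theta_i - b_j)))

with latent facility readiness theta ~ N(0, 1), item discrimination a_j
and item difficulty b_j. Estimation is marginal maximum likelihood via
EM with Gauss–Hermite quadrature: the E-step computes each facility's
posterior weight on the quadrature nodes, the M-step maximises the
expected complete-data log-likelihood item by item (bounded L-BFGS-B).
The marginal log-likelihood is nondecreasing across iterations.

Also here: interitem (phi) correlation, Cronbach's alpha, and the
rare/widely-available item variation classification used in reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import DegenerateItemError, InsufficientDataError
from .rounding import percent
from .survey_io import ResponseMatrix

#: Default exclusion threshold for near-universal availability (strict >).
UNIVERSAL_THRESHOLD = 0.97
#: Default variation thresholds: rare strictly below 40%, widely
#: available at or above 90% (the reporting table's convention).
RARE_THRESHOLD = 0.40
WIDE_THRESHOLD = 0.90
#: Default minimum discrimination for retaining a candidate item. Real
#: selection mixes statistical with conceptual criteria; this knob is
#: the statistical half and is deliberately configurable.
DISCRIMINATION_THRESHOLD = 0.65


@dataclass
class ItemDiagnostics:
    item_id: str
    availability: float
    excluded_universal: bool
    discrimination_a: Optional[float] = None
    difficulty_b: Optional[float] = None
    fit_converged: bool = False


@dataclass
class TwoPlFit:
    """Fitted 2PL parameters for one item set."""

    item_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    log_likelihood: float
    n_quadrature: int
    converged: bool
    n_iter: int
    ll_path: list[float] = field(default_factory=list)


def availability(matrix: ResponseMatrix) -> dict[str, float]:
    """Per-item availability among facilities where the item applies.

    Items applicable nowhere get NaN (undefined, reported as such).
    """
    out: dict[str, float] = {}
    for j, iid in enumerate(matrix.item_ids):
        mask = matrix.applicable[:, j]
        n = int(mask.sum())
        out[iid] = float(matrix.values[mask, j].mean()) if n else float("nan")
    return out


def screen_universal(availabilities: Mapping[str, float],
                     threshold: float = UNIVERSAL_THRESHOLD,
                     ) -> tuple[list[str], list[str]]:
    """Split items into (retained, excluded): excluded iff availability
    strictly exceeds the threshold. NaN availability is retained (it
    signals a coverage problem, not universality)."""
    retained, excluded = [], []
    for iid, p in availabilities.items():
        (excluded if (p == p and p > threshold) else retained).append(iid)
    return retained, excluded


def screen_discrimination(fit: "TwoPlFit",
                          threshold: float = DISCRIMINATION_THRESHOLD,
                          ) -> tuple[list[str], list[str]]:
    """Split a fitted item set into (retained, excluded) by estimated
    discrimination: excluded iff a < threshold."""
    retained, excluded = [], []
    for iid, a in zip(fit.item_ids, fit.a):
        (retained if a >= threshold else excluded).append(iid)
    return retained, excluded


def _gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    # physicists' rule transformed for a standard-normal weight
    x, w = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def fit_2pl(matrix: ResponseMatrix, n_quadrature: int = 21,
            max_iter: int = 500, tol: float = 1e-4,
            a_bounds: tuple[float, float] = (0.05, 10.0),
            b_bounds: tuple[float, float] = (-6.0, 6.0)) -> TwoPlFit:
    """Marginal-ML 2PL fit by EM with Gauss–Hermite quadrature.

    Convergence: max absolute parameter change below `tol`; otherwise
    the result is returned flagged ``converged=False`` after `max_iter`
    iterations. Items constant over their applicable facilities are
    refused (correlation with the trait is undefined).
    """
    Y = matrix.values.astype(float)
    M = matrix.applicable.astype(float)
    n, p = Y.shape
    if p < 2:
        raise InsufficientDataError("2PL fit needs at least 2 items")
    if n < 2:
        raise InsufficientDataError("2PL fit needs at least 2 facilities")
    dead = []
    for j in range(p):
        vals = Y[M[:, j] > 0, j]
        if vals.size == 0 or vals.min() == vals.max():
            dead.append(matrix.item_ids[j])
    if dead:
        raise DegenerateItemError(dead)

    theta, A = _gauss_hermite(n_quadrature)
    logA = np.log(A)
    # moment-based starting values: a = 1, b from observed availability
    avail = (Y * M).sum(axis=0) / M.sum(axis=0)
    a = np.ones(p)
    b = np.clip(-np.log(avail / (1 - avail)), b_bounds[0], b_bounds[1])

    YM = Y * M
    CM = (1 - Y) * M
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        z = a[:, None] * (theta[None, :] - b[:, None])       # (p, Q)
        logp, log1mp = _log_sigmoid(z), _log_sigmoid(-z)
        L = YM @ logp + CM @ log1mp + logA[None, :]          # (n, Q)
        ll_i = logsumexp(L, axis=1)
        ll = float(ll_i.sum())
        ll_path.append(ll)
        post = np.exp(L - ll_i[:, None])                     # (n, Q)
        r = YM.T @ post                                      # expected successes
        m = M.T @ post                                       # expected trials

        # M-step: bounded 2-parameter optimisation per item
        a_new, b_new = a.copy(), b.copy()
        for j in range(p):
            rj, mj = r[j], m[j]

            def nll(params, rj=rj, mj=mj):
                aj, bj = params
                zq = aj * (theta - bj)
                val = -(rj @ _log_sigmoid(zq) + (mj - rj) @ _log_sigmoid(-zq))
                pq = 1.0 / (1.0 + np.exp(-zq))
                resid = rj - mj * pq
                grad = np.array([-(resid @ (theta - bj)), aj * resid.sum()])
                return val, grad

            res = minimize(nll, x0=np.array([a[j], b[j]]), jac=True,
                           method="L-BFGS-B", bounds=[a_bounds, b_bounds])
            a_new[j], b_new[j] = res.x
        delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        a, b = a_new, b_new
        if delta < tol:
            converged = True
            break

    # final marginal log-likelihood at the accepted parameters
    z = a[:, None] * (theta[None, :] - b[:, None])
    L = YM @ _log_sigmoid(z) + CM @ _log_sigmoid(-z) + logA[None, :]
    ll = float(logsumexp(L, axis=1).sum())
    ll_path.append(ll)
    return TwoPlFit(item_ids=list(matrix.item_ids), a=a, b=b,
                    log_likelihood=ll, n_quadrature=n_quadrature,
                    converged=converged, n_iter=it, ll_path=ll_path)


def build_item_diagnostics(matrix: ResponseMatrix,
                           fit: Optional[TwoPlFit] = None,
                           threshold: float = UNIVERSAL_THRESHOLD,
                           ) -> list[ItemDiagnostics]:
    """Combine availability screening with optional 2PL parameters."""
    avail = availability(matrix)
    params = {}
    if fit is not None:
        params = {iid: (float(ai), float(bi), fit.converged)
                  for iid, ai, bi in zip(fit.item_ids, fit.a, fit.b)}
    out = []
    for iid, pav in avail.items():
        ai, bi, conv = params.get(iid, (None, None, False))
        out.append(ItemDiagnostics(
            item_id=iid, availability=pav,
            excluded_universal=bool(pav == pav and pav > threshold),
            discrimination_a=ai, difficulty_b=bi, fit_converged=conv))
    return out


def interitem_correlation(matrix: ResponseMatrix,
                          ) -> tuple[float, np.ndarray, list[str], list[str]]:
    """Pearson (phi) correlation between 0/1 items.

    Returns (mean off-diagonal correlation, full matrix, kept item ids,
    dropped zero-variance item ids). Dropped items are warned about.
    """
    X = matrix.values.astype(float)
    sds = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sds > 0)
    dropped = [matrix.item_ids[j] for j in np.flatnonzero(sds == 0)]
    if dropped:
        warnings.warn(f"dropping zero-variance items from correlation: {dropped}",
                      stacklevel=2)
    if keep.size < 2:
        raise InsufficientDataError("need at least 2 items with variance")
    R = np.corrcoef(X[:, keep], rowvar=False)
    off = R[~np.eye(keep.size, dtype=bool)]
    return float(off.mean()), R, [matrix.item_ids[j] for j in keep], dropped


def cronbach_alpha(matrix: ResponseMatrix) -> float:
    """Internal consistency: alpha = K/(K-1) (1 - sum item var / total var),
    sample variances. NaN (with a warning) when the total score has no
    variance."""
    X = matrix.values.astype(float)
    k = X.shape[1]
    if k < 2:
        raise InsufficientDataError("alpha needs at least 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("total score has zero variance; alpha undefined",
                      stacklevel=2)
        return float("nan")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


@dataclass
class ItemVariationReport:
    n_items: int
    n_rare: int
    n_widely_available: int
    pct_rare: int
    pct_widely_available: int


def classify_item_variation(availabilities: Mapping[str, float],
                            low: float = RARE_THRESHOLD,
                            high: float = WIDE_THRESHOLD,
                            ) -> ItemVariationReport:
    """Count items that are rare (availability < low) or widely available
    (availability >= high); percentages integer-rounded half-to-even."""
    vals = [v for v in availabilities.values() if v == v]
    n = len(vals)
    if n == 0:
        raise InsufficientDataError("no defined availabilities")
    n_rare = sum(v < low for v in vals)
    n_wide = sum(v >= high for v in vals)
    return ItemVariationReport(
        n_items=n, n_rare=n_rare, n_widely_available=n_wide,
        pct_rare=int(percent(n_rare, n, 0)),
        pct_widely_available=int(percent(n_wide, n, 0)))
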