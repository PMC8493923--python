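"""The index-comparison battery.

For each of the nine indices (three item-selection frameworks x three
aggregation methods) and each tier this module computes distributional
summaries (moment skewness/kurtosis, coefficient of variation),
floor/ceiling percentages, tie structure of the facility ranking,
pairwise Bland–Altman agreement between indices (limits of agreement at
mean +/- 2 SD of the per-facility differences), Spearman rank
correlation with monthly delivery volume, and interdomain correlations
of the deconstructed domain scores.

Reporting conventions: percentages are rounded half-to-even at one
decimal; kurtosis is non-excess (normal = 3); limits of agreement use
exactly 2 SD; p-values are two-sided with no multiple-testing
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AggregationMethod, Framework, Tier
from .errors import AlignmentError
from .rounding import percent
from .scoring import ReadinessScore

#: Scores are exact rationals under additive aggregation (exact equality
#: is safe); PCA endpoints are exact only up to floating-point rescaling.
PCA_SCORE_ATOL = 1e-9


# ---------------------------------------------------------------- ranks

def average_ranks(x: Sequence[float]) -> np.ndarray:
    """Average ranks (1 = smallest), ties share the mean rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided t-approximation p-value.

    Pairs with a missing value in either variable are deleted pairwise.
    Returns (nan, nan) when either variable has no rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    rx, ry = average_ranks(x), average_ranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    # concordant / reversed rankings are exactly +/-1, no float residue
    if (rx == ry).all():
        return 1.0, 0.0
    if (rx == len(rx) + 1 - ry).all():
        return -1.0, 0.0
    rho = float(((rx - rx.mean()) @ (ry - ry.mean())) / (n * sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class TieReport:
    """Tie structure of one score vector (higher score = better rank)."""

    n: int
    n_distinct: int
    n_top: int                  # facilities at the maximum score
    n_second: int               # facilities at the second-largest distinct score
    pct_top: float
    pct_second: float
    average_ranks: np.ndarray   # ascending convention, for correlations
    dense_ranks: np.ndarray     # 1 = best, ties share the rank
    ordinal_ranks: np.ndarray   # 1 = best, ties broken by input order
    tie_group_sizes: dict[float, int]


def rank_with_ties(scores: Sequence[float]) -> TieReport:
    """Rank facilities by score and report tie structure.

    "Second-highest" means the second-largest *distinct* score value;
    grouping uses exact equality (additive scores are exact rationals).
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no scores to rank")
    uniq, counts = np.unique(x, return_counts=True)  # ascending
    groups = {float(v): int(c) for v, c in zip(uniq, counts)}
    n_top = int(counts[-1])
    n_second = int(counts[-2]) if len(uniq) > 1 else 0
    dense = len(uniq) - np.searchsorted(uniq, x)  # 1 = highest value
    ordinal = np.empty(n, dtype=int)
    ordinal[np.argsort(-x, kind="mergesort")] = np.arange(1, n + 1)
    return TieReport(
        n=n, n_distinct=len(uniq), n_top=n_top, n_second=n_second,
        pct_top=percent(n_top, n), pct_second=percent(n_second, n),
        average_ranks=average_ranks(x), dense_ranks=dense.astype(int),
        ordinal_ranks=ordinal, tie_group_sizes=groups)


# ------------------------------------------------------- distributional

@dataclass
class FloorCeiling:
    n: int
    n_floor: int
    n_ceiling: int
    floor_pct: float
    ceiling_pct: float


def floor_ceiling(scores: Sequence[float], atol: float = 0.0) -> FloorCeiling:
    """Counts and one-decimal percentages of scores at exactly 0 / 1.

    `atol` accommodates PCA scores whose endpoints are exact only up to
    floating point (use :data:`PCA_SCORE_ATOL`); additive scores use 0.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    n_floor = int((np.abs(x - 0.0) <= atol).sum())
    n_ceiling = int((np.abs(x - 1.0) <= atol).sum())
    return FloorCeiling(n=n, n_floor=n_floor, n_ceiling=n_ceiling,
                        floor_pct=percent(n_floor, n),
                        ceiling_pct=percent(n_ceiling, n))


@dataclass
class IndexSummary:
    index_name: Optional[Framework]
    method: Optional[AggregationMethod]
    tier: Optional[Tier]
    n: int
    mean: float
    median: float
    sd: float
    iqr: float
    skewness: float
    kurtosis: float          # non-excess: normal distribution = 3
    cv: float
    floor_pct: float
    ceiling_pct: float
    n_perfect: int
    n_second_rank_tie: int


def summarize_index(scores: Sequence[float],
                    index_name: Framework | None = None,
                    method: AggregationMethod | None = None,
                    tier: Tier | None = None,
                    score_atol: float = 0.0) -> IndexSummary:
    """Distributional summary of one score vector.

    Skewness and kurtosis are moment-based on population moments
    (m3/m2^1.5 and m4/m2^2, non-excess); sd and cv use the sample
    (n-1) standard deviation. Constant scores yield NaN skewness and
    kurtosis (undefined, reported as such).
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("summary needs at least 2 scores")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    d = x - mean
    m2 = float((d ** 2).mean())
    if m2 == 0:
        skew = kurt = float("nan")
    else:
        skew = float((d ** 3).mean() / m2 ** 1.5)
        kurt = float((d ** 4).mean() / m2 ** 2)
    fc = floor_ceiling(x, atol=score_atol)
    ties = rank_with_ties(x)
    q75, q25 = np.percentile(x, [75, 25])
    return IndexSummary(
        index_name=index_name, method=method, tier=tier, n=n,
        mean=mean, median=float(np.median(x)), sd=sd, iqr=float(q75 - q25),
        skewness=skew, kurtosis=kurt,
        cv=sd / mean if mean > 0 else float("nan"),
        floor_pct=fc.floor_pct, ceiling_pct=fc.ceiling_pct,
        n_perfect=fc.n_ceiling, n_second_rank_tie=ties.n_second)


# ----------------------------------------------------------- agreement

@dataclass
class AgreementResult:
    """Bland–Altman agreement between two score sets (a - b)."""

    index_pair: tuple[str, str]
    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n_outside_loa: int
    rank_correlation: float


def _aligned_values(scores_a, scores_b) -> tuple[np.ndarray, np.ndarray]:
    if len(scores_a) and isinstance(scores_a[0], ReadinessScore):
        da = {s.facility_id: s.score for s in scores_a}
        db = {s.facility_id: s.score for s in scores_b}
        if set(da) != set(db):
            only_a = sorted(set(da) - set(db))[:5]
            only_b = sorted(set(db) - set(da))[:5]
            raise AlignmentError(
                f"facility sets differ (only in a: {only_a}, only in b: {only_b})")
        ids = sorted(da)
        return (np.array([da[i] for i in ids]), np.array([db[i] for i in ids]))
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    return a, b


def bland_altman(scores_a, scores_b,
                 pair: tuple[str, str] = ("a", "b")) -> AgreementResult:
    """Agreement between two indices scored on the same facilities.

    Differences are a - b; limits of agreement are mean +/- 2 * sample SD.
    Also reports the Spearman correlation of the two score sets.
    """
    a, b = _aligned_values(scores_a, scores_b)
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    lo, hi = mean - 2 * sd, mean + 2 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    rho, _ = spearman(a, b) if len(a) >= 3 else (float("nan"), float("nan"))
    return AgreementResult(index_pair=pair, n=len(d), mean_difference=mean,
                           sd_difference=sd, loa_lower=lo, loa_upper=hi,
                           n_outside_loa=outside, rank_correlation=rho)


def plot_bland_altman(result: AgreementResult, scores_a, scores_b, path) -> None:
    """Difference-vs-mean plot with mean-difference and 2 SD lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _aligned_values(scores_a, scores_b)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.6)
    ax.axhline(result.mean_difference, ls=(0, (2, 2)), color="k", lw=1)
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, ls=(0, (6, 3)), color="k", lw=1)
    ax.set_xlabel("mean of scores")
    ax.set_ylabel(f"{result.index_pair[0]} − {result.index_pair[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -------------------------------------------------- domain deconstruction

def collect_domain_scores(scores_by_framework: Mapping[Framework, Sequence[ReadinessScore]],
                          ) -> pd.DataFrame:
    """Facilities x (framework:domain) table of domain scores."""
    columns: dict[str, dict[str, float]] = {}
    for fw, scores in scores_by_framework.items():
        for s in scores:
            if not s.domain_scores:
                raise ValueError(
                    f"score for {s.facility_id!r} carries no domain scores "
                    f"(method {s.method})")
            for dom, val in s.domain_scores.items():
                columns.setdefault(f"{Framework(fw).value}:{dom}", {})[s.facility_id] = val
    return pd.DataFrame(columns).sort_index()


def domain_deconstruction(domain_scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between domain-score vectors.

    Constant vectors produce NaN rows/columns (undefined, reported)."""
    cols = list(domain_scores.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for ca, cb in combinations(cols, 2):
        sub = domain_scores[[ca, cb]].dropna()
        r, _ = spearman(sub[ca].to_numpy(), sub[cb].to_numpy())
        rho.loc[ca, cb] = rho.loc[cb, ca] = r
    for c in cols:
        v = domain_scores[c].dropna().to_numpy()
        rho.loc[c, c] = 1.0 if len(np.unique(v)) > 1 else float("nan")
    return rho


# -------------------------------------------------------------- battery

@dataclass
class ComparisonReport:
    """Per-tier battery: the per-index characteristics table plus the
    full pairwise-agreement set."""

    tier: Tier
    table: pd.DataFrame
    agreement: pd.DataFrame
    summaries: list[IndexSummary]


def compare_all(scores_by_index: Mapping[tuple[Framework, AggregationMethod],
                                         Sequence[ReadinessScore]],
                volumes: Mapping[str, Optional[float]],
                availabilities_by_framework: Mapping[Framework, Mapping[str, float]],
                tier: Tier, rare_threshold: float = 0.40,
                wide_threshold: float = 0.90) -> ComparisonReport:
    """Compute the full per-tier comparison battery.

    `volumes` maps facility_id to monthly delivery volume (None/NaN
    allowed; such facilities are dropped pairwise from the volume
    correlation only).
    """
    from .item_analysis import classify_item_variation

    rows = []
    summaries = []
    for (fw, method), scores in scores_by_index.items():
        fw, method = Framework(fw), AggregationMethod(method)
        atol = PCA_SCORE_ATOL if method is AggregationMethod.PCA else 0.0
        vals = np.array([s.score for s in scores], dtype=float)
        summ = summarize_index(vals, index_name=fw, method=method, tier=tier,
                               score_atol=atol)
        summaries.append(summ)
        variation = classify_item_variation(availabilities_by_framework[fw],
                                            low=rare_threshold,
                                            high=wide_threshold)
        vol = np.array([np.nan if volumes.get(s.facility_id) is None
                        else float(volumes[s.facility_id]) for s in scores])
        rho, p = spearman(vals, vol)
        rows.append({
            "framework": fw.value, "method": method.value,
            "n_items": variation.n_items,
            "n_rare_items": variation.n_rare, "pct_rare_items": variation.pct_rare,
            "n_wide_items": variation.n_widely_available,
            "pct_wide_items": variation.pct_widely_available,
            "cv": summ.cv, "floor_pct": summ.floor_pct,
            "ceiling_pct": summ.ceiling_pct, "n_perfect": summ.n_perfect,
            "n_second_rank_tie": summ.n_second_rank_tie,
            "volume_spearman_r": rho, "volume_spearman_p": p, "n": summ.n,
        })
    table = pd.DataFrame(rows)

    ag_rows = []
    keys = list(scores_by_index)
    for ka, kb in combinations(keys, 2):
        label_a = f"{Framework(ka[0]).value}/{AggregationMethod(ka[1]).value}"
        label_b = f"{Framework(kb[0]).value}/{AggregationMethod(kb[1]).value}"
        res = bland_altman(list(scores_by_index[ka]), list(scores_by_index[kb]),
                           pair=(label_a, label_b))
        ag_rows.append({
            "index_a": label_a, "index_b": label_b, "n": res.n,
            "mean_difference": res.mean_difference,
            "sd_difference": res.sd_difference,
            "loa_lower": res.loa_lower, "loa_upper": res.loa_upper,
            "n_outside_loa": res.n_outside_loa,
            "rank_correlation": res.rank_correlation,
        })
    agreement = pd.DataFrame(ag_rows)
    return ComparisonReport(tier=tier, table=table, agreement=agreement,
                            summaries=summaries)
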