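"""Index-comparison battery: summaries, floor/ceiling, ties, agreement,
rank correlation and domain deconstruction."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import facility_readiness as fr
from facility_readiness.core import AggregationMethod, Framework, Tier
from facility_readiness.errors import AlignmentError
from facility_readiness.scoring import ReadinessScore

# ------------------------------------------------------------- summaries

def test_summary_mean_sd_cv():
    s = fr.summarize_index([0.2, 0.4, 0.6])
    assert s.mean == pytest.approx(0.4)
    assert s.sd == pytest.approx(0.2)
    assert s.cv == pytest.approx(0.5)


def test_symmetric_sample_has_zero_skewness():
    s = fr.summarize_index([0.1, 0.3, 0.5, 0.7, 0.9])
    assert s.skewness == pytest.approx(0.0, abs=1e-12)


def test_summary_matches_moment_formula_oracle():
    x = [0.12, 0.55, 0.71, 0.33, 0.98, 0.44, 0.27, 0.81]
    s = fr.summarize_index(x)
    mean = sum(x) / len(x)
    m2 = sum((v - mean) ** 2 for v in x) / len(x)
    m3 = sum((v - mean) ** 3 for v in x) / len(x)
    m4 = sum((v - mean) ** 4 for v in x) / len(x)
    assert s.skewness == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
    assert s.kurtosis == pytest.approx(m4 / m2 ** 2, abs=1e-12)
    assert s.sd == pytest.approx(statistics.stdev(x), abs=1e-12)


def test_constant_scores_yield_undefined_shape_statistics():
    s = fr.summarize_index([0.5, 0.5, 0.5])
    assert np.isnan(s.skewness) and np.isnan(s.kurtosis)


def test_kurtosis_is_non_excess():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20000)
    s = fr.summarize_index(x)
    assert s.kurtosis == pytest.approx(3.0, abs=0.15)


# --------------------------------------------------------- floor/ceiling

@pytest.mark.parametrize("count, total, expected", [
    (34, 160, 21.2),   # .x25 cases round half-to-even, down
    (50, 160, 31.2),
    (16, 246, 6.5),
    (45, 246, 18.3),
])
def test_percentages_round_half_to_even(count, total, expected):
    scores = [1.0] * count + [0.5] * (total - count)
    assert fr.floor_ceiling(scores).ceiling_pct == expected


def test_floor_and_ceiling_extremes():
    assert fr.floor_ceiling([0.2, 0.4]).floor_pct == 0.0
    assert fr.floor_ceiling([1.0, 1.0]).ceiling_pct == 100.0


def test_pca_tolerance_catches_float_endpoints():
    scores = [0.0 + 1e-12, 0.5, 1.0 - 1e-12]
    fc = fr.floor_ceiling(scores, atol=1e-9)
    assert fc.n_floor == 1 and fc.n_ceiling == 1
    strict = fr.floor_ceiling(scores)
    assert strict.n_floor == 0 and strict.n_ceiling == 0


# ------------------------------------------------------------------ ties

def test_second_highest_tie_count_and_percentage():
    scores = [1.0] * 34 + [21 / 22] * 50 + [0.5] * 76
    ties = fr.rank_with_ties(scores)
    assert ties.n_top == 34 and ties.n_second == 50
    assert ties.pct_second == 31.2


def test_all_distinct_scores_have_singleton_tie_groups():
    ties = fr.rank_with_ties([0.1, 0.5, 0.9])
    assert all(c == 1 for c in ties.tie_group_sizes.values())
    assert ties.n_top == 1 and ties.n_second == 1
    assert sorted(ties.ordinal_ranks.tolist()) == [1, 2, 3]


def test_constant_scores_form_one_tie_group():
    ties = fr.rank_with_ties([0.7] * 5)
    assert ties.n_distinct == 1 and ties.n_top == 5 and ties.n_second == 0
    assert (ties.dense_ranks == 1).all()
    assert (ties.average_ranks == 3.0).all()


def test_dense_ranks_put_best_facility_first():
    ties = fr.rank_with_ties([0.2, 0.9, 0.9, 0.5])
    assert ties.dense_ranks.tolist() == [3, 1, 1, 2]


# ---------------------------------------------------------- bland-altman

def test_identical_scores_agree_perfectly():
    res = fr.bland_altman([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
    assert res.mean_difference == 0.0 and res.sd_difference == 0.0
    assert res.n_outside_loa == 0


def test_constant_offset_has_zero_sd():
    a = np.array([0.2, 0.4, 0.6])
    res = fr.bland_altman(a, a + 0.1)
    assert res.mean_difference == pytest.approx(-0.1)
    assert res.sd_difference == pytest.approx(0.0, abs=1e-15)


def test_bland_altman_matches_direct_formula():
    rng = np.random.default_rng(17)
    a, b = rng.random(10), rng.random(10)
    res = fr.bland_altman(a, b)
    d = (a - b).tolist()
    mean = sum(d) / 10
    sd = statistics.stdev(d)
    assert res.mean_difference == pytest.approx(mean, abs=1e-12)
    assert res.sd_difference == pytest.approx(sd, abs=1e-12)
    assert res.loa_lower == pytest.approx(mean - 2 * sd, abs=1e-12)
    assert res.loa_upper == pytest.approx(mean + 2 * sd, abs=1e-12)
    assert res.loa_upper >= res.loa_lower
    assert res.n_outside_loa == sum(v < mean - 2 * sd or v > mean + 2 * sd
                                    for v in d)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(0, 1, width=32), min_size=3, max_size=20),
       st.lists(st.floats(0, 1, width=32), min_size=3, max_size=20))
def test_mean_difference_antisymmetric_sd_symmetric(xs, ys):
    n = min(len(xs), len(ys))
    a, b = np.array(xs[:n]), np.array(ys[:n])
    fwd, rev = fr.bland_altman(a, b), fr.bland_altman(b, a)
    assert fwd.mean_difference == pytest.approx(-rev.mean_difference, abs=1e-12)
    assert fwd.sd_difference == pytest.approx(rev.sd_difference, abs=1e-12)


def test_mismatched_facility_sets_raise_alignment_error():
    mk = lambda fid, v: ReadinessScore(facility_id=fid, index_name=Framework.SARA,
                                       method=AggregationMethod.SIMPLE,
                                       score=v, n_applicable=4)
    with pytest.raises(AlignmentError):
        fr.bland_altman([mk("A", 0.5), mk("B", 0.6)],
                        [mk("A", 0.5), mk("C", 0.6)])


# --------------------------------------------------------------- spearman

def test_spearman_perfect_monotone():
    rho, p = fr.spearman([1, 2, 3, 4], [10, 20, 25, 70])
    assert rho == 1.0 and p == 0.0
    rho, _ = fr.spearman([1, 2, 3, 4], [5, 4, 2, 1])
    assert rho == -1.0


def test_spearman_with_ties_matches_scipy():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0, 9.0, 11.0, 12.0]
    y = [3.0, 1.0, 4.0, 4.0, 6.0, 2.0, 7.0, 7.0, 7.0, 10.0, 9.0, 12.0]
    rho, p = fr.spearman(x, y)
    expected = sps.spearmanr(x, y)
    assert rho == pytest.approx(expected.statistic, abs=1e-12)
    assert p == pytest.approx(expected.pvalue, rel=1e-9)


def test_spearman_deletes_missing_pairs():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 3.0, 9.0, np.nan, 7.0]
    rho, _ = fr.spearman(x, y)
    assert rho == 1.0  # remaining pairs are strictly monotone


def test_spearman_undefined_for_constant_input():
    rho, p = fr.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(rho) and np.isnan(p)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=15, unique=True))
def test_spearman_invariant_under_monotone_transform(xs):
    rng = np.random.default_rng(len(xs))
    ys = rng.normal(size=len(xs))
    rho, _ = fr.spearman(xs, ys)
    cubed = np.array(xs, dtype=float) ** 3  # strictly monotone, exact on ints
    rho2, _ = fr.spearman(cubed, ys)
    assert -1.0 <= rho <= 1.0
    assert rho2 == pytest.approx(rho, abs=1e-12)


# ------------------------------------------------- domain deconstruction

def test_domain_correlates_perfectly_with_itself_and_its_copy():
    rng = np.random.default_rng(3)
    v = rng.random(30)
    df = pd.DataFrame({"SARA:equipment": v, "WHO:equipment": v,
                       "WHO:staffing": rng.random(30)})
    rho = fr.domain_deconstruction(df)
    assert rho.loc["SARA:equipment", "SARA:equipment"] == 1.0
    assert rho.loc["SARA:equipment", "WHO:equipment"] == 1.0
    assert rho.equals(rho.T)


def test_single_latent_trait_makes_all_interdomain_correlations_positive():
    rng = np.random.default_rng(40)
    theta = rng.normal(size=400)
    cols = {}
    for k in range(6):
        probs = 1 / (1 + np.exp(-(theta[:, None] - rng.normal(0, 1, 5))))
        items = (rng.random((400, 5)) < probs)
        cols[f"fw{k // 3}:dom{k % 3}"] = items.mean(axis=1)
    rho = fr.domain_deconstruction(pd.DataFrame(cols))
    off = rho.to_numpy()[~np.eye(6, dtype=bool)]
    assert (off > 0).all()


# ------------------------------------------------------------- compare_all

def test_self_agreement_mean_difference_is_zero():
    scores = [0.2, 0.5, 0.8, 1.0]
    res = fr.bland_altman(scores, scores)
    assert res.mean_difference == 0.0 and res.sd_difference == 0.0


def test_battery_emits_nine_rows_per_tier(registry, cohort_by_tier):
    recs = cohort_by_tier[Tier.HOSPITAL]
    report, scores = fr.compare_tier(recs, registry, Tier.HOSPITAL)
    assert len(report.table) == 9
    assert set(report.table.framework) == {f.value for f in Framework}
    assert set(report.table.method) == {m.value for m in AggregationMethod}
    assert len(report.agreement) == 36  # all unordered pairs of 9 indices
    assert (report.table.floor_pct + report.table.ceiling_pct <= 100).all()


def test_battery_volume_correlations_positive_on_linked_cohort(registry, cohort_by_tier):
    for tier, recs in cohort_by_tier.items():
        report, _ = fr.compare_tier(recs, registry, tier)
        assert (report.table.volume_spearman_r > 0).all()
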