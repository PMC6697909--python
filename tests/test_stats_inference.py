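import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crackletrack.stats_inference import (TermSpec, auc_bootstrap_ci,
                                          chi_squared, counts_pct,
                                          dichotomize, fit_logistic,
                                          format_median_iqr, gwet_ac1,
                                          mann_whitney, roc_analysis,
                                          select_multivariate_terms,
                                          summarize_group)


# ---------------------------------------------------------------------------
# descriptive summaries

def test_summarize_group_interpolated_quartiles():
    med, q1, q3 = summarize_group(range(1, 10))
    assert (med, q1, q3) == (5.0, 3.0, 7.0)
    with pytest.raises(ValueError):
        summarize_group([])


def test_counts_pct_rounding_half_up():
    assert counts_pct(13, 24) == "13 (54.2)"
    assert counts_pct(6, 24) == "6 (25.0)"
    assert counts_pct(8, 47) == "8 (17.0)"
    assert counts_pct(1, 16) == "1 (6.3)"  # 6.25 rounds half-up to 6.3
    with pytest.raises(ValueError):
        counts_pct(5, 0)
    with pytest.raises(ValueError):
        counts_pct(25, 24)


def test_format_median_iqr():
    assert format_median_iqr(range(1, 10)) == "5.0 [3.0–7.0]"


# ---------------------------------------------------------------------------
# group comparisons

def test_mann_whitney_exact_against_enumeration():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    u, p = mann_whitney(x, y)
    assert u == 0.0
    # oracle: enumerate all C(6,3) = 20 label assignments
    pooled = x + y
    count_extreme = 0
    u_obs = sum(1 for a in x for b in y if a > b)
    stat = min(u_obs, 9 - u_obs)
    for combo in itertools.combinations(range(6), 3):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(6) if i not in combo]
        u_c = sum(1 for a in xs for b in ys if a > b)
        if min(u_c, 9 - u_c) <= stat:
            count_extreme += 1
    assert p == pytest.approx(count_extreme / 20)
    assert p == pytest.approx(0.1)


def test_mann_whitney_symmetry_and_approximation():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = mann_whitney(x, x)
    assert p == pytest.approx(1.0, abs=0.01)
    rng = np.random.default_rng(0)
    a = rng.normal(size=15)
    b = rng.normal(0.5, size=15)
    _, p_exact = mann_whitney(a, b)  # 225 <= 400, tie-free -> exact
    from scipy.stats import mannwhitneyu
    p_approx = mannwhitneyu(a, b, alternative="two-sided",
                            method="asymptotic", use_continuity=True).pvalue
    assert abs(p_exact - p_approx) < 0.01


def test_chi_squared_closed_forms():
    stat, df, p = chi_squared([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)
    assert df == 1
    stat0, _, p0 = chi_squared([[5, 5], [5, 5]])
    assert stat0 == pytest.approx(0.0)
    assert p0 == pytest.approx(1.0)


def test_chi_squared_onset_timing_table():
    # published early/mid/late split differs strongly between groups
    _, df, p = chi_squared([[20, 4, 0], [12, 27, 8]])
    assert df == 2
    assert p < 0.001


def test_chi_squared_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_squared([[5, 0], [7, 0]])


# ---------------------------------------------------------------------------
# Gwet's AC1

def test_ac1_perfect_agreement_and_disagreement():
    same = [[1, 1], [0, 0], [1, 1], [0, 0]]
    assert gwet_ac1(same).ac1 == pytest.approx(1.0)
    flipped = [[1, 0], [0, 1], [1, 0], [0, 1]]
    assert gwet_ac1(flipped).ac1 == pytest.approx(-1.0)


def test_ac1_hand_computed_example():
    # p_a = 0.75, pi_+ = 0.625, p_e = 0.46875 -> AC1 = 0.28125/0.53125
    ratings = [[1, 1], [1, 1], [0, 0], [1, 0]]
    res = gwet_ac1(ratings)
    assert res.ac1 == pytest.approx(0.5294, abs=1e-4)
    assert res.ci_low <= res.ac1 <= res.ci_high
    assert res.ci_high <= 1.0


def test_ac1_validation():
    with pytest.raises(ValueError):
        gwet_ac1([[1], [0]])  # single rater
    with pytest.raises(ValueError):
        gwet_ac1([[1, 0]])  # single item


def _ac1_oracle(mat):
    """Direct textbook evaluation: mean pairwise agreement vs chance."""
    mat = np.asarray(mat)
    n, r = mat.shape
    pa = np.mean([
        np.mean([mat[i, a] == mat[i, b]
                 for a in range(r) for b in range(r) if a != b])
        for i in range(n)])
    pi1 = np.mean(mat)
    pe = 2 * pi1 * (1 - pi1)
    return (pa - pe) / (1 - pe)


def test_ac1_exhaustive_two_rater_tables():
    # all 2-rater binary tables with up to 4 items (exhaustive subset;
    # the full <= 6-item sweep runs in the acceptance suite)
    for n in (2, 3, 4):
        for bits in itertools.product([0, 1], repeat=2 * n):
            mat = np.array(bits).reshape(n, 2)
            want = _ac1_oracle(mat)
            assert gwet_ac1(mat).ac1 == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic regression

def test_logistic_null_no_spurious_effect():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"x": rng.normal(size=400),
                       "y": rng.integers(0, 2, size=400)})
    fit = fit_logistic(df, "y", [TermSpec("x")])
    t = fit.term("x")
    assert 0.7 < t.or_value < 1.4
    assert t.p > 0.05


def test_logistic_parameter_recovery():
    rng = np.random.default_rng(11)
    x = rng.normal(size=2000)
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
    y = (rng.random(2000) < p).astype(int)
    fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", [TermSpec("x")])
    t = fit.term("x")
    assert fit.converged
    assert abs(t.beta - 0.8) < 3 * t.se


def test_or_unit_scaling_identity():
    rng = np.random.default_rng(2)
    x = rng.normal(size=300)
    y = (rng.random(300) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
    df = pd.DataFrame({"x": x, "y": y})
    or1 = fit_logistic(df, "y", [TermSpec("x", 1.0)]).term("x").or_value
    or100 = fit_logistic(df, "y", [TermSpec("x", 100.0)]).term("x").or_value
    assert or100 == pytest.approx(or1 ** 100, rel=1e-9)


def test_logistic_affine_invariance_of_probabilities():
    rng = np.random.default_rng(9)
    x = rng.normal(size=500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
    df = pd.DataFrame({"x": x, "x_scaled": 10 * x + 3, "y": y})
    f1 = fit_logistic(df, "y", [TermSpec("x")])
    f2 = fit_logistic(df, "y", [TermSpec("x_scaled")])
    assert f1.term("x").beta == pytest.approx(
        10 * f2.term("x_scaled").beta, rel=1e-4)
    assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)


def test_logistic_separation_flagged():
    df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                       "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
    fit = fit_logistic(df, "y", [TermSpec("x")])
    assert not fit.converged


def test_logistic_requires_both_classes():
    df = pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]})
    with pytest.raises(ValueError):
        fit_logistic(df, "y", [TermSpec("x")])


def test_logistic_complete_cases_only():
    rng = np.random.default_rng(4)
    x = rng.normal(size=100)
    y = (rng.random(100) < 0.5).astype(int)
    x[:10] = np.nan
    fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", [TermSpec("x")])
    assert fit.n_used == 90


# ---------------------------------------------------------------------------
# term selection

def _make_cohort(seed=0, n=300):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    f99 = 700 + 80 * z + 5 * rng.standard_normal(n)
    f95 = 450 + 60 * z + 5 * rng.standard_normal(n)  # strongly correlated
    noise = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
    return pd.DataFrame({"f99_hz": f99, "f95_hz": f95, "noise": noise,
                         "y": y})


def test_selection_keeps_representative_of_correlated_cluster():
    df = _make_cohort()
    terms = select_multivariate_terms(
        df, "y", [TermSpec("f99_hz", 100), TermSpec("f95_hz", 100),
                  TermSpec("noise")])
    names = [t.name for t in terms]
    assert names == ["f99_hz"]  # f95 pruned by |rho| > 0.7, noise by p


def test_selection_single_significant_candidate():
    df = _make_cohort(seed=1)
    terms = select_multivariate_terms(df, "y", [TermSpec("f99_hz", 100)])
    assert [t.name for t in terms] == ["f99_hz"]


def test_selection_warns_when_nothing_significant():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"a": rng.normal(size=80),
                       "y": rng.integers(0, 2, 80)})
    with pytest.warns(UserWarning):
        terms = select_multivariate_terms(df, "y", [TermSpec("a")])
    assert terms == []


# ---------------------------------------------------------------------------
# ROC

def test_roc_perfect_separation():
    r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == pytest.approx(1.0)
    assert r.cutoff == pytest.approx(6.5)
    assert r.cutoff_sens == 1.0 and r.cutoff_spec == 1.0


def test_roc_validation():
    with pytest.raises(ValueError):
        roc_analysis([1, 2, 3], [1, 1, 1])


def test_auc_mann_whitney_identity():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n1, n0 = rng.integers(5, 20), rng.integers(5, 20)
        scores = rng.permutation(np.arange(n1 + n0, dtype=float))  # tie-free
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        r = roc_analysis(scores, labels)
        u_neg, _ = mann_whitney(scores[labels == 0], scores[labels == 1])
        assert r.auc * n1 * n0 + u_neg == pytest.approx(n1 * n0)


def test_roc_cutoff_matches_bruteforce_minimizer():
    rng = np.random.default_rng(8)
    for _ in range(20):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            continue
        r = roc_analysis(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]

        def dist(t):
            sens = (pos >= t).mean()
            spec = (neg < t).mean()
            return math.hypot(1 - sens, 1 - spec)

        best = min(dist(t) for t in r.thresholds)
        assert dist(r.cutoff) == pytest.approx(best, abs=1e-12)


def test_roc_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(10)
    for _ in range(20):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        assert roc_analysis(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


def test_roc_null_auc_near_half():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=2000)
    labels = rng.permutation(np.r_[np.ones(1000, int), np.zeros(1000, int)])
    r = roc_analysis(scores, labels)
    assert 0.47 < r.auc < 0.53


def test_auc_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(12)
    scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 60)]
    labels = np.r_[np.ones(40, int), np.zeros(60, int)]
    auc = roc_analysis(scores, labels).auc
    lo, hi = auc_bootstrap_ci(scores, labels, n_boot=200, seed=0)
    assert lo <= auc <= hi


# ---------------------------------------------------------------------------
# dichotomization

def test_dichotomize_ge_convention_and_missing():
    df = pd.DataFrame({"v": [13.2, 13.19, np.nan]})
    out = dichotomize(df, "v", 13.2, new_name="ind")
    assert out["ind"].tolist()[:2] == [1.0, 0.0]
    assert np.isnan(out["ind"].iloc[2])
    with pytest.raises(ValueError):
        dichotomize(df, "v", float("nan"))
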