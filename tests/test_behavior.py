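"""Behavioral statistics: segmentation, signed-rank test, bias tests, ICC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bistableflow.behavior import (
    group_bias_test,
    icc_oneway,
    individual_bias,
    percept_time_fractions,
    segment_percepts,
    wilcoxon_signed_rank,
)
from bistableflow.containers import EventLog, PerceptPeriod


def make_events(rows, length=30.0):
    df = pd.DataFrame(rows, columns=["presentation_id", "time_s", "percept_code"])
    return EventLog(events=df, presentation_length=length)


def test_segment_percepts_half_open_periods():
    ev = make_events([(0, 1.0, "A"), (0, 4.0, "B"), (0, 9.0, "A"), (0, 12.0, "B")])
    periods = segment_percepts(ev)
    assert [(p.start_s, p.end_s, p.percept_code) for p in periods] == [
        (1.0, 4.0, "A"), (4.0, 9.0, "B"), (9.0, 12.0, "A"),
    ]


def test_segment_percepts_skips_single_press_presentations():
    ev = make_events([(0, 1.0, "A"), (1, 2.0, "B"), (1, 5.0, "A")])
    periods = segment_percepts(ev)
    assert len(periods) == 1 and periods[0].presentation_id == 1


def test_time_fractions_sum_to_100_and_include_unsure():
    periods = [
        PerceptPeriod(0, 0.0, 6.0, "A"),
        PerceptPeriod(0, 6.0, 8.0, "B"),
        PerceptPeriod(0, 8.0, 10.0, "unsure"),
    ]
    fr = percept_time_fractions(periods)
    assert sum(fr.values()) == pytest.approx(100.0)
    assert fr["A"] == pytest.approx(60.0)
    assert fr["unsure"] == pytest.approx(20.0)
    with pytest.raises(ValueError):
        percept_time_fractions([])


def test_signed_rank_statistic_matches_exact_enumeration():
    """W+ and exact p agree with brute-force enumeration over sign flips."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = 8
        d = rng.normal(0.4, 1.0, size=n)
        d = d[d != 0]
        w_pos, z, p, n_eff = wilcoxon_signed_rank(d, np.zeros_like(d))
        ranks = stats.rankdata(np.abs(d))
        assert w_pos == pytest.approx(float(ranks[d > 0].sum()))
        # exact two-sided p over all 2^n sign assignments
        stats_all = []
        for signs in itertools.product([1, -1], repeat=len(d)):
            stats_all.append(float(ranks[np.array(signs) > 0].sum()))
        stats_all = np.array(stats_all)
        mean_w = len(d) * (len(d) + 1) / 4
        p_exact = np.mean(np.abs(stats_all - mean_w) >= abs(w_pos - mean_w) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)


def test_signed_rank_sign_convention_and_zero_handling():
    x = np.array([3.0, 4.0, 5.0, 6.0, 2.0])
    y = np.array([1.0, 1.0, 1.0, 1.0, 2.0])  # one zero difference discarded
    w, z, p, n = wilcoxon_signed_rank(x, y)
    assert n == 4 and z > 0
    assert w == pytest.approx(10.0)  # all positive ranks
    w2, z2, _, _ = wilcoxon_signed_rank(y, x)
    assert z2 == pytest.approx(-z)


def test_group_bias_requires_five_participants_and_finds_preference():
    a = np.array([62, 58, 71, 55, 60, 65.0])
    b = 100 - a
    res = group_bias_test(a, b)
    assert res.preferred_code == "A"
    assert res.p < 0.05
    with pytest.raises(ValueError, match="at least 5"):
        group_bias_test(a[:4], b[:4])


def test_individual_bias_detects_longer_durations():
    rng = np.random.default_rng(11)
    periods = []
    t = 0.0
    for i in range(30):
        da = rng.gamma(6, 8 / 6)
        db = rng.gamma(6, 3 / 6)
        periods.append(PerceptPeriod(0, t, t + da, "A")); t += da
        periods.append(PerceptPeriod(0, t, t + db, "B")); t += db
    res = individual_bias(periods)
    assert res.preferred_code == "A" and res.p < 0.01
    # too few pairs -> NaN result, not an error
    small = individual_bias(periods[:4])
    assert np.isnan(small.z) and small.preferred_code is None


def brute_force_icc(m):
    """One-way ANOVA ICC computed by an independent route (group sums)."""
    n, k = m.shape
    groups = [m[i] for i in range(n)]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw), msb / msw


def test_icc_matches_brute_force_anova():
    rng = np.random.default_rng(13)
    for _ in range(5):
        m = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        icc, f, (df_b, df_w), p = icc_oneway(m)
        icc_ref, f_ref = brute_force_icc(m)
        assert icc == pytest.approx(icc_ref, abs=1e-10)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert (df_b, df_w) == (5, 12)
        assert p == pytest.approx(float(stats.f.sf(f, df_b, df_w)), abs=1e-12)


def test_icc_degrees_of_freedom_for_24_by_3_design():
    rng = np.random.default_rng(14)
    m = rng.normal(size=(24, 3))
    _, _, (df_b, df_w), _ = icc_oneway(m)
    assert (df_b, df_w) == (23, 48)


def test_icc_perfect_consistency_is_one():
    m = np.tile(np.arange(5.0)[:, None], (1, 4))
    icc, f, _, p = icc_oneway(m)
    assert icc == 1.0 and np.isinf(f) and p == 0.0


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_oneway(np.zeros((2, 3)))
    with pytest.raises(ValueError):
        icc_oneway(np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]]))
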