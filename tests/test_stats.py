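"""Clinical statistics: exact-test enumeration oracles, AUC pairwise oracle,
Kaplan-Meier/log-rank, dynamics classification and the full analysis report."""

import itertools
import math
from math import comb

import numpy as np
import pytest

from ccfdna.cohort import CohortConfig, PatientRecord, Timepoint, simulate_cohort
from ccfdna.stats import (
    Dynamics,
    classify_dynamics,
    fisher_exact,
    km_logrank,
    mann_whitney,
    roc_auc,
    run_response_analysis,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def mw_exact_oracle(a, b, alternative):
    """Exact Mann-Whitney p by enumerating every assignment of the pooled
    (untied) values to the two groups."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    n, m = len(a), len(b)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n + m) if i not in set(idx)]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    center = n * m / 2
    if alternative == "one-sided-less":
        p = np.mean(us <= u_obs)
    elif alternative == "one-sided-greater":
        p = np.mean(us >= u_obs)
    else:
        p = np.mean(np.abs(us - center) >= abs(u_obs - center))
    return float(p)


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all same-margin tables no more likely than observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):  # table [[k, r1-k], [c1-k, r2-(c1-k)]]
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return None
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        p = prob(k)
        if p is not None and p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def auc_pair_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "alt,expected",
    [("one-sided-less", 0.05), ("two-sided", 0.10), ("one-sided-greater", 1.0)],
)
def test_mann_whitney_fully_separated_triplets(alt, expected):
    res = mann_whitney([1, 2, 3], [4, 5, 6], alt)
    assert res.p_value == pytest.approx(expected)
    assert res.detail["exact"]


def test_mann_whitney_identical_groups_p_one():
    res = mann_whitney([1, 2, 3], [1, 2, 3], "two-sided")
    assert res.p_value == 1.0


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_matches_enumeration_oracle():
    """Exact small-sample p agrees with brute-force enumeration for every
    group-size pair up to 6+6 on random untied data."""
    rng = np.random.default_rng(0)
    for n, m in [(1, 1), (2, 3), (3, 3), (4, 5), (5, 5), (6, 6), (2, 6)]:
        for _ in range(3):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = list(vals[:n]), list(vals[n:])
            for alt in ("one-sided-less", "one-sided-greater", "two-sided"):
                assert mann_whitney(a, b, alt).p_value == pytest.approx(
                    mw_exact_oracle(a, b, alt), abs=1e-12
                ), (a, b, alt)


def test_mann_whitney_large_or_tied_uses_normal_approximation():
    rng = np.random.default_rng(1)
    a = rng.normal(size=30)
    b = rng.normal(size=40) + 1.0
    res = mann_whitney(a, b)
    assert not res.detail["exact"]
    assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# Fisher's exact
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[7, 0], [7, 10]], 0.0188),  # to 3 significant figures
        ([[1, 1], [1, 1]], 1.0),
        ([[5, 0], [0, 5]], 2 / 252),
    ],
)
def test_fisher_worked_examples(table, expected):
    assert fisher_exact(table).p_value == pytest.approx(expected, rel=5e-3)


def test_fisher_matches_enumeration_oracle_all_small_tables():
    """Agreement with the hypergeometric enumeration oracle over every 2x2
    table with all margins at most 12."""
    for a in range(0, 13):
        for b in range(0, 13 - a):
            for c in range(0, 13):
                for d in range(0, 13 - c):
                    if a + b == 0 and c + d == 0:
                        continue
                    if a + c == 0 and b + d == 0:
                        continue
                    t = [[a, b], [c, d]]
                    assert fisher_exact(t).p_value == pytest.approx(
                        fisher_oracle(t), abs=1e-9
                    ), t


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_auc_perfect_separation_and_antisymmetry():
    r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
    assert r.auc == 1.0
    r = roc_auc([1, 2, 3, 4], [1, 1, 0, 0])
    assert r.auc == 0.0


def test_auc_tie_counts_half():
    r = roc_auc([1, 2, 2, 3], [0, 0, 1, 1])
    assert r.auc == pytest.approx(0.875)


def test_auc_matches_pairwise_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 200))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        scores = rng.integers(0, 20, size=n).astype(float)  # ties likely
        if labels.all() or not labels.any():
            continue
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1


def test_auc_positive_direction_less():
    r = roc_auc([4, 3, 2, 1], [0, 0, 1, 1], positive_direction="less")
    assert r.auc == 1.0


def test_roc_curve_monotone_with_endpoints():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    r = roc_auc(scores, labels)
    assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
    assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


def test_auc_bootstrap_ci_is_seeded():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.5).astype(int)
    r1 = roc_auc(scores, labels, ci_method="bootstrap", n_boot=200, seed=9)
    r2 = roc_auc(scores, labels, ci_method="bootstrap", n_boot=200, seed=9)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


def test_auc_single_class_is_error():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def test_km_identical_groups_null():
    times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
    events = [1, 1, 0, 1, 0] * 2
    groups = ["a"] * 5 + ["b"] * 5
    res = km_logrank(times, events, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_km_early_events_vs_censored_significant():
    times = [1, 2, 3, 10, 10, 10]
    events = [1, 1, 1, 0, 0, 0]
    groups = ["a", "a", "a", "b", "b", "b"]
    res = km_logrank(times, events, groups)
    assert res.p_value < 0.05
    assert np.allclose(res.curves["b"]["survival"], 1.0)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, size=25).round(2) + 0.01
    res = km_logrank(
        np.concatenate([t, [1.0]]),
        [1] * 25 + [0],
        ["a"] * 25 + ["b"],
    )
    curve = res.curves["a"]
    for time, surv in zip(curve["time"], curve["survival"]):
        assert surv == pytest.approx((t > time).mean(), abs=1e-12)


def test_km_survival_monotone_and_bounded():
    rng = np.random.default_rng(8)
    t = rng.exponential(10, size=40) + 0.01
    e = (rng.random(40) < 0.7).astype(int)
    g = np.where(rng.random(40) < 0.5, "x", "y")
    if len(set(g)) < 2:
        g[0] = "x" if g[0] == "y" else "y"
    res = km_logrank(t, e, g)
    for curve in res.curves.values():
        s = curve["survival"].to_numpy()
        assert s[0] <= 1.0 + 1e-12
        assert np.all(np.diff(s) <= 1e-12)
        assert (curve["events"] <= curve["at_risk"]).all()


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "baseline,w2,expected",
    [
        (10.0, 12.0, Dynamics.INCREASE),
        (10.0, 10.0, Dynamics.NO_INCREASE),  # tie is conservative
        (10.0, 8.0, Dynamics.NO_INCREASE),
    ],
)
def test_classify_dynamics(baseline, w2, expected):
    series = {Timepoint(1, 1): baseline, Timepoint(2, 1): w2}
    assert classify_dynamics(series, "p").call is expected


def test_classify_dynamics_missing_timepoint_raises():
    with pytest.raises(ValueError, match="W2D1"):
        classify_dynamics({Timepoint(1, 1): 5.0}, "p7")


# ---------------------------------------------------------------------------
# full analysis report
# ---------------------------------------------------------------------------


def _patient(pid, trg, relapse, t, base, w2):
    return PatientRecord(
        patient_id=pid, trg=trg, relapse=relapse, time_to_event_months=t,
        series={Timepoint(1, 1): base, Timepoint(2, 1): w2},
    )


def test_report_perfect_separation_gives_auc_one():
    records = [
        _patient(f"cr{i}", 0, False, 30, 20, 1.0 + i) for i in range(5)
    ] + [
        _patient(f"res{i}", 2, i < 2, 20, 25, 50.0 + i) for i in range(7)
    ]
    report = run_response_analysis(records)
    row = report.table.set_index("analysis").loc["w2d1_pathcr_vs_residual"]
    assert row["auc"] == 1.0
    assert row["p_value"] < 0.01


def test_report_reproduces_printed_contingency_table():
    """A cohort constructed to show the 7/7 vs 7/17 increase split yields the
    Fisher table [[7,0],[7,10]] and its p-value."""
    records = []
    for i in range(7):  # relapsers, all increasing
        records.append(_patient(f"r{i}", 2, True, 12, 10.0, 20.0))
    for i in range(7):  # non-relapsers with an increase
        records.append(_patient(f"ni{i}", 1, False, 30, 10.0, 15.0))
    for i in range(10):  # non-relapsers without an increase
        records.append(_patient(f"nd{i}", 1, False, 30, 10.0, 5.0))
    report = run_response_analysis(records)
    row = report.table.set_index("analysis").loc["dynamics_increase_vs_relapse"]
    assert row["table"] == "[[7, 0], [7, 10]]"
    assert row["p_value"] == pytest.approx(0.0188, rel=5e-3)


def test_report_skips_underpowered_tests_with_reason():
    records = [_patient("p1", 0, False, 10, 5, 6), _patient("p2", 0, False, 10, 5, 4)]
    report = run_response_analysis(records)
    tab = report.table.set_index("analysis")
    assert tab.loc["w2d1_pathcr_vs_residual", "skipped_reason"] is not None
    assert report.n_tests == int(tab["p_value"].notna().sum())


def test_report_excludes_patients_missing_w2d1():
    records = [
        _patient(f"p{i}", 1, i % 2 == 0, 20, 10, 12) for i in range(6)
    ]
    records.append(
        PatientRecord("px", trg=1, relapse=False, time_to_event_months=9.0,
                      series={Timepoint(1, 1): 5.0})
    )
    report = run_response_analysis(records)
    assert any(pid == "px" for pid, _ in report.excluded)


def test_type_one_error_of_null_week2_comparison_quick():
    """Small-scale null calibration of the W2D1 comparison (the full 2,000
    cohort version runs in the acceptance suite)."""
    rejections = 0
    n_sims = 200
    null_medians = {
        "pathCR": {"W1D1": 30.0, "W2D1": 30.0},
        "residual": {"W1D1": 30.0, "W2D1": 30.0},
    }
    for s in range(n_sims):
        cfg = CohortConfig(
            medians=null_medians,
            relapse_prob_pathcr=0.25,
            relapse_prob_residual=0.25,
            couple_increase=False,  # identical distributions in both groups
            seed=40_000 + s,
        )
        records = simulate_cohort(cfg)
        a = [r.series[Timepoint(2, 1)] for r in records if r.path_cr]
        b = [r.series[Timepoint(2, 1)] for r in records if not r.path_cr]
        if len(a) < 2 or len(b) < 2:
            continue
        if mann_whitney(a, b, "two-sided").p_value < 0.05:
            rejections += 1
    assert 0.0 <= rejections / n_sims <= 0.09
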