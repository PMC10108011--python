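"""Treatment-response statistics for longitudinal c-cfDNA measurements.

Group comparisons use the Mann-Whitney U test (exact enumeration for small
untied samples, normal approximation with tie and continuity correction
otherwise), contingency tables use Fisher's exact test (two-sided by summing
hypergeometric probabilities at most that of the observed table), ROC AUC
comes with a DeLong (or stratified-bootstrap) confidence interval, and
survival is compared by Kaplan-Meier estimates with the log-rank test.

The dynamics classification dichotomizes patients by whether the combined
c-cfDNA level strictly increased from baseline (W1D1) to the first day of the
second treatment week (W2D1); a tie counts as no increase, the conservative
side for the negative-prognosis call.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import BASELINE, WEEK2, PatientRecord, Timepoint

__all__ = [
    "TestResult",
    "ROCResult",
    "SurvivalResult",
    "DynamicsCall",
    "Dynamics",
    "AnalysisReport",
    "mann_whitney",
    "fisher_exact",
    "roc_auc",
    "km_logrank",
    "classify_dynamics",
    "run_response_analysis",
]

_ALTERNATIVES = {
    "two-sided": "two-sided",
    "one-sided-less": "less",
    "one-sided-greater": "greater",
    "less": "less",
    "greater": "greater",
}

EXACT_MW_MAX_N = 8  # exact enumeration when the smaller group is this size or less


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of rank assignments) when the
    smaller group has at most 8 observations and the pooled data are untied;
    otherwise the normal approximation with tie and continuity correction is
    used.  ``alternative`` 'one-sided-less' means group A stochastically
    smaller.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alt = _ALTERNATIVES.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (min(a.size, b.size) <= EXACT_MW_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative=alt, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        method="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_a=int(a.size),
        n_b=int(b.size),
        detail={"exact": exact, "ties": bool(has_ties)},
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities at most that of the observed table (within
    a small relative tolerance for floating-point ties); the conditional
    odds ratio is reported alongside.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t != np.floor(t)) or np.any(t < 0):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if t.sum() == 0 or (t.sum(axis=0) == 0).all() or (t.sum(axis=1) == 0).all():
        raise ValueError("at least one margin must be positive")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        alternative="two-sided",
        n_a=int(t[0].sum()),
        n_b=int(t[1].sum()),
        detail={"table": t.tolist()},
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong or bootstrap CI
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float  # against AUC = 0.5
    fpr: np.ndarray
    tpr: np.ndarray
    positive_class: str
    n_positive: int
    n_negative: int
    ci_method: str

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError(
                f"CI ordering violated: {self.ci_low}, {self.auc}, {self.ci_high}"
            )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and variance via midrank placements."""
    m, n = pos.size, neg.size
    z = np.concatenate([pos, neg])
    tz = sps.rankdata(z)
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n          # placements of positives among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placements of negatives among positives
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_class: str = "positive",
    positive_direction: str = "greater",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ROCResult:
    """ROC AUC as the concordance probability (ties count 1/2).

    ``positive_direction`` 'greater' means higher scores indicate the
    positive class.  The confidence interval is DeLong by default;
    ``ci_method='bootstrap'`` uses a seeded stratified bootstrap.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    if positive_direction == "less":
        s = -s
    elif positive_direction != "greater":
        raise ValueError("positive_direction must be 'greater' or 'less'")

    pos, neg = s[y], s[~y]
    auc, var = _delong_variance(pos, neg)

    zq = sps.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        half = zq * math.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            aucs[i], _ = _delong_variance(bp, bn)
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    lo = min(max(float(lo), 0.0), auc)
    hi = max(min(float(hi), 1.0), auc)

    if var > 0:
        zstat = (auc - 0.5) / math.sqrt(var)
        p = 2 * sps.norm.sf(abs(zstat))
    else:
        p = 0.0 if auc != 0.5 else 1.0

    # curve with explicit (0,0) and (1,1) endpoints
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y.astype(int), s)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.insert(fpr, 0, 0.0), np.insert(tpr, 0, 0.0)
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.append(fpr, 1.0), np.append(tpr, 1.0)

    return ROCResult(
        auc=float(auc),
        ci_low=lo,
        ci_high=hi,
        p_value=float(min(max(p, 0.0), 1.0)),
        fpr=fpr,
        tpr=tpr,
        positive_class=positive_class,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, events, survival
    statistic: float
    p_value: float
    n_per_group: dict[str, int]


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> SurvivalResult:
    """Kaplan-Meier estimates per group plus the log-rank test.

    Two groups give the classic 1-df log-rank chi-square; more give the
    k-sample generalization.  A fully censored group is fine (its curve stays
    at 1).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    g = np.asarray(groups)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    labels = pd.unique(g)
    if labels.size < 2:
        raise ValueError("need at least two groups")

    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(lab))
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[str(lab)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "events": tab["observed"].to_numpy(dtype=int),
                "survival": surv.reindex(tab.index).to_numpy(dtype=float),
            }
        )

    if labels.size == 2:
        m = g == labels[0]
        res = logrank_test(t[m], t[~m], e[m], e[~m])
    else:
        res = multivariate_logrank_test(t, g, e)
    return SurvivalResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group={str(lab): int((g == lab).sum()) for lab in labels},
    )


# ---------------------------------------------------------------------------
# dynamics classification
# ---------------------------------------------------------------------------


class Dynamics(enum.Enum):
    INCREASE = "INCREASE"
    NO_INCREASE = "NO_INCREASE"


@dataclass(frozen=True)
class DynamicsCall:
    patient_id: str
    baseline: float
    w2d1: float
    call: Dynamics


def classify_dynamics(
    series: Mapping[Timepoint, float], patient_id: str = ""
) -> DynamicsCall:
    """INCREASE iff the W2D1 value strictly exceeds the W1D1 baseline;
    equality is NO_INCREASE.  Raises if either timepoint is missing."""
    if BASELINE not in series or WEEK2 not in series:
        missing = [tp.label for tp in (BASELINE, WEEK2) if tp not in series]
        raise ValueError(f"patient {patient_id or '?'}: missing timepoint(s) {missing}")
    v1, v2 = float(series[BASELINE]), float(series[WEEK2])
    call = Dynamics.INCREASE if v2 > v1 else Dynamics.NO_INCREASE
    return DynamicsCall(patient_id=patient_id, baseline=v1, w2d1=v2, call=call)


# ---------------------------------------------------------------------------
# end-to-end response analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    table: pd.DataFrame
    dynamics: list[DynamicsCall]
    excluded: list[tuple[str, str]]  # (patient_id, reason)
    survival: SurvivalResult | None
    rocs: dict[str, ROCResult]
    n_tests: int

    def to_json(self) -> str:
        rows = self.table.where(pd.notna(self.table), None).to_dict(orient="records")
        return json.dumps(
            {
                "tests": rows,
                "n_tests": self.n_tests,
                "excluded_patients": self.excluded,
            },
            indent=2,
        )


def _row(analysis: str, result: TestResult | None, skipped: str | None = None, **extra):
    base = {
        "analysis": analysis,
        "method": result.method if result else None,
        "alternative": result.alternative if result else None,
        "n_a": result.n_a if result else None,
        "n_b": result.n_b if result else None,
        "statistic": result.statistic if result else None,
        "p_value": result.p_value if result else None,
        "skipped_reason": skipped,
    }
    base.update(extra)
    return base


def run_response_analysis(
    records: Sequence[PatientRecord],
    healthy_scores: Sequence[float] | None = None,
    dynamics_subgroup: Iterable[str] | None = None,
    roc_seed: int = 0,
) -> AnalysisReport:
    """Run the full panel of response analyses on a cohort.

    (a) healthy vs patient baseline comparison plus ROC, when healthy-control
    scores are supplied; (b) baseline c-cfDNA in good responders (TRG 0-1)
    vs poor responders (TRG 2-3), one-tailed with responders pre-registered
    lower; (c) W2D1 c-cfDNA in pathCR vs residual disease, two-tailed, with
    ROC; (d) Fisher's exact test of the W1D1->W2D1 increase against relapse,
    optionally restricted to an explicit patient subgroup; (e) Kaplan-Meier /
    log-rank of time to event by dynamics group.  Tests with fewer than two
    observations in an arm are skipped with an explicit reason.  P-values are
    reported unadjusted; the total count of performed tests is part of the
    report.
    """
    rows = []
    rocs: dict[str, ROCResult] = {}

    def values_at(tp: Timepoint, recs: Sequence[PatientRecord]) -> np.ndarray:
        return np.asarray(
            [r.series[tp] for r in recs if tp in r.series], dtype=float
        )

    # (a) healthy vs patients at baseline
    if healthy_scores is not None:
        patient_base = values_at(BASELINE, records)
        healthy = np.asarray(healthy_scores, dtype=float)
        if patient_base.size >= 2 and healthy.size >= 2:
            res = mann_whitney(healthy, patient_base, "two-sided")
            roc = roc_auc(
                np.concatenate([healthy, patient_base]),
                np.r_[np.zeros(healthy.size), np.ones(patient_base.size)],
                positive_class="patient",
                seed=roc_seed,
            )
            rocs["healthy_vs_patient"] = roc
            rows.append(
                _row(
                    "healthy_vs_patient_baseline",
                    res,
                    auc=roc.auc,
                    ci_low=roc.ci_low,
                    ci_high=roc.ci_high,
                )
            )
        else:
            rows.append(
                _row("healthy_vs_patient_baseline", None, "fewer than 2 per arm")
            )

    # (b) baseline by response: TRG 0-1 (responders) vs TRG 2-3, responders lower
    responders = [r for r in records if r.trg <= 1 and BASELINE in r.series]
    poor = [r for r in records if r.trg >= 2 and BASELINE in r.series]
    if len(responders) >= 2 and len(poor) >= 2:
        res = mann_whitney(
            values_at(BASELINE, responders),
            values_at(BASELINE, poor),
            "one-sided-less",
        )
        rows.append(_row("baseline_trg01_vs_trg23", res))
    else:
        rows.append(_row("baseline_trg01_vs_trg23", None, "fewer than 2 per arm"))

    # (c) W2D1 by pathCR
    pathcr = [r for r in records if r.path_cr and WEEK2 in r.series]
    residual = [r for r in records if not r.path_cr and WEEK2 in r.series]
    if len(pathcr) >= 2 and len(residual) >= 2:
        v_cr, v_res = values_at(WEEK2, pathcr), values_at(WEEK2, residual)
        res = mann_whitney(v_cr, v_res, "two-sided")
        roc = roc_auc(
            np.concatenate([v_cr, v_res]),
            np.r_[np.zeros(v_cr.size), np.ones(v_res.size)],
            positive_class="residual_disease",
            seed=roc_seed,
        )
        rocs["w2d1_pathcr"] = roc
        rows.append(
            _row(
                "w2d1_pathcr_vs_residual",
                res,
                auc=roc.auc,
                ci_low=roc.ci_low,
                ci_high=roc.ci_high,
                median_a=float(np.median(v_cr)),
                median_b=float(np.median(v_res)),
            )
        )
    else:
        rows.append(_row("w2d1_pathcr_vs_residual", None, "fewer than 2 per arm"))

    # dynamics calls (shared by d and e)
    calls: list[DynamicsCall] = []
    excluded: list[tuple[str, str]] = []
    call_by_pid: dict[str, DynamicsCall] = {}
    for r in records:
        try:
            c = classify_dynamics(r.series, r.patient_id)
        except ValueError as exc:
            excluded.append((r.patient_id, str(exc)))
            continue
        calls.append(c)
        call_by_pid[r.patient_id] = c

    # (d) increase x relapse Fisher's exact
    subgroup = set(dynamics_subgroup) if dynamics_subgroup is not None else None
    analyzable = [
        r
        for r in records
        if r.patient_id in call_by_pid
        and (subgroup is None or r.patient_id in subgroup)
    ]
    n_rel = sum(r.relapse for r in analyzable)
    n_norel = len(analyzable) - n_rel
    if n_rel >= 1 and n_norel >= 1:
        tab = [[0, 0], [0, 0]]
        for r in analyzable:
            inc = call_by_pid[r.patient_id].call is Dynamics.INCREASE
            tab[0 if r.relapse else 1][0 if inc else 1] += 1
        res = fisher_exact(tab)
        rows.append(_row("dynamics_increase_vs_relapse", res, table=str(tab)))
    else:
        rows.append(
            _row("dynamics_increase_vs_relapse", None, "a relapse arm is empty")
        )

    # (e) survival by dynamics group
    survival = None
    with_call = [r for r in records if r.patient_id in call_by_pid]
    labels = [call_by_pid[r.patient_id].call.value for r in with_call]
    if len(set(labels)) == 2 and len(with_call) >= 4:
        survival = km_logrank(
            [r.time_to_event_months for r in with_call],
            [int(r.relapse) for r in with_call],
            labels,
        )
        rows.append(
            _row(
                "km_logrank_by_dynamics",
                TestResult(
                    method="log-rank",
                    statistic=survival.statistic,
                    p_value=survival.p_value,
                    alternative="two-sided",
                    n_a=survival.n_per_group.get("INCREASE", 0),
                    n_b=survival.n_per_group.get("NO_INCREASE", 0),
                ),
            )
        )
    else:
        rows.append(_row("km_logrank_by_dynamics", None, "need both dynamics groups"))

    table = pd.DataFrame(rows)
    n_tests = int(table["p_value"].notna().sum())
    return AnalysisReport(
        table=table,
        dynamics=calls,
        excluded=excluded,
        survival=survival,
        rocs=rocs,
        n_tests=n_tests,
    )
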