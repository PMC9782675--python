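"""Post-transplant outcome comparison across clusters.

Time-to-event outcomes (patient death, death-censored graft failure,
all-cause graft failure) are summarized by Kaplan-Meier survival at 1 and
5 years and compared with the G-group log-rank test; early binary outcomes
(primary non-function, delayed graft function, 1-year acute rejection —
the registry records rejection only as a within-first-year indicator, so it
is treated as binary) are summarized as counts/percentages and compared
with Pearson chi-squared tests.  One-way ANOVA is provided for continuous
comparisons.  Kaplan-Meier fitting and the log-rank statistic go through
lifelines; chi-squared and ANOVA through scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import CohortError
from .consensus import ClusterAssignment

SURVIVAL_OUTCOMES = {
    "death": "patient survival",
    "dc_graft": "death-censored graft survival",
    "graft": "overall graft survival",
}
BINARY_OUTCOMES = (
    "primary_non_function",
    "delayed_graft_function",
    "rejection_1yr",
)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str
    undefined: bool = False


@dataclass
class KMEstimate:
    """Product-limit survival curve (right-continuous step function)."""

    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray
    max_followup: float

    def evaluate(self, t: float) -> float:
        return survival_at(self, t)[0]


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Ties between events and censorings at the same time are resolved
    events-first (the standard product-limit convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != len(events):
        raise CohortError("times and events must have equal length")
    if (times < 0).any():
        raise CohortError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival = sf.loc[ev.index].to_numpy(dtype=float)
    # Greenwood variance: S(t)^2 * sum d/(n(n-d)) over event times <= t
    d = ev["observed"].to_numpy(dtype=float)
    n_risk = ev["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    greenwood = survival**2 * np.cumsum(terms)
    return KMEstimate(
        event_times=event_times,
        survival=survival,
        at_risk=n_risk.astype(int),
        events=d.astype(int),
        greenwood_var=greenwood,
        max_followup=float(times.max(initial=0.0)),
    )


def survival_at(km: KMEstimate, t: float) -> tuple[float, bool]:
    """Right-continuous S(t) and an extrapolation flag set when t exceeds
    the last observed follow-up time."""
    if t < 0:
        raise CohortError("t must be non-negative")
    extrapolated = t > km.max_followup
    idx = np.searchsorted(km.event_times, t, side="right") - 1
    value = 1.0 if idx < 0 else float(km.survival[idx])
    return value, extrapolated


def logrank_test(groups: list[tuple]) -> TestResult:
    """G-group log-rank test; statistic ~ chi-squared(G-1) under the null."""
    if len(groups) < 2:
        raise CohortError("log-rank needs at least 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise CohortError("each group needs at least one subject")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    df = len(groups) - 1
    if events.sum() == 0:
        return TestResult(0.0, df, 1.0, "log-rank", undefined=True)
    res = multivariate_logrank_test(times, labels, events)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):  # degenerate variance (e.g. identical groups)
        return TestResult(0.0, df, 1.0, "log-rank", undefined=True)
    return TestResult(stat, df, float(res.p_value), "log-rank")


def chi_squared_test(contingency) -> TestResult:
    """Pearson chi-squared on an r x c count table, no continuity
    correction; df = (r-1)(c-1)."""
    table = np.asarray(contingency, dtype=float)
    if (table < 0).any():
        raise CohortError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CohortError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        float(res.statistic), float(res.dof), float(res.pvalue), "chi-squared"
    )


def anova_oneway(groups: list) -> TestResult:
    """One-way ANOVA F test, df = (G-1, N-G).

    Degenerate data (zero within-group variance) yields F = 0 with p = 1
    when group means are equal, and an infinite-F flag (p = 0) otherwise.
    """
    if len(groups) < 2:
        raise CohortError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise CohortError("each group needs at least one observation")
    n_total = sum(len(a) for a in arrays)
    G = len(arrays)
    if n_total <= G:
        raise CohortError("total n must exceed the number of groups")
    df = (G - 1, n_total - G)
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within == 0:
        means = [a.mean() for a in arrays]
        if np.allclose(means, means[0]):
            return TestResult(0.0, df[0], 1.0, "anova")
        return TestResult(float("inf"), df[0], 0.0, "anova", undefined=True)
    res = stats.f_oneway(*arrays)
    return TestResult(float(res.statistic), df[0], float(res.pvalue), "anova")


def percent(count: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (presentation
    convention for outcome tables)."""
    if denom <= 0:
        raise CohortError("denominator must be positive")
    pct = Decimal(count) / Decimal(denom) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def outcome_summary(
    outcomes: pd.DataFrame,
    assignment: ClusterAssignment,
    horizons: tuple[float, ...] = (1.0, 5.0),
) -> pd.DataFrame:
    """Cluster-wise outcome table with per-outcome comparison p-values.

    One row per outcome measure; per cluster, binary outcomes report
    "count (pct%)" and survival outcomes report KM survival percentages at
    the horizons.  Binary outcomes carry chi-squared p-values, survival
    outcomes log-rank p-values; a Bonferroni-adjusted column (across the
    outcome comparisons) is emitted alongside for transparency.
    """
    labels = np.asarray(assignment.labels)
    if len(labels) != len(outcomes):
        raise CohortError("assignment does not cover the outcome table")
    clusters = sorted(np.unique(labels))
    rows = []

    def check(col: str) -> None:
        if col not in outcomes.columns:
            raise CohortError(f"outcome column {col!r} missing")

    n_comparisons = 0
    for name in BINARY_OUTCOMES:
        if name in outcomes.columns:
            n_comparisons += 1
    for name in SURVIVAL_OUTCOMES:
        if f"{name}_time" in outcomes.columns:
            n_comparisons += 1

    for name in BINARY_OUTCOMES:
        check(name)
        row = {"outcome": name, "measure": "count (pct)"}
        counts = []
        for c in clusters:
            in_c = labels == c
            n_c = int(in_c.sum())
            k_c = int(outcomes.loc[in_c, name].sum())
            counts.append([k_c, n_c - k_c])
            row[f"cluster_{c}"] = f"{k_c} ({percent(k_c, n_c)}%)"
        test = chi_squared_test(np.asarray(counts).T)
        row["p_value"] = test.p_value
        row["p_bonferroni"] = min(1.0, test.p_value * n_comparisons)
        rows.append(row)

    for name, label in SURVIVAL_OUTCOMES.items():
        tcol, ecol = f"{name}_time", f"{name}_event"
        check(tcol)
        check(ecol)
        groups = []
        kms = {}
        for c in clusters:
            in_c = labels == c
            t = outcomes.loc[in_c, tcol].to_numpy(dtype=float)
            e = outcomes.loc[in_c, ecol].to_numpy(dtype=int)
            groups.append((t, e))
            kms[c] = km_estimate(t, e)
        test = logrank_test(groups)
        for h in horizons:
            row = {"outcome": label, "measure": f"KM survival at {h:g} yr (%)"}
            for c in clusters:
                s, _ = survival_at(kms[c], h)
                row[f"cluster_{c}"] = percent(round(s * 1e9), 1e9)  # s*100, half-up
            row["p_value"] = test.p_value
            row["p_bonferroni"] = min(1.0, test.p_value * n_comparisons)
            rows.append(row)
    return pd.DataFrame(rows)


def km_curves(
    outcomes: pd.DataFrame, assignment: ClusterAssignment, outcome: str
) -> pd.DataFrame:
    """Plot-ready KM step curves per cluster for one time-to-event
    outcome: columns time, survival, at_risk, cluster."""
    labels = np.asarray(assignment.labels)
    tcol, ecol = f"{outcome}_time", f"{outcome}_event"
    frames = []
    for c in sorted(np.unique(labels)):
        in_c = labels == c
        km = km_estimate(
            outcomes.loc[in_c, tcol].to_numpy(dtype=float),
            outcomes.loc[in_c, ecol].to_numpy(dtype=int),
        )
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "time": np.concatenate([[0.0], km.event_times]),
                    "survival": np.concatenate([[1.0], km.survival]),
                    "at_risk": np.concatenate([[int(in_c.sum())], km.at_risk]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
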