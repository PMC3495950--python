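"""Case/control statistics on validated peak clusters.

Heights and areas are compared with a Welch two-sample t-test and a
Mann-Whitney U test; presence/absence (prevalence) is compared with a
Fisher exact test carrying the mid-P correction, which counts only half
the observed table's probability and so is less conservative than the
plain exact test.  No multiple-testing correction is applied; reports
carry an explicit warning to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import PeakCluster

__all__ = [
    "TestKind",
    "ClusterTestResult",
    "two_sample_t",
    "mann_whitney_u",
    "fisher_midp",
    "cluster_report",
    "NO_CORRECTION_WARNING",
]

NO_CORRECTION_WARNING = (
    "WARNING: p-values are not corrected for multiple testing"
)


class TestKind(str, Enum):
    T_AREA = "t_area"
    T_HEIGHT = "t_height"
    U_AREA = "u_area"
    U_HEIGHT = "u_height"
    FISHER_MIDP = "fisher_midp"


@dataclass
class ClusterTestResult:
    mean_mz: float
    test: TestKind
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _summaries(a: np.ndarray, b: np.ndarray) -> dict:
    def one(v: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "n": int(len(v)),
        }

    return {"a": one(a), "b": one(b)}


def two_sample_t(
    a, b, mean_mz: float = np.nan, test: TestKind = TestKind.T_HEIGHT
) -> ClusterTestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    flags = {}
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        stat, p = 0.0, 1.0
        flags["degenerate"] = True
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(stat), float(p)
        if np.isnan(p):
            stat, p = 0.0, 1.0
            flags["degenerate"] = True
    return ClusterTestResult(
        mean_mz=mean_mz, test=test, statistic=stat, p_value=p,
        group_summaries=_summaries(a, b), flags=flags,
    )


def mann_whitney_u(
    a, b, mean_mz: float = np.nan, test: TestKind = TestKind.U_HEIGHT
) -> ClusterTestResult:
    """Two-sided Mann-Whitney U: exact enumeration when the smaller group
    has <= 8 values and there are no ties, normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need at least 1 value per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a), len(b)) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ClusterTestResult(
        mean_mz=mean_mz,
        test=test,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_summaries=_summaries(a, b),
        flags={"exact": exact},
    )


def fisher_midp_one_tailed(table: np.ndarray) -> float:
    """One-tailed mid-P in the observed direction: the probability of
    strictly more extreme tables plus half the observed table's
    probability, under the hypergeometric null with fixed margins.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be non-negative 2x2 counts")
    x = int(table[0, 0])
    row1 = int(table[0].sum())
    col1 = int(table[:, 0].sum())
    total = int(table.sum())
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        raise ValueError("both margins must be positive")
    rv = stats.hypergeom(total, col1, row1)
    expected = row1 * col1 / total
    if x <= expected:
        tail = float(rv.cdf(x - 1)) if x > 0 else 0.0
    else:
        tail = float(rv.sf(x))
    return tail + 0.5 * float(rv.pmf(x))


def fisher_midp(table, mean_mz: float = np.nan) -> ClusterTestResult:
    """Two-sided mid-P Fisher exact test: twice the one-tailed mid-P,
    capped at 1.
    """
    table = np.asarray(table, dtype=int)
    one = fisher_midp_one_tailed(table)
    p = min(1.0, 2.0 * one)
    n1, n2 = int(table[0].sum()), int(table[1].sum())
    return ClusterTestResult(
        mean_mz=mean_mz,
        test=TestKind.FISHER_MIDP,
        statistic=float(table[0, 0]),
        p_value=p,
        group_summaries={
            "a": {"prevalence": table[0, 0] / n1 if n1 else np.nan, "n": n1},
            "b": {"prevalence": table[1, 0] / n2 if n2 else np.nan, "n": n2},
        },
        flags={"one_tailed_midp": one},
    )


def cluster_report(
    clusters: list[PeakCluster],
    group_of: dict[str, str],
    group_a: str,
    group_b: str,
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run all five tests on every cluster and keep rows with p < alpha.

    ``group_of`` maps spectrum id to group label; ``n_a``/``n_b`` are the
    spectra counts per group (the Fisher denominators).  The returned
    frame's ``attrs['warning']`` carries the no-correction notice.
    """
    if not clusters:
        raise ValueError("no clusters to report on")
    rows = []
    for cl in clusters:
        ha, hb, aa, ab = [], [], [], []
        present_a = present_b = 0
        for p in cl.members:
            g = group_of.get(p.spectrum_id)
            if g == group_a:
                present_a += 1
                ha.append(p.height)
                aa.append(p.area)
            elif g == group_b:
                present_b += 1
                hb.append(p.height)
                ab.append(p.area)
        results: list[ClusterTestResult] = []
        if len(ha) >= 2 and len(hb) >= 2:
            results.append(two_sample_t(ha, hb, cl.mean_mz, TestKind.T_HEIGHT))
            results.append(two_sample_t(aa, ab, cl.mean_mz, TestKind.T_AREA))
        if ha and hb:
            results.append(mann_whitney_u(ha, hb, cl.mean_mz, TestKind.U_HEIGHT))
            results.append(mann_whitney_u(aa, ab, cl.mean_mz, TestKind.U_AREA))
        table = [[present_a, n_a - present_a], [present_b, n_b - present_b]]
        if n_a > 0 and n_b > 0 and (present_a + present_b) > 0 and (
            (n_a - present_a) + (n_b - present_b)
        ) > 0:
            results.append(fisher_midp(table, cl.mean_mz))
        for r in results:
            if r.p_value < alpha:
                summ = r.group_summaries
                rows.append(
                    {
                        "mean_mz": r.mean_mz,
                        "test": r.test.value,
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "group_a_summary": summ.get("a"),
                        "group_b_summary": summ.get("b"),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["mean_mz", "test", "statistic", "p_value",
                 "group_a_summary", "group_b_summary"],
    )
    df.attrs["warning"] = NO_CORRECTION_WARNING
    df.attrs["groups"] = (group_a, group_b)
    return df.sort_values(["p_value", "mean_mz"]).reset_index(drop=True)
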