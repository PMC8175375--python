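"""Cohort-level aggregation and paired tissue comparisons.

Per-patient metrics (peak enhancement, artery-normalized AUC) are
collected into a long-format table, summarized per tissue group
(count / sum / average / sample variance), and compared with paired
t-tests between tissue types.  "Brain" in the comparisons maps to the
``white_matter`` label: white matter is the measurable low-perfusion
reference, grey matter being too small or poorly visualized to measure
reliably in every case.

Missing data are handled by pairwise-complete deletion: each comparison
drops only the patients missing a value on either side, so removing one
patient's tumor value leaves the artery-brain comparison at full n while
the tumor comparisons run on n-1 pairs.

No multiple-testing adjustment is applied; p-values are raw two-sided
paired-t probabilities compared against the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUPPORTED_METRICS = ("peak_enhancement", "normalized_auc")

#: (comparison label, first tissue, second tissue); "brain" == white_matter
COMPARISONS = (
    ("artery_vs_brain", "artery", "white_matter"),
    ("artery_vs_tumor", "artery", "tumor"),
    ("brain_vs_tumor", "white_matter", "tumor"),
)


@dataclass
class CohortTable:
    """Long-format per-patient metric table.

    ``records`` is a list of (patient_id, tissue_label, metric_name,
    value) tuples with at most one value per (patient, tissue, metric).
    """

    records: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(p, t, m) for p, t, m, _ in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (patient, tissue, metric) entries")
        for p, t, m, v in self.records:
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for ({p}, {t}, {m})")
            if m == "normalized_auc" and v < 0:
                raise ValueError(f"normalized_auc must be >= 0, got {v} for {p}/{t}")

    def add(self, patient_id: str, tissue: str, metric: str, value: float) -> None:
        self.records.append((patient_id, tissue, metric, float(value)))
        self.__post_init__()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["patient_id", "tissue", "metric", "value"]
        )

    def pivot(self, metric: str) -> pd.DataFrame:
        """Patient x tissue grid for one metric (NaN where missing)."""
        df = self.to_frame()
        df = df[df["metric"] == metric]
        return df.pivot(index="patient_id", columns="tissue", values="value")

    @classmethod
    def from_summary_frames(cls, frames: Iterable[pd.DataFrame]) -> "CohortTable":
        """Build from per-clip summary tables (as written by tic_analysis)."""
        table = cls()
        for df in frames:
            for _, row in df.iterrows():
                for metric in SUPPORTED_METRICS:
                    val = row.get(metric)
                    if val is not None and pd.notna(val):
                        table.records.append(
                            (str(row["patient_id"]), str(row["roi_label"]), metric, float(val))
                        )
        table.__post_init__()
        return table


@dataclass
class GroupSummary:
    """Count / sum / average / sample variance for one tissue group."""

    group: str
    count: int
    sum: float
    average: float
    variance: float | None  # n-1 denominator; absent for a single record

    def __post_init__(self) -> None:
        if self.count >= 1 and abs(self.average * self.count - self.sum) > 1e-9 * max(
            1.0, abs(self.sum)
        ):
            raise ValueError("inconsistent group summary: average * count != sum")


@dataclass
class PairedTestResult:
    """Two-sided paired t-test between two tissue types."""

    comparison: str
    metric: str
    n_pairs: int
    mean_difference: float
    t_statistic: float
    p_value: float
    significant: bool | None = None


def summarize_groups(table: CohortTable, metric: str) -> list[GroupSummary]:
    """Per-tissue count, sum, arithmetic mean and sample (n-1) variance.

    Groups with a single record report the variance as absent.  Groups
    appear in sorted label order.
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {SUPPORTED_METRICS}")
    df = table.to_frame()
    df = df[df["metric"] == metric]
    out = []
    for group, vals in df.groupby("tissue")["value"]:
        v = vals.to_numpy()
        out.append(
            GroupSummary(
                group=str(group),
                count=len(v),
                sum=float(v.sum()),
                average=float(v.mean()),
                variance=float(v.var(ddof=1)) if len(v) >= 2 else None,
            )
        )
    return out


def paired_t_test(
    x: Sequence[float], y: Sequence[float], comparison: str = "", metric: str = ""
) -> PairedTestResult:
    """Two-sided paired t-test on pairwise-complete observations.

    Pairs with a missing (NaN) side are dropped first.  The statistic is
    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and sd the n-1 sample
    standard deviation; p comes from Student's t with n-1 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    d = x - y
    if np.all(d == d[0]) and d.std(ddof=1) == 0:
        raise ValueError("all paired differences identical: degenerate variance")
    res = stats.ttest_rel(x, y)
    return PairedTestResult(
        comparison=comparison,
        metric=metric,
        n_pairs=n,
        mean_difference=float(d.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_all(
    table: CohortTable, metric: str, alpha: float = 0.05
) -> list[PairedTestResult]:
    """Run the pairwise tissue comparisons for one metric.

    For ``peak_enhancement``: artery-brain, artery-tumor, brain-tumor.
    For ``normalized_auc``: only brain-tumor — the artery's normalized
    AUC is identically 1, so artery comparisons are not applicable and
    are omitted.  Each result is annotated as significant at ``alpha``
    (unadjusted).
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {SUPPORTED_METRICS}")
    grid = table.pivot(metric)
    needed = (
        {"tumor", "white_matter"} if metric == "normalized_auc"
        else {"artery", "tumor", "white_matter"}
    )
    missing = sorted(needed - set(grid.columns))
    if missing:
        raise ValueError(f"tissue(s) absent from cohort table: {missing}")
    results = []
    for label, a, b in COMPARISONS:
        if metric == "normalized_auc" and "artery" in (a, b):
            continue
        res = paired_t_test(grid[a], grid[b], comparison=label, metric=metric)
        res.significant = res.p_value < alpha
        results.append(res)
    return results


def groups_to_csv(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    rows = [
        {"group": s.group, "count": s.count, "sum": s.sum,
         "average": s.average, "variance": s.variance}
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def tests_to_csv(results: Sequence[PairedTestResult], path: str | Path) -> None:
    rows = [
        {"comparison": r.comparison, "metric": r.metric, "n_pairs": r.n_pairs,
         "mean_difference": r.mean_difference, "t": r.t_statistic,
         "p": r.p_value, "significant": r.significant}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
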