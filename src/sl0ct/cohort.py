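"""Adverse-event incidence and a two-proportion comparison.

Small worked-example module for two-arm surgical cohorts: per-
complication counts are reduced to an incidence (each counted case is
treated as a distinct patient) and two arms are compared with a Pearson
chi-square test on the 2x2 events / non-events table.

A bundled example dataset describes postoperative adverse events after
radical gastrectomy in two arms of 50 patients stratified by immune
status (CD4+ T-cell count below vs. above 200 cells/uL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from scipy import stats

EVENT_NAMES = (
    "gastrointestinal dysfunction",
    "wound infection",
    "anastomotic leakage",
    "pulmonary infection",
    "pleural effusion",
)


@dataclass
class AdverseEventCounts:
    """Per-complication case counts for one cohort arm of size ``n``."""

    label: str
    n: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size n must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("event counts must be nonnegative")
        if self.total_events > self.n:
            raise ValueError(
                f"total events {self.total_events} exceed group size {self.n}")

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


def control_arm() -> AdverseEventCounts:
    """Example low-CD4 arm: 2+3+2+4+1 = 12 events among 50 patients."""
    return AdverseEventCounts(
        label="control (CD4+ < 200 cells/uL)", n=50,
        counts=dict(zip(EVENT_NAMES, (2, 3, 2, 4, 1))))


def experimental_arm() -> AdverseEventCounts:
    """Example high-CD4 arm: 1+1+0+2+0 = 4 events among 50 patients."""
    return AdverseEventCounts(
        label="experimental (CD4+ > 200 cells/uL)", n=50,
        counts=dict(zip(EVENT_NAMES, (1, 1, 0, 2, 0))))


def incidence(c: AdverseEventCounts) -> float:
    """Adverse-event incidence in percent: 100 * total events / n.

    Assumes one event per affected patient (counts are distinct
    patients), so the result is an exact percentage of the arm size.
    """
    return 100.0 * c.total_events / c.n


def two_proportion_test(c1: AdverseEventCounts, c2: AdverseEventCounts,
                        correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of equal incidence between two arms.

    Builds the 2x2 table of (events, non-events) per arm and returns
    (statistic, p-value) with 1 degree of freedom.  Yates continuity
    correction is off by default (the conventional large-sample test);
    enable with ``correction=True``.  Degenerate tables (a zero margin)
    raise ``ValueError``.
    """
    e1, e2 = c1.total_events, c2.total_events
    table = [[e1, c1.n - e1], [e2, c2.n - e2]]
    if e1 + e2 == 0 or (c1.n - e1) + (c2.n - e2) == 0:
        raise ValueError("degenerate table: a margin of the 2x2 table is zero")
    if e1 == e2 and c1.n == c2.n:
        return 0.0, 1.0  # identical arms; chi2_contingency also yields 0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
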