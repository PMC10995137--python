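"""Contingency statistics for chamber-expression cohorts.

Embryos injected with a reporter construct are classified by cardiac
expression pattern — atrium only, ventricle only, or both chambers — and
constructs are compared per category with 2x2 chi-square tests (category
vs rest, cohort vs cohort), without continuity correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import chi2_contingency

CATEGORIES = ("atrium", "ventricle", "both")


@dataclass(frozen=True)
class CohortCounts:
    construct: str
    n_at: int
    n_vt: int
    n_both: int
    n_total: int

    def __post_init__(self):
        if min(self.n_at, self.n_vt, self.n_both) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_at + self.n_vt + self.n_both > self.n_total:
            raise ValueError("category counts exceed total")

    def count(self, category: str) -> int:
        return {"atrium": self.n_at, "ventricle": self.n_vt, "both": self.n_both}[category]


def proportions(c: CohortCounts) -> dict[str, dict[str, float]]:
    """Category fractions and integer-rounded percentages."""
    if c.n_total <= 0:
        raise ValueError("zero total")
    out = {}
    for cat in CATEGORIES:
        frac = c.count(cat) / c.n_total
        out[cat] = {"fraction": frac, "percent": round(frac * 100)}
    return out


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float
    low_expected: bool  # True when any expected cell < 1


def chisq_compare(
    a: CohortCounts, b: CohortCounts, category: str, correction: bool = False
) -> ChisqResult:
    """2x2 chi-square of ``category`` vs the rest between two cohorts."""
    if a.n_total == 0 or b.n_total == 0:
        raise ValueError("both cohorts need nonzero totals")
    table = [
        [a.count(category), a.n_total - a.count(category)],
        [b.count(category), b.n_total - b.count(category)],
    ]
    res = chi2_contingency(table, correction=correction)
    return ChisqResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        low_expected=bool((res.expected_freq < 1).any()),
    )


def read_cohorts(path: str | Path) -> list[CohortCounts]:
    """CSV with columns construct, n_at, n_vt, n_both, n_total."""
    df = pd.read_csv(path, comment="#")
    return [
        CohortCounts(str(r.construct), int(r.n_at), int(r.n_vt), int(r.n_both), int(r.n_total))
        for r in df.itertuples()
    ]


def compare_all(cohorts: list[CohortCounts], reference: str) -> pd.DataFrame:
    """Per-category contrasts of every cohort against a reference cohort."""
    ref = next(c for c in cohorts if c.construct == reference)
    rows = []
    for c in cohorts:
        if c.construct == reference:
            continue
        for cat in CATEGORIES:
            r = chisq_compare(ref, c, cat)
            rows.append(
                dict(construct=c.construct, category=cat, statistic=r.statistic,
                     df=r.df, p=r.p, low_expected=r.low_expected)
            )
    return pd.DataFrame(rows)
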