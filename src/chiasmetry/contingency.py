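"""Pearson chi-square tests and Cramér's V for region-count tables.

The Pearson statistic is computed from the explicit expected matrix
``E = outer(row totals, column totals) / n`` with no continuity
correction, and Cramér's V is the uncorrected
``sqrt(chi2 / (n * min(r - 1, c - 1)))`` — the plain formulas, no bias
correction, because the published pairwise effect sizes recompute exactly
under these and not under corrected variants. Pairwise sample
comparisons run each unordered row pair as its own 2×c sub-table with
Bonferroni adjustment over the number of pairs performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .localization import SampleChiasmaSummary


@dataclass(frozen=True)
class ContingencyTable:
    """Integer counts indexed by sample (rows) and region (columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match the label lengths")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_summaries(
        cls, summaries: list[SampleChiasmaSummary]
    ) -> "ContingencyTable":
        return cls(
            row_labels=tuple(s.sample_id for s in summaries),
            col_labels=("proximal", "interstitial", "distal"),
            counts=np.array(
                [[s.n_proximal, s.n_interstitial, s.n_distal] for s in summaries]
            ),
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(
            row_labels=tuple(str(i) for i in frame.index),
            col_labels=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )


@dataclass(frozen=True)
class TestResult:
    """A chi-square test with its effect size.

    ``comparison`` names the row pair for pairwise results (``None`` for
    the overall test); ``p_adjusted`` is the Bonferroni-adjusted p-value
    for pairwise results. ``dropped_columns`` flags columns removed from
    a pairwise sub-table because both rows were zero there.
    """

    chi2: float
    df: int
    p_value: float
    cramers_v: float
    n: int
    comparison: tuple[str, str] | None = None
    p_adjusted: float | None = None
    dropped_columns: tuple[str, ...] = field(default=())


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Uncorrected Cramér's V: ``sqrt(chi2 / (n * min(r-1, c-1)))``."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if n < 1 or r < 2 or c < 2:
        raise ValueError("need n >= 1 and at least a 2x2 table")
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence on the full table."""
    counts = table.counts.astype(float)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any():
        empty = table.row_labels[int(np.argmin(row_tot))]
        raise ValueError(f"row {empty!r} has zero marginal total")
    if (col_tot == 0).any():
        empty = table.col_labels[int(np.argmin(col_tot))]
        raise ValueError(f"column {empty!r} has zero marginal total")
    n = counts.sum()
    expected = np.outer(row_tot, col_tot) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    r, c = counts.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(chi2, df))
    return TestResult(
        chi2=chi2,
        df=df,
        p_value=p,
        cramers_v=cramers_v(chi2, int(n), r, c),
        n=int(n),
    )


def pairwise_comparisons(
    table: ContingencyTable, adjustment: str = "bonferroni"
) -> list[TestResult]:
    """Chi-square + V for every unordered row pair, Bonferroni-adjusted.

    Each pair is tested on its own 2×c sub-table. Columns that are zero
    in both rows of a pair are dropped before testing and recorded on the
    result. ``p_adjusted = min(1, p * m)`` with m the number of pairs.
    Results are sorted by descending Cramér's V.
    """
    if adjustment != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    pairs = list(itertools.combinations(range(len(table.row_labels)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        sub = table.counts[[i, j], :]
        keep = sub.sum(axis=0) > 0
        dropped = tuple(
            lab for lab, k in zip(table.col_labels, keep) if not k
        )
        sub_table = ContingencyTable(
            row_labels=(table.row_labels[i], table.row_labels[j]),
            col_labels=tuple(
                lab for lab, k in zip(table.col_labels, keep) if k
            ),
            counts=sub[:, keep],
        )
        res = chi_square(sub_table)
        results.append(
            TestResult(
                chi2=res.chi2,
                df=res.df,
                p_value=res.p_value,
                cramers_v=res.cramers_v,
                n=res.n,
                comparison=(table.row_labels[i], table.row_labels[j]),
                p_adjusted=min(1.0, res.p_value * m),
                dropped_columns=dropped,
            )
        )
    return sorted(results, key=lambda r: -r.cramers_v)


def format_p(p: float, floor: float = 1e-300) -> str:
    """Text form of a p-value; values below ``floor`` print as '< 1e-300'."""
    if p < floor:
        return "< 1e-300"
    return f"{p:.3g}"


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comparison": [
                " vs ".join(r.comparison) if r.comparison else "overall"
                for r in results
            ],
            "cramers_v": [r.cramers_v for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "p_bonferroni": [r.p_adjusted for r in results],
            "dropped_columns": [
                ",".join(r.dropped_columns) for r in results
            ],
        }
    )
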