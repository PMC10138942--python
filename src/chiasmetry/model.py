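"""Model/Results entry points for the two analyses.

:class:`ChiasmaLocalization` fits the positional analysis: per-sample
regional summaries, the overall chi-square test of independence across
samples, and Bonferroni-adjusted pairwise comparisons with Cramér's V.

:class:`FociAnalysis` fits the focus-count analysis: per-sample marker
means and class I/II shares, artificial-population ratio estimates with
slide-consistency diagnostics, and pairwise Wilcoxon rank-sum tests with
BH-FDR across the family.

Both follow the model → ``fit()`` → results pattern: construct from
records (or TSV tables via ``from_tables``), call ``fit()``, then read
attributes, ``summary()``, or ``to_files()``.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import contingency as _contingency
from . import foci as _foci
from .io import (
    read_bivalent_table,
    read_chiasma_table,
    read_foci_table,
    read_sample_table,
)
from .localization import (
    RegionBoundaries,
    SampleChiasmaSummary,
    summaries_to_frame,
    summarize_chiasmata,
)
from .records import (
    MARKERS,
    BivalentRecord,
    ChiasmaRecord,
    FociRecord,
    SampleMeta,
)


class ChiasmaLocalization:
    """Positional analysis of chiasmata across one or more samples."""

    def __init__(
        self,
        chiasmata: list[ChiasmaRecord],
        bivalents: list[BivalentRecord],
        samples: list[SampleMeta] | None = None,
        boundaries: RegionBoundaries = RegionBoundaries(),
    ):
        self.chiasmata = list(chiasmata)
        self.bivalents = list(bivalents)
        self.samples = list(samples) if samples is not None else None
        self.boundaries = boundaries

    @classmethod
    def from_tables(
        cls,
        chiasmata_path: str | os.PathLike,
        bivalents_path: str | os.PathLike,
        samples_path: str | os.PathLike | None = None,
        boundaries: RegionBoundaries = RegionBoundaries(),
    ) -> "ChiasmaLocalization":
        return cls(
            chiasmata=read_chiasma_table(chiasmata_path),
            bivalents=read_bivalent_table(bivalents_path),
            samples=read_sample_table(samples_path) if samples_path else None,
            boundaries=boundaries,
        )

    def fit(self) -> "ChiasmaLocalizationResults":
        summaries = summarize_chiasmata(
            self.chiasmata, self.bivalents, self.samples, self.boundaries
        )
        table = overall = pairwise = None
        if len(summaries) >= 2:
            table = _contingency.ContingencyTable.from_summaries(summaries)
            overall = _contingency.chi_square(table)
            pairwise = _contingency.pairwise_comparisons(table)
        return ChiasmaLocalizationResults(
            summaries=summaries,
            contingency=table,
            overall=overall,
            pairwise=pairwise or [],
        )


@dataclass
class ChiasmaLocalizationResults:
    summaries: list[SampleChiasmaSummary]
    contingency: _contingency.ContingencyTable | None
    overall: _contingency.TestResult | None
    pairwise: list[_contingency.TestResult] = field(default_factory=list)

    @property
    def summary_frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries)

    @property
    def pairwise_frame(self) -> pd.DataFrame:
        return _contingency.results_to_frame(self.pairwise)

    def summary(self) -> str:
        lines = ["Chiasma localization summary", "=" * 60]
        lines.append(self.summary_frame.to_string(index=False))
        if self.overall is not None:
            o = self.overall
            lines.append("")
            lines.append(
                f"Overall test of independence: chi2 = {o.chi2:.1f}, "
                f"df = {o.df}, p = {_contingency.format_p(o.p_value)}, "
                f"Cramer's V = {o.cramers_v:.2f} (n = {o.n})"
            )
        if self.pairwise:
            lines.append("")
            lines.append("Pairwise comparisons (Bonferroni-adjusted):")
            frame = self.pairwise_frame.copy()
            frame["p"] = frame["p"].map(_contingency.format_p)
            frame["p_bonferroni"] = frame["p_bonferroni"].map(
                _contingency.format_p
            )
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def to_files(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.summary_frame.to_csv(
            os.path.join(outdir, "table1_like.tsv"), sep="\t", index=False
        )
        if self.pairwise:
            self.pairwise_frame.to_csv(
                os.path.join(outdir, "table2_like.tsv"), sep="\t", index=False
            )
        if self.overall is not None:
            _contingency.results_to_frame([self.overall]).to_csv(
                os.path.join(outdir, "overall_test.tsv"), sep="\t", index=False
            )

    def to_dict(self) -> dict:
        out = {
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "n_cells": s.n_cells,
                    "n_bivalents": s.n_bivalents,
                    "n_chiasmata": s.n_chiasmata,
                    "mean_chiasma_frequency": s.mean_chiasma_frequency_exact,
                    "percent_proximal": s.percent_proximal_exact,
                    "percent_interstitial": s.percent_interstitial_exact,
                    "percent_distal": s.percent_distal_exact,
                }
                for s in self.summaries
            ]
        }
        if self.overall is not None:
            out["overall"] = {
                "chi2": self.overall.chi2,
                "df": self.overall.df,
                "p": self.overall.p_value,
                "cramers_v": self.overall.cramers_v,
                "n": self.overall.n,
            }
        out["pairwise"] = [
            {
                "comparison": list(r.comparison),
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p_value,
                "p_bonferroni": r.p_adjusted,
                "cramers_v": r.cramers_v,
            }
            for r in self.pairwise
        ]
        return out


class FociAnalysis:
    """Class I/II focus-count analysis across samples.

    ``weighting`` selects the artificial-population scheme (see
    :func:`chiasmetry.foci.weighted_mean_ratio`). Samples missing a
    marker are flagged rather than fatal.
    """

    def __init__(
        self,
        foci: list[FociRecord],
        weighting: str = "inverse_ratio",
    ):
        self.foci = list(foci)
        self.weighting = weighting

    @classmethod
    def from_tables(
        cls, foci_path: str | os.PathLike, weighting: str = "inverse_ratio"
    ) -> "FociAnalysis":
        return cls(read_foci_table(foci_path), weighting=weighting)

    def fit(self) -> "FociAnalysisResults":
        sample_ids = sorted({r.sample_id for r in self.foci})
        shares: dict[str, _foci.MarkerShare] = {}
        ratios: dict[str, _foci.RatioEstimate] = {}
        consistency: dict[str, tuple[bool, str]] = {}
        flagged: list[str] = []
        counts: dict[tuple[str, str], list[int]] = {}
        for sid in sample_ids:
            for marker in MARKERS:
                counts[(sid, marker)] = [
                    r.count
                    for r in self.foci
                    if r.sample_id == sid and r.marker == marker
                ]
        for sid in sample_ids:
            if not counts[(sid, "MLH1")] or not counts[(sid, "MUS81")]:
                flagged.append(sid)
                continue
            shares[sid] = _foci.marker_means(self.foci, sid)
            pop = _foci.artificial_population(
                counts[(sid, "MLH1")], counts[(sid, "MUS81")]
            )
            ratios[sid] = _foci.weighted_mean_ratio(
                pop, weighting=self.weighting, sample_id=sid
            )
            consistency[sid] = _foci.slide_consistency_check(
                shares[sid], ratios[sid]
            )
        comparisons: list[_foci.FociComparison] = []
        for marker in MARKERS:
            with_marker = [s for s in sample_ids if counts[(s, marker)]]
            for a, b in itertools.combinations(with_marker, 2):
                comparisons.append(
                    _foci.compare_counts(
                        counts[(a, marker)],
                        counts[(b, marker)],
                        marker=marker,
                        pair=(a, b),
                    )
                )
        comparisons = _foci.adjust_comparisons(comparisons)
        return FociAnalysisResults(
            shares=shares,
            ratio_estimates=ratios,
            comparisons=comparisons,
            consistency=consistency,
            flagged_samples=flagged,
            weighting=self.weighting,
        )


@dataclass
class FociAnalysisResults:
    shares: dict[str, _foci.MarkerShare]
    ratio_estimates: dict[str, _foci.RatioEstimate]
    comparisons: list[_foci.FociComparison]
    consistency: dict[str, tuple[bool, str]]
    flagged_samples: list[str]
    weighting: str

    @property
    def share_frame(self) -> pd.DataFrame:
        rows = []
        for sid, s in self.shares.items():
            for marker in MARKERS:
                low = marker.lower()
                rows.append(
                    {
                        "sample_id": sid,
                        "marker": marker,
                        "total_cells": getattr(s, f"{low}_cells"),
                        "total_signals": getattr(s, f"{low}_signals"),
                        "mean_per_cell": getattr(s, f"{low}_mean"),
                        "share_pct": getattr(s, f"{low}_share"),
                    }
                )
        for sid in self.flagged_samples:
            rows.append(
                {
                    "sample_id": sid,
                    "marker": "FLAGGED",
                    "total_cells": 0,
                    "total_signals": 0,
                    "mean_per_cell": float("nan"),
                    "share_pct": -1,
                }
            )
        return pd.DataFrame(rows)

    @property
    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [" vs ".join(c.pair) for c in self.comparisons],
                "marker": [c.marker for c in self.comparisons],
                "statistic": [c.statistic for c in self.comparisons],
                "p": [c.p_value for c in self.comparisons],
                "p_fdr": [c.p_fdr for c in self.comparisons],
                "mean_difference": [c.mean_difference for c in self.comparisons],
            }
        )

    def ratio_report(self) -> str:
        lines = [f"Artificial-population ratio estimates ({self.weighting})"]
        for sid, est in self.ratio_estimates.items():
            lo, hi = est.percentile_interval
            lines.append(
                f"  {sid}: MLH1/MUS81 = {est.estimate:.3f} "
                f"[{lo:.3f}, {hi:.3f}] over {est.n_pairs} pairs "
                f"({est.n_excluded} excluded)"
            )
            ok, report = self.consistency[sid]
            lines.append(f"    slide consistency: {report}")
        for sid in self.flagged_samples:
            lines.append(f"  {sid}: FLAGGED (missing a marker); ratio skipped")
        return "\n".join(lines)

    def summary(self) -> str:
        lines = ["Focus-count summary", "=" * 60]
        lines.append(self.share_frame.to_string(index=False))
        if self.comparisons:
            lines.append("")
            lines.append("Pairwise Wilcoxon rank-sum tests (BH-FDR):")
            frame = self.comparison_frame.copy()
            frame["p"] = frame["p"].map(_contingency.format_p)
            frame["p_fdr"] = frame["p_fdr"].map(_contingency.format_p)
            lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append(self.ratio_report())
        return "\n".join(lines)

    def to_files(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.share_frame.to_csv(
            os.path.join(outdir, "table3_like.tsv"), sep="\t", index=False
        )
        self.comparison_frame.to_csv(
            os.path.join(outdir, "foci_tests.tsv"), sep="\t", index=False
        )
        with open(
            os.path.join(outdir, "ratio_report.txt"), "w", encoding="utf-8"
        ) as fh:
            fh.write(self.ratio_report() + "\n")

    def to_dict(self) -> dict:
        return {
            "shares": {
                sid: {
                    "mlh1_mean": s.mlh1_mean_exact,
                    "mus81_mean": s.mus81_mean_exact,
                    "mlh1_share": s.mlh1_share,
                    "mus81_share": s.mus81_share,
                }
                for sid, s in self.shares.items()
            },
            "ratio_estimates": {
                sid: {
                    "weighting": e.weighting,
                    "estimate": e.estimate,
                    "n_pairs": e.n_pairs,
                    "n_excluded": e.n_excluded,
                    "percentile_interval": list(e.percentile_interval),
                }
                for sid, e in self.ratio_estimates.items()
            },
            "comparisons": [
                {
                    "pair": list(c.pair),
                    "marker": c.marker,
                    "statistic": c.statistic,
                    "p": c.p_value,
                    "p_fdr": c.p_fdr,
                    "mean_difference": c.mean_difference,
                }
                for c in self.comparisons
            ],
            "flagged_samples": list(self.flagged_samples),
        }


def summary_json(
    localization: ChiasmaLocalizationResults | None,
    foci: FociAnalysisResults | None,
    path: str | os.PathLike,
) -> None:
    """Write the full-precision combined summary for a report run."""
    payload = {}
    if localization is not None:
        payload["localization"] = localization.to_dict()
    if foci is not None:
        payload["foci"] = foci.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
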