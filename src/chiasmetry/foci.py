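"""Per-cell focus statistics for class I (MLH1) and class II (MUS81) COs.

MLH1 and MUS81 foci are counted on separate slides, so no cell carries
both counts. The per-cell MLH1/MUS81 ratio is therefore estimated from
an *artificial population*: the Cartesian product of per-cell MLH1 counts
with per-cell MUS81 counts, each pair contributing one ratio. A weighted
mean with inverse weights (w = 1/r, i.e. the harmonic mean) damps the
influence of pairs with extreme ratios; an inverse-absolute-deviation
scheme and the plain mean are available as sensitivity checks.

Group comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test — exact null by enumeration for small tie-free groups, otherwise
the normal approximation with tie and continuity corrections — with
Benjamini–Hochberg FDR across a family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .localization import round_half_up
from .records import MARKERS, FociRecord

WEIGHTINGS = ("inverse_ratio", "inverse_abs_deviation", "unweighted")

EXACT_MAX_TOTAL = 12  # exact rank-sum null up to this combined group size


@dataclass(frozen=True)
class MarkerShare:
    """Per-sample marker means and class I/II shares.

    ``mlh1_share`` is the MLH1 percentage of the combined per-cell mean,
    rounded to the nearest integer; ``mus81_share = 100 - mlh1_share``.
    Exact (full-precision) means are kept alongside the one-decimal
    display values.
    """

    sample_id: str
    mlh1_cells: int
    mlh1_signals: int
    mlh1_mean: float
    mus81_cells: int
    mus81_signals: int
    mus81_mean: float
    mlh1_share: int
    mus81_share: int
    combined_mean: float
    mlh1_mean_exact: float
    mus81_mean_exact: float


@dataclass(frozen=True)
class ArtificialPopulation:
    """All finite pair ratios from the MLH1 × MUS81 cross product."""

    ratios: np.ndarray
    n_pairs: int
    n_excluded: int


@dataclass(frozen=True)
class RatioEstimate:
    """Weighted-mean MLH1/MUS81 ratio with diagnostics."""

    sample_id: str | None
    weighting: str
    estimate: float
    n_pairs: int
    n_excluded: int
    percentile_interval: tuple[float, float]


@dataclass(frozen=True)
class FociComparison:
    """One two-group rank-sum comparison (before/after FDR)."""

    marker: str | None
    pair: tuple[str, str] | None
    statistic: float
    p_value: float
    mean_difference: float
    p_fdr: float | None = None

    @property
    def mean_difference_display(self) -> float:
        return round_half_up(self.mean_difference)


def _counts_by_marker(
    records: Sequence[FociRecord], sample_id: str
) -> dict[str, list[int]]:
    counts: dict[str, list[int]] = {m: [] for m in MARKERS}
    for rec in records:
        if rec.sample_id == sample_id:
            counts[rec.marker].append(rec.count)
    return counts


def marker_means(records: Sequence[FociRecord], sample_id: str) -> MarkerShare:
    """Per-marker means and the integer-percent class I/II split."""
    counts = _counts_by_marker(records, sample_id)
    for marker in MARKERS:
        if not counts[marker]:
            raise ValueError(
                f"sample {sample_id!r} has no {marker} cells"
            )
    mlh1 = np.asarray(counts["MLH1"], dtype=float)
    mus81 = np.asarray(counts["MUS81"], dtype=float)
    mlh1_mean = float(mlh1.mean())
    mus81_mean = float(mus81.mean())
    combined = mlh1_mean + mus81_mean
    share = int(round_half_up(100.0 * mlh1_mean / combined, 0))
    return MarkerShare(
        sample_id=sample_id,
        mlh1_cells=len(mlh1),
        mlh1_signals=int(mlh1.sum()),
        mlh1_mean=round_half_up(mlh1_mean),
        mus81_cells=len(mus81),
        mus81_signals=int(mus81.sum()),
        mus81_mean=round_half_up(mus81_mean),
        mlh1_share=share,
        mus81_share=100 - share,
        combined_mean=round_half_up(combined),
        mlh1_mean_exact=mlh1_mean,
        mus81_mean_exact=mus81_mean,
    )


def artificial_population(
    mlh1_counts: Sequence[int], mus81_counts: Sequence[int]
) -> ArtificialPopulation:
    """All pairwise MLH1/MUS81 count ratios across the two cell sets.

    Pairs with a zero MUS81 count have no finite ratio; they are excluded
    and tallied, never imputed.
    """
    mlh1 = np.asarray(mlh1_counts, dtype=float)
    mus81 = np.asarray(mus81_counts, dtype=float)
    if mlh1.size == 0 or mus81.size == 0:
        raise ValueError("both marker count collections must be non-empty")
    denom_ok = mus81 > 0
    n_excluded = int(mlh1.size * (~denom_ok).sum())
    if not denom_ok.any():
        raise ValueError("all pairs have zero MUS81 denominator; no finite ratios")
    ratios = (mlh1[:, None] / mus81[None, denom_ok]).ravel()
    return ArtificialPopulation(
        ratios=ratios, n_pairs=int(ratios.size), n_excluded=n_excluded
    )


def weighted_mean_ratio(
    ratios: ArtificialPopulation | Sequence[float],
    weighting: str = "inverse_ratio",
    eps: float = 1e-9,
    sample_id: str | None = None,
) -> RatioEstimate:
    """Weighted mean of the pair ratios under the chosen scheme.

    ``inverse_ratio`` uses w = 1/r (zero ratios get the floor ``eps`` in
    the denominator), which makes the estimate the harmonic mean of the
    ratios and down-weights extreme large ratios. ``inverse_abs_deviation``
    uses w = 1/(|r - median| + eps). ``unweighted`` is the plain mean.
    The central 95% percentile interval of the ratios is always reported.
    """
    if isinstance(ratios, ArtificialPopulation):
        pop = ratios
    else:
        arr = np.asarray(ratios, dtype=float)
        pop = ArtificialPopulation(ratios=arr, n_pairs=int(arr.size), n_excluded=0)
    r = pop.ratios
    if r.size == 0:
        raise ValueError("no ratios to average")
    if weighting == "inverse_ratio":
        w = 1.0 / np.maximum(r, eps)
    elif weighting == "inverse_abs_deviation":
        w = 1.0 / (np.abs(r - np.median(r)) + eps)
    elif weighting == "unweighted":
        w = np.ones_like(r)
    else:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")
    estimate = float((w * r).sum() / w.sum())
    lo, hi = np.percentile(r, [2.5, 97.5])
    return RatioEstimate(
        sample_id=sample_id,
        weighting=weighting,
        estimate=estimate,
        n_pairs=pop.n_pairs,
        n_excluded=pop.n_excluded,
        percentile_interval=(float(lo), float(hi)),
    )


def slide_consistency_check(
    share: MarkerShare, estimate: RatioEstimate
) -> tuple[bool, str]:
    """Check the slide-based mean ratio against the artificial population.

    The separate-slide design is considered consistent when the ratio of
    slide means (mean MLH1 per cell / mean MUS81 per cell) falls inside
    the central 95% percentile interval of the artificial-population pair
    ratios.
    """
    if estimate.sample_id is not None and share.sample_id != estimate.sample_id:
        raise ValueError(
            f"sample mismatch: {share.sample_id!r} vs {estimate.sample_id!r}"
        )
    slide_ratio = share.mlh1_mean_exact / share.mus81_mean_exact
    lo, hi = estimate.percentile_interval
    ok = lo <= slide_ratio <= hi
    report = (
        f"sample {share.sample_id}: slide mean ratio {slide_ratio:.4g} "
        f"{'inside' if ok else 'OUTSIDE'} artificial-population 95% interval "
        f"[{lo:.4g}, {hi:.4g}] ({estimate.n_pairs} pairs, "
        f"{estimate.n_excluded} excluded)"
    )
    return ok, report


def compare_counts(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    marker: str | None = None,
    pair: tuple[str, str] | None = None,
) -> FociComparison:
    """Two-sided Wilcoxon rank-sum comparison of two independent groups.

    The exact null distribution (full enumeration) is used when the
    combined size is at most 12 and there are no ties across the pooled
    data; otherwise the normal approximation with tie correction and
    continuity correction. ``mean_difference = mean(a) - mean(b)`` at
    full precision.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_TOTAL and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return FociComparison(
        marker=marker,
        pair=pair,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_comparisons(comparisons: list[FociComparison]) -> list[FociComparison]:
    """Attach BH-FDR-adjusted p-values across a family of comparisons."""
    adjusted = fdr_adjust([c.p_value for c in comparisons])
    return [
        FociComparison(
            marker=c.marker,
            pair=c.pair,
            statistic=c.statistic,
            p_value=c.p_value,
            mean_difference=c.mean_difference,
            p_fdr=float(q),
        )
        for c, q in zip(comparisons, adjusted)
    ]
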