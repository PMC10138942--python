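"""Positional classification of chiasmata and per-sample summaries.

Each chromosome arm is divided into three regions of equal length —
proximal (nearest the centromere), interstitial and distal — and every
chiasma is classified by its relative arm position. Region intervals are
half-open, ``[0, lower) / [lower, upper) / [upper, 1]``, so the partition
is total: every valid position maps to exactly one region.

Percentages and per-cell means are displayed rounded half-up to one
decimal; full-precision values are retained on the summary objects.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .records import BivalentRecord, ChiasmaRecord, SampleMeta, ValidationError

REGIONS = ("proximal", "interstitial", "distal")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegionBoundaries:
    """Region cut points on the [0, 1] arm; defaults give equal thirds."""

    lower: float = 1.0 / 3.0
    upper: float = 2.0 / 3.0

    def __post_init__(self):
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ValueError(
                f"boundaries must satisfy 0 < lower < upper < 1, "
                f"got ({self.lower}, {self.upper})"
            )


def classify_position(
    rel_pos: float, boundaries: RegionBoundaries = RegionBoundaries()
) -> str:
    """Map a relative arm position to its region label.

    Proximal for ``rel_pos < lower``, interstitial for
    ``lower <= rel_pos < upper``, distal for ``rel_pos >= upper``.
    """
    if not (0.0 <= rel_pos <= 1.0):
        raise ValueError(f"rel_pos must lie in [0, 1], got {rel_pos!r}")
    if rel_pos < boundaries.lower:
        return "proximal"
    if rel_pos < boundaries.upper:
        return "interstitial"
    return "distal"


@dataclass(frozen=True)
class SampleChiasmaSummary:
    """Per-sample chiasma frequency and regional distribution.

    ``percent_*`` and ``mean_chiasma_frequency`` are display values (one
    decimal, half-up); the ``*_exact`` attributes keep full precision.
    """

    sample_id: str
    n_cells: int
    n_bivalents: int
    n_proximal: int
    n_interstitial: int
    n_distal: int
    percent_proximal: float
    percent_interstitial: float
    percent_distal: float
    mean_chiasma_frequency: float
    percent_proximal_exact: float
    percent_interstitial_exact: float
    percent_distal_exact: float
    mean_chiasma_frequency_exact: float

    @property
    def n_chiasmata(self) -> int:
        return self.n_proximal + self.n_interstitial + self.n_distal


def _region_counts(
    chiasmata: list[ChiasmaRecord], boundaries: RegionBoundaries
) -> dict[str, int]:
    counts = {r: 0 for r in REGIONS}
    for rec in chiasmata:
        counts[classify_position(rec.rel_pos, boundaries)] += 1
    return counts


def summarize_chiasmata(
    chiasmata: list[ChiasmaRecord],
    bivalents: list[BivalentRecord],
    samples: list[SampleMeta] | None = None,
    boundaries: RegionBoundaries = RegionBoundaries(),
) -> list[SampleChiasmaSummary]:
    """Build one summary per sample.

    Cell membership (for mean chiasmata per cell) comes from the bivalent
    table, so cells whose bivalents are all univalent pairs still count.
    Every chiasma must reference a bivalent present in the bivalent table.
    Output is sorted by sample_id, and invariant to input record order.
    """
    known = {b.bivalent_key for b in bivalents}
    for rec in chiasmata:
        if rec.bivalent_key not in known:
            raise ValidationError(
                f"chiasma references unknown bivalent {rec.bivalent_key!r}"
            )

    by_sample: dict[str, list[ChiasmaRecord]] = defaultdict(list)
    for rec in chiasmata:
        by_sample[rec.sample_id].append(rec)
    cells: dict[str, set[str]] = defaultdict(set)
    n_biv: dict[str, int] = defaultdict(int)
    for biv in bivalents:
        cells[biv.sample_id].add(biv.cell_id)
        n_biv[biv.sample_id] += 1

    sample_ids = sorted(cells)
    if samples is not None:
        order = [s.sample_id for s in samples]
        sample_ids = [s for s in order if s in cells] + [
            s for s in sample_ids if s not in order
        ]

    summaries = []
    for sample_id in sample_ids:
        n_cells = len(cells[sample_id])
        if n_cells == 0:
            raise ValidationError(f"sample {sample_id!r} has zero cells")
        counts = _region_counts(by_sample.get(sample_id, []), boundaries)
        total = sum(counts.values())
        pct = {
            r: (100.0 * counts[r] / total if total else 0.0) for r in REGIONS
        }
        mean = total / n_cells
        summaries.append(
            SampleChiasmaSummary(
                sample_id=sample_id,
                n_cells=n_cells,
                n_bivalents=n_biv[sample_id],
                n_proximal=counts["proximal"],
                n_interstitial=counts["interstitial"],
                n_distal=counts["distal"],
                percent_proximal=round_half_up(pct["proximal"]),
                percent_interstitial=round_half_up(pct["interstitial"]),
                percent_distal=round_half_up(pct["distal"]),
                mean_chiasma_frequency=round_half_up(mean),
                percent_proximal_exact=pct["proximal"],
                percent_interstitial_exact=pct["interstitial"],
                percent_distal_exact=pct["distal"],
                mean_chiasma_frequency_exact=mean,
            )
        )
    return summaries


def summaries_to_frame(summaries: list[SampleChiasmaSummary]) -> pd.DataFrame:
    """Tabulate summaries in the layout of a chiasma-distribution table."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "n_cells": [s.n_cells for s in summaries],
            "mean_chiasma_frequency": [
                s.mean_chiasma_frequency for s in summaries
            ],
            "n_bivalents": [s.n_bivalents for s in summaries],
            "proximal_pct": [s.percent_proximal for s in summaries],
            "proximal_n": [s.n_proximal for s in summaries],
            "interstitial_pct": [s.percent_interstitial for s in summaries],
            "interstitial_n": [s.n_interstitial for s in summaries],
            "distal_pct": [s.percent_distal for s in summaries],
            "distal_n": [s.n_distal for s in summaries],
        }
    )


def classify_bivalent(
    chiasmata: list[ChiasmaRecord],
    boundaries: RegionBoundaries = RegionBoundaries(),
) -> tuple[str, str]:
    """Classify one bivalent's chiasmata into (configuration, subtype).

    Configuration is ``univalent_pair`` (no chiasmata), ``ring`` (at least
    one chiasma on each arm) or ``open`` (all chiasmata on one arm). The
    subtype annotation lists region labels arm by arm, ordered by arm then
    position, e.g. ``"ring: distal+distal"``. A ring whose chiasmata are
    all proximal is annotated with the ``cross`` prefix (cross-bivalent
    morphology) while keeping the ring configuration.
    """
    if not chiasmata:
        return "univalent_pair", ""
    keys = {c.bivalent_key for c in chiasmata}
    if len(keys) > 1:
        raise ValidationError(
            f"chiasmata span multiple bivalents: {sorted(keys)!r}"
        )
    arms = {c.arm_id for c in chiasmata}
    configuration = "ring" if arms == {1, 2} else "open"
    ordered = sorted(chiasmata, key=lambda c: (c.arm_id, c.rel_pos))
    regions = [classify_position(c.rel_pos, boundaries) for c in ordered]
    prefix = configuration
    if configuration == "ring" and all(r == "proximal" for r in regions):
        prefix = "cross"
    return configuration, f"{prefix}: " + "+".join(regions)
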