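"""Published summary counts for the *Allium* crossover-localization study.

These are the printed per-sample summary counts from the cytological
study of chiasma localization in *Allium cepa*, *A. fistulosum* and
their F1 diploid (8C + 8F) and F1 triploid (16F + 8C) hybrids: regional
chiasma counts scored at metaphase I, and MLH1 / MUS81 focus totals
counted at pachytene on separate slides. The raw per-cell observations
were not deposited, so these marginals are the reference inputs: the
reconstruction helpers below expand them into representative record sets
whose regional counts, cell counts and totals match the published
numbers exactly, which is sufficient for every frequency, percentage,
chi-square / Cramér's V and marker-share statistic of the pipeline
(those statistics depend on the data only through these marginals).
"""

from __future__ import annotations

import pandas as pd

from .localization import RegionBoundaries
from .records import BivalentRecord, ChiasmaRecord, FociRecord, SampleMeta

SAMPLES = ("A_cepa", "A_fistulosum", "F1_diploid", "F1_triploid")

_CHIASMA_ROWS = {
    # sample: (n_cells, n_bivalents, proximal, interstitial, distal)
    "A_cepa": (54, 435, 18, 207, 808),
    "A_fistulosum": (43, 340, 643, 8, 11),
    "F1_diploid": (35, 248, 48, 180, 191),
    "F1_triploid": (29, 231, 167, 110, 146),
}

_FOCI_ROWS = {
    # sample: (mlh1_cells, mlh1_signals, mus81_cells, mus81_signals)
    "A_cepa": (37, 409, 39, 158),
    "A_fistulosum": (40, 257, 41, 272),
    "F1_diploid": (38, 320, 37, 136),
    "F1_triploid": (36, 311, 38, 214),
}

_DISPLAY = {
    "A_cepa": ("A. cepa", "16C"),
    "A_fistulosum": ("A. fistulosum", "16F"),
    "F1_diploid": ("F1 diploid hybrid", "8F+8C"),
    "F1_triploid": ("F1 triploid hybrid", "16F+8C"),
}


def allium_chiasma_region_counts() -> pd.DataFrame:
    """Cells scored, bivalents analyzed, and regional chiasma counts."""
    return pd.DataFrame.from_dict(
        _CHIASMA_ROWS,
        orient="index",
        columns=["n_cells", "n_bivalents", "proximal", "interstitial", "distal"],
    ).rename_axis("sample_id")


def allium_foci_totals() -> pd.DataFrame:
    """Cells scored and total focus signals per marker."""
    return pd.DataFrame.from_dict(
        _FOCI_ROWS,
        orient="index",
        columns=["mlh1_cells", "mlh1_signals", "mus81_cells", "mus81_signals"],
    ).rename_axis("sample_id")


def allium_sample_meta() -> list[SampleMeta]:
    return [
        SampleMeta(
            sample_id=s,
            display_label=_DISPLAY[s][0],
            genome_composition=_DISPLAY[s][1],
        )
        for s in SAMPLES
    ]


def _region_midpoints(boundaries: RegionBoundaries) -> dict[str, float]:
    return {
        "proximal": boundaries.lower / 2.0,
        "interstitial": (boundaries.lower + boundaries.upper) / 2.0,
        "distal": (boundaries.upper + 1.0) / 2.0,
    }


def chiasma_records_from_region_counts(
    counts: pd.DataFrame | None = None,
    boundaries: RegionBoundaries = RegionBoundaries(),
) -> tuple[list[ChiasmaRecord], list[BivalentRecord]]:
    """Expand regional marginals into a representative record set.

    Bivalents are dealt round-robin over the scored cells and chiasmata
    round-robin over the bivalents (alternating arms), each placed at its
    region's midpoint, so regional counts, bivalent counts and cells per
    sample reproduce the marginals exactly. Positions within a region are
    representative, not observed — only region membership matters to the
    downstream statistics.
    """
    if counts is None:
        counts = allium_chiasma_region_counts()
    mid = _region_midpoints(boundaries)
    chiasmata: list[ChiasmaRecord] = []
    bivalents: list[BivalentRecord] = []
    for sample_id, row in counts.iterrows():
        n_cells = int(row.n_cells)
        n_biv = int(row.n_bivalents)
        biv_keys = [
            (f"c{(i % n_cells) + 1:03d}", f"b{i // n_cells + 1}")
            for i in range(n_biv)
        ]
        positions: list[float] = []
        for region in ("proximal", "interstitial", "distal"):
            positions.extend([mid[region]] * int(row[region]))
        per_biv: dict[tuple[str, str], int] = {k: 0 for k in biv_keys}
        for j, pos in enumerate(positions):
            cell_id, bivalent_id = biv_keys[j % n_biv]
            arm_id = 1 + (per_biv[(cell_id, bivalent_id)] % 2)  # alternate arms
            per_biv[(cell_id, bivalent_id)] += 1
            chiasmata.append(
                ChiasmaRecord(
                    sample_id=sample_id,
                    cell_id=cell_id,
                    bivalent_id=bivalent_id,
                    arm_id=arm_id,
                    rel_pos=pos,
                )
            )
        for (cell_id, bivalent_id), k in per_biv.items():
            configuration = "univalent_pair" if k == 0 else ("open" if k == 1 else "ring")
            bivalents.append(
                BivalentRecord(
                    sample_id=sample_id,
                    cell_id=cell_id,
                    bivalent_id=bivalent_id,
                    chiasma_count=k,
                    configuration=configuration,
                )
            )
    return chiasmata, bivalents


def foci_records_from_totals(
    totals: pd.DataFrame | None = None,
) -> list[FociRecord]:
    """Expand per-marker totals into per-cell counts with exact sums.

    Signals are spread as evenly as integers allow (the first
    ``total mod cells`` cells get one extra), so per-marker means equal
    ``total / cells`` exactly; the within-marker spread is artificial.
    """
    if totals is None:
        totals = allium_foci_totals()
    records: list[FociRecord] = []
    for sample_id, row in totals.iterrows():
        for marker, n_cells, total in (
            ("MLH1", int(row.mlh1_cells), int(row.mlh1_signals)),
            ("MUS81", int(row.mus81_cells), int(row.mus81_signals)),
        ):
            base, extra = divmod(total, n_cells)
            records.extend(
                FociRecord(
                    sample_id=sample_id,
                    slide_id=f"slide_{marker}",
                    cell_id=f"{marker.lower()}_c{ci + 1:03d}",
                    marker=marker,
                    count=base + (1 if ci < extra else 0),
                )
                for ci in range(n_cells)
            )
    return records
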