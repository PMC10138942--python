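"""Domain record types for cytological observations.

Records are plain frozen dataclasses validated on construction:

* :class:`ChiasmaRecord` — one chiasma on one bivalent arm, with its
  relative position along the arm (0 = centromere, 1 = telomere);
* :class:`BivalentRecord` — one bivalent (or univalent pair) per cell,
  with its chiasma count and configuration class;
* :class:`FociRecord` — one cell's focus count for one marker on one
  slide (markers are scored on separate preparations);
* :class:`SampleMeta` — labelling metadata for a sample.

Univalent pairs carry no :class:`ChiasmaRecord`; they enter the data as
:class:`BivalentRecord` rows with ``chiasma_count == 0`` so that per-cell
chiasma frequencies still see every cell while positional percentages run
over chiasmata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MARKERS = ("MLH1", "MUS81")
CONFIGURATIONS = ("ring", "open", "univalent_pair")


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """A record violates a stated invariant.

    ``row`` is the 1-based data-row number when the record came from a
    table, else ``None``.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ChiasmaRecord:
    """One observed chiasma.

    ``rel_pos`` is the fraction of the arm length from the centromere (0)
    toward the telomere (1). ``arm_id`` is 1 or 2; bivalents with more
    than two arms (trivalents) are out of scope and rejected.
    """

    sample_id: str
    cell_id: str
    bivalent_id: str
    arm_id: int
    rel_pos: float

    def __post_init__(self):
        if self.arm_id not in (1, 2):
            raise ValidationError(f"arm_id must be 1 or 2, got {self.arm_id!r}")
        if not (0.0 <= self.rel_pos <= 1.0):
            raise ValidationError(
                f"rel_pos must lie in [0, 1], got {self.rel_pos!r}"
            )

    @property
    def bivalent_key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.cell_id, self.bivalent_id)


@dataclass(frozen=True)
class BivalentRecord:
    """One bivalent (or unpaired univalent pair) in one cell.

    ``configuration`` follows metaphase-I morphology: a *ring* bivalent
    holds at least one chiasma on each arm, an *open* (rod) bivalent has
    all its chiasmata on a single arm, and a *univalent_pair* has none.
    ``subtype`` is a free-text annotation (e.g. ``"ring: distal+distal"``
    or ``"cross: proximal+proximal"`` for cross-bivalent morphology).
    """

    sample_id: str
    cell_id: str
    bivalent_id: str
    chiasma_count: int
    configuration: str
    subtype: str = ""

    def __post_init__(self):
        if self.chiasma_count < 0 or self.chiasma_count != int(self.chiasma_count):
            raise ValidationError(
                f"chiasma_count must be a non-negative integer, got {self.chiasma_count!r}"
            )
        if self.configuration not in CONFIGURATIONS:
            raise ValidationError(
                f"configuration must be one of {CONFIGURATIONS}, got {self.configuration!r}"
            )
        if (self.configuration == "univalent_pair") != (self.chiasma_count == 0):
            raise ValidationError(
                "univalent_pair configuration and chiasma_count == 0 must coincide "
                f"(got {self.configuration!r} with count {self.chiasma_count})"
            )
        if self.configuration == "ring" and self.chiasma_count < 2:
            raise ValidationError(
                "ring configuration requires at least 2 chiasmata "
                f"(got {self.chiasma_count})"
            )

    @property
    def is_univalent_pair(self) -> bool:
        return self.chiasma_count == 0

    @property
    def bivalent_key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.cell_id, self.bivalent_id)


@dataclass(frozen=True)
class FociRecord:
    """One cell's focus count for one marker, on one slide."""

    sample_id: str
    slide_id: str
    cell_id: str
    marker: str
    count: int

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValidationError(
                f"marker must be one of {MARKERS}, got {self.marker!r}"
            )
        if self.count < 0 or self.count != int(self.count):
            raise ValidationError(
                f"count must be a non-negative integer, got {self.count!r}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Display metadata for one sample (labels, genome composition)."""

    sample_id: str
    display_label: str = ""
    genome_composition: str = ""
    expected_bivalents_per_cell: int = 8

    def __post_init__(self):
        if self.expected_bivalents_per_cell < 1:
            raise ValidationError(
                "expected_bivalents_per_cell must be a positive integer, "
                f"got {self.expected_bivalents_per_cell!r}"
            )


def check_one_marker_per_slide(records: list[FociRecord]) -> None:
    """Enforce the separate-slide design: one marker per slide_id.

    MLH1 and MUS81 are immunodetected on different preparations, so a
    slide carrying both markers indicates mislabelled input.
    """
    seen: dict[tuple[str, str], str] = {}
    for i, rec in enumerate(records, start=1):
        key = (rec.sample_id, rec.slide_id)
        prev = seen.setdefault(key, rec.marker)
        if prev != rec.marker:
            raise ValidationError(
                f"slide {rec.slide_id!r} of sample {rec.sample_id!r} carries both "
                f"{prev} and {rec.marker}; markers are scored on separate slides",
                row=i,
            )
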