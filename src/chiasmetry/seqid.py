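"""Longest-ORF translation and pairwise amino-acid identity.

Used to compare MLH1 and MUS81 transcripts between species: extract the
longest open reading frame (ATG…stop) from each transcript, translate it
with the standard genetic code, and report the fraction of identical
residues. Transcripts are assumed sense-strand, so only the three
forward frames are searched by default; ``both_strands=True`` adds the
reverse complement. ORFs must terminate at an in-sequence stop codon;
open-ended runs are not counted.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

_VALID = re.compile(r"^[ACGTN]+$", re.IGNORECASE)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfResult:
    """The longest ORF of a transcript.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    searched strand, spanning ATG through the stop codon inclusive;
    ``protein`` excludes the stop. ``found`` is False when no ATG…stop
    span exists, in which case the other fields are None/empty.
    """

    found: bool
    frame: int | None = None
    start: int | None = None
    end: int | None = None
    protein: str = ""
    strand: int = 1

    def __len__(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class IdentityResult:
    matches: int
    aligned_length: int

    def __post_init__(self):
        if not (0 <= self.matches <= self.aligned_length):
            raise ValueError("matches must lie in [0, aligned_length]")

    @property
    def identity_fraction(self) -> float:
        return self.matches / self.aligned_length

    @property
    def percent(self) -> float:
        """Identity as a percent rounded to one decimal for display."""
        return round(100.0 * self.identity_fraction, 1)


def _scan_strand(seq: str, strand: int) -> list[OrfResult]:
    results = []
    n = len(seq)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        orf_start = None
        for i in codon_starts:
            codon = seq[i : i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in _STOPS:
                results.append(
                    OrfResult(
                        found=True,
                        frame=frame,
                        start=orf_start,
                        end=i + 3,
                        protein=str(
                            Seq(seq[orf_start:i]).translate(table="Standard")
                        ),
                        strand=strand,
                    )
                )
                orf_start = None
        # an ORF still open at sequence end is discarded (no stop codon)
    return results


def longest_orf(sequence: str, both_strands: bool = False) -> OrfResult:
    """Longest ATG…stop ORF across the searched frames.

    Ties break toward the smallest start coordinate (forward strand
    preferred when both are searched). ``N`` anywhere in a codon
    translates to ``X``.
    """
    seq = str(sequence).upper().replace("U", "T")
    if len(seq) < 6:
        raise ValueError("sequence must be at least 6 nucleotides")
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    candidates = _scan_strand(seq, strand=1)
    if both_strands:
        candidates += _scan_strand(str(Seq(seq).reverse_complement()), strand=-1)
    if not candidates:
        return OrfResult(found=False)
    return max(candidates, key=lambda o: (o.end - o.start, -o.start, o.strand))


def pairwise_identity(protein_a: str, protein_b: str) -> IdentityResult:
    """Amino-acid identity between two protein sequences.

    Equal-length pairs are compared position by position. Unequal-length
    pairs are globally aligned (match +1, mismatch 0, linear gap −1) and
    identity is matches over the alignment length including gaps.
    """
    a, b = str(protein_a), str(protein_b)
    if not a or not b:
        raise ValueError("protein sequences must be non-empty")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return IdentityResult(matches=matches, aligned_length=len(a))
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return IdentityResult(matches=matches, aligned_length=len(ga))


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file → ordered {record id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def compare_transcripts(
    seq_a: str, seq_b: str, both_strands: bool = False
) -> tuple[OrfResult, OrfResult, IdentityResult]:
    """Longest-ORF translate both transcripts and score their identity."""
    orf_a = longest_orf(seq_a, both_strands=both_strands)
    orf_b = longest_orf(seq_b, both_strands=both_strands)
    if not orf_a.found or not orf_b.found:
        raise ValueError("no ORF found in at least one transcript")
    return orf_a, orf_b, pairwise_identity(orf_a.protein, orf_b.protein)
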