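"""Detection of telomeric-repeat-containing reads (TERRA analogs).

A read counts as repeat-containing when it carries a contiguous block of
four exact copies of the telomeric motif on either strand: ``(TTAGGG)4``
(G-strand) or its reverse complement ``(CCCTAA)4`` (C-strand).  Matching is
exact — no mismatches, and ``N`` never matches — which mirrors extracting
matching sequence lines with a fixed pattern.  Each read contributes at
most once per motif class no matter how many blocks it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ReadRecord",
    "RepeatCountReport",
    "TELOMERE_MOTIF",
    "reverse_complement",
    "contains_tandem_motif",
    "classify_read",
    "count_repeat_reads",
]

TELOMERE_MOTIF = "TTAGGG"
DEFAULT_REPEATS = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; sequence is uppercased on construction."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


def contains_tandem_motif(
    sequence: str, motif: str = TELOMERE_MOTIF, n_repeats: int = DEFAULT_REPEATS
) -> bool:
    """True iff ``motif`` repeated ``n_repeats`` times occurs as one
    contiguous substring of the uppercased sequence."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return (motif.upper() * n_repeats) in sequence.upper()


def classify_read(
    read: ReadRecord, motif: str = TELOMERE_MOTIF, n_repeats: int = DEFAULT_REPEATS
) -> str:
    """Classify a read as ``g_strand``, ``c_strand``, ``both`` or ``neither``.

    G-strand means the motif block itself (default ``(TTAGGG)4``); C-strand
    means the reverse-complement block (default ``(CCCTAA)4``).
    """
    g = contains_tandem_motif(read.sequence, motif, n_repeats)
    c = contains_tandem_motif(read.sequence, reverse_complement(motif), n_repeats)
    if g and c:
        return "both"
    if g:
        return "g_strand"
    if c:
        return "c_strand"
    return "neither"


@dataclass
class RepeatCountReport:
    """Per-library tally of telomeric-repeat-containing reads.

    ``per_million`` values are each count scaled by ``1e6 / total_reads``
    and are ``None`` for an empty library.
    """

    library_id: str
    total_reads: int = 0
    g_strand_reads: int = 0
    c_strand_reads: int = 0
    either_reads: int = 0
    motif: str = TELOMERE_MOTIF
    n_repeats: int = DEFAULT_REPEATS

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if self.either_reads > self.g_strand_reads + self.c_strand_reads:
            raise ValueError("either_reads exceeds g + c strand counts")
        if self.either_reads > self.total_reads:
            raise ValueError("either_reads exceeds total_reads")
        if max(self.g_strand_reads, self.c_strand_reads) > self.either_reads:
            raise ValueError("single-strand count exceeds either_reads")

    def per_million(self, count: int) -> Optional[float]:
        if self.total_reads == 0:
            return None
        return count * 1e6 / self.total_reads

    def to_dict(self) -> dict:
        return {
            "library_id": self.library_id,
            "total_reads": self.total_reads,
            "g_strand_reads": self.g_strand_reads,
            "c_strand_reads": self.c_strand_reads,
            "either_reads": self.either_reads,
            "g_strand_per_million": self.per_million(self.g_strand_reads),
            "c_strand_per_million": self.per_million(self.c_strand_reads),
            "either_per_million": self.per_million(self.either_reads),
        }


def count_repeat_reads(
    library: Iterable[ReadRecord],
    library_id: str,
    motif: str = TELOMERE_MOTIF,
    n_repeats: int = DEFAULT_REPEATS,
) -> RepeatCountReport:
    """Single-pass tally of G-strand / C-strand repeat reads in a library.

    A read carrying both motifs increments ``g_strand_reads``,
    ``c_strand_reads`` and ``either_reads`` once each.
    """
    g_pat = motif.upper() * n_repeats
    c_pat = reverse_complement(motif) * n_repeats
    total = g = c = either = 0
    for read in library:
        total += 1
        seq = read.sequence
        has_g = g_pat in seq
        has_c = c_pat in seq
        g += has_g
        c += has_c
        either += has_g or has_c
    report = RepeatCountReport(
        library_id=library_id,
        total_reads=total,
        g_strand_reads=g,
        c_strand_reads=c,
        either_reads=either,
        motif=motif,
        n_repeats=n_repeats,
    )
    return report
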