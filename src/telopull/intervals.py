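"""Genomic interval arithmetic in the 1-based fully-closed convention.

The pipeline's coordinate currency is the convention used by locus strings
such as ``chr16:4871450–4874336``: both endpoints are 1-based and inclusive,
so the span length is ``end - start + 1``.  BED input (0-based, half-open)
is converted at the boundary and never used internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "LocusParseError",
    "parse_locus_string",
    "format_locus_string",
    "interval_length",
    "overlaps",
    "merge_intervals",
    "from_bed_record",
    "to_bed_record",
    "read_bed",
    "write_bed",
    "read_gff3",
]

#: strand symbols: forward, reverse, unknown
FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."

_STRANDS = frozenset({FORWARD, REVERSE, UNKNOWN})

# locus strings as printed use an en-dash; user files typically use a hyphen
_LOCUS_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)[–-](?P<end>\d+)$")
_EN_DASH = "–"


class LocusParseError(ValueError):
    """Raised when a locus string or interval record cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic span ``chrom:start–end`` with optional strand.

    ``start`` and ``end`` are 1-based and both inclusive; ``strand`` is one
    of ``'+'`` (forward), ``'-'`` (reverse) or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)


def parse_locus_string(s: str) -> GenomicInterval:
    """Parse ``<chrom>:<start>–<end>`` (en-dash or hyphen) into an interval.

    The returned interval has unknown strand.  Raises
    :class:`LocusParseError` naming the offending token on malformed input.
    """
    s = s.strip()
    if ":" not in s:
        raise LocusParseError(f"locus string {s!r}: missing ':' separator")
    m = _LOCUS_RE.match(s)
    if m is None:
        chrom, _, span = s.partition(":")
        if not re.search(r"[–-]", span):
            raise LocusParseError(f"locus string {s!r}: missing dash in span {span!r}")
        raise LocusParseError(f"locus string {s!r}: span {span!r} is not <start>-<end>")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise LocusParseError(f"locus string {s!r}: start {start} > end {end}")
    return GenomicInterval(m["chrom"], start, end)


def format_locus_string(iv: GenomicInterval, dash: str = _EN_DASH) -> str:
    """Render an interval as a locus string (en-dash by default, as printed
    in the telomere-enriched lncRNA table)."""
    return f"{iv.chrom}:{iv.start}{dash}{iv.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Span length in bases: ``end - start + 1``."""
    return iv.end - iv.start + 1


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Closed-interval intersection test; strand is ignored.

    Shared endpoints count as overlap (``chr1:10-20`` overlaps
    ``chr1:20-30``).  Chromosome names are compared as exact strings.
    """
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _abuts_or_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start <= b.end + 1 and b.start <= a.end + 1


def merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal set of maximal closed intervals covering the union.

    Overlapping *and abutting* (``end + 1 == next start``) inputs merge —
    probe tiling produces contiguous, non-overlapping probes covering one
    locus.  Output is sorted by (chrom, start); strand of merged spans is
    unknown unless every merged member agrees.
    """
    if not ivs:
        raise ValueError("merge_intervals requires a non-empty list")
    merged: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and _abuts_or_overlaps(merged[-1], iv):
            last = merged[-1]
            strand = last.strand if last.strand == iv.strand else UNKNOWN
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), strand
            )
        else:
            merged.append(iv)
    return merged


def from_bed_record(
    chrom: str, bed_start: int, bed_end: int, strand: str = UNKNOWN
) -> GenomicInterval:
    """Convert a BED (0-based, half-open) record to the internal convention.

    ``(chrom, s, e)`` becomes ``(chrom, s + 1, e)``; empty BED intervals
    (``bed_start >= bed_end``) are rejected.
    """
    if bed_start < 0:
        raise ValueError(f"BED start must be >= 0, got {bed_start}")
    if bed_start >= bed_end:
        raise ValueError(
            f"empty BED interval: start {bed_start} >= end {bed_end}"
        )
    return GenomicInterval(chrom, bed_start + 1, bed_end, strand)


def to_bed_record(iv: GenomicInterval) -> tuple[str, int, int, str]:
    """Inverse of :func:`from_bed_record`."""
    return iv.chrom, iv.start - 1, iv.end, iv.strand


def read_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read a 3–6 column BED file into ``(name, interval)`` pairs.

    The name column defaults to ``<chrom>:<start>-<end>`` when absent.
    Track/browser/comment lines are skipped.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LocusParseError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise LocusParseError(f"{path}:{lineno}: non-numeric BED bounds") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else UNKNOWN
            iv = from_bed_record(chrom, s, e, strand)
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"{chrom}:{s}-{e}"
            out.append((name, iv))
    return out


def write_bed(records: Iterable[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in records:
            chrom, s, e, strand = to_bed_record(iv)
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")


def read_gff3(path) -> list[tuple[str, GenomicInterval]]:
    """Read GFF3 (1-based, closed) feature lines into ``(ID, interval)``.

    The identifier comes from the ``ID=`` attribute, falling back to
    ``Name=`` and then to a positional label.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LocusParseError(f"{path}:{lineno}: GFF3 line has {len(fields)} columns, expected 9")
            chrom, _, _, start, end, _, strand, _, attrs = fields
            try:
                iv = GenomicInterval(
                    chrom, int(start), int(end),
                    strand if strand in _STRANDS else UNKNOWN,
                )
            except ValueError as exc:
                raise LocusParseError(f"{path}:{lineno}: {exc}") from exc
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            rec_id = attr_map.get("ID") or attr_map.get("Name") or f"feature_{lineno}"
            out.append((rec_id, iv))
    return out
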