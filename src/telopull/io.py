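"""Readers and writers for the pipeline's interchange formats.

Machine interchange is plain TSV (tab-delimited, header row, ``.``
decimal, no thousands separators); FASTQ is accepted plain or
gzip-compressed; probe sets come as BED or 5-column TSV; catalogs as GFF3
or BED.  Every writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .discovery import AnnotationRecord, ProbeRecord
from .enrichment import SAMPLES, CountTable
from .intervals import (
    UNKNOWN,
    GenomicInterval,
    from_bed_record,
    read_bed,
    read_gff3,
    to_bed_record,
)
from .repeats import ReadRecord

__all__ = [
    "FastqFormatError",
    "read_fastq",
    "write_fastq",
    "read_count_table",
    "write_count_table",
    "read_probes",
    "write_probes_bed",
    "read_catalog",
    "write_catalog_gff3",
    "write_repeat_report",
    "file_sha256",
    "write_manifest",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ input, reported with the 1-based record index."""


def _open_text(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a plain or gzipped FASTQ file.

    Validates the 4-line record structure ('@'/'+' markers,
    sequence/quality length equality); violations raise
    :class:`FastqFormatError` naming the first bad record.
    """
    with _open_text(path) as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            index += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {index}: {exc}") from exc
            try:
                yield ReadRecord(title.split()[0], seq, qual)
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {index}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_count_table(path) -> CountTable:
    """Parse a ``feature_id<TAB>target<TAB>control`` TSV into a CountTable.

    Duplicate ids and negative or non-numeric counts are rejected with the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = ["feature_id", *SAMPLES]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected header {required}, got {list(df.columns[:3])}"
        )
    for col in SAMPLES:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}:{line}: invalid {col} count {df[col][bad.idxmax()]!r}"
            )
        df[col] = numeric.astype(int)
    dup = df["feature_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}:{line}: duplicate feature_id {df['feature_id'][dup.idxmax()]!r}")
    return CountTable(df.set_index("feature_id")[list(SAMPLES)])


def write_count_table(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_probes(path) -> list[ProbeRecord]:
    """Read a probe set from BED or from a 5-column TSV
    (``probe_id, chrom, start, end, strand`` — 1-based closed)."""
    path = Path(path)
    if path.suffix == ".bed":
        return [ProbeRecord(name, iv) for name, iv in read_bed(path)]
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: probe TSV needs columns {sorted(required)}")
    probes = []
    for _, row in df.iterrows():
        strand = row.get("strand", UNKNOWN)
        strand = strand if strand in ("+", "-") else UNKNOWN
        probes.append(
            ProbeRecord(
                str(row["probe_id"]),
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), strand),
            )
        )
    return probes


def write_probes_bed(probes: Sequence[ProbeRecord], path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            chrom, s, e, strand = to_bed_record(p.interval)
            fh.write(f"{chrom}\t{s}\t{e}\t{p.probe_id}\t0\t{strand}\n")


def read_catalog(path, catalog_label: str) -> list[AnnotationRecord]:
    """Read one annotation catalog (GFF3 or BED) under a catalog label."""
    path = Path(path)
    if path.suffix == ".bed":
        records = read_bed(path)
    else:
        records = read_gff3(path)
    return [AnnotationRecord(rec_id, catalog_label, iv) for rec_id, iv in records]


def write_catalog_gff3(records: Sequence[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\ttelopull\ttranscript\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={rec.record_id}\n"
            )


def write_repeat_report(reports, path) -> None:
    """TSV with one row per library: totals, per-strand counts, per-million."""
    rows = [r.to_dict() for r in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: Sequence, seed=None) -> None:
    """Run manifest: config echo, input checksums, package version, seed —
    enough to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            str(p): file_sha256(p) for p in inputs if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
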