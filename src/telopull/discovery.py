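"""Probe-based lncRNA discovery: re-annotation, locus assembly, filtering.

Microarray-design probes with genomic coordinates are re-annotated against
one or more transcript catalogs by closed-interval overlap, grouped into
loci by single-linkage connectivity (overlapping/abutting probes, or probes
sharing an annotation record), aggregated to locus-level counts, and passed
through the three-way filter chain:

    target RPM  >  target_min   (default 50)
    control RPM <  control_max  (default 500)
    log2 ratio  >  log2_min     (default 1.36, i.e. > 2.5-fold)

All comparisons are strict.  Surviving loci are reported in descending
log2-ratio order with the locus span, a strand consensus label
(Forward / Reverse / N.D.), length, covered probe ids, and per-catalog
record ids (``N.A.`` when a catalog contributes none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .enrichment import (
    DEFAULT_PSEUDOCOUNT,
    CountTable,
    fold_enrichment,
    rpm_normalize,
)
from .intervals import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    GenomicInterval,
    format_locus_string,
    interval_length,
    merge_intervals,
)

__all__ = [
    "ProbeRecord",
    "AnnotationRecord",
    "LocusCall",
    "DEFAULT_TARGET_MIN",
    "DEFAULT_CONTROL_MAX",
    "DEFAULT_LOG2_MIN",
    "reannotate_probes",
    "build_loci",
    "locus_counts",
    "filter_candidates",
    "make_report",
    "render_report",
]

logger = logging.getLogger(__name__)

DEFAULT_TARGET_MIN = 50.0
DEFAULT_CONTROL_MAX = 500.0
DEFAULT_LOG2_MIN = 1.36

NOT_AVAILABLE = "N.A."
NOT_DETERMINED = "N.D."

_STRAND_LABEL = {FORWARD: "Forward", REVERSE: "Reverse"}


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class AnnotationRecord:
    record_id: str
    catalog: str
    interval: GenomicInterval


@dataclass
class LocusCall:
    """One row of the discovery report (a merged multi-probe locus)."""

    interval: GenomicInterval
    strand_label: str
    covered_probes: list[str]
    catalog_ids: dict[str, list[str]]  # catalog label -> record ids (may be empty)
    target_value: float = 0.0
    control_value: float = 0.0
    log2_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not self.covered_probes:
            raise ValueError("a locus call must cover at least one probe")

    @property
    def length(self) -> int:
        return interval_length(self.interval)

    @property
    def locus_id(self) -> str:
        return format_locus_string(self.interval, dash="-")


def reannotate_probes(
    probes: Sequence[ProbeRecord], catalogs: Sequence[AnnotationRecord]
) -> dict[str, list[AnnotationRecord]]:
    """Map each probe to every catalog record overlapping it.

    Overlap is closed-interval and strand-agnostic; probes with no overlap
    map to an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in catalogs:
        iv = rec.interval
        # interval tree is half-open; +1 on the end makes the closed span queryable
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, rec)
    out: dict[str, list[AnnotationRecord]] = {}
    for probe in probes:
        iv = probe.interval
        tree = trees.get(iv.chrom)
        hits = [h.data for h in tree.overlap(iv.start, iv.end + 1)] if tree else []
        hits.sort(key=lambda r: (r.catalog, r.record_id))
        out[probe.probe_id] = hits
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _strand_consensus(strands: Sequence[str]) -> str:
    known = {s for s in strands if s in (FORWARD, REVERSE)}
    if len(known) == 1:
        return _STRAND_LABEL[next(iter(known))]
    return NOT_DETERMINED  # conflicting or all unknown


def build_loci(
    probe_map: Mapping[str, list[AnnotationRecord]],
    probes: Sequence[ProbeRecord],
    catalogs: Sequence[AnnotationRecord],
) -> list[LocusCall]:
    """Group probes into loci and assemble Table-style call skeletons.

    Single-linkage connectivity: two probes join the same locus when their
    intervals overlap or abut, or when they share at least one annotation
    record.  The locus span merges member probe intervals with their
    annotation intervals on the same chromosome; strand consensus over
    member probes yields Forward, Reverse or N.D. (conflicting / unknown).
    """
    probe_by_id = {p.probe_id: p for p in probes}
    uf = _UnionFind(probe_by_id)

    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom_probes in by_chrom.values():
        chrom_probes.sort(key=lambda p: (p.interval.start, p.interval.end))
        for prev, cur in zip(chrom_probes, chrom_probes[1:]):
            if cur.interval.start <= prev.interval.end + 1:
                uf.union(prev.probe_id, cur.probe_id)

    shared: dict[tuple[str, str], str] = {}
    for probe_id, hits in probe_map.items():
        if probe_id not in probe_by_id:
            continue
        for rec in hits:
            key = (rec.catalog, rec.record_id)
            if key in shared:
                uf.union(shared[key], probe_id)
            else:
                shared[key] = probe_id

    groups: dict[str, list[str]] = {}
    for probe_id in probe_by_id:
        groups.setdefault(uf.find(probe_id), []).append(probe_id)

    catalog_labels = sorted({rec.catalog for rec in catalogs})
    calls: list[LocusCall] = []
    for member_ids in groups.values():
        members = sorted(
            (probe_by_id[pid] for pid in member_ids),
            key=lambda p: (p.interval.chrom, p.interval.start, p.probe_id),
        )
        spans = [p.interval for p in members]
        locus_chrom = spans[0].chrom
        ann_records: list[AnnotationRecord] = []
        seen: set[tuple[str, str]] = set()
        for p in members:
            for rec in probe_map.get(p.probe_id, []):
                key = (rec.catalog, rec.record_id)
                if key not in seen:
                    seen.add(key)
                    ann_records.append(rec)
        spans += [r.interval for r in ann_records if r.interval.chrom == locus_chrom]
        merged = merge_intervals(spans)
        on_chrom = [m for m in merged if m.chrom == locus_chrom]
        if len(on_chrom) == 1:
            locus_iv = on_chrom[0]
        else:  # disjoint pieces bridged only by annotation identity: take the envelope
            locus_iv = GenomicInterval(
                locus_chrom, on_chrom[0].start, on_chrom[-1].end
            )
        ids_per_catalog = {label: [] for label in catalog_labels}
        for rec in ann_records:
            ids_per_catalog.setdefault(rec.catalog, []).append(rec.record_id)
        for label in ids_per_catalog:
            ids_per_catalog[label] = sorted(set(ids_per_catalog[label]))
        calls.append(
            LocusCall(
                interval=locus_iv,
                strand_label=_strand_consensus([p.interval.strand for p in members]),
                covered_probes=[p.probe_id for p in members],
                catalog_ids=ids_per_catalog,
            )
        )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return calls


def locus_counts(loci: Sequence[LocusCall], probe_counts: CountTable) -> CountTable:
    """Aggregate probe-level counts to locus level by summation.

    Probes missing from the count table contribute 0 (with a warning);
    when loci partition the probe set, column totals are conserved.
    """
    rows = {}
    counts = probe_counts.counts
    for locus in loci:
        present = [p for p in locus.covered_probes if p in counts.index]
        missing = set(locus.covered_probes) - set(present)
        if missing:
            logger.warning(
                "locus %s: no counts for probes %s, treated as 0",
                locus.locus_id,
                sorted(missing),
            )
        sub = counts.loc[present].sum() if present else pd.Series({"target": 0, "control": 0})
        rows[locus.locus_id] = sub
    df = pd.DataFrame(rows).T.astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["target", "control"], dtype=int)
    return CountTable(df, dict(probe_counts.library_sizes))


def filter_candidates(
    loci: Sequence[LocusCall],
    locus_table: CountTable,
    target_min: float = DEFAULT_TARGET_MIN,
    control_max: float = DEFAULT_CONTROL_MAX,
    log2_min: float = DEFAULT_LOG2_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize: bool = True,
) -> list[LocusCall]:
    """Apply the three-way filter chain to locus-level counts.

    A locus passes iff ``target > target_min`` AND ``control < control_max``
    AND ``log2_ratio > log2_min`` — all strict.  Values are RPM-normalized
    by default (``normalize=False`` applies the cutoffs to raw counts; the
    log2 ratio is always computed on the filtered value scale).
    """
    values = rpm_normalize(locus_table) if normalize else locus_table.counts.astype(float)
    passed: list[LocusCall] = []
    for locus in loci:
        if locus.locus_id not in values.index:
            continue
        t = float(values.at[locus.locus_id, "target"])
        c = float(values.at[locus.locus_id, "control"])
        _, log2_ratio = fold_enrichment(t, c, pseudocount)
        locus.target_value = t
        locus.control_value = c
        locus.log2_ratio = log2_ratio
        if t > target_min and c < control_max and log2_ratio > log2_min:
            passed.append(locus)
    return passed


def make_report(calls: Sequence[LocusCall]) -> pd.DataFrame:
    """Machine-readable discovery report, one row per passing locus.

    Rows are sorted by descending log2 ratio, ties broken by (chrom, start).
    Catalog columns carry comma-joined record ids or ``N.A.``; numbers are
    plain (no thousands separators) for parseability.
    """
    catalog_labels = sorted({label for c in calls for label in c.catalog_ids})
    ordered = sorted(
        calls,
        key=lambda c: (-c.log2_ratio, c.interval.chrom, c.interval.start),
    )
    rows = []
    for c in ordered:
        row = {
            "location": format_locus_string(c.interval, dash="-"),
            "strand": c.strand_label,
            "length": c.length,
            "covered_probes": ", ".join(c.covered_probes),
        }
        for label in catalog_labels:
            ids = c.catalog_ids.get(label, [])
            row[f"{label}_ids"] = ", ".join(ids) if ids else NOT_AVAILABLE
        row["target_value"] = c.target_value
        row["control_value"] = c.control_value
        row["log2_ratio"] = c.log2_ratio
        rows.append(row)
    columns = (
        ["location", "strand", "length", "covered_probes"]
        + [f"{label}_ids" for label in catalog_labels]
        + ["target_value", "control_value", "log2_ratio"]
    )
    return pd.DataFrame(rows, columns=columns)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable rendering: thousands-separated lengths, en-dash
    location strings, log2 ratios to three decimals."""
    if report.empty:
        return "(no loci passed the filter chain)\n"
    pretty = report.copy()
    pretty["length"] = pretty["length"].map(lambda n: f"{n:,}")
    pretty["location"] = pretty["location"].str.replace("-", "–", regex=False)
    for col in ("target_value", "control_value", "log2_ratio"):
        pretty[col] = pretty[col].map(lambda x: f"{x:.3f}")
    return pretty.to_string(index=False) + "\n"
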