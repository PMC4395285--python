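"""Reads-per-million normalization and fold-enrichment ranking.

The pull-down design compares exactly two libraries — a target pull-down
and a non-targeting negative control — with no replicates, so enrichment
is a plain ratio, not a statistical test.  Counts are brought onto a
common scale as reads per million (RPM = count × 1e6 / library size) and
each feature's fold enrichment is

    fold = (target_rpm + p) / (control_rpm + p),      log2_ratio = log2(fold)

with a symmetric pseudocount ``p`` (default 0.5 RPM) keeping the ratio
finite and monotone when the control count is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_MIN_FOLD",
    "rpm_normalize",
    "fold_enrichment",
    "enrichment_table",
    "rank_candidates",
]

DEFAULT_PSEUDOCOUNT = 0.5  # RPM units
DEFAULT_MIN_FOLD = 1.4

SAMPLES = ("target", "control")


@dataclass
class CountTable:
    """Features × {target, control} non-negative read counts.

    ``library_sizes`` are total mapped reads per sample and default to the
    column sums; they may exceed the column sums (reads assigned to
    features the table does not cover) but must be positive for
    normalization.
    """

    counts: pd.DataFrame  # index = feature_id, columns = target, control
    library_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SAMPLES if s not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        self.counts = self.counts[list(SAMPLES)]
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
            raise ValueError("counts must be non-negative numbers")
        sums = self.counts.sum()
        for s in SAMPLES:
            self.library_sizes.setdefault(s, int(sums[s]))
        for s in SAMPLES:
            if self.library_sizes[s] < 0:
                raise ValueError(f"negative library size for {s}")

    @classmethod
    def from_mapping(
        cls,
        target: Mapping[str, int],
        control: Mapping[str, int],
        library_sizes: Optional[dict] = None,
    ) -> "CountTable":
        df = pd.DataFrame({"target": pd.Series(target), "control": pd.Series(control)})
        df = df.fillna(0).astype(int)
        return cls(df, dict(library_sizes or {}))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)


def rpm_normalize(table: CountTable) -> pd.DataFrame:
    """Scale each sample to reads per million: count × 1e6 / library size.

    When the library size equals the column sum, the normalized column sums
    to 1e6 (within floating tolerance).  Zero library sizes are an error.
    """
    for s in SAMPLES:
        if table.library_sizes[s] <= 0:
            raise ValueError(f"library size for {s!r} must be > 0 to normalize")
    scale = pd.Series({s: 1e6 / table.library_sizes[s] for s in SAMPLES})
    return table.counts.astype(float).mul(scale, axis=1)


def fold_enrichment(
    target_rpm: float, control_rpm: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[float, float]:
    """Pseudocounted target/control ratio and its log2.

    Strictly increasing in ``target_rpm`` and strictly decreasing in
    ``control_rpm``; with both RPMs > 0 the ratio tends to the plain
    ``target_rpm / control_rpm`` as the pseudocount goes to 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if target_rpm < 0 or control_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    fold = (target_rpm + pseudocount) / (control_rpm + pseudocount)
    return fold, math.log2(fold)


def enrichment_table(
    table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-feature enrichment results.

    Columns: target_count, control_count, target_rpm, control_rpm,
    fold_enrichment, log2_ratio; index = feature_id.
    """
    rpm = rpm_normalize(table)
    fold = (rpm["target"] + pseudocount) / (rpm["control"] + pseudocount)
    return pd.DataFrame(
        {
            "target_count": table.counts["target"],
            "control_count": table.counts["control"],
            "target_rpm": rpm["target"],
            "control_rpm": rpm["control"],
            "fold_enrichment": fold,
            "log2_ratio": np.log2(fold),
        }
    )


def rank_candidates(
    results: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    coordinates: Optional[Mapping[str, tuple[str, int]]] = None,
) -> pd.DataFrame:
    """Retain features with fold enrichment strictly above ``min_fold``,
    sorted by descending fold.

    Ties are broken by genomic coordinate ``(chrom, start)`` when supplied,
    otherwise by feature id, so repeated runs on shuffled input produce
    identical output.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be > 0")
    kept = results[results["fold_enrichment"] > min_fold].copy()
    if coordinates:
        key = [coordinates.get(fid, ("", 0)) for fid in kept.index]
    else:
        key = list(kept.index)
    kept["_tiebreak"] = key
    kept = kept.sort_values(
        by=["fold_enrichment", "_tiebreak"], ascending=[False, True], kind="mergesort"
    )
    return kept.drop(columns="_tiebreak")
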