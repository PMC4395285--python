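"""Umbrella pipeline: repeat counting → enrichment ranking → lncRNA discovery.

``run_pipeline`` executes whichever stages its config enables (FASTQ paths
enable repeat counting; a count table enables enrichment; probes plus at
least one catalog enable discovery), writes one TSV report per stage plus
a JSON run manifest, and is deterministic: identical inputs and config
yield byte-identical machine outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as tio
from .discovery import (
    DEFAULT_CONTROL_MAX,
    DEFAULT_LOG2_MIN,
    DEFAULT_TARGET_MIN,
    build_loci,
    filter_candidates,
    locus_counts,
    make_report,
    reannotate_probes,
)
from .enrichment import (
    DEFAULT_MIN_FOLD,
    DEFAULT_PSEUDOCOUNT,
    enrichment_table,
    rank_candidates,
)
from .repeats import DEFAULT_REPEATS, TELOMERE_MOTIF, count_repeat_reads

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("telopull")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage label."""


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds in one validated bundle."""

    # inputs (any subset; each enables its stage)
    target_fastq: Optional[str] = None
    control_fastq: Optional[str] = None
    counts: Optional[str] = None
    probes: Optional[str] = None
    catalogs: dict = field(default_factory=dict)  # label -> path
    outdir: str = "telopull_out"

    # thresholds (study defaults)
    # total mapped reads per library; default: column sums of the count table
    library_size_target: Optional[int] = None
    library_size_control: Optional[int] = None

    min_fold: float = DEFAULT_MIN_FOLD
    target_min: float = DEFAULT_TARGET_MIN
    control_max: float = DEFAULT_CONTROL_MAX
    log2_min: float = DEFAULT_LOG2_MIN
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    motif: str = TELOMERE_MOTIF
    repeats: int = DEFAULT_REPEATS
    normalize: bool = True

    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        problems = []
        for name in ("min_fold", "target_min", "control_max", "pseudocount"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.repeats < 1:
            problems.append("repeats must be >= 1")
        if not self.motif:
            problems.append("motif must be non-empty")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def wrap(exc):
        return PipelineError(f"[{name}] {exc}")

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns {stage: output path}.

    Raises :class:`PipelineError` with a stage-labeled message on any
    failure; partially written stage outputs are removed.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="[%(name)s] %(levelname)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    inputs = [p for p in (config.target_fastq, config.control_fastq,
                          config.counts, config.probes,
                          *config.catalogs.values()) if p]

    want_discovery = bool(config.probes or config.catalogs)
    if want_discovery and not (config.probes and config.catalogs and config.counts):
        raise PipelineError(
            "[config] discovery requires probes, at least one catalog, and probe-level counts"
        )
    for p in inputs:
        if not Path(p).exists():
            raise PipelineError(f"[config] input not found: {p}")

    # stage 1: telomeric-repeat read counting
    if config.target_fastq or config.control_fastq:
        reports = []
        try:
            for lib, path in (("target", config.target_fastq),
                              ("control", config.control_fastq)):
                if path:
                    logger.info("[terra] counting repeat reads in %s", path)
                    reports.append(
                        count_repeat_reads(
                            tio.read_fastq(path), lib,
                            motif=config.motif, n_repeats=config.repeats,
                        )
                    )
            out = outdir / "terra_report.tsv"
            tio.write_repeat_report(reports, out)
            outputs["terra"] = str(out)
        except Exception as exc:
            _cleanup(outdir / "terra_report.tsv")
            raise PipelineError(f"[terra] {exc}") from exc

    # stage 2: enrichment ranking
    table = None
    if config.counts:
        try:
            logger.info("[enrich] ranking features from %s", config.counts)
            table = tio.read_count_table(config.counts)
            if config.library_size_target:
                table.library_sizes["target"] = config.library_size_target
            if config.library_size_control:
                table.library_sizes["control"] = config.library_size_control
            results = enrichment_table(table, pseudocount=config.pseudocount)
            ranked = rank_candidates(results, min_fold=config.min_fold)
            out = outdir / "enrichment.tsv"
            ranked.index.name = "feature_id"
            ranked.to_csv(out, sep="\t", float_format="%.6g")
            outputs["enrich"] = str(out)
        except PipelineError:
            raise
        except Exception as exc:
            _cleanup(outdir / "enrichment.tsv")
            raise PipelineError(f"[enrich] {exc}") from exc

    # stage 3: probe-based lncRNA discovery
    if want_discovery:
        try:
            logger.info("[discover] probe re-annotation and locus filtering")
            probes = tio.read_probes(config.probes)
            catalogs = []
            for label, path in sorted(config.catalogs.items()):
                catalogs.extend(tio.read_catalog(path, label))
            probe_map = reannotate_probes(probes, catalogs)
            loci = build_loci(probe_map, probes, catalogs)
            locus_table = locus_counts(loci, table)
            calls = filter_candidates(
                loci, locus_table,
                target_min=config.target_min,
                control_max=config.control_max,
                log2_min=config.log2_min,
                pseudocount=config.pseudocount,
                normalize=config.normalize,
            )
            report = make_report(calls)
            out = outdir / "discovery.tsv"
            report.to_csv(out, sep="\t", index=False, float_format="%.6g")
            outputs["discover"] = str(out)
        except PipelineError:
            raise
        except Exception as exc:
            _cleanup(outdir / "discovery.tsv")
            raise PipelineError(f"[discover] {exc}") from exc

    manifest = outdir / "manifest.json"
    tio.write_manifest(manifest, config.to_dict(), inputs, seed=config.seed)
    outputs["manifest"] = str(manifest)
    return outputs


def _cleanup(path: Path) -> None:
    try:
        path.unlink(missing_ok=True)
    except OSError:
        pass
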