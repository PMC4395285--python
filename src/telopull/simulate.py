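"""Seeded synthetic pull-down experiments with known ground truth.

The generator emulates the shape of a locus-specific chromatin RNA
pull-down experiment: one target library and one negative-control library,
no replicates.  It produces

* a feature × {target, control} count table with negative-binomial counts,
  a small planted subset of features carrying elevated target/control
  ratio and a background at ratio 1;
* paired FASTQ libraries in which an exact number of reads carries a
  contiguous telomeric-repeat block — (TTAGGG)4-or-longer, half in the
  reverse-complement (CCCTAA) form — at different rates in target vs.
  control, against motif-free random background reads;
* a probe set tiling each feature and two toy annotation catalogs, with
  configurable dropout (exercising N.A. rendering) and strand conflicts
  (exercising N.D.).

Everything derives from one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .enrichment import CountTable
from .intervals import FORWARD, REVERSE, GenomicInterval
from .repeats import TELOMERE_MOTIF, reverse_complement

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_fastq",
    "simulate_probes_and_catalogs",
    "simulate_probe_counts",
    "simulate_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults mirror the study shape
    (two libraries, no replicates, overdispersed counts).

    ``planted_log2_fold`` is the mean log2 target/control enrichment of the
    planted telomere-associated features (background sits at 0);
    ``nb_dispersion`` is the negative-binomial dispersion phi in
    var = mu + phi * mu^2; ``terra_rate_*`` are the exact fractions of reads
    per library carrying a telomeric-repeat block.
    """

    seed: int = 0
    n_features: int = 500
    planted_fraction: float = 0.04
    planted_log2_fold: float = 2.585  # ~6-fold
    baseline_mean: float = 20.0      # mean control reads per feature
    baseline_log_sd: float = 0.5     # log-normal spread of per-feature means
    planted_jitter_sd: float = 0.2   # sd of per-feature log2-fold jitter
    nb_dispersion: float = 0.1
    library_depth_target: int = 200_000
    library_depth_control: int = 200_000
    terra_rate_target: float = 0.005
    terra_rate_control: float = 0.001
    read_length: int = 100
    probe_per_feature: int = 3
    catalog_dropout: float = 0.2     # fraction of features absent per catalog
    strand_conflict_fraction: float = 0.1
    genome: tuple = (("chr1", 20_000_000), ("chr2", 20_000_000), ("chr3", 20_000_000))
    feature_length_range: tuple = (1_000, 9_000)

    def validate(self) -> None:
        problems = []
        if self.n_features < 1:
            problems.append("n_features must be >= 1")
        if not 0 < self.planted_fraction < 1:
            problems.append("planted_fraction must be in (0, 1)")
        if self.baseline_mean <= 0:
            problems.append("baseline_mean must be > 0")
        if self.nb_dispersion <= 0:
            problems.append("nb_dispersion must be > 0")
        for name in ("library_depth_target", "library_depth_control"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("terra_rate_target", "terra_rate_control",
                     "catalog_dropout", "strand_conflict_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{name} must be in [0, 1]")
        if self.read_length < 24 and (self.terra_rate_target > 0 or self.terra_rate_control > 0):
            problems.append("read_length must be >= 24 to fit a (TTAGGG)x4 block")
        if self.probe_per_feature < 1:
            problems.append("probe_per_feature must be >= 1")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    @property
    def n_planted(self) -> int:
        return round(self.planted_fraction * self.n_features)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["feature_length_range"] = list(self.feature_length_range)
        return d


@dataclass
class GroundTruth:
    """What the generator actually planted, sufficient to score every
    downstream stage without re-reading the config."""

    features: pd.DataFrame  # index feature_id; planted, true_log2, chrom, start, end, strand
    terra_read_ids: dict = field(default_factory=dict)  # library -> list of read ids

    @property
    def planted_ids(self) -> list[str]:
        return list(self.features.index[self.features["planted"]])

    @property
    def background_ids(self) -> list[str]:
        return list(self.features.index[~self.features["planted"]])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per stage so stages can be re-run in isolation
    return np.random.default_rng([config.seed, stream])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _place_features(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping feature intervals round-robined over the genome."""
    chroms = list(config.genome)
    lo, hi = config.feature_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_features)
    rows = []
    gap = 50_000
    cursors = {name: 1 for name, _ in chroms}
    for i in range(config.n_features):
        name, chrom_len = chroms[i % len(chroms)]
        start = cursors[name] + int(rng.integers(1_000, 10_000))
        end = start + int(lengths[i]) - 1
        if end > chrom_len:  # wrap is a config error at these defaults; fail loudly
            raise ValueError(f"features do not fit on {name}; enlarge the genome")
        cursors[name] = end + gap
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        rows.append((f"feat{i:04d}", name, start, end, strand))
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "strand"])
    return df.set_index("feature_id")


def simulate_counts(config: SimulationConfig) -> tuple[CountTable, GroundTruth]:
    """Negative-binomial two-library count table with planted enrichment.

    Control counts are NB with per-feature means mu_i drawn log-normally
    around ``baseline_mean``; target counts are NB with mean
    ``mu_i * 2^f_i * depth_ratio`` where f_i is the planted log2 fold
    (jittered, sd ``planted_jitter_sd``) for planted features and 0
    otherwise.  Same seed, same table.
    """
    config.validate()
    rng = _rng(config, stream=1)
    features = _place_features(config, rng)
    n = config.n_features
    planted = np.zeros(n, dtype=bool)
    planted_idx = rng.choice(n, size=config.n_planted, replace=False)
    planted[planted_idx] = True

    log_mu = np.log(config.baseline_mean) - config.baseline_log_sd**2 / 2
    mu = rng.lognormal(mean=log_mu, sigma=config.baseline_log_sd, size=n)
    true_log2 = np.zeros(n)
    true_log2[planted] = config.planted_log2_fold + rng.normal(
        0.0, config.planted_jitter_sd, size=planted.sum()
    )
    depth_ratio = config.library_depth_target / config.library_depth_control
    control = _nb_draw(rng, mu, config.nb_dispersion)
    target = _nb_draw(rng, mu * 2.0**true_log2 * depth_ratio, config.nb_dispersion)

    features = features.assign(planted=planted, true_log2=true_log2)
    counts = pd.DataFrame(
        {"target": target, "control": control}, index=features.index
    )
    table = CountTable(
        counts,
        {
            "target": config.library_depth_target,
            "control": config.library_depth_control,
        },
    )
    return table, GroundTruth(features=features)


def _random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode() for row in arr]


def _background_reads(
    rng: np.random.Generator, n: int, length: int, forbidden: tuple[str, str]
) -> list[str]:
    """Uniform-random reads rejection-sampled to contain neither motif block."""
    out: list[str] = []
    while len(out) < n:
        for seq in _random_reads(rng, n - len(out), length):
            if forbidden[0] not in seq and forbidden[1] not in seq:
                out.append(seq)
    return out


def _planted_read(
    rng: np.random.Generator, length: int, unit: str, forbidden: tuple[str, str]
) -> str:
    """A read carrying one contiguous block of >= 4 repeat units."""
    max_reps = length // len(unit)
    reps = int(rng.integers(4, max_reps + 1))
    block = unit * reps
    pad = length - len(block)
    offset = int(rng.integers(0, pad + 1)) if pad else 0
    while True:
        flanks = _random_reads(rng, 1, pad)[0] if pad else ""
        seq = flanks[:offset] + block + flanks[offset:]
        # flanks must not themselves contain a motif block (either strand);
        # the planted block is masked out before checking
        masked = seq.replace(block, "X" * len(block), 1)
        if forbidden[0] not in masked and forbidden[1] not in masked:
            return seq


def simulate_fastq(
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
    target_path: Optional[Path] = None,
    control_path: Optional[Path] = None,
    motif: str = TELOMERE_MOTIF,
) -> GroundTruth:
    """Write paired FASTQ libraries with exact-count planted repeat reads.

    ``round(rate * depth)`` reads per library carry a contiguous block of
    >= 4 motif repeats (half as the reverse-complement form); every other
    read is rejection-sampled background free of both motif blocks.
    Quality strings are constant ``'I'``.  Read-level truth (planted read
    ids) is recorded on the returned :class:`GroundTruth`.
    """
    config.validate()
    if truth is None:
        truth = GroundTruth(features=pd.DataFrame())
    g_block = motif.upper() * 4
    c_block = reverse_complement(motif) * 4
    libraries = {
        "target": (config.library_depth_target, config.terra_rate_target, target_path, 2),
        "control": (config.library_depth_control, config.terra_rate_control, control_path, 3),
    }
    for lib, (depth, rate, path, stream) in libraries.items():
        rng = _rng(config, stream=stream)
        n_planted = round(rate * depth)
        n_g = n_planted // 2 + n_planted % 2
        n_c = n_planted // 2
        seqs = _background_reads(rng, depth - n_planted, config.read_length, (g_block, c_block))
        planted_seqs = [
            _planted_read(rng, config.read_length, motif.upper(), (g_block, c_block))
            for _ in range(n_g)
        ] + [
            _planted_read(rng, config.read_length, reverse_complement(motif), (g_block, c_block))
            for _ in range(n_c)
        ]
        seqs.extend(planted_seqs)
        order = rng.permutation(depth)
        planted_flags = np.zeros(depth, dtype=bool)
        planted_flags[depth - n_planted:] = True
        read_ids = [f"{lib}_read{i:07d}" for i in range(depth)]
        truth.terra_read_ids[lib] = [
            read_ids[pos] for pos, j in enumerate(order) if planted_flags[j]
        ]
        if path is not None:
            qual = "I" * config.read_length
            opener = _opener(path)
            with opener(path, "wt") as fh:
                for pos, j in enumerate(order):
                    fh.write(f"@{read_ids[pos]}\n{seqs[j]}\n+\n{qual}\n")
    return truth


def _opener(path):
    import gzip

    return gzip.open if str(path).endswith(".gz") else open


def simulate_probes_and_catalogs(
    config: SimulationConfig, truth: GroundTruth
):
    """Tile probes over each feature and build two toy catalogs.

    Each feature gets ``probe_per_feature`` probes tiled without gaps
    across its span; catalogs A and B carry the feature interval under
    catalog-specific ids, with a ``catalog_dropout`` fraction of features
    absent from each catalog and a ``strand_conflict_fraction`` of features
    carrying mixed probe strands.
    """
    from .discovery import AnnotationRecord, ProbeRecord

    config.validate()
    rng = _rng(config, stream=4)
    probes: list[ProbeRecord] = []
    catalogs: list[AnnotationRecord] = []
    feat = truth.features
    conflicted = rng.random(len(feat)) < config.strand_conflict_fraction
    drop_a = rng.random(len(feat)) < config.catalog_dropout
    drop_b = rng.random(len(feat)) < config.catalog_dropout
    probe_ids_col = []
    k = config.probe_per_feature
    for i, (fid, row) in enumerate(feat.iterrows()):
        start, end = int(row["start"]), int(row["end"])
        bounds = np.linspace(start, end + 1, k + 1).astype(int)
        fid_probes = []
        for j in range(k):
            p_start, p_end = int(bounds[j]), int(bounds[j + 1]) - 1
            strand = row["strand"]
            if conflicted[i] and j == k - 1 and k > 1:
                strand = REVERSE if strand == FORWARD else FORWARD
            pid = f"{fid}_p{j}"
            fid_probes.append(pid)
            probes.append(
                ProbeRecord(pid, GenomicInterval(row["chrom"], p_start, p_end, strand))
            )
        probe_ids_col.append(",".join(fid_probes))
        iv = GenomicInterval(row["chrom"], start, end, row["strand"])
        if not drop_a[i]:
            catalogs.append(AnnotationRecord(f"catA_{i:05d}", "catalog_A", iv))
        if not drop_b[i]:
            catalogs.append(AnnotationRecord(f"catB_{i:05d}", "catalog_B", iv))
    truth.features = feat.assign(
        probe_ids=probe_ids_col,
        strand_conflict=conflicted,
        in_catalog_A=~drop_a,
        in_catalog_B=~drop_b,
    )
    return probes, catalogs


def simulate_probe_counts(
    config: SimulationConfig, truth: GroundTruth, feature_table: CountTable
) -> CountTable:
    """Split each feature's counts over its probes (multinomial, near-even).

    Locus-level re-aggregation by summation then conserves the feature
    totals exactly.
    """
    rng = _rng(config, stream=5)
    if "probe_ids" not in truth.features.columns:
        raise ValueError("run simulate_probes_and_catalogs first")
    rows = {}
    for fid, row in truth.features.iterrows():
        pids = row["probe_ids"].split(",")
        k = len(pids)
        probs = np.full(k, 1.0 / k)
        for sample in ("target", "control"):
            total = int(feature_table.counts.at[fid, sample])
            split = rng.multinomial(total, probs)
            for pid, c in zip(pids, split):
                rows.setdefault(pid, {})[sample] = int(c)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return CountTable(df, dict(feature_table.library_sizes))


def simulate_experiment(config: SimulationConfig, outdir: Path) -> GroundTruth:
    """Generate and write a complete synthetic experiment bundle.

    Writes target.fastq.gz, control.fastq.gz, counts.tsv (feature level),
    probe_counts.tsv, probes.bed, catalogA.gff3, catalogB.gff3, truth.tsv.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_counts(config)
    probes, catalogs = simulate_probes_and_catalogs(config, truth)
    probe_table = simulate_probe_counts(config, truth, table)
    simulate_fastq(
        config,
        truth,
        target_path=outdir / "target.fastq.gz",
        control_path=outdir / "control.fastq.gz",
    )
    tio.write_count_table(table, outdir / "counts.tsv")
    tio.write_count_table(probe_table, outdir / "probe_counts.tsv")
    tio.write_probes_bed(probes, outdir / "probes.bed")
    tio.write_catalog_gff3(
        [c for c in catalogs if c.catalog == "catalog_A"], outdir / "catalogA.gff3"
    )
    tio.write_catalog_gff3(
        [c for c in catalogs if c.catalog == "catalog_B"], outdir / "catalogB.gff3"
    )
    truth.features.to_csv(outdir / "truth.tsv", sep="\t")
    return truth
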