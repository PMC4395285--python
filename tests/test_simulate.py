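"""Synthetic-experiment generator: determinism, planted truth, FASTQ."""

import numpy as np
import pandas as pd
import pytest

from telopull.enrichment import enrichment_table
from telopull.io import read_fastq
from telopull.repeats import count_repeat_reads
from telopull.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_fastq,
    simulate_probe_counts,
    simulate_probes_and_catalogs,
)

SMALL = dict(
    n_features=50,
    library_depth_target=2000,
    library_depth_control=2000,
    read_length=60,
)


class TestConfigValidation:
    def test_planted_count_is_config_arithmetic(self):
        cfg = SimulationConfig(planted_fraction=0.04, n_features=500)
        assert cfg.n_planted == 20

    def test_invalid_fields_are_all_listed(self):
        cfg = SimulationConfig(planted_fraction=1.5, nb_dispersion=-1, read_length=10)
        with pytest.raises(ValueError) as exc:
            cfg.validate()
        msg = str(exc.value)
        assert "planted_fraction" in msg
        assert "nb_dispersion" in msg
        assert "read_length" in msg

    def test_short_reads_allowed_when_no_motifs_planted(self):
        SimulationConfig(
            read_length=10, terra_rate_target=0, terra_rate_control=0
        ).validate()


class TestSimulateCounts:
    def test_same_seed_identical_tables(self):
        a, ta = simulate_counts(SimulationConfig(seed=7, **SMALL))
        b, tb = simulate_counts(SimulationConfig(seed=7, **SMALL))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta.features, tb.features)

    def test_different_seed_differs(self):
        a, _ = simulate_counts(SimulationConfig(seed=7, **SMALL))
        b, _ = simulate_counts(SimulationConfig(seed=8, **SMALL))
        assert not a.counts.equals(b.counts)

    def test_ground_truth_marks_exactly_the_planted_fraction(self):
        _, truth = simulate_counts(SimulationConfig(seed=1, **SMALL))
        assert truth.features["planted"].sum() == round(0.04 * 50)
        assert set(truth.planted_ids).isdisjoint(truth.background_ids)

    def test_planted_log2_recovery_at_study_depth(self):
        """With planted log2 fold 2.0 at depth 2e5, the pooled median
        estimated log2 ratio over planted features sits within +-0.3."""
        pooled = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, planted_log2_fold=2.0)
            table, truth = simulate_counts(cfg)
            res = enrichment_table(table)
            pooled.extend(res.loc[truth.planted_ids, "log2_ratio"])
        assert abs(np.median(pooled) - 2.0) <= 0.3

    def test_feature_intervals_are_valid_and_disjoint(self):
        _, truth = simulate_counts(SimulationConfig(seed=3, **SMALL))
        feats = truth.features.sort_values(["chrom", "start"])
        assert (feats["end"] >= feats["start"]).all()
        for _, group in feats.groupby("chrom"):
            starts, ends = group["start"].to_numpy(), group["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()


class TestSimulateFastq:
    def test_zero_rate_means_zero_repeat_reads(self, tmp_path):
        cfg = SimulationConfig(seed=5, terra_rate_target=0.0, **SMALL)
        path = tmp_path / "t.fastq"
        simulate_fastq(cfg, target_path=path)
        report = count_repeat_reads(read_fastq(path), "t")
        assert report.either_reads == 0
        assert report.total_reads == 2000

    def test_planting_is_by_exact_count(self, tmp_path):
        cfg = SimulationConfig(seed=5, terra_rate_target=0.01, **SMALL)
        path = tmp_path / "t.fastq"
        truth = simulate_fastq(cfg, target_path=path)
        report = count_repeat_reads(read_fastq(path), "t")
        assert report.g_strand_reads + report.c_strand_reads == 20  # 0.01 * 2000
        assert report.either_reads == 20
        assert len(truth.terra_read_ids["target"]) == 20

    def test_detector_finds_exactly_the_planted_reads(self, tmp_path):
        cfg = SimulationConfig(seed=11, terra_rate_target=0.02, **SMALL)
        path = tmp_path / "t.fastq"
        truth = simulate_fastq(cfg, target_path=path)
        planted = set(truth.terra_read_ids["target"])
        from telopull.repeats import classify_read

        found = {
            r.read_id for r in read_fastq(path) if classify_read(r) != "neither"
        }
        assert found == planted

    def test_gzip_round_trip_and_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        p1, p2 = tmp_path / "a.fastq.gz", tmp_path / "b.fastq.gz"
        simulate_fastq(cfg, target_path=p1)
        simulate_fastq(cfg, target_path=p2)
        reads1 = list(read_fastq(p1))
        reads2 = list(read_fastq(p2))
        assert reads1 == reads2
        assert len(reads1) == 2000
        assert all(len(r.sequence) == 60 for r in reads1)


class TestProbesAndCatalogs:
    @pytest.fixture
    def experiment(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        table, truth = simulate_counts(cfg)
        probes, catalogs = simulate_probes_and_catalogs(cfg, truth)
        return cfg, table, truth, probes, catalogs

    def test_probe_tiling_shape(self, experiment):
        cfg, _, truth, probes, _ = experiment
        assert len(probes) == cfg.probe_per_feature * cfg.n_features
        by_feature = {}
        for p in probes:
            by_feature.setdefault(p.probe_id.rsplit("_p", 1)[0], []).append(p)
        for fid, group in by_feature.items():
            row = truth.features.loc[fid]
            group.sort(key=lambda p: p.interval.start)
            assert group[0].interval.start == row["start"]
            assert group[-1].interval.end == row["end"]
            for a, b in zip(group, group[1:]):  # gapless tiling
                assert b.interval.start == a.interval.end + 1

    def test_catalog_dropout_recorded_in_truth(self, experiment):
        _, _, truth, _, catalogs = experiment
        in_a = {c.record_id for c in catalogs if c.catalog == "catalog_A"}
        expected = int(truth.features["in_catalog_A"].sum())
        assert len(in_a) == expected
        assert 0 < expected < len(truth.features)

    def test_strand_conflicts_present(self, experiment):
        _, _, truth, probes, _ = experiment
        conflicted = truth.features.index[truth.features["strand_conflict"]]
        assert len(conflicted) > 0
        for fid in conflicted:
            strands = {
                p.interval.strand for p in probes if p.probe_id.startswith(f"{fid}_p")
            }
            assert strands == {"+", "-"}

    def test_probe_counts_conserve_feature_totals(self, experiment):
        cfg, table, truth, _, _ = experiment
        probe_table = simulate_probe_counts(cfg, truth, table)
        assert probe_table.counts["target"].sum() == table.counts["target"].sum()
        assert probe_table.counts["control"].sum() == table.counts["control"].sum()
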