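"""Probe re-annotation, locus assembly, filter chain and report."""

import numpy as np
import pandas as pd
import pytest

from telopull.discovery import (
    AnnotationRecord,
    LocusCall,
    ProbeRecord,
    build_loci,
    filter_candidates,
    locus_counts,
    make_report,
    reannotate_probes,
    render_report,
)
from telopull.enrichment import CountTable
from telopull.intervals import GenomicInterval, interval_length, parse_locus_string


def P(pid, chrom, start, end, strand="."):
    return ProbeRecord(pid, GenomicInterval(chrom, start, end, strand))


def A(rid, catalog, chrom, start, end):
    return AnnotationRecord(rid, catalog, GenomicInterval(chrom, start, end))


def table_from(probe_counts: dict, sizes=None) -> CountTable:
    df = pd.DataFrame(probe_counts, index=["target", "control"]).T
    return CountTable(df, dict(sizes or {}))


class TestReannotateProbes:
    def test_probe_inside_one_transcript(self):
        got = reannotate_probes([P("p1", "chr1", 100, 160)], [A("tx1", "catalog_A", "chr1", 50, 500)])
        assert [r.record_id for r in got["p1"]] == ["tx1"]

    def test_probe_spanning_two_catalogs_gets_both(self):
        cats = [A("tx1", "catalog_A", "chr1", 50, 150), A("tx9", "catalog_B", "chr1", 140, 400)]
        got = reannotate_probes([P("p1", "chr1", 100, 160)], cats)
        assert {(r.catalog, r.record_id) for r in got["p1"]} == {
            ("catalog_A", "tx1"),
            ("catalog_B", "tx9"),
        }

    def test_unknown_chromosome_maps_to_empty(self):
        got = reannotate_probes([P("p1", "chrZ", 1, 50)], [A("tx1", "catalog_A", "chr1", 1, 100)])
        assert got["p1"] == []

    def test_closed_interval_endpoint_overlap(self):
        got = reannotate_probes([P("p1", "chr1", 100, 200)], [A("tx1", "catalog_A", "chr1", 200, 300)])
        assert [r.record_id for r in got["p1"]] == ["tx1"]


class TestBuildLoci:
    def test_tiled_probes_form_one_forward_locus(self):
        probes = [
            P("p1", "chr1", 100, 199, "+"),
            P("p2", "chr1", 200, 299, "+"),
            P("p3", "chr1", 300, 399, "+"),
        ]
        loci = build_loci({p.probe_id: [] for p in probes}, probes, [])
        assert len(loci) == 1
        locus = loci[0]
        assert locus.strand_label == "Forward"
        assert locus.covered_probes == ["p1", "p2", "p3"]
        assert (locus.interval.start, locus.interval.end) == (100, 399)
        assert locus.length == 300

    def test_opposite_strands_sharing_annotation_give_nd(self):
        probes = [P("p1", "chr1", 100, 199, "+"), P("p2", "chr1", 5000, 5099, "-")]
        ann = A("tx1", "catalog_A", "chr1", 50, 6000)
        probe_map = {"p1": [ann], "p2": [ann]}
        loci = build_loci(probe_map, probes, [ann])
        assert len(loci) == 1
        assert loci[0].strand_label == "N.D."
        # the locus span includes the bridging annotation interval
        assert (loci[0].interval.start, loci[0].interval.end) == (50, 6000)

    def test_orphan_probe_is_a_singleton_with_na(self):
        probes = [P("p1", "chr3", 10, 40)]
        loci = build_loci({"p1": []}, probes, [A("x", "catalog_A", "chr1", 1, 9)])
        assert len(loci) == 1
        assert loci[0].catalog_ids == {"catalog_A": []}
        assert loci[0].strand_label == "N.D."  # strand unknown

    def test_reverse_consensus(self):
        probes = [P("p1", "chr1", 1, 10, "-"), P("p2", "chr1", 11, 20, "-")]
        loci = build_loci({"p1": [], "p2": []}, probes, [])
        assert loci[0].strand_label == "Reverse"

    def test_disjoint_probe_groups_stay_separate(self):
        probes = [P("p1", "chr1", 1, 10), P("p2", "chr1", 10_000, 10_100)]
        loci = build_loci({"p1": [], "p2": []}, probes, [])
        assert len(loci) == 2


class TestLocusCounts:
    def _locus(self, pids, offset=0):
        return LocusCall(
            interval=GenomicInterval("chr1", 1 + 1000 * offset, 100 + 1000 * offset),
            strand_label="Forward",
            covered_probes=pids,
            catalog_ids={},
        )

    def test_sum_over_member_probes(self):
        probe_table = table_from({"p1": [5, 1], "p2": [7, 2], "p3": [8, 3]})
        out = locus_counts([self._locus(["p1", "p2", "p3"])], probe_table)
        assert out.counts.iloc[0].tolist() == [20, 6]

    def test_missing_probe_counts_as_zero_with_warning(self, caplog):
        probe_table = table_from({"p1": [5, 1]})
        with caplog.at_level("WARNING"):
            out = locus_counts([self._locus(["p1", "ghost"])], probe_table)
        assert out.counts.iloc[0].tolist() == [5, 1]
        assert "ghost" in caplog.text

    def test_partition_conserves_column_totals(self, rng):
        probe_ids = [f"p{i}" for i in range(100)]
        probe_table = table_from(
            {p: [int(rng.integers(0, 50)), int(rng.integers(0, 50))] for p in probe_ids}
        )
        edges = sorted(rng.choice(np.arange(1, 100), size=9, replace=False))
        groups = np.split(np.array(probe_ids), edges)
        loci = [self._locus(list(g), i) for i, g in enumerate(groups) if len(g)]
        out = locus_counts(loci, probe_table)
        assert out.counts["target"].sum() == probe_table.counts["target"].sum()
        assert out.counts["control"].sum() == probe_table.counts["control"].sum()


class TestFilterCandidates:
    def _one_locus_setup(self, target, control):
        locus = LocusCall(
            interval=GenomicInterval("chr1", 1, 100),
            strand_label="Forward",
            covered_probes=["p1"],
            catalog_ids={},
        )
        # library sizes of exactly 1e6 make RPM equal to the raw count
        df = pd.DataFrame({"target": [target], "control": [control]}, index=[locus.locus_id])
        table = CountTable(df, {"target": 10**6, "control": 10**6})
        return locus, table

    @pytest.mark.parametrize(
        "target,control,passes",
        [
            (60, 10, True),    # log2((60+.5)/(10+.5)) ~ 2.527 > 1.36
            (50, 10, False),   # target not strictly above 50
            (600, 500, False), # control not strictly below 500
            (51, 499, False),  # ratio too small
        ],
    )
    def test_strict_threshold_chain(self, target, control, passes):
        locus, table = self._one_locus_setup(target, control)
        got = filter_candidates([locus], table)
        assert bool(got) is passes
        if passes:
            assert got[0].log2_ratio == pytest.approx(2.527, abs=5e-4)

    def test_raising_thresholds_never_admits_more(self, rng):
        loci, rows = [], {}
        for i in range(200):
            locus = LocusCall(
                interval=GenomicInterval("chr1", 1 + 1000 * i, 500 + 1000 * i),
                strand_label="N.D.",
                covered_probes=[f"p{i}"],
                catalog_ids={},
            )
            loci.append(locus)
            rows[locus.locus_id] = [int(rng.integers(0, 800)), int(rng.integers(0, 800))]
        df = pd.DataFrame(rows, index=["target", "control"]).T
        table = CountTable(df, {"target": 10**6, "control": 10**6})
        base = len(filter_candidates(loci, table))
        assert len(filter_candidates(loci, table, target_min=80)) <= base
        assert len(filter_candidates(loci, table, control_max=300)) <= base
        assert len(filter_candidates(loci, table, log2_min=2.0)) <= base


class TestMakeReport:
    def _call(self, chrom, start, end, log2, probes=("pA",), strand="Forward", cats=None):
        c = LocusCall(
            interval=GenomicInterval(chrom, start, end),
            strand_label=strand,
            covered_probes=list(probes),
            catalog_ids=cats or {"catalog_A": [], "catalog_B": []},
        )
        c.log2_ratio = log2
        return c

    def test_sorted_by_descending_log2(self):
        calls = [
            self._call("chr1", 1, 10, 1.5),
            self._call("chr2", 1, 10, 2.4),
            self._call("chr3", 1, 10, 2.0),
        ]
        report = make_report(calls)
        assert list(report["log2_ratio"]) == [2.4, 2.0, 1.5]

    def test_published_style_row_self_consistency(self):
        call = self._call(
            "chr16", 4871450, 4874336, 3.084,
            probes=("A_30_P01027969", "A_30_P01023954", "A_30_P01020286"),
            strand="Reverse",
            cats={"catalog_A": ["n278024"], "catalog_B": []},
        )
        report = make_report([call])
        row = report.iloc[0]
        assert row["location"] == "chr16:4871450-4874336"
        assert row["length"] == 2887
        assert interval_length(parse_locus_string(row["location"])) == row["length"]
        assert row["catalog_A_ids"] == "n278024"
        assert row["catalog_B_ids"] == "N.A."

    def test_empty_call_list_gives_header_only(self):
        report = make_report([])
        assert report.empty
        assert "location" in report.columns

    def test_every_row_length_matches_its_location_string(self):
        calls = [
            self._call("chr1", 5, 5, 1.0),
            self._call("chr2", 100, 4999, 2.0),
        ]
        report = make_report(calls)
        for _, row in report.iterrows():
            assert interval_length(parse_locus_string(row["location"])) == row["length"]

    def test_render_uses_thousands_separators_and_en_dash(self):
        text = render_report(make_report([self._call("chr16", 4871450, 4874336, 3.084)]))
        assert "2,887" in text
        assert "chr16:4871450–4874336" in text
        assert "3.084" in text
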