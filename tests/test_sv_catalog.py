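"""Bubble enumeration, SV classification and NRUI extraction."""

import numpy as np
import pytest

from pangraphsv import synthetic_data as sd
from pangraphsv.graph_io import Node, PangenomeGraph, SamplePath
from pangraphsv.sv_catalog import (call_svs, classify_sv, enumerate_bubbles,
                                   extract_nrui, length_spectrum,
                                   project_path, summarize_catalog)


def backbone_graph(*alt_nodes):
    """Backbone s1-s2-s3 (each 100 bp) plus any off-backbone nodes given."""
    nodes = {f"s{i}": Node("ACGT" * 25, 0, ("chr1", (i - 1) * 100))
             for i in (1, 2, 3)}
    nodes.update(alt_nodes and dict(alt_nodes) or {})
    edges = {("s1", "+", "s2", "+"), ("s2", "+", "s3", "+"),
             ("s1", "+", "s3", "+")}
    for nid in dict(alt_nodes or {}):
        edges |= {("s1", "+", nid, "+"), (nid, "+", "s3", "+")}
    return PangenomeGraph(nodes=nodes, edges=edges,
                          backbone={"chr1": ["s1", "s2", "s3"]})


class TestProjectPath:
    def test_reference_identical_path_has_no_deviation(self):
        g = backbone_graph()
        p = SamplePath("A", "chr1", [("s1", "+"), ("s2", "+"), ("s3", "+")])
        pp = project_path(p, g)
        assert pp.deviations == [] and not pp.flagged
        assert sorted(pp.visits) == [0, 1, 2]

    def test_substitution_evidence(self):
        g = backbone_graph(("sX", Node("T" * 80, 1)))
        p = SamplePath("A", "chr1", [("s1", "+"), ("sX", "+"), ("s3", "+")])
        pp = project_path(p, g)
        assert pp.deviations == [(0, 2, ("sX",))]

    def test_out_of_order_backbone_visit_flagged(self):
        g = backbone_graph()
        p = SamplePath("A", "chr1", [("s2", "+"), ("s1", "+"), ("s3", "+")])
        pp = project_path(p, g)
        assert pp.flagged

    def test_planted_insertion_yields_one_traversal(self, desk_truth,
                                                    desk_graph_paths):
        graph, paths = desk_graph_paths
        ins = next(sv for sv in desk_truth.svs if sv.sv_type == "INS")
        carrier = next(s for s, a in ins.alleles.items() if a == 1)
        p = next(p for p in paths if p.sample_id == carrier)
        pp = project_path(p, graph)
        hits = [d for d in pp.deviations if ins.alt_node_ids[0] in d[2]]
        assert len(hits) == 1
        assert hits[0][2] == (ins.alt_node_ids[0],)


class TestEnumerateBubbles:
    def test_no_deviation_no_bubbles(self):
        g = backbone_graph()
        paths = [SamplePath("A", "chr1",
                            [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        assert enumerate_bubbles(g, paths) == []

    def test_shared_deletion_single_bubble_two_alleles(self):
        g = backbone_graph()
        del_path = [("s1", "+"), ("s3", "+")]
        ref_path = [("s1", "+"), ("s2", "+"), ("s3", "+")]
        paths = [SamplePath("A", "chr1", del_path),
                 SamplePath("B", "chr1", del_path),
                 SamplePath("C", "chr1", ref_path)]
        (bub,) = enumerate_bubbles(g, paths)
        assert set(bub.traversals) == {"ref", "alt1"}
        assert bub.traversals["alt1"] == ()
        assert bub.carriers == {"A": "alt1", "B": "alt1", "C": "ref"}
        assert bub.ref_interval == (100, 200)

    def test_sample_not_covering_anchors_is_missing(self):
        g = backbone_graph()
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1", [("s1", "+")])]
        (bub,) = enumerate_bubbles(g, paths)
        assert bub.carriers["B"] is None

    def test_planted_catalog_recovered_exactly(self, desk_truth,
                                               desk_graph_paths):
        """Site, allele paths and carriers all equal generator truth."""
        graph, paths = desk_graph_paths
        bubbles = enumerate_bubbles(graph, paths)
        assert len(bubbles) == len(desk_truth.svs)
        planted = {(sv.start, sv.end): sv for sv in desk_truth.svs}
        for bub in bubbles:
            sv = planted[bub.ref_interval]
            truth_alts = set(sv.alt_seqs)
            got_alts = {bub.allele_sequence(graph, a)
                        for a in bub.traversals if a != "ref"}
            assert got_alts == truth_alts


class TestClassify:
    def _bubble(self, g, paths):
        return enumerate_bubbles(g, paths)[0]

    def test_biallelic_insertion(self):
        g = backbone_graph(("sI", Node("T" * 60, 1)))
        g.edges |= {("s1", "+", "sI", "+"), ("sI", "+", "s2", "+")}
        paths = [SamplePath("A", "chr1",
                            [("s1", "+"), ("sI", "+"), ("s2", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1",
                            [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        rec = classify_sv(self._bubble(g, paths), g)
        assert (rec.sv_type, rec.allelicity) == ("INS", "biallelic")
        assert rec.ref_len == 0 and rec.alt_lens == [60]

    def test_biallelic_deletion(self):
        g = backbone_graph()
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1",
                            [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        rec = classify_sv(self._bubble(g, paths), g)
        assert (rec.sv_type, rec.allelicity) == ("DEL", "biallelic")
        assert rec.ref_len == 100 and rec.alt_lens == [0]

    def test_substitution_when_both_sides_sequenced(self):
        # 30 bp reference segment replaced by an 80 bp alternative
        nodes = {"s1": Node("A" * 100, 0, ("chr1", 0)),
                 "s2": Node("C" * 30, 0, ("chr1", 100)),
                 "s3": Node("G" * 100, 0, ("chr1", 130)),
                 "sX": Node("T" * 80, 1)}
        edges = {("s1", "+", "s2", "+"), ("s2", "+", "s3", "+"),
                 ("s1", "+", "sX", "+"), ("sX", "+", "s3", "+")}
        g = PangenomeGraph(nodes=nodes, edges=edges,
                           backbone={"chr1": ["s1", "s2", "s3"]})
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("sX", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1", [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        rec = classify_sv(self._bubble(g, paths), g)
        assert rec.sv_type == "SUB"

    def test_three_traversals_multiallelic(self):
        g = backbone_graph(("sX", Node("T" * 80, 1)), ("sY", Node("G" * 70, 2)))
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("sX", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1", [("s1", "+"), ("sY", "+"), ("s3", "+")]),
                 SamplePath("C", "chr1", [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        rec = classify_sv(self._bubble(g, paths), g)
        assert rec.allelicity == "multiallelic"
        assert len(rec.alt_seqs) == 2

    def test_sub_sv_size_bubble_dropped(self):
        # 10 bp vs 20 bp alleles: below SV size on both sides
        nodes = {"s1": Node("A" * 100, 0, ("chr1", 0)),
                 "s2": Node("C" * 10, 0, ("chr1", 100)),
                 "s3": Node("G" * 100, 0, ("chr1", 110)),
                 "sX": Node("T" * 20, 1)}
        edges = {("s1", "+", "s2", "+"), ("s2", "+", "s3", "+"),
                 ("s1", "+", "sX", "+"), ("sX", "+", "s3", "+")}
        g = PangenomeGraph(nodes=nodes, edges=edges,
                           backbone={"chr1": ["s1", "s2", "s3"]})
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("sX", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1", [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        assert classify_sv(self._bubble(g, paths), g) is None

    def test_small_allele_tolerance_relaxes_deletion(self):
        # 3 bp residual allele: DEL only when the tolerance admits it
        nodes = {"s1": Node("A" * 100, 0, ("chr1", 0)),
                 "s2": Node("C" * 60, 0, ("chr1", 100)),
                 "s3": Node("G" * 100, 0, ("chr1", 160)),
                 "sX": Node("T" * 3, 1)}
        edges = {("s1", "+", "s2", "+"), ("s2", "+", "s3", "+"),
                 ("s1", "+", "sX", "+"), ("sX", "+", "s3", "+")}
        g = PangenomeGraph(nodes=nodes, edges=edges,
                           backbone={"chr1": ["s1", "s2", "s3"]})
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("sX", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1", [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        bub = self._bubble(g, paths)
        assert classify_sv(bub, g, small_allele_tol=0).sv_type == "SUB"
        assert classify_sv(bub, g, small_allele_tol=5).sv_type == "DEL"

    def test_single_allele_bubble_rejected(self):
        from pangraphsv.sv_catalog import Bubble

        bub = Bubble(chromosome="chr1", ref_interval=(0, 0),
                     anchors=("s1", "s2"), anchor_idx=(0, 1),
                     traversals={"ref": ()}, ref_allele_id="ref", carriers={})
        with pytest.raises(ValueError):
            classify_sv(bub, backbone_graph())


class TestCallSVs:
    def test_full_recall_precision_and_genotypes(self, desk_truth,
                                                 desk_graph_paths):
        """Site, type and genotype calls equal generator truth exactly."""
        graph, paths = desk_graph_paths
        records = call_svs(graph, paths)
        planted = {(sv.start, sv.end): sv for sv in desk_truth.svs}
        called = {(r.start, r.end): r for r in records}
        assert set(called) == set(planted)  # recall = precision = 1
        for key, rec in called.items():
            sv = planted[key]
            assert rec.sv_type == sv.sv_type
            expected_allelicity = ("biallelic" if len(sv.alt_seqs) == 1
                                   else "multiallelic")
            assert rec.allelicity == expected_allelicity
            alleles = [rec.ref_seq] + rec.alt_seqs
            for s in desk_truth.samples:
                a_true = sv.alleles[s]
                seq_true = (sv.alt_seqs[a_true - 1] if a_true else
                            desk_truth.reference[sv.start:sv.end])
                assert alleles[rec.genotypes[s]] == seq_true

    def test_carrier_sequence_reconstruction(self, desk_truth,
                                             desk_graph_paths):
        """Splicing each called allele into the reference reproduces the
        carrier's haplotype substring around the locus."""
        graph, paths = desk_graph_paths
        records = call_svs(graph, paths)
        ref = desk_truth.reference
        rec = max(records, key=lambda r: max(r.alt_lens))
        carrier = next(s for s, a in rec.genotypes.items() if a and a == 1)
        local = ref[rec.start - 50:rec.start] + rec.alt_seqs[0] \
            + ref[rec.end:rec.end + 50]
        assert local in desk_truth.haplotypes[carrier]


class TestNRUI:
    def test_deletion_only_catalog_empty(self):
        g = backbone_graph()
        paths = [SamplePath("A", "chr1", [("s1", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1",
                            [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        records = call_svs(g, paths)
        assert extract_nrui(records, g) == set()

    def test_inserted_node_above_cutoff_kept(self):
        g = backbone_graph(("sI", Node("T" * 70, 1)))
        g.edges |= {("s1", "+", "sI", "+"), ("sI", "+", "s2", "+")}
        paths = [SamplePath("A", "chr1",
                            [("s1", "+"), ("sI", "+"), ("s2", "+"), ("s3", "+")]),
                 SamplePath("B", "chr1",
                            [("s1", "+"), ("s2", "+"), ("s3", "+")])]
        records = call_svs(g, paths)
        assert extract_nrui(records, g) == {"sI"}

    def test_nrui_subset_of_nrs_many_seeds(self):
        from pangraphsv.graph_partition import compute_occupancy, extract_nrs

        for seed in range(8):
            cfg = sd.desk_preset(seed=seed, n_svs=40, ref_length=500_000,
                                 samples_per_breed=2)
            truth = sd.simulate_population(cfg)
            graph, paths = sd.emit_graph_and_paths(truth)
            records = call_svs(graph, paths)
            nrui = extract_nrui(records, graph)
            nrs = extract_nrs(graph, compute_occupancy(graph, paths))
            assert nrui <= nrs
            assert nrui == truth.nrui_nodes


class TestLengthSpectrum:
    def test_empty_catalog(self):
        assert length_spectrum([]).empty

    def test_totals_conserved_and_modes_visible(self, desk_records):
        spec = length_spectrum(desk_records, bin_width=50)
        assert spec.sum() == len(desk_records)
        ins = length_spectrum(desk_records, sv_type="INS", bin_width=50)
        dele = length_spectrum(desk_records, sv_type="DEL", bin_width=50)
        sub = length_spectrum(desk_records, sv_type="SUB", bin_width=50)
        assert ins.sum() + dele.sum() + sub.sum() == len(desk_records)
        # planted point masses at 150 and 250 bp dominate their bins
        assert spec.loc[150] >= spec.drop(index=[150, 250]).max() or \
            spec.loc[250] >= spec.drop(index=[150, 250]).max()


class TestSummary:
    def test_counts_partition_catalog(self, desk_records):
        s = summarize_catalog(desk_records)
        assert s.n_biallelic + s.n_multiallelic == s.n_total == len(desk_records)
        assert s.n_ins_biallelic + s.n_del_biallelic + s.n_sub_biallelic \
            == s.n_biallelic
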