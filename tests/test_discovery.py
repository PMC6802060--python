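"""Retrocopy catalogue tests: candidate calling, parent assignment,
intron-retention discard, classification, chimeric flagging, summaries."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from conftest import match_truth
from retroforge.discovery import (
    DiscoveryParams,
    RetrocopyRecord,
    catalogue_frame,
    classify,
    discover,
    flag_chimeric,
    summarize,
)
from retroforge.homology import SplicedStructure
from retroforge.io_formats import GeneModel
from retroforge.simulate import SimulationConfig, simulate_dataset


def _structure(fs=(), stops=(), protein_length=200):
    return SplicedStructure(
        score=500.0,
        exons=[],
        frameshift_positions=list(fs),
        stop_positions=list(stops),
        codon_matches=[],
        aligned_aa=protein_length,
        matched_aa=protein_length,
        protein_length=protein_length,
    )


class TestClassify:
    def test_clean_copy_is_intact(self):
        assert classify(_structure()) == "intact"

    def test_stop_at_codon_40_of_200_is_pseudogene(self):
        assert classify(_structure(stops=[40])) == "pseudogene"

    def test_frameshift_is_pseudogene(self):
        assert classify(_structure(fs=[120])) == "pseudogene"

    def test_grace_fraction_forgives_terminal_stops_only(self):
        st = _structure(stops=[195])
        assert classify(st) == "pseudogene"
        assert classify(st, grace_fraction=0.05) == "intact"
        assert classify(_structure(stops=[40]), grace_fraction=0.05) == "pseudogene"


class TestFlagChimeric:
    def _trees(self, host):
        tree = IntervalTree()
        tree.addi(host.start, host.end, host)
        return {host.chrom: tree}

    def setup_method(self):
        self.host = GeneModel("hostG", "t", "chr1", "+", [(1000, 1300), (5000, 5400)], "ph")

    def test_intact_copy_inside_host_intron_same_strand_is_chimeric(self):
        trees = self._trees(self.host)
        assert flag_chimeric("chr1", "+", 2000, 2900, "intact", "parentG", trees)

    def test_intergenic_intact_copy_is_not_chimeric(self):
        trees = self._trees(self.host)
        assert not flag_chimeric("chr1", "+", 10_000, 10_900, "intact", "parentG", trees)

    def test_pseudogene_inside_host_intron_is_not_chimeric(self):
        trees = self._trees(self.host)
        assert not flag_chimeric("chr1", "+", 2000, 2900, "pseudogene", "parentG", trees)

    def test_opposite_strand_insertion_is_not_chimeric(self):
        trees = self._trees(self.host)
        assert not flag_chimeric("chr1", "-", 2000, 2900, "intact", "parentG", trees)

    def test_own_parent_locus_is_not_a_host(self):
        trees = self._trees(self.host)
        assert not flag_chimeric("chr1", "+", 2000, 2900, "intact", "hostG", trees)


class TestDiscoverOnSimulatedData:
    def test_every_event_recovered_with_correct_parent_and_class(self, small_ds, small_catalogue):
        truth = [t for t in small_ds.truth if t.kind == "retro"]
        assert truth
        matched = {}
        for rec in small_catalogue:
            t = match_truth(rec, truth)
            if t is not None:
                matched[t.event_id] = rec
        assert len(matched) == len(truth)
        for t in truth:
            rec = matched[t.event_id]
            assert rec.parent_gene == t.parent_gene
            assert rec.cls == t.intended_class
            assert rec.chimeric == t.chimeric

    def test_no_record_overlaps_its_parent_and_no_single_exon_parents(
        self, small_ds, small_catalogue
    ):
        models = {m.gene_id: m for m in small_ds.models}
        for rec in small_catalogue:
            parent = models[rec.parent_gene]
            assert parent.n_exons >= 2
            if parent.chrom == rec.chrom:
                assert rec.end <= parent.start or rec.start >= parent.end

    def test_records_satisfy_identity_and_coverage_gates(self, small_catalogue):
        for rec in small_catalogue:
            assert rec.identity > 0.5 and rec.coverage > 0.5
            assert (rec.cls == "intact") == (rec.n_frameshifts == 0 and rec.n_stops == 0)

    def test_catalogue_is_deterministic(self, small_ds, small_catalogue):
        again = discover(small_ds.genome, small_ds.models, small_ds.proteins)
        assert catalogue_frame(again).equals(catalogue_frame(small_catalogue))

    def test_dna_level_duplicates_are_discarded(self):
        cfg = SimulationConfig(
            seed=6,
            n_genes=6,
            n_retro_events=5,
            n_chromosomes=3,
            chromosome_length=150_000,
            n_dna_duplicates=4,
            n_ests=0,
        )
        ds = simulate_dataset(cfg)
        recs = discover(ds.genome, ds.models, ds.proteins)
        dups = [t for t in ds.truth if t.kind == "dna_duplicate"]
        retro = [t for t in ds.truth if t.kind == "retro"]
        assert dups and retro

        def overlaps(t, r):
            return t.chrom == r.chrom and min(t.end, r.end) - max(t.start, r.start) > 0

        assert not [t for t in dups for r in recs if overlaps(t, r)]
        recovered = {t.event_id for t in retro for r in recs if overlaps(t, r)}
        assert len(recovered) == len(retro)


def _record(i, parent, cls="intact", chimeric=False, overlaps=False):
    return RetrocopyRecord(
        retro_id=f"r{i}",
        chrom="chr1",
        strand="+",
        start=i * 1000,
        end=i * 1000 + 500,
        parent_gene=parent,
        parent_protein=f"p_{parent}",
        cls=cls,
        chimeric=chimeric,
        overlaps_annotation=overlaps,
        identity=0.95,
        coverage=1.0,
        n_frameshifts=0 if cls == "intact" else 1,
        n_stops=0,
        score=500.0,
    )


class TestSummarize:
    def test_empty_catalogue_is_all_zero(self):
        s = summarize([])
        assert s.total == s.intact == s.chimeric == s.n_parents == 0
        assert s.intact_fraction == 0.0 and s.retrocopies_per_parent == 0.0

    def test_fractions_and_per_parent_distribution(self):
        records = (
            [_record(i, "gA") for i in range(3)]
            + [_record(10 + i, "gB", cls="pseudogene") for i in range(2)]
            + [_record(20, "gC", chimeric=True)]
        )
        s = summarize(records)
        assert s.total == 6 and s.intact == 4 and s.pseudogene == 2
        assert s.intact + s.pseudogene == s.total
        assert s.chimeric == 1 and s.chimeric <= s.intact
        assert s.n_parents == 3
        assert s.per_parent == {"gA": 3, "gB": 2, "gC": 1}
        assert s.single_retrocopy_parent_fraction == pytest.approx(1 / 3)
        assert s.retrocopies_per_parent == pytest.approx(2.0)
        assert s.top_parents(1) == [("gA", 3)]

    def test_novel_counts_require_no_annotation_overlap(self):
        records = [_record(1, "gA", overlaps=True), _record(2, "gA", overlaps=False)]
        s = summarize(records)
        assert s.novel_total == 1 and s.novel_intact == 1
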