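"""Exact-match classification, composition and length summaries."""

import random

import numpy as np
import pandas as pd
import pytest

from srnaproc.classify import (CompositionTable, build_index,
                               class_abundance_ratio, classify_reads,
                               composition, length_histogram, modal_length,
                               resolve_class, Hit)
from srnaproc.preprocess import collapse_reads
from srnaproc.references import DEFAULT_HIERARCHY, ReferenceSet, TRNAGene


def naive_scan(refs, query):
    """O(n*m) oracle: scan every reference sequence for every occurrence."""
    feats = []
    seen = set()
    for l in refs.mirna_loci:
        if l.precursor_id not in seen:
            seen.add(l.precursor_id)
            feats.append(("miRNA", l.precursor_id, l.precursor_seq))
    feats += [("tRNA", g.gene_id, g.seq) for g in refs.trna_genes]
    for label, entries in refs.background.items():
        feats += [(label, fid, s) for fid, s in entries]
    hits = []
    for cls, fid, seq in feats:
        for off in range(len(seq) - len(query) + 1):
            if seq[off:off + len(query)] == query:
                hits.append((cls, fid, off))
    return sorted(hits)


class TestIndex:
    def test_unique_hit(self, toy_refs, toy_locus):
        idx = build_index(toy_refs)
        hits = idx.query(toy_locus.mature_seq)
        assert len(hits) == 1
        assert hits[0].class_label == "miRNA"
        assert hits[0].offset == toy_locus.mature_start

    def test_two_genes_one_isotype_two_hits(self, toy_trna):
        g2 = TRNAGene("toy-tRNA-Gly-GCC-2", "Gly-GCC", toy_trna.seq,
                      toy_trna.anticodon_start, toy_trna.loop_start,
                      toy_trna.loop_end)
        refs = ReferenceSet(trna_genes=[toy_trna, g2])
        hits = build_index(refs).query(toy_trna.seq[:32])
        assert len(hits) == 2
        assert {h.feature_id for h in hits} == {toy_trna.gene_id, g2.gene_id}

    def test_absent_query_no_hits(self, toy_refs):
        assert build_index(toy_refs).query("T" * 20) == []

    def test_hits_are_exact_substrings(self, toy_refs, toy_locus):
        idx = build_index(toy_refs)
        q = toy_locus.precursor_seq[3:25]
        for h in idx.query(q):
            assert h.class_label == "miRNA"
            assert toy_locus.precursor_seq[h.offset:h.offset + len(q)] == q

    def test_agrees_with_naive_scan_oracle(self, sim_refs, sim_control):
        rng = random.Random(3)
        reads = rng.sample(sim_control.reads.records,
                           min(200, len(sim_control.reads)))
        idx = build_index(sim_refs)
        for seq, _ in reads:
            got = sorted((h.class_label, h.feature_id, h.offset)
                         for h in idx.query(seq))
            assert got == naive_scan(sim_refs, seq)


class TestResolveClass:
    def test_hierarchy_prefers_trna_over_pirna(self):
        hits = [Hit("piRNA", "p1", 0), Hit("tRNA", "t1", 3)]
        assert resolve_class(hits, DEFAULT_HIERARCHY) == "tRNA"

    def test_repeat_only(self):
        assert resolve_class([Hit("repeat", "r", 0)], DEFAULT_HIERARCHY) == "repeat"

    def test_no_hits_unassigned(self):
        assert resolve_class([], DEFAULT_HIERARCHY) == "unassigned"


class TestIsomirRescue:
    def test_tailed_read_classified_mirna(self, toy_refs, toy_locus):
        # mature + non-templated base: not an exact substring, still miRNA
        tail_base = "A" if toy_locus.downstream_context[0] != "A" else "C"
        reads = collapse_reads([toy_locus.mature_seq + tail_base])
        (a,) = classify_reads(reads, toy_refs)
        assert a.resolved_class == "miRNA"
        assert all(h.class_label != "miRNA" for h in a.hits)  # hits stay exact

    def test_rescue_disabled_leaves_unassigned(self, toy_refs, toy_locus):
        tail_base = "A" if toy_locus.downstream_context[0] != "A" else "C"
        reads = collapse_reads([toy_locus.mature_seq + tail_base])
        (a,) = classify_reads(reads, toy_refs, isomir_rescue=False)
        assert a.resolved_class == "unassigned"


class TestComposition:
    def test_single_class_fraction_one(self, toy_refs, toy_locus):
        reads = collapse_reads([toy_locus.mature_seq] * 5)
        comp = composition(classify_reads(reads, toy_refs))
        t = comp.table
        for stratum in t["stratum"].unique():
            sub = t[(t.stratum == stratum) & (t["class"] != "unassigned")]
            if sub["count"].sum():
                assert comp.fraction("miRNA", stratum) == 1.0

    def test_fractions_sum_to_one_per_stratum(self, sim_refs, sim_control):
        comp = composition(classify_reads(sim_control.reads, sim_refs))
        t = comp.table
        for stratum in t["stratum"].unique():
            sub = t[(t.stratum == stratum) & (t["class"] != "unassigned")]
            if sub["count"].sum() > 0:
                assert sub["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self, toy_refs, toy_locus, toy_trna):
        seqs = [toy_locus.mature_seq] * 3 + [toy_trna.seq[:32]] * 2
        a = composition(classify_reads(collapse_reads(seqs), toy_refs))
        b = composition(classify_reads(collapse_reads(seqs[::-1]), toy_refs))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_stratum_reports_zero(self, toy_refs, toy_locus):
        reads = collapse_reads([toy_locus.mature_seq])  # 22 nt only
        comp = composition(classify_reads(reads, toy_refs), strata=(18,))
        sub = comp.table[comp.table.stratum == "18"]
        assert (sub["count"] == 0).all()


class TestLengthHistogram:
    def test_single_read(self):
        hist = length_histogram(collapse_reads(["A" * 20]))
        assert hist[20] == 1 and hist.sum() == 1

    def test_mode_tie_flagged_smallest_wins(self):
        hist = length_histogram(collapse_reads(["A" * 20, "C" * 22]))
        mode, tie = modal_length(hist)
        assert mode == 20 and tie

    def test_simulated_mirna_mode_is_22(self, sim_refs, sim_control):
        assignments = classify_reads(sim_control.reads, sim_refs)
        mode, _ = modal_length(length_histogram(assignments, cls="miRNA"))
        assert mode == 22

    def test_simulated_trna_mode_is_32(self, sim_refs, sim_control):
        assignments = classify_reads(sim_control.reads, sim_refs)
        mode, _ = modal_length(length_histogram(assignments, cls="tRNA"))
        assert mode == 32


def _comp_table(fracs, sample="s"):
    rows = [("all", cls, int(f * 1000), f) for cls, f in fracs.items()]
    return CompositionTable(sample, pd.DataFrame(
        rows, columns=["stratum", "class", "count", "fraction"]))


class TestAbundanceRatio:
    def test_identical_tables_ratio_one(self):
        t = _comp_table({"miRNA": 0.5, "tRNA": 0.5})
        ratios = class_abundance_ratio(t, t)
        assert (ratios["ratio"] == 1.0).all()

    def test_trna_enrichment_from_printed_fractions(self):
        # 7.5% -> 13% of mapped reads is a 1.73-fold enrichment
        ctrl = _comp_table({"miRNA": 0.090, "tRNA": 0.075, "rRNA": 0.835})
        stress = _comp_table({"miRNA": 0.047, "tRNA": 0.130, "rRNA": 0.823})
        ratios = class_abundance_ratio(ctrl, stress)
        assert ratios.loc["tRNA", "ratio"] == pytest.approx(13 / 7.5, rel=1e-9)
        assert ratios.loc["miRNA", "ratio"] < 1.0

    def test_class_only_in_stress_is_flagged_infinite(self):
        ctrl = _comp_table({"miRNA": 1.0})
        stress = _comp_table({"miRNA": 0.9, "piRNA": 0.1})
        with pytest.warns(UserWarning):
            ratios = class_abundance_ratio(ctrl, stress)
        assert np.isinf(ratios.loc["piRNA", "ratio"])
        assert ratios.loc["piRNA", "flag"] == "absent_in_control"
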