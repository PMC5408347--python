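"""isomiR decomposition, tail typing, NTA statistics and length tests."""

import numpy as np
import pandas as pd
import pytest

from srnaproc.isomir import (IsomirMatcher, NTAProfile, arm_nta_ratio,
                             call_isomir, call_reads, categorize, compare_nta,
                             fiveprime_isomir_summary, length_shift_test,
                             mirna_counts, nta_expression_correlation,
                             nta_fractions, premodified_length_distribution,
                             premodified_modes, tail_type)
from srnaproc.references import MiRNALocus
from srnaproc.simulate import SimulationSpec, simulate_reads


def _locus(downstream="GTCCATAAGG", mature="GATTACAGATTACAGATTACAG",
           upstream="ACGTT"):
    prec = upstream + mature + downstream
    return MiRNALocus("p1", "m1-5p", "5p", prec,
                      len(upstream), len(upstream) + len(mature))


class TestCallIsomir:
    def test_canonical(self):
        loc = _locus()
        c = call_isomir(loc.mature_seq, loc)
        assert (c.shift5, c.shift3_templated, c.tail, c.category) == \
            (0, 0, "", "canonical")

    def test_tail_when_next_template_base_differs(self, oracle):
        loc = _locus(downstream="GTCCATAAGG")  # next base G
        seq = loc.mature_seq + "A"
        c = call_isomir(seq, loc)
        assert (c.tail, c.shift3_templated, c.category) == ("A", 0, "nta")
        assert oracle(seq, loc) == (0, 0, "A")

    def test_templated_priority_when_next_base_matches(self, oracle):
        loc = _locus(downstream="ATCCATAAGG")  # next base A
        seq = loc.mature_seq + "A"
        c = call_isomir(seq, loc)
        assert (c.tail, c.shift3_templated, c.category) == ("", 1, "shift3")
        assert oracle(seq, loc) == (0, 1, "")

    def test_four_nontemplated_bases_is_no_call(self):
        loc = _locus(downstream="GTCCATAAGG")
        assert call_isomir(loc.mature_seq + "AAAA", loc) is None

    def test_five_prime_shifts_within_two(self):
        loc = _locus()
        prec = loc.precursor_seq
        for s5 in (-2, -1, 1, 2):
            seq = prec[loc.mature_start + s5: loc.mature_end]
            c = call_isomir(seq, loc)
            assert c.shift5 == s5
        # three bases upstream is out of range
        seq = prec[loc.mature_start - 3: loc.mature_end]
        c = call_isomir(seq, loc)
        assert c is None or c.shift5 >= -2

    def test_reconstruction_invariant(self, sim_refs, sim_control):
        """Template at the called start plus tail reproduces the read."""
        matcher = IsomirMatcher(sim_refs.mirna_loci)
        loci = sim_refs.mirna_by_id()
        checked = 0
        for seq, _ in sim_control.reads.records[:2000]:
            for c in matcher.call_all(seq):
                loc = loci[c.mature_id]
                start = loc.mature_start + c.shift5
                end = loc.mature_end + c.shift3_templated
                assert loc.precursor_seq[start:end] + c.tail == seq
                checked += 1
        assert checked > 100

    def test_oracle_equivalence_sample(self, oracle, sim_refs, sim_control):
        """Spot equivalence on simulated reads (full sweep in acceptance)."""
        for seq, _ in sim_control.reads.records[:300]:
            for loc in sim_refs.mirna_loci:
                mine = call_isomir(seq, loc)
                ref = oracle(seq, loc)
                if ref is None:
                    assert mine is None
                else:
                    assert mine is not None
                    assert (mine.shift5, mine.shift3_templated, mine.tail) == ref


class TestCategorize:
    @pytest.mark.parametrize("shift5,shift3,tail,expected", [
        (-1, 0, "T", "nta"),       # tail beats shifts
        (1, 0, "", "shift5"),
        (0, -2, "", "shift3"),
        (0, 0, "", "canonical"),
        (2, 2, "CC", "nta"),
    ])
    def test_precedence(self, shift5, shift3, tail, expected):
        assert categorize(shift5, shift3, tail) == expected


class TestTailType:
    @pytest.mark.parametrize("tail,expected", [
        ("", ""), ("A", "A"), ("T", "U"), ("TT", "U"), ("CCC", "C"),
        ("AT", "mixed"), ("GAC", "mixed"),
    ])
    def test_labels(self, tail, expected):
        assert tail_type(tail) == expected


class TestCounts:
    def test_sum_over_isomirs(self):
        calls = pd.DataFrame({
            "mature_id": ["m1"] * 3, "count": [5, 2, 1],
        })
        assert mirna_counts(calls)["m1"] == 8

    def test_identical_mature_at_two_loci_full_count_each(self):
        loc_a = _locus()
        loc_b = MiRNALocus("p2", "m2-5p", "5p", loc_a.precursor_seq,
                           loc_a.mature_start, loc_a.mature_end)
        calls = call_reads([(loc_a.mature_seq, 10)], [loc_a, loc_b])
        counts = mirna_counts(calls)
        assert counts["m1-5p"] == 10 and counts["m2-5p"] == 10
        # but only one call is primary, so global totals count the read once
        assert calls["primary"].sum() == 1

    def test_no_calls_empty(self):
        assert mirna_counts(call_reads([], [_locus()])).empty


class TestNTAFractions:
    def _calls(self, tails, n_each=10):
        loc = _locus(downstream="GTCCATAAGG")
        reads = []
        for t in tails:
            reads.append((loc.mature_seq + t, n_each))
        reads.append((loc.mature_seq, n_each))  # untailed
        return call_reads(reads, [loc])

    def test_no_tails_all_zero(self):
        loc = _locus()
        calls = call_reads([(loc.mature_seq, 50)], [loc])
        prof = nta_fractions(calls)
        assert prof.total == 50
        assert (prof.type_counts == 0).all()

    def test_all_mono_u_fraction_one_of_tailed(self):
        loc = _locus(downstream="GTCCATAAGG")
        calls = call_reads([(loc.mature_seq + "T", 30)], [loc])
        prof = nta_fractions(calls)
        assert prof.fraction("U") == 1.0

    def test_mono_and_multi_tabulated_separately(self):
        calls = self._calls(["A", "AA", "C"])
        prof = nta_fractions(calls)
        assert prof.type_counts["A"] == 10
        assert prof.type_counts["A_multi"] == 10
        assert prof.type_counts["C"] == 10
        assert prof.fraction("A") == pytest.approx(0.25)

    def test_zero_scope_flagged(self):
        prof = NTAProfile("global", 0, pd.Series({"A": 0}))
        with pytest.warns(UserWarning):
            fr = prof.fractions
        assert fr.isna().all()


class TestCompareNTA:
    def _profile(self, total, counts):
        return NTAProfile("global", total, pd.Series(counts, dtype=float))

    def test_identical_profiles_null(self):
        p = self._profile(10000, {"A": 840, "C": 660, "G": 30, "U": 520})
        res = compare_nta(p, p)
        assert (res["delta"] == 0).all()
        assert (res["p_global"] > 0.9).all()

    def test_published_shift_magnitudes_detected(self):
        # mono-A 8.4% -> 5.6% at 200k reads/side is overwhelming evidence
        ctrl = self._profile(200_000, {"A": 16800, "C": 13200, "G": 600, "U": 10400})
        stress = self._profile(200_000, {"A": 11200, "C": 10000, "G": 600, "U": 13000})
        res = compare_nta(ctrl, stress)
        assert res.loc["A", "p_global"] < 1e-10
        assert res.loc["U", "p_global"] < 1e-10
        assert res.loc["C", "p_global"] < 1e-10
        assert res.loc["A", "delta"] < 0 < res.loc["U", "delta"]

    def test_min_read_filter_excludes_499(self):
        per = pd.DataFrame({"total": [499, 600], "A": [50, 60],
                            "C": [0, 0], "G": [0, 0], "U": [0, 0]},
                           index=["m1", "m2"])
        p1 = NTAProfile("per-miRNA", 1099, per[["A", "C", "G", "U"]].sum(), per)
        res = None
        with pytest.warns(UserWarning, match="eligible"):
            res = compare_nta(p1, p1, min_features=2)
        assert res.loc["A", "n_eligible_mirnas"] == 1  # m1 excluded


class TestArmRatio:
    def _arm_calls(self, n5_tailed, n5_total, n3_tailed, n3_total):
        up, down = "ACGTT", "GTCCATAAGGTTCAAGCTTGGATCC"
        m5 = "GATTACAGATTACAGATTACAG"
        m3 = "CCATGGCCATGGCCATGGCCAT"
        prec = up + m5 + "GCTTAGGCAT" + m3 + down
        l5 = MiRNALocus("p", "x-5p", "5p", prec, 5, 27)
        s3 = 5 + 22 + 10
        l3 = MiRNALocus("p", "x-3p", "3p", prec, s3, s3 + 22)
        reads = [(l5.mature_seq + "T", n5_tailed), (l5.mature_seq, n5_total - n5_tailed),
                 (l3.mature_seq + "T", n3_tailed), (l3.mature_seq, n3_total - n3_tailed)]
        return call_reads([r for r in reads if r[1] > 0], [l5, l3])

    def test_equal_fractions_ratio_one(self):
        calls = self._arm_calls(10, 100, 10, 100)
        assert arm_nta_ratio(calls, "U") == pytest.approx(1.0)

    def test_known_bias_recovered(self):
        calls = self._arm_calls(10, 100, 27, 100)
        assert arm_nta_ratio(calls, "U") == pytest.approx(2.7)

    def test_no_3p_tails_ratio_zero(self):
        calls = self._arm_calls(10, 100, 0, 100)
        assert arm_nta_ratio(calls, "U") == 0.0

    def test_zero_5p_denominator_infinite(self):
        calls = self._arm_calls(0, 100, 10, 100)
        with pytest.warns(UserWarning):
            assert np.isinf(arm_nta_ratio(calls, "U"))


class TestLengthShift:
    def test_identical_sets_null(self):
        reads = [("A" * 20, 50), ("C" * 22, 50)]
        res = length_shift_test(reads, reads)
        assert res.pvalue > 0.9 and res.shift == 0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        lens = rng.choice([20, 21, 22, 23], size=10_000, p=[.1, .2, .5, .2])
        ctrl = [("A" * int(l), 1) for l in lens]
        shifted = lens.copy()
        idx = rng.random(lens.size) < 0.3
        shifted[idx] += 1
        stress = [("A" * int(l), 1) for l in shifted]
        res = length_shift_test(ctrl, stress)
        assert res.pvalue < 0.01
        assert res.median_stress >= res.median_ctrl

    def test_singleton_vs_singleton(self):
        with pytest.warns(UserWarning):
            res = length_shift_test([("A" * 20, 1)], [("A" * 25, 1)])
        assert res.pvalue == 1.0

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            length_shift_test([], [("A" * 20, 1)])


class TestPremodifiedLengths:
    def test_modes_follow_construction(self):
        down = "GTCCATAAGGTTCAAGCTTGG"
        loc = _locus(downstream=down)
        m = loc.mature_seq  # 22 nt; next base G
        reads = [
            (m[:21] + "C", 30),   # C on 21-nt bodies
            (m + "A", 30),        # A on 22-nt bodies
            (m + "T", 5),
        ]
        calls = call_reads(reads, [loc])
        hist = premodified_length_distribution(calls)
        modes = premodified_modes(hist)
        assert modes["C"] == 21 and modes["A"] == 22

    def test_empty_type_is_nan(self):
        loc = _locus()
        calls = call_reads([(loc.mature_seq, 5)], [loc])
        modes = premodified_modes(premodified_length_distribution(calls))
        assert modes.isna().all()


class TestExpressionCorrelation:
    def test_perfect_anticorrelation(self):
        d = pd.Series(np.arange(20), index=[f"m{i}" for i in range(20)])
        rho, p = nta_expression_correlation(d, -d)
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_error(self):
        d = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            nta_expression_correlation(d, d)

    def test_constant_vector_flagged(self):
        d = pd.Series(np.arange(15.0), index=[f"m{i}" for i in range(15)])
        with pytest.warns(UserWarning):
            rho, p = nta_expression_correlation(d, d * 0)
        assert np.isnan(rho)

    def test_planted_coupling_in_generator(self, sim_refs):
        """Stress C-tail loss is coupled to expression gain: recover rho<0."""
        n = 60_000
        ctrl = simulate_reads(SimulationSpec.control(
            seed=29, n_reads=n, n_loci=100,
            class_fractions={"miRNA": 1.0}), None)
        stress = simulate_reads(SimulationSpec.stress(
            seed=29, n_reads=n, n_loci=100,
            class_fractions={"miRNA": 1.0}), ctrl.refs)
        calls_c = call_reads(ctrl.reads.records, ctrl.refs.mirna_loci)
        calls_s = call_reads(stress.reads.records, ctrl.refs.mirna_loci)
        prof_c = nta_fractions(calls_c, scope="per-miRNA").per_feature
        prof_s = nta_fractions(calls_s, scope="per-miRNA").per_feature
        merged = prof_c.join(prof_s, lsuffix="_c", rsuffix="_s", how="inner")
        merged = merged[(merged["total_c"] >= 100) & (merged["total_s"] >= 100)]
        delta_c = merged["C_s"] / merged["total_s"] - merged["C_c"] / merged["total_c"]
        logfc = np.log2((merged["total_s"] + 0.5) / (merged["total_c"] + 0.5))
        rho, p = nta_expression_correlation(delta_c, logfc)
        assert rho < 0 and p < 0.05


class TestFivePrimeSummary:
    def test_all_canonical_no_flags(self):
        loc = _locus()
        calls = call_reads([(loc.mature_seq, 20)], [loc])
        summ = fiveprime_isomir_summary(calls)
        assert (summ["fraction"] == 0).all() and not summ["rich"].any()

    def test_planted_rich_mirna_flagged(self, sim_refs):
        matcher = IsomirMatcher(sim_refs.mirna_loci)
        target = sim_refs.mirna_loci[0]
        other = sim_refs.mirna_loci[2]
        prec = target.precursor_seq
        reads = [(prec[target.mature_start:target.mature_end], 60),
                 (prec[target.mature_start + 1:target.mature_end], 40),
                 (other.precursor_seq[other.mature_start:other.mature_end], 50)]
        summ = fiveprime_isomir_summary(
            call_reads(reads, sim_refs.mirna_loci, matcher=matcher))
        assert summ.loc[target.mature_id, "rich"]
        assert not summ.loc[other.mature_id, "rich"]

    def test_zero_threshold_flags_any_shift(self):
        loc = _locus()
        prec = loc.precursor_seq
        reads = [(prec[loc.mature_start:loc.mature_end], 99),
                 (prec[loc.mature_start + 1:loc.mature_end], 1)]
        summ = fiveprime_isomir_summary(call_reads(reads, [loc]), threshold=0.0)
        assert summ["rich"].all()
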