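"""Consensus intersection, de novo filters, contamination screen."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from malspectra import (
    ExclusionSet,
    SimParams,
    VariantCall,
    apply_filters,
    consensus_intersect,
    curate_replicate,
    detect_cross_contamination,
    normalize_indel,
    simulate_mal_experiment,
)
from malspectra.simulate import MALDesign


def snv(chrom="chrI", pos=100, ref="C", alt="T", depth=50, rep="r1", flags=()):
    return VariantCall(chrom, pos, ref, alt, depth, rep, frozenset(flags))


class TestConsensusIntersect:
    def test_empty_input_gives_empty_consensus(self):
        assert consensus_intersect([], [snv()]) == []
        assert consensus_intersect([snv()], []) == []

    def test_simple_intersection(self):
        a = [snv("chrI", 100, "C", "T", flags={"callerA"})]
        b = [
            snv("chrI", 100, "C", "T", flags={"callerB"}),
            snv("chrII", 5, "A", "G", flags={"callerB"}),
        ]
        out = consensus_intersect(a, b)
        assert [c.key for c in out] == [("chrI", 100, "C", "T")]
        assert out[0].caller_flags == {"callerA", "callerB"}

    def test_depth_is_minimum_of_both_callers(self):
        a = [snv(depth=40)]
        b = [snv(depth=25)]
        assert consensus_intersect(a, b)[0].depth == 25

    def test_indels_intersect_after_left_normalization(self):
        # one T deleted from the TTT homopolymer at chrI:11-13, represented
        # with different anchors and padding by the two callers
        from malspectra.genome import Genome

        genome = Genome({"chrI": "CCCCCCCCCATTTGCCCC"})
        a = [VariantCall("chrI", 10, "ATTT", "ATT", depth=30)]
        b = [VariantCall("chrI", 11, "TT", "T", depth=30)]
        out = consensus_intersect(a, b, genome)
        assert len(out) == 1
        assert out[0].key == ("chrI", 10, "AT", "A")  # left-aligned form

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.data())
    def test_matches_brute_force_double_loop(self, data):
        def callset(name):
            keys = data.draw(
                st.lists(
                    st.tuples(
                        st.sampled_from(["chrI", "chrII"]),
                        st.integers(1, 50),
                        st.sampled_from(["A", "C"]),
                        st.sampled_from(["G", "T"]),
                    ),
                    max_size=20,
                    unique=True,
                )
            )
            return [
                VariantCall(c, p, r, a, depth=30, caller_flags=frozenset({name}))
                for c, p, r, a in keys
            ]

        a, b = callset("callerA"), callset("callerB")
        expected = {
            x.key for x in a for y in b if x.key == y.key
        }
        assert {c.key for c in consensus_intersect(a, b)} == expected

    def test_simulated_consensus_is_truth_ancestor_and_chance_shared_fps(
        self, toy_genome
    ):
        design = MALDesign("S", generations_total=1260, replicate_count=2)
        params = SimParams(
            snv_rate=3e-7, caller_fp_rate=1e-7, caller_fn_rate=0.0,
            ancestor_variant_count=4, seed=21,
        )
        exp = simulate_mal_experiment(toy_genome, design, params)
        rep = design.replicate_ids[0]
        out = {c.key for c in consensus_intersect(
            exp.caller_calls[rep]["callerA"], exp.caller_calls[rep]["callerB"]
        )}
        truth = {v.key for v in exp.truth.truth[rep]}
        anc = {v.key for v in exp.truth.ancestor}
        fp_shared = {v.key for v in exp.truth.false_positives[(rep, "callerA")]} & {
            v.key for v in exp.truth.false_positives[(rep, "callerB")]
        }
        assert out == truth | anc | fp_shared


class TestFilters:
    def test_depth_boundary_keeps_11_removes_10(self):
        calls = [snv(pos=1, depth=10), snv(pos=2, depth=11)]
        kept, log = apply_filters(calls, min_depth=11)
        assert [c.position for c in kept] == [2]
        assert log.low_depth == 1

    def test_ancestor_calls_removed(self):
        calls = [snv(pos=1), snv(pos=2)]
        kept, log = apply_filters(calls, ancestor=[snv(pos=1, rep="ancestor")])
        assert [c.position for c in kept] == [2]
        assert log.ancestor == 1

    def test_missing_depth_kept_with_warning(self, caplog):
        calls = [snv(depth=None)]
        with caplog.at_level("WARNING"):
            kept, _ = apply_filters(calls, min_depth=11)
        assert len(kept) == 1
        assert "no depth" in caplog.text

    @pytest.mark.parametrize(
        "position,interval,removed",
        # 1-based call positions vs 0-based half-open intervals, enumerated
        # around the boundary: position p is inside (s, e) iff s <= p-1 < e
        [
            (pos, iv, iv[0] <= pos - 1 < iv[1])
            for pos in (98, 99, 100, 101, 102)
            for iv in ((99, 100), (100, 101))
        ],
    )
    def test_exclusion_coordinate_frame(self, position, interval, removed):
        excluded = ExclusionSet([("chrI", *interval)], label="subtelomere")
        kept, _ = apply_filters([snv(pos=position)], excluded=excluded, min_depth=0)
        assert (len(kept) == 0) == removed

    def test_unknown_chromosome_in_exclusions_warns_and_is_ignored(self, caplog):
        excluded = ExclusionSet([("chrZZ", 0, 1000)])
        with caplog.at_level("WARNING"):
            kept, _ = apply_filters(
                [snv()], excluded=excluded, known_chromosomes=["chrI"]
            )
        assert len(kept) == 1
        assert "unknown chromosome" in caplog.text

    def test_filter_order_independence(self):
        calls = [
            snv(pos=p, depth=d)
            for p, d in [(50, 5), (99, 50), (100, 50), (150, 50), (200, 9), (250, 88)]
        ]
        ancestor = [snv(pos=150)]
        excluded = ExclusionSet([("chrI", 95, 105)])

        def f_anc(cs):
            return apply_filters(cs, ancestor=ancestor, min_depth=0)[0]

        def f_exc(cs):
            return apply_filters(cs, excluded=excluded, min_depth=0)[0]

        def f_dep(cs):
            return apply_filters(cs, min_depth=11)[0]

        combined, _ = apply_filters(calls, ancestor, excluded, 11)
        expected = {c.key for c in combined}
        for order in itertools.permutations([f_anc, f_exc, f_dep]):
            out = calls
            for f in order:
                out = f(out)
            assert {c.key for c in out} == expected

    def test_output_is_subset_of_input_chain(self, toy_genome):
        design = MALDesign("S", generations_total=1260, replicate_count=1)
        params = SimParams(
            snv_rate=4e-7, caller_fp_rate=5e-8, caller_fn_rate=0.1, seed=5
        )
        exp = simulate_mal_experiment(toy_genome, design, params)
        rep = design.replicate_ids[0]
        a = exp.caller_calls[rep]["callerA"]
        b = exp.caller_calls[rep]["callerB"]
        consensus = consensus_intersect(a, b)
        curated, _ = curate_replicate(a, b, min_depth=11)
        keys = lambda cs: {c.key for c in cs}
        assert keys(consensus) <= keys(a) and keys(consensus) <= keys(b)
        assert keys(curated) <= keys(consensus)

    def test_perfect_callers_recover_truth_exactly(self, toy_genome):
        """With FN=0 the curated set equals truth minus excluded/low-depth
        variants (exact set equality against the simulator's ground truth)."""
        design = MALDesign("S", generations_total=1260, replicate_count=2)
        params = SimParams(
            snv_rate=4e-7, indel_rate=5e-8, caller_fp_rate=0.0,
            caller_fn_rate=0.0, ancestor_variant_count=6, seed=13,
        )
        exp = simulate_mal_experiment(toy_genome, design, params)
        excluded = ExclusionSet([("chrI", 0, 10_000), ("chrII", 70_000, 80_000)])
        for rep in design.replicate_ids:
            curated, _ = curate_replicate(
                exp.caller_calls[rep]["callerA"],
                exp.caller_calls[rep]["callerB"],
                ancestor=exp.ancestor_calls,
                excluded=excluded,
                min_depth=0,
            )
            expected = {
                normalize_indel(v).key
                for v in exp.truth.truth[rep]
                if not excluded.contains(v.chromosome, v.position)
            }
            assert {c.key for c in curated} == expected


class TestContamination:
    def test_disjoint_sets_not_flagged(self):
        sets = {"r1": [snv(pos=1)], "r2": [snv(pos=2)]}
        (flag,) = detect_cross_contamination(sets)
        assert flag.shared_fraction == 0.0 and not flag.flagged

    def test_identical_sets_fully_shared_and_flagged(self):
        calls = [snv(pos=p) for p in (1, 2, 3)]
        (flag,) = detect_cross_contamination({"r1": calls, "r2": list(calls)})
        assert flag.shared_fraction == 1.0 and flag.flagged

    def test_hand_counted_shared_fraction(self):
        r1 = [snv(pos=p) for p in (1, 2, 3, 4)]  # {a,b,c,d}
        r2 = [snv(pos=p) for p in (3, 4, 5)]  # {c,d,e}
        (flag,) = detect_cross_contamination({"r1": r1, "r2": r2})
        assert flag.shared_fraction == pytest.approx(2 / 3)
        assert flag.flagged  # 0.667 >= default 0.2

    def test_empty_set_gives_zero_fraction(self):
        (flag,) = detect_cross_contamination({"r1": [], "r2": [snv()]})
        assert flag.shared_fraction == 0.0 and not flag.flagged

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            detect_cross_contamination({"r1": []})
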