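"""Scanner behaviour: extension/gap/restart rules, invariants, determinism."""

import random

import pytest

from tandemhash import (
    DNA,
    OpCounter,
    RunParams,
    build_degeneration_buffers,
    build_presence_table,
    brute_force_repeats,
    scan_all,
    scan_sequence,
)
from tandemhash.degeneration import neighborhood_size


def scan_with_budget(sequence, j, params, max_mm=None, counter=None, seq_id="s"):
    """Build per-sequence tables and scan; max_mm overrides the params budget."""
    mm = params.max_mm_for(j) if max_mm is None else max_mm
    presence = build_presence_table(sequence, j, params.alphabet)
    buffers = build_degeneration_buffers(presence, mm, params.alphabet)
    return scan_sequence(sequence, seq_id, j, buffers, params, counter=counter)


def as_tuples(candidates):
    return [
        (c.sp, c.fp, c.motif, c.bucket.g, c.bucket.lt) for c in candidates
    ]


class TestScanSequence:
    def test_perfect_dinucleotide_run_single_phase_survives(self):
        params = RunParams(min_motif=2, max_motif=2, min_repeats=5)
        out = scan_with_budget("ACACACACAC", 2, params)
        # the CA-phase bucket only reaches four units and is dropped
        assert as_tuples(out) == [(1, 10, "AC", 0, 5)]

    def test_degenerate_unit_extends_the_locus(self):
        # AT at position 5 is one substitution from AC; with a budget of one
        # it extends the AC locus across the full ten bases
        params = RunParams(min_motif=2, max_motif=2, min_repeats=5)
        out = scan_with_budget("ACACATACAC", 2, params, max_mm=1)
        assert as_tuples(out) == [(1, 10, "AC", 0, 5)]

    def test_under_floor_budget_no_degenerate_match(self):
        # at 35% a dinucleotide motif gets floor(0.7) = 0 substitutions
        params = RunParams(
            min_motif=2, max_motif=2, min_repeats=5, degeneration_percent=35
        )
        assert scan_with_budget("ACACATACAC", 2, params) == []

    def test_empty_sequence_yields_nothing(self):
        params = RunParams(min_motif=2, max_motif=2, min_repeats=2)
        assert scan_with_budget("", 2, params) == []

    def test_homopolymer_run(self):
        params = RunParams(min_motif=1, max_motif=1, min_repeats=5)
        assert as_tuples(scan_with_budget("AAAAAAA", 1, params)) == [
            (1, 7, "A", 0, 7)
        ]

    def test_gap_tolerance_bridges_interruptions(self):
        # two gap characters total, one per junction, within ga=1
        seq = "ACACGACACTACAC"
        params = RunParams(min_motif=2, max_motif=2, min_repeats=6, max_gap=1)
        assert as_tuples(scan_with_budget(seq, 2, params)) == [(1, 14, "AC", 2, 6)]

    def test_gap_beyond_tolerance_splits_and_reports_both(self):
        # two AC runs separated by five non-motif bases; both meet min_repeats
        seq = "ACACACAC" + "GTGTG" + "ACACACAC"
        params = RunParams(min_motif=2, max_motif=2, min_repeats=4, max_gap=0)
        out = as_tuples(scan_with_budget(seq, 2, params))
        assert (1, 8, "AC", 0, 4) in out
        assert (14, 21, "AC", 0, 4) in out

    def test_mid_sequence_emission_on_gap_failure(self):
        # first run qualifies and must be emitted when the bucket restarts
        seq = "ACACACACACAC" + "GGGGG" + "AC"
        params = RunParams(min_motif=2, max_motif=2, min_repeats=5, max_gap=0)
        assert (1, 12, "AC", 0, 6) in as_tuples(scan_with_budget(seq, 2, params))

    def test_span_consistency_and_gap_bound_on_random_sequences(self, rng):
        params = RunParams(
            min_motif=1, max_motif=4, min_repeats=3, max_gap=2,
            degeneration_percent=35,
        )
        for _ in range(30):
            seq = "".join(rng.choices("ACGT", k=rng.randint(20, 150)))
            for j in range(1, 5):
                for c in scan_with_budget(seq, j, params):
                    b = c.bucket
                    assert b.fp - b.sp + 1 == b.lt * j + b.g
                    assert b.g <= (b.lt - 1) * params.max_gap

    def test_mismatched_buffer_word_length_is_rejected(self):
        params = RunParams(min_motif=2, max_motif=2, min_repeats=2)
        buffers = build_degeneration_buffers(
            build_presence_table("ACAC", 3, DNA), 0, DNA
        )
        with pytest.raises(ValueError):
            scan_sequence("ACAC", "s", 2, buffers, params)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_perfect_repeats(self, rng):
        params = RunParams(min_motif=1, max_motif=6, min_repeats=3, max_gap=1)
        for _ in range(40):
            n = rng.randint(30, 200)
            # skewed composition makes chance repeats common
            seq = "".join(rng.choices("ACGT", weights=[6, 2, 1, 1], k=n))
            got = scan_all([("s", seq)], params)
            expected = brute_force_repeats(seq, params, sequence_id="s")
            assert as_tuples(got) == as_tuples(expected)

    def test_matches_brute_force_with_degeneration(self, rng):
        params = RunParams(
            min_motif=3, max_motif=4, min_repeats=3, max_gap=1,
            degeneration_percent=35,
        )
        for _ in range(15):
            seq = "".join(rng.choices("ACGT", weights=[5, 3, 1, 1], k=120))
            got = scan_all([("s", seq)], params)
            expected = brute_force_repeats(seq, params, sequence_id="s")
            assert as_tuples(got) == as_tuples(expected)


class TestScanAll:
    def test_single_length_equals_scan_sequence(self):
        params = RunParams(min_motif=2, max_motif=2, min_repeats=5)
        seq = "ACACACACAC"
        assert as_tuples(scan_all([("s", seq)], params)) == as_tuples(
            scan_with_budget(seq, 2, params)
        )

    def test_length_range_unions_per_length_results(self):
        params = RunParams(min_motif=1, max_motif=2, min_repeats=5)
        out = scan_all([("s", "ACACACACAC")], params)
        assert [(c.motif_length,) + t for c, t in zip(out, as_tuples(out))] == [
            (2, 1, 10, "AC", 0, 5)
        ]

    def test_parallel_and_serial_runs_are_identical(self, rng):
        params = RunParams(min_motif=1, max_motif=4, min_repeats=3, max_gap=1)
        records = [
            (f"s{i}", "".join(rng.choices("ACGT", weights=[5, 3, 1, 1], k=120)))
            for i in range(10)
        ]
        assert scan_all(records, params) == scan_all(records, params, processes=2)

    def test_empty_record_is_an_error_naming_it(self):
        params = RunParams(min_motif=2, max_motif=2, min_repeats=2)
        with pytest.raises(ValueError, match="bad_record"):
            scan_all([("bad_record", "")], params)


class TestRunParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min_motif=0),
            dict(min_motif=4, max_motif=2),
            dict(max_motif=13),
            dict(min_repeats=1),
            dict(min_repeats=(3, 3)),        # wrong list length for 1..6
            dict(max_gap=-1),
            dict(degeneration_percent=40),
            dict(overlap_percent=120),
            dict(run_mode="rna"),
        ],
    )
    def test_invalid_parameters_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunParams(**kwargs)

    def test_per_length_minimum_repeats(self):
        params = RunParams(min_motif=2, max_motif=4, min_repeats=(5, 4, 3))
        assert [params.min_repeats_for(j) for j in (2, 3, 4)] == [5, 4, 3]


class TestLinearWork:
    def test_bucket_operations_bounded_by_neighbourhood_constant(self):
        rng = random.Random(7)
        params = RunParams(
            min_motif=3, max_motif=3, min_repeats=5, degeneration_percent=35
        )
        c = neighborhood_size(3, 4, params.max_mm_for(3))
        per_n = []
        for n in (1_000, 10_000):
            seq = "".join(rng.choices("ACGT", k=n))
            counter = OpCounter()
            scan_with_budget(seq, 3, params, counter=counter)
            assert counter.bucket_ops <= (1 + c) * n
            per_n.append(counter.bucket_ops / n)
        # work per symbol is flat across a decade of n
        assert per_n[1] == pytest.approx(per_n[0], rel=0.15)
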