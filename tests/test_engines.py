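"""The four merge engines: k-way grouping, tree plans, and engine equivalence."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcfmerge.engines import (
    MergeJob,
    StreamOrderError,
    kway_merge,
    plan_tree,
    run,
    run_single,
)
from vcfmerge.synthetic import CohortSpec, generate_cohort
from vcfmerge.vcf_io import (
    MISSING_CALL,
    VariantKey,
    VcfRecord,
    read_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)


def _mkrec(chrom, pos, sample="S1"):
    return VcfRecord(
        VariantKey(chrom, pos), ".", "A", ("G",), 50.0, "PASS", ("DP=1",),
        MISSING_CALL, sample,
    )


def _write_vcf(path, sample, lines):
    with open(path, "w") as fh:
        fh.write(HEADER.format(sample=sample))
        for line in lines:
            fh.write(line + "\n")
    return path


class TestKwayMerge:
    def test_single_stream_groups_duplicate_keys(self):
        stream = [_mkrec("1", 5), _mkrec("1", 5), _mkrec("1", 9)]
        out = [(k.pos, len(g)) for k, g in kway_merge([stream])]
        assert out == [(5, 2), (9, 1)]

    def test_two_streams_grouped_by_key(self):
        s1 = [_mkrec("1", 5), _mkrec("1", 9)]
        s2 = [_mkrec("1", 5, "S2"), _mkrec("2", 1, "S2")]
        out = [
            ((k.chrom, k.pos), [r.sample_id for r in g])
            for k, g in kway_merge([s1, s2])
        ]
        assert out == [
            (("1", 5), ["S1", "S2"]),
            (("1", 9), ["S1"]),
            (("2", 1), ["S2"]),
        ]

    def test_out_of_order_stream_rejected_naming_stream_and_keys(self):
        bad = [_mkrec("2", 9), _mkrec("1", 5)]
        with pytest.raises(StreamOrderError, match="stream 0"):
            list(kway_merge([bad]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=500), max_size=40),
            min_size=1,
            max_size=6,
        )
    )
    def test_flattened_output_equals_sorted_concatenation(self, streams):
        """Brute-force oracle: k-way merge == sort of the concatenated input."""
        sorted_streams = [
            [_mkrec("1", p, f"S{i}") for p in sorted(s)]
            for i, s in enumerate(streams)
        ]
        flat = [
            r.key.pos for _, grp in kway_merge(sorted_streams) for r in grp
        ]
        assert flat == sorted(p for s in streams for p in s)
        out_keys = [k.pos for k, _ in kway_merge(sorted_streams)]
        assert out_keys == sorted(set(out_keys))


class TestTreePlan:
    def test_single_worker_one_round_no_pairs(self):
        plan = plan_tree(1)
        assert plan.rounds == 1 and plan.pair_rounds == ()

    def test_two_workers(self):
        plan = plan_tree(2)
        assert plan.rounds == 2
        assert plan.pair_rounds == (((0, 1),),)

    def test_four_workers_eight_files_schedule(self):
        plan = plan_tree(4)
        assert plan.rounds == 3
        assert plan.pair_rounds[0] == ((0, 1), (2, 3))
        assert plan.pair_rounds[1] == ((0, 2),)

    def test_receivers_divisible_senders_adjacent(self):
        plan = plan_tree(16)
        for r, pairs in enumerate(plan.pair_rounds, start=2):
            for recv, send in pairs:
                assert recv % (2 ** (r - 1)) == 0
                assert send == recv + 2 ** (r - 2)

    @pytest.mark.parametrize("p", list(range(1, 33)))
    def test_every_worker_routed_to_zero_exactly_once(self, p):
        """Simulate the plan: all p data sets end on worker 0, each moved
        into a merge exactly once."""
        import math

        plan = plan_tree(p)
        assert plan.rounds == (1 if p == 1 else 1 + math.ceil(math.log2(p)))
        holdings = {w: {w} for w in range(p)}
        merged_away = set()
        for pairs in plan.pair_rounds:
            for recv, send in pairs:
                assert send not in merged_away  # each sender merged once
                holdings[recv] |= holdings.pop(send)
                merged_away.add(send)
        assert holdings[0] == set(range(p))
        assert merged_away == set(range(p)) - {0}


@pytest.fixture(scope="module")
def toy_inputs(tmp_path_factory):
    """Three files: one non-PASS record, one sample missing a position."""
    d = tmp_path_factory.mktemp("toy")
    a = _write_vcf(d / "a.vcf", "A", [
        "1\t100\t.\tA\tG\t50\tPASS\tDP=1\tGT\t0/1",
        "1\t147\t.\tG\tA\t15\tq10\tDP=1\tGT\t0/1",
        "1\t200\t.\tC\tT\t50\tPASS\tDP=1\tGT\t1/1",
    ])
    b = _write_vcf(d / "b.vcf", "B", [
        "1\t100\t.\tA\tG\t30\tPASS\tDP=1\tGT\t1/1",
    ])
    c = _write_vcf(d / "c.vcf", "C", [
        "1\t200\t.\tC\tT\t20\tPASS\tDP=1\tGT\t0/1",
        "X\t40\t.\tT\tA\t20\tPASS\tDP=1\tGT\t0/1",
    ])
    return [a, b, c]


class TestRunSingle:
    def test_nonpass_key_absent_and_homref_fill(self, toy_inputs, tmp_path):
        job = MergeJob(inputs=toy_inputs, output=tmp_path / "o", out_format="tped")
        res = run_single(job)
        lines = res.path.read_text().splitlines()
        assert lines == [
            "1 1:100 0 100 A G G G A A",
            "1 1:200 0 200 T T C C C T",
            "X X:40 0 40 T T T T T A",
        ]
        assert res.rows == 3
        assert not any("147" in line for line in lines)

    def test_worked_example_reproduced(self, worked_example, tmp_path):
        paths, expected = worked_example
        job = MergeJob(inputs=paths, output=tmp_path / "o", out_format="tped")
        res = run_single(job)
        assert res.path.read_text().splitlines() == expected

    def test_single_input_single_sample_one_row_per_pass_record(
        self, toy_inputs, tmp_path
    ):
        job = MergeJob(inputs=toy_inputs[:1], output=tmp_path / "o")
        res = run_single(job)
        assert res.rows == 2  # the q10 record is dropped

    def test_removing_a_nonpass_record_never_changes_output(
        self, toy_inputs, tmp_path
    ):
        """Filtering monotonicity at the engine level."""
        pruned = tmp_path / "a_pruned.vcf"
        with open(toy_inputs[0]) as fh:
            kept = [l for l in fh if "\tq10\t" not in l]
        pruned.write_text("".join(kept))
        inputs2 = [pruned] + list(toy_inputs[1:])
        out1 = run_single(
            MergeJob(inputs=toy_inputs, output=tmp_path / "o1")
        ).path.read_bytes()
        out2 = run_single(
            MergeJob(inputs=inputs2, output=tmp_path / "o2")
        ).path.read_bytes()
        assert out1 == out2

    def test_unsorted_input_detected(self, tmp_path):
        bad = _write_vcf(tmp_path / "bad.vcf", "S1", [
            "2\t10\t.\tA\tG\t50\tPASS\tDP=1\tGT\t0/1",
            "1\t99\t.\tA\tG\t50\tPASS\tDP=1\tGT\t0/1",
        ])
        with pytest.raises(StreamOrderError, match="bad.vcf"):
            run_single(MergeJob(inputs=[bad], output=tmp_path / "o"))

    def test_presort_recovers_unsorted_input(self, tmp_path):
        lines = [
            "1\t99\t.\tA\tG\t50\tPASS\tDP=1\tGT\t0/1",
            "2\t10\t.\tC\tT\t50\tPASS\tDP=1\tGT\t1/1",
        ]
        ordered = _write_vcf(tmp_path / "ok.vcf", "S1", lines)
        shuffled = _write_vcf(tmp_path / "sh.vcf", "S1", lines[::-1])
        out1 = run_single(
            MergeJob(inputs=[ordered], output=tmp_path / "o1")
        ).path.read_bytes()
        out2 = run_single(
            MergeJob(inputs=[shuffled], output=tmp_path / "o2", presort=True)
        ).path.read_bytes()
        assert out1 == out2


ENGINE_GRID = [
    ("single", 1),
    ("partitioned", 1),
    ("partitioned", 3),
    ("tree", 1),
    ("tree", 2),
    ("tree", 5),
    ("interval", 1),
    ("interval", 4),
]


class TestEngineEquivalence:
    @pytest.mark.parametrize("out_format", ["tped", "vcf"])
    def test_every_engine_matches_the_naive_oracle(
        self, small_cohort, tmp_path, oracle, out_format
    ):
        expected = oracle(small_cohort.paths, out_format)
        for engine, workers in ENGINE_GRID:
            job = MergeJob(
                inputs=small_cohort.paths,
                output=tmp_path / f"{engine}{workers}",
                out_format=out_format,
                engine=engine,
                workers=workers,
                seed=9,
            )
            res = run(job)
            assert res.path.read_text() == expected, (engine, workers)

    def test_ground_truth_rendered_through_writer_matches_engines(
        self, small_cohort, tmp_path
    ):
        import io

        from vcfmerge.vcf_io import write_tped

        sink = io.StringIO()
        write_tped(
            small_cohort.truth.expected_tped_rows(), small_cohort.roster, sink
        )
        res = run(MergeJob(inputs=small_cohort.paths, output=tmp_path / "o"))
        assert res.path.read_text() == sink.getvalue()
        assert res.rows == small_cohort.truth.n_keys

    def test_chromosome_selection_matches_restricted_single(
        self, small_cohort, tmp_path, oracle
    ):
        expected = oracle(small_cohort.paths, "tped", chromosomes=("21", "22"))
        for engine, workers in [("partitioned", 2), ("interval", 2), ("tree", 2)]:
            job = MergeJob(
                inputs=small_cohort.paths,
                output=tmp_path / f"sel_{engine}",
                engine=engine,
                workers=workers,
                chromosomes=("21", "22"),
            )
            res = run(job)
            text = res.path.read_text()
            assert text == expected
            assert all(l.split(" ", 1)[0] in ("21", "22") for l in text.splitlines())

    def test_partitioned_output_invariant_to_sampling_seed(
        self, small_cohort, tmp_path
    ):
        """The seed moves partition boundaries, never output content."""
        outs = set()
        for seed in (0, 1, 12345):
            job = MergeJob(
                inputs=small_cohort.paths,
                output=tmp_path / f"seed{seed}",
                engine="partitioned",
                workers=4,
                seed=seed,
            )
            outs.add(run(job).path.read_bytes())
        assert len(outs) == 1

    def test_rerun_is_byte_deterministic(self, small_cohort, tmp_path):
        job1 = MergeJob(
            inputs=small_cohort.paths, output=tmp_path / "r1",
            engine="partitioned", workers=2, seed=4,
        )
        job2 = MergeJob(
            inputs=small_cohort.paths, output=tmp_path / "r2",
            engine="partitioned", workers=2, seed=4,
        )
        assert run(job1).path.read_bytes() == run(job2).path.read_bytes()

    def test_partitioned_launches_one_job_per_selected_chromosome(
        self, small_cohort, tmp_path
    ):
        job = MergeJob(
            inputs=small_cohort.paths, output=tmp_path / "o",
            engine="partitioned", chromosomes=("1", "2", "3"),
        )
        assert run(job).stats["phase2_jobs"] == 3

    def test_skewed_cohort_still_identical_across_engines(self, tmp_path, oracle):
        """All variants on one chromosome arm: interval splitting is
        imbalanced but output is unchanged."""
        spec = CohortSpec(
            n_samples=4,
            variants_per_sample=300,
            overlap=0.6,
            filter_fail=0.05,
            multiallelic=0.1,
            chromosome_weights={"7": 1.0},
            seed=13,
        )
        cohort = generate_cohort(spec, tmp_path / "skew", include_truth=False)
        expected = oracle(cohort.paths, "tped")
        for engine, workers in [("interval", 4), ("partitioned", 4), ("tree", 3)]:
            job = MergeJob(
                inputs=cohort.paths, output=tmp_path / f"sk_{engine}",
                engine=engine, workers=workers,
            )
            assert run(job).path.read_text() == expected

    def test_all_records_filtered_gives_empty_output(self, tmp_path):
        spec = CohortSpec(
            n_samples=2, variants_per_sample=50, filter_fail=1.0, seed=5
        )
        cohort = generate_cohort(spec, tmp_path / "allfail")
        assert cohort.truth.n_keys == 0
        for engine in ("single", "partitioned", "tree", "interval"):
            job = MergeJob(
                inputs=cohort.paths, output=tmp_path / f"e_{engine}",
                engine=engine, workers=2,
            )
            res = run(job)
            assert res.rows == 0
            assert res.path.read_text() == ""
            vjob = MergeJob(
                inputs=cohort.paths, output=tmp_path / f"v_{engine}",
                out_format="vcf", engine=engine, workers=2,
            )
            vres = run(vjob)
            assert vres.rows == 0
            assert all(
                l.startswith("#") for l in vres.path.read_text().splitlines()
            )

    def test_within_file_duplicate_keys_strict_vs_lenient(self, tmp_path, oracle):
        spec = CohortSpec(
            n_samples=3, variants_per_sample=200, seed=21, with_duplicates=True
        )
        cohort = generate_cohort(spec, tmp_path / "dups", include_truth=False)
        from vcfmerge.merge_semantics import MergeConflictError

        with pytest.raises(MergeConflictError, match="two records"):
            run(MergeJob(inputs=cohort.paths, output=tmp_path / "strict"))
        expected = oracle(cohort.paths, "tped", duplicates="lenient")
        for engine, workers in [("single", 1), ("partitioned", 2), ("tree", 2)]:
            job = MergeJob(
                inputs=cohort.paths, output=tmp_path / f"len_{engine}",
                engine=engine, workers=workers, duplicates="lenient",
            )
            assert run(job).path.read_text() == expected


class TestRandomizedOracleEquivalence:
    def test_engines_match_oracle_on_randomized_cohorts(self, tmp_path, oracle):
        """Randomized parameter draws, all engines vs the brute-force merge."""
        rng = random.Random(2024)
        for trial in range(25):
            spec = CohortSpec(
                n_samples=rng.randint(2, 5),
                variants_per_sample=rng.randint(40, 200),
                overlap=rng.uniform(0.0, 0.9),
                filter_fail=rng.uniform(0.0, 0.3),
                multiallelic=rng.uniform(0.0, 0.4),
                seed=rng.randrange(2**31),
            )
            d = tmp_path / f"t{trial}"
            cohort = generate_cohort(spec, d, include_truth=False)
            fmt = "tped" if trial % 2 == 0 else "vcf"
            expected = oracle(cohort.paths, fmt)
            for engine, workers in [
                ("single", 1), ("partitioned", 2), ("tree", 3), ("interval", 2),
            ]:
                job = MergeJob(
                    inputs=cohort.paths, output=d / f"o_{engine}",
                    out_format=fmt, engine=engine, workers=workers,
                    seed=trial,
                )
                assert run(job).path.read_text() == expected, (trial, engine)
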