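"""Shared fixtures: synthetic cohorts, the worked example, and the naive
in-memory merge oracle every engine must reproduce."""

from __future__ import annotations

import io
from collections import defaultdict
from pathlib import Path

import pytest

from vcfmerge.merge_semantics import merge_site_tped, merge_site_vcf, passes_filter
from vcfmerge.synthetic import CohortSpec, generate_cohort, generate_worked_example
from vcfmerge.vcf_io import (
    CHROMOSOMES,
    SampleRoster,
    read_sample_id,
    read_vcf,
    write_merged_vcf,
    write_tped,
)


def naive_merge_text(
    paths,
    out_format: str,
    chromosomes=CHROMOSOMES,
    duplicates: str = "error",
) -> str:
    """Brute-force merge: load everything, filter, group in a map, sort,
    apply the per-site rules, render through the standard writers."""
    selected = set(chromosomes)
    roster = SampleRoster(tuple(read_sample_id(p) for p in paths))
    groups = defaultdict(list)
    for path in paths:
        for rec in read_vcf(path):
            if passes_filter(rec) and rec.key.chrom in selected:
                groups[rec.key.sort_key].append(rec)
    merge = merge_site_tped if out_format == "tped" else merge_site_vcf
    rows = (
        merge(groups[sk], roster, duplicates=duplicates) for sk in sorted(groups)
    )
    sink = io.StringIO()
    if out_format == "tped":
        write_tped(rows, roster, sink)
    else:
        write_merged_vcf(rows, roster, sink)
    return sink.getvalue()


@pytest.fixture(scope="session")
def oracle():
    return naive_merge_text


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The 3-sample toy cohort and its hand-derived expected TPED lines."""
    out = tmp_path_factory.mktemp("worked")
    paths, expected = generate_worked_example(out)
    return paths, expected


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """5 samples x 800 variants with ground truth; exercises every rule."""
    out = tmp_path_factory.mktemp("small_cohort")
    spec = CohortSpec(
        n_samples=5,
        variants_per_sample=800,
        overlap=0.5,
        filter_fail=0.1,
        multiallelic=0.2,
        seed=42,
    )
    return generate_cohort(spec, out)
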