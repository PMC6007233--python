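"""Interchangeable sorted-merge engines.

Four execution strategies, one contract: given the same inputs every engine
produces byte-identical, globally key-sorted output.

``single``
    One-pass k-way multiway merge of all input streams through a priority
    queue; memory stays bounded by the number of streams plus one same-key
    group.
``partitioned``
    Two-phase divide-and-conquer. Phase 1 scans each file, filters, bins
    records by chromosome into sorted intermediate runs, and draws a
    two-round Bernoulli key sample (a fixed first-round rate, then the
    reciprocal of the file count) to compute balanced partition boundaries.
    Phase 2 launches one logical merge job per selected chromosome (25 when
    all are selected); within a job records are routed to half-open key
    ranges, each range is sorted, merged, and written as a shard, and
    shards are concatenated in (chromosome rank, partition) order.
``tree``
    Task-parallel log-round schedule: each worker first multiway-merges its
    share of the files into a local sorted run, then workers pairwise merge
    runs (receiver ids divisible by 2^(r-1), senders offset 2^(r-2)) until
    worker 0 holds everything; a final pass aggregates same-key records
    against the full roster.
``interval``
    Data-parallel merge: the concatenated genomic extent is cut into
    equal-coordinate-span intervals (uniform-position assumption) and each
    worker runs a full multiway merge restricted to its interval,
    emulating an indexed region seek; shards are concatenated in interval
    order.

Workers are isolated tasks communicating only through files; the scheduler
runs the tasks of each phase to completion before the next phase starts (a
serial loop here, which satisfies that contract).
"""

from __future__ import annotations

import gzip
import heapq
import logging
import math
import shutil
import tempfile
import time
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import groupby
from operator import itemgetter
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .merge_semantics import merge_site_tped, merge_site_vcf, passes_filter
from .partitioning import (
    DEFAULT_SAMPLING_RATE,
    KeyInterval,
    SampleSet,
    compute_boundaries,
    interval_split,
    sample_stream,
    second_round_rate,
)
from .vcf_io import (
    CHROM_RANK,
    CHROMOSOMES,
    SampleRoster,
    VariantKey,
    VcfRecord,
    _open_text,
    format_tped_row,
    format_vcf_record,
    normalize_chrom,
    parse_genotype,
    read_sample_id,
    read_vcf,
    vcf_header_lines,
    write_merged_vcf,
    write_tped,
)

__all__ = [
    "ENGINES",
    "MergeJob",
    "MergeResult",
    "SortedRun",
    "TreePlan",
    "StreamOrderError",
    "kway_merge",
    "plan_tree",
    "run",
    "run_single",
    "run_partitioned",
    "run_tree",
    "run_interval_parallel",
]

logger = logging.getLogger("vcfmerge")

Envelope = tuple[tuple[int, int], int, int, VcfRecord]


class StreamOrderError(ValueError):
    """An input stream violated its promised sort order."""


@dataclass
class MergeJob:
    """Configuration of one merge: inputs, engine, output format, knobs."""

    inputs: Sequence[str | Path]
    output: str | Path
    out_format: str = "tped"
    engine: str = "single"
    workers: int = 1
    seed: int = 0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    chromosomes: Sequence[str] = CHROMOSOMES
    ref_conflict: str = "error"
    duplicates: str = "error"
    presort: bool = False
    keep_temp: bool = False
    temp_dir: str | Path | None = None

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("at least one input VCF is required")
        if self.workers < 1:
            raise ValueError(f"worker count must be >= 1, got {self.workers}")
        if self.out_format not in ("tped", "vcf"):
            raise ValueError(f"unknown output format {self.out_format!r}")
        if self.engine not in ENGINES:
            raise ValueError(
                f"unknown engine {self.engine!r}; accepted: {', '.join(ENGINES)}"
            )
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(normalize_chrom(str(c)))
        self.chromosomes = tuple(sorted(seen, key=CHROM_RANK.__getitem__))


@dataclass
class MergeResult:
    path: Path
    rows: int
    roster: SampleRoster
    stats: dict = field(default_factory=dict)


@dataclass
class SortedRun:
    """A temporary file of serialized records, sorted by the global key order."""

    path: Path
    chrom: str | None
    min_key: VariantKey | None
    max_key: VariantKey | None
    count: int


@dataclass(frozen=True)
class TreePlan:
    """Round-by-round pairwise merge schedule: (receiver, sender) per round."""

    workers: int
    rounds: int
    pair_rounds: tuple[tuple[tuple[int, int], ...], ...]


def plan_tree(p: int) -> TreePlan:
    """Merge schedule for ``p`` workers: ``1 + ceil(log2(p))`` rounds.

    Round 1 is the local multiway merge on every worker. In round r >= 2,
    workers whose id is divisible by ``2^(r-1)`` receive from the worker
    ``2^(r-2)`` to their right; a worker without a right neighbour carries
    its data forward unmerged. After the final round worker 0 holds all
    data.
    """
    if p < 1:
        raise ValueError(f"worker count must be >= 1, got {p}")
    rounds = 1 if p == 1 else 1 + math.ceil(math.log2(p))
    pair_rounds = []
    for r in range(2, rounds + 1):
        step = 2 ** (r - 1)
        half = 2 ** (r - 2)
        pair_rounds.append(
            tuple((i, i + half) for i in range(0, p, step) if i + half < p)
        )
    return TreePlan(p, rounds, tuple(pair_rounds))


# ---------------------------------------------------------------------------
# Streams, grouping, and the k-way merge primitive
# ---------------------------------------------------------------------------


def _checked_envelopes(stream: Iterable[VcfRecord], ordinal: int, label: str):
    """Wrap a record stream as sortable envelopes, verifying its order."""
    prev = None
    prev_key = None
    for seq, rec in enumerate(stream):
        sk = rec.key.sort_key
        if prev is not None and sk < prev:
            raise StreamOrderError(
                f"{label}: record {rec.key.chrom}:{rec.key.pos} follows "
                f"{prev_key.chrom}:{prev_key.pos}; the stream is not key-sorted"
            )
        prev = sk
        prev_key = rec.key
        yield (sk, ordinal, seq, rec)


def _grouped(
    merged: Iterable[Envelope],
) -> Iterator[tuple[VariantKey, list[VcfRecord]]]:
    """Group a key-sorted envelope stream into (key, same-key records)."""
    for _, grp in groupby(merged, key=itemgetter(0)):
        recs = [e[3] for e in grp]
        yield recs[0].key, recs


def kway_merge(
    streams: Sequence[Iterable[VcfRecord]],
) -> Iterator[tuple[VariantKey, list[VcfRecord]]]:
    """Single-pass priority-queue merge of individually sorted record streams.

    Yields ``(key, group)`` with keys strictly increasing; each group holds
    exactly the records of that key from all streams, in stream order.
    Detects and reports out-of-order input.
    """
    envs = [
        _checked_envelopes(s, i, f"stream {i}") for i, s in enumerate(streams)
    ]
    return _grouped(heapq.merge(*envs))


def _file_envelopes(
    path: str | Path,
    ordinal: int,
    sample_id: str,
    selected: frozenset[str],
    *,
    presort: bool = False,
    interval: KeyInterval | None = None,
) -> Iterator[Envelope]:
    """Filtered, order-checked envelope stream for one input file."""
    it: Iterable[VcfRecord] = read_vcf(path, sample_id)
    if presort:
        it = sorted(it, key=lambda r: r.key.sort_key)  # stable: file order kept
    prev = None
    seq = 0
    for rec in it:
        sk = rec.key.sort_key
        if not presort and prev is not None and sk < prev:
            raise StreamOrderError(
                f"{path}: record {rec.key.chrom}:{rec.key.pos} is out of order; "
                "input VCFs must be coordinate-sorted (or enable presort)"
            )
        prev = sk
        if not passes_filter(rec):
            continue
        if rec.key.chrom not in selected:
            continue
        if interval is not None and not interval.contains(rec.key):
            continue
        yield (sk, ordinal, seq, rec)
        seq += 1


# ---------------------------------------------------------------------------
# Intermediate run serialization (internal format, version 1)
# ---------------------------------------------------------------------------

_RUN_VERSION = "1"


def _serialize_envelope(env: Envelope) -> str:
    _, ordinal, seq, rec = env
    alts = ",".join(rec.alts) if rec.alts else "."
    info = ";".join(rec.info) if rec.info else "."
    qual = "." if rec.qual is None else repr(rec.qual)
    return (
        f"{rec.key.chrom}\t{rec.key.pos}\t{ordinal}\t{seq}\t{rec.id}\t{rec.ref}"
        f"\t{alts}\t{qual}\t{rec.filter}\t{info}\t{rec.call.to_text()}"
        f"\t{rec.sample_id}\n"
    )


def _write_run(envelopes: Iterable[Envelope], path: Path) -> int:
    count = 0
    with gzip.open(path, "wt", compresslevel=1) as fh:
        for env in envelopes:
            fh.write(_serialize_envelope(env))
            count += 1
    return count


def _read_run(path: Path) -> Iterator[Envelope]:
    rank_of = CHROM_RANK
    with gzip.open(path, "rt") as fh:
        for line in fh:
            c = line.rstrip("\n").split("\t")
            chrom = c[0]
            pos = int(c[1])
            rec = VcfRecord(
                VariantKey(chrom, pos, rank_of[chrom]),
                c[4],
                c[5],
                () if c[6] == "." else tuple(c[6].split(",")),
                None if c[7] == "." else float(c[7]),
                c[8],
                () if c[9] == "." else tuple(c[9].split(";")),
                parse_genotype(c[10]),
                c[11],
            )
            yield (rec.key.sort_key, int(c[2]), int(c[3]), rec)


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def _build_roster(job: MergeJob) -> tuple[SampleRoster, list[str]]:
    """Sample ids in input-file order (header sample name, else file stem)."""
    ids = []
    for p in job.inputs:
        sid = read_sample_id(p)
        if sid is None:
            name = Path(p).name
            for suffix in (".gz", ".vcf"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
            sid = name
        ids.append(sid)
    return SampleRoster(tuple(ids)), ids


def _output_path(job: MergeJob) -> Path:
    out = Path(job.output)
    suffix = ".tped" if job.out_format == "tped" else ".vcf"
    if out.suffix == suffix:
        return out
    return out.with_name(out.name + suffix)


def _rows(groups, roster: SampleRoster, job: MergeJob):
    merge = merge_site_tped if job.out_format == "tped" else merge_site_vcf
    for _, recs in groups:
        yield merge(
            recs,
            roster,
            ref_conflict=job.ref_conflict,
            duplicates=job.duplicates,
        )


def _write_final(rows, roster: SampleRoster, job: MergeJob, out_path: Path) -> int:
    if job.out_format == "tped":
        return write_tped(rows, roster, out_path)
    return write_merged_vcf(rows, roster, out_path)


def _write_shard(rows, roster: SampleRoster, job: MergeJob, path: Path) -> int:
    n = len(roster)
    count = 0
    fmt = format_tped_row if job.out_format == "tped" else format_vcf_record
    arg = n if job.out_format == "tped" else roster
    with open(path, "w") as fh:
        for row in rows:
            fh.write(fmt(row, arg))
            fh.write("\n")
            count += 1
    return count


def _assemble_shards(
    shards: Sequence[Path], roster: SampleRoster, job: MergeJob, out_path: Path
) -> None:
    """Single-writer, ordered concatenation of shard bodies (plus header/TFAM)."""
    with open(out_path, "w") as out:
        if job.out_format == "vcf":
            for line in vcf_header_lines(roster):
                out.write(line)
                out.write("\n")
        for shard in shards:
            with open(shard) as fh:
                shutil.copyfileobj(fh, out)
    if job.out_format == "tped":
        with open(out_path.with_suffix(".tfam"), "w") as fh:
            for s in roster.samples:
                fh.write(f"{s} {s} 0 0 0 -9\n")


class _TempDir:
    """Job-scoped temp directory, removed on success unless keep_temp."""

    def __init__(self, job: MergeJob):
        self.job = job
        if job.temp_dir is not None:
            self.path = Path(job.temp_dir)
            self.path.mkdir(parents=True, exist_ok=True)
            self._own = False
        else:
            self.path = Path(tempfile.mkdtemp(prefix="vcfmerge-"))
            self._own = True

    def __enter__(self) -> Path:
        return self.path

    def __exit__(self, exc_type, exc, tb):
        if self._own and not self.job.keep_temp and exc_type is None:
            shutil.rmtree(self.path, ignore_errors=True)
        return False


def _log_phase(phase: str, t0: float, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    logger.info("phase=%s seconds=%.3f %s", phase, time.perf_counter() - t0, pairs)


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------


def run_single(job: MergeJob) -> MergeResult:
    """One-scan k-way multiway merge of all inputs (the classic method)."""
    t0 = time.perf_counter()
    roster, ids = _build_roster(job)
    selected = frozenset(job.chromosomes)
    out_path = _output_path(job)
    streams = [
        _file_envelopes(p, i, ids[i], selected, presort=job.presort)
        for i, p in enumerate(job.inputs)
    ]
    groups = _grouped(heapq.merge(*streams))
    rows = _rows(groups, roster, job)
    count = _write_final(rows, roster, job, out_path)
    _log_phase("single_merge", t0, files=len(ids), rows_out=count)
    return MergeResult(
        out_path, count, roster, {"engine": "single", "rows": count}
    )


def run_partitioned(job: MergeJob) -> MergeResult:
    """Two-phase sampling-partitioned merge (one phase-2 job per chromosome)."""
    roster, ids = _build_roster(job)
    selected = list(job.chromosomes)
    selected_set = frozenset(selected)
    out_path = _output_path(job)
    n_files = len(job.inputs)
    max_partitions = 4 * job.workers

    with _TempDir(job) as tmp:
        # ---- Phase 1: per-file scan, chromosome binning, first-round sample
        t0 = time.perf_counter()
        bins: list[dict[str, Path]] = []
        samples1 = SampleSet(rate1=job.sampling_rate)
        records_in = 0
        for ordinal, path in enumerate(job.inputs):
            file_bins: dict[str, Path] = {}
            handles: dict[str, gzip.GzipFile] = {}
            keys: list[VariantKey] = []
            try:
                for env in _file_envelopes(
                    path, ordinal, ids[ordinal], selected_set, presort=job.presort
                ):
                    chrom = env[3].key.chrom
                    fh = handles.get(chrom)
                    if fh is None:
                        bp = tmp / f"bin_f{ordinal:05d}_{chrom}.gz"
                        fh = gzip.open(bp, "wt", compresslevel=1)
                        handles[chrom] = fh
                        file_bins[chrom] = bp
                    fh.write(_serialize_envelope(env))
                    keys.append(env[3].key)
                    records_in += 1
            finally:
                for fh in handles.values():
                    fh.close()
            bins.append(file_bins)
            samples1.update(
                sample_stream(keys, job.sampling_rate, job.seed + ordinal)
            )
        _log_phase(
            "partitioned_phase1",
            t0,
            files=n_files,
            records_in=records_in,
            sampled=samples1.total(),
        )

        # ---- Second-round sampling (reciprocal of the file count) and plan
        t0 = time.perf_counter()
        rate2 = second_round_rate(n_files)
        samples2 = SampleSet(rate1=job.sampling_rate, rate2=rate2)
        for chrom, keys in samples1.by_chrom.items():
            frag = sample_stream(
                keys, rate2, job.seed + 99991 + CHROM_RANK[chrom]
            )
            samples2.update(frag)
        plan = compute_boundaries(
            samples2, max_partitions=max_partitions, chromosomes=selected
        )
        plan.save(tmp / "partition_plan.tsv")
        _log_phase(
            "partitioned_sampling", t0, sampled=samples2.total(), rate2=rate2
        )

        # ---- Phase 2: one merge job per selected chromosome
        t0 = time.perf_counter()
        shards: list[Path] = []
        total_rows = 0
        phase2_jobs = 0
        partitions_used = 0
        for chrom in selected:
            phase2_jobs += 1
            envs: list[Envelope] = []
            for ordinal in range(n_files):
                bp = bins[ordinal].get(chrom)
                if bp is not None:
                    envs.extend(_read_run(bp))
            if not envs:
                continue
            bounds = plan.boundaries[chrom]
            nparts = len(bounds) + 1
            parts: list[list[Envelope]] = [[] for _ in range(nparts)]
            for env in envs:
                parts[bisect_right(bounds, env[0][1])].append(env)
            for pi, part in enumerate(parts):
                if not part:
                    continue  # empty partitions are skipped silently
                part.sort(key=itemgetter(0, 1, 2))
                rows = _rows(_grouped(part), roster, job)
                shard = tmp / f"shard_{CHROM_RANK[chrom]:02d}_{pi:05d}.txt"
                total_rows += _write_shard(rows, roster, job, shard)
                shards.append(shard)
                partitions_used += 1
        _assemble_shards(shards, roster, job, out_path)
        _log_phase(
            "partitioned_phase2",
            t0,
            jobs=phase2_jobs,
            partitions=partitions_used,
            rows_out=total_rows,
        )

    stats = {
        "engine": "partitioned",
        "rows": total_rows,
        "records_in": records_in,
        "phase2_jobs": phase2_jobs,
        "partitions_used": partitions_used,
        "sampled_round1": samples1.total(),
        "sampled_round2": samples2.total(),
    }
    return MergeResult(out_path, total_rows, roster, stats)


def run_tree(job: MergeJob) -> MergeResult:
    """Tree-structured merge: local multiway merges, then log2(p) pair rounds."""
    roster, ids = _build_roster(job)
    selected = frozenset(job.chromosomes)
    out_path = _output_path(job)
    p = job.workers
    plan = plan_tree(p)
    n = len(job.inputs)

    # Contiguous, approximately equal file assignment preserving file order.
    base, rem = divmod(n, p)
    chunks: list[list[int]] = []
    start = 0
    for w in range(p):
        size = base + (1 if w < rem else 0)
        chunks.append(list(range(start, start + size)))
        start += size

    with _TempDir(job) as tmp:
        t0 = time.perf_counter()
        runs: dict[int, Path] = {}
        for w, chunk in enumerate(chunks):
            streams = [
                _file_envelopes(
                    job.inputs[i], i, ids[i], selected, presort=job.presort
                )
                for i in chunk
            ]
            path = tmp / f"run_w{w:03d}_r1.gz"
            _write_run(heapq.merge(*streams), path)
            runs[w] = path
        _log_phase("tree_round1", t0, workers=p, files=n)

        for r, pairs in enumerate(plan.pair_rounds, start=2):
            t0 = time.perf_counter()
            for recv, send in pairs:
                merged = heapq.merge(_read_run(runs[recv]), _read_run(runs[send]))
                path = tmp / f"run_w{recv:03d}_r{r}.gz"
                _write_run(merged, path)
                runs[recv] = path
            _log_phase(f"tree_round{r}", t0, pairs=len(pairs))

        t0 = time.perf_counter()
        rows = _rows(_grouped(_read_run(runs[0])), roster, job)
        count = _write_final(rows, roster, job, out_path)
        _log_phase("tree_final", t0, rows_out=count)

    stats = {
        "engine": "tree",
        "rows": count,
        "tree_rounds": plan.rounds,
        "workers": p,
    }
    return MergeResult(out_path, count, roster, stats)


def _scan_extents(
    paths: Sequence[str | Path], selected: frozenset[str]
) -> dict[str, tuple[int, int]]:
    """Per-chromosome [min, max] position ranges over all inputs (fast scan)."""
    extents: dict[str, tuple[int, int]] = {}
    rank_of = CHROM_RANK
    for path in paths:
        with _open_text(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                chrom, pos_s = line.split("\t", 2)[:2]
                if chrom not in rank_of:
                    chrom = normalize_chrom(chrom)
                if chrom not in selected:
                    continue
                pos = int(pos_s)
                cur = extents.get(chrom)
                if cur is None:
                    extents[chrom] = (pos, pos)
                elif pos < cur[0]:
                    extents[chrom] = (pos, cur[1])
                elif pos > cur[1]:
                    extents[chrom] = (cur[0], pos)
    return extents


def run_interval_parallel(job: MergeJob) -> MergeResult:
    """Data-parallel multiway merge over equal-span genomic intervals."""
    roster, ids = _build_roster(job)
    selected = frozenset(job.chromosomes)
    out_path = _output_path(job)
    p = job.workers

    t0 = time.perf_counter()
    extents = _scan_extents(job.inputs, selected)
    _log_phase("interval_scan", t0, chromosomes=len(extents))
    if not extents:
        count = _write_final(iter(()), roster, job, out_path)
        return MergeResult(
            out_path, count, roster, {"engine": "interval", "rows": 0, "intervals": 0}
        )

    intervals = interval_split(extents, p)
    with _TempDir(job) as tmp:
        t0 = time.perf_counter()
        shards: list[Path] = []
        shard_rows: list[int] = []
        total = 0
        for idx, itv in enumerate(intervals):
            if itv.is_empty():
                continue
            streams = [
                _file_envelopes(
                    path, i, ids[i], selected, presort=job.presort, interval=itv
                )
                for i, path in enumerate(job.inputs)
            ]
            rows = _rows(_grouped(heapq.merge(*streams)), roster, job)
            shard = tmp / f"interval_{idx:04d}.txt"
            n_rows = _write_shard(rows, roster, job, shard)
            shards.append(shard)
            shard_rows.append(n_rows)
            total += n_rows
        _assemble_shards(shards, roster, job, out_path)
        _log_phase("interval_merge", t0, intervals=len(intervals), rows_out=total)

    if shard_rows:
        mean = total / len(shard_rows)
        if mean > 0 and max(shard_rows) > 1.5 * mean:
            logger.warning(
                "interval imbalance: max shard %d rows vs mean %.1f "
                "(positions are not uniform)",
                max(shard_rows),
                mean,
            )
    stats = {
        "engine": "interval",
        "rows": total,
        "intervals": len(intervals),
        "shard_rows": shard_rows,
    }
    return MergeResult(out_path, total, roster, stats)


ENGINES = {
    "single": run_single,
    "partitioned": run_partitioned,
    "tree": run_tree,
    "interval": run_interval_parallel,
}


def run(job: MergeJob) -> MergeResult:
    """Dispatch a merge job to its engine."""
    return ENGINES[job.engine](job)
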