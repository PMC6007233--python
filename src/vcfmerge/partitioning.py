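"""Two-round key sampling and balanced range-partition boundaries.

The partitioned merge engine needs key ranges whose record counts are
approximately equal so that every parallel merge task does a similar amount
of work. Boundaries are estimated from a Bernoulli sample of the key
stream: a first round at a small fixed rate (default 1e-4) taken while each
input file is scanned, and a second round at rate ``1 / n_files`` that caps
the expected final sample size regardless of how many files there are.
Per-chromosome boundaries are then evenly spaced order statistics of the
sampled keys, defining half-open ranges ``[lo, hi)`` on the global key
order.

The same machinery serves the pre-split heuristic of a sorted key-value
store bulk load (region count = half the file count) and the
uniform-coordinate interval splitting used by the data-parallel multiway
merge.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .vcf_io import CHROM_RANK, CHROMOSOMES, VariantKey

__all__ = [
    "DEFAULT_SAMPLING_RATE",
    "SampleSet",
    "PartitionPlan",
    "RegionSpec",
    "KeyInterval",
    "sample_stream",
    "second_round_rate",
    "compute_boundaries",
    "assign_partition",
    "region_count",
    "interval_split",
]

#: Default first-round Bernoulli sampling rate.
DEFAULT_SAMPLING_RATE = 0.0001


@dataclass
class SampleSet:
    """Sampled keys grouped by chromosome, with the rates that produced them."""

    by_chrom: dict[str, list[VariantKey]] = field(default_factory=dict)
    rate1: float = DEFAULT_SAMPLING_RATE
    rate2: float | None = None

    def add(self, key: VariantKey) -> None:
        self.by_chrom.setdefault(key.chrom, []).append(key)

    def update(self, other: "SampleSet") -> None:
        for chrom, keys in other.by_chrom.items():
            self.by_chrom.setdefault(chrom, []).extend(keys)

    def total(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())


def sample_stream(
    records: Iterable[VariantKey], rate: float, seed: int
) -> SampleSet:
    """Retain each key independently with probability ``rate`` (seeded PRNG)."""
    if not (0 < rate <= 1):
        raise ValueError(f"sampling rate must be in (0, 1], got {rate}")
    rng = random.Random(seed)
    out = SampleSet(rate1=rate)
    rand = rng.random
    for key in records:
        if rand() < rate:
            out.add(key)
    return out


def second_round_rate(n_files: int) -> float:
    """Second-round rate: the reciprocal of the input file count.

    Composed with the first round this caps the expected final sample size
    at ``total_records * rate1 / n_files``, independent of the number of
    files.
    """
    if n_files < 1:
        raise ValueError(f"n_files must be >= 1, got {n_files}")
    return 1.0 / n_files


@dataclass
class PartitionPlan:
    """Per-chromosome sorted boundary positions defining half-open key ranges.

    A chromosome with ``b`` boundaries has ``b + 1`` partitions; partition
    ``i`` holds keys with ``boundary[i-1] <= key < boundary[i]``.
    """

    boundaries: dict[str, list[int]]

    def n_partitions(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) + 1

    def boundary_keys(self, chrom: str) -> list[VariantKey]:
        return [VariantKey(chrom, p) for p in self.boundaries[chrom]]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.boundaries, key=CHROM_RANK.__getitem__)

    def save(self, path: str | Path) -> None:
        """Serialize as text: a chromosome list line, then one boundary per line."""
        with open(path, "w") as fh:
            fh.write("#chromosomes\t" + ",".join(self.chromosomes) + "\n")
            for chrom in self.chromosomes:
                for pos in self.boundaries[chrom]:
                    fh.write(f"{chrom}\t{pos}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PartitionPlan":
        boundaries: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#chromosomes\t"):
                    listed = line.split("\t", 1)[1]
                    for chrom in listed.split(","):
                        if chrom:
                            boundaries.setdefault(chrom, [])
                    continue
                chrom, pos = line.split("\t")
                boundaries.setdefault(chrom, []).append(int(pos))
        return cls(boundaries)


@dataclass(frozen=True)
class RegionSpec:
    """A pre-split of the whole key space into a fixed number of regions."""

    n_regions: int
    boundaries: tuple[VariantKey, ...]

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("region count must be >= 1")


def compute_boundaries(
    samples: SampleSet,
    max_partitions: int | None = None,
    chromosomes: Sequence[str] | None = None,
) -> PartitionPlan:
    """Quantile boundaries from sampled keys, per chromosome.

    With ``m`` sampled keys the partition count is ``min(m + 1,
    max_partitions)``; boundary ``j`` (1-based, ``k`` partitions) is the
    sampled key of rank ``ceil(j * m / k)``. Duplicate quantiles are
    collapsed, reducing the partition count. A chromosome with no samples
    gets a single partition covering its whole extent.
    """
    if max_partitions is not None and max_partitions < 1:
        raise ValueError(f"max_partitions must be >= 1, got {max_partitions}")
    if chromosomes is None:
        chromosomes = sorted(samples.by_chrom, key=CHROM_RANK.__getitem__)
    plan: dict[str, list[int]] = {}
    for chrom in chromosomes:
        keys = samples.by_chrom.get(chrom, [])
        m = len(keys)
        k = m + 1 if max_partitions is None else min(m + 1, max_partitions)
        if m == 0 or k <= 1:
            plan[chrom] = []
            continue
        positions = sorted(key.pos for key in keys)
        bounds: list[int] = []
        for j in range(1, k):
            rank = math.ceil(j * m / k)  # 1-based rank into the sorted sample
            pos = positions[rank - 1]
            if not bounds or pos > bounds[-1]:
                bounds.append(pos)
        plan[chrom] = bounds
    return PartitionPlan(plan)


def assign_partition(key: VariantKey, plan: PartitionPlan) -> int:
    """Index of the half-open partition holding ``key`` (binary search)."""
    bounds = plan.boundaries.get(key.chrom)
    if bounds is None:
        raise KeyError(
            f"chromosome {key.chrom!r} absent from the partition plan "
            f"(covers: {', '.join(plan.chromosomes) or 'none'})"
        )
    return bisect_right(bounds, key.pos)


def region_count(n_files: int) -> int:
    """Pre-split region count: half the input file count, clamped to >= 1."""
    if n_files < 1:
        raise ValueError(f"n_files must be >= 1, got {n_files}")
    return max(1, n_files // 2)


@dataclass(frozen=True)
class KeyInterval:
    """A contiguous slice of the global key space, as inclusive
    per-chromosome position segments in key order."""

    segments: tuple[tuple[str, int, int], ...]

    def contains(self, key: VariantKey) -> bool:
        for chrom, lo, hi in self.segments:
            if key.chrom == chrom and lo <= key.pos <= hi:
                return True
        return False

    def is_empty(self) -> bool:
        return not self.segments


def interval_split(
    extents: Mapping[str, tuple[int, int]], p: int
) -> list[KeyInterval]:
    """Cut the concatenated genomic extent into ``p`` equal-span intervals.

    Assumes positions are uniformly distributed over the per-chromosome
    ``[min, max]`` extents (the stated simplification of the data-parallel
    multiway merge); the intervals are contiguous, pairwise disjoint, cover
    the whole extent, and are returned in key order. Spans differ by at
    most one coordinate unit.
    """
    if p < 1:
        raise ValueError(f"worker count must be >= 1, got {p}")
    if not extents:
        raise ValueError("extents must be non-empty")
    chroms = sorted(extents, key=CHROM_RANK.__getitem__)
    spans = []
    total = 0
    for chrom in chroms:
        lo, hi = extents[chrom]
        if lo < 1 or hi < lo:
            raise ValueError(f"bad extent for chromosome {chrom}: [{lo}, {hi}]")
        spans.append((chrom, lo, hi))
        total += hi - lo + 1

    cuts = [(i * total) // p for i in range(p + 1)]
    intervals: list[KeyInterval] = []
    for i in range(p):
        start, stop = cuts[i], cuts[i + 1]  # half-open in linear coordinates
        segs: list[tuple[str, int, int]] = []
        offset = 0
        for chrom, lo, hi in spans:
            span = hi - lo + 1
            s = max(start, offset)
            e = min(stop, offset + span)
            if s < e:
                segs.append((chrom, lo + (s - offset), lo + (e - offset) - 1))
            offset += span
        intervals.append(KeyInterval(tuple(segs)))
    return intervals
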