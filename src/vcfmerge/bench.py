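"""Scalability-efficiency metric and a small benchmarking harness.

Efficiency compares the per-core, per-file time cost of a run against a
baseline::

    Efficiency = (T_b * C_b / N_b) / (T_i * C_i / N_i)

where T is wall time (seconds), C the core count and N the number of input
files; subscript b is the baseline run and i the run under test. A value of
1 means the current run processes a file per core at the same cost as the
baseline; in a strong-scaling test (fixed N, growing C) perfect speedup
keeps Efficiency at 1, and in a weak-scaling test (C and N growing at the
same pace) a flat wall time keeps it at 1.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .engines import MergeJob, run

__all__ = ["TimingRecord", "compute_efficiency", "run_benchmark"]


@dataclass(frozen=True)
class TimingRecord:
    """One timed run: wall seconds, cores used, input files processed."""

    seconds: float
    cores: int
    files: int
    label: str = ""

    def __post_init__(self):
        if self.seconds <= 0:
            raise ValueError(f"wall time must be > 0, got {self.seconds}")
        if self.cores < 1:
            raise ValueError(f"core count must be >= 1, got {self.cores}")
        if self.files < 1:
            raise ValueError(f"file count must be >= 1, got {self.files}")

    @property
    def unit_cost(self) -> float:
        """Time cost of processing one file on one core."""
        return self.seconds * self.cores / self.files


def compute_efficiency(baseline: TimingRecord, current: TimingRecord) -> float:
    """``(T_b * C_b / N_b) / (T_i * C_i / N_i)``; 1.0 for baseline vs itself."""
    return baseline.unit_cost / current.unit_cost


def run_benchmark(
    inputs: Sequence[str | Path],
    out_dir: str | Path,
    engines: Sequence[str] = ("single", "partitioned", "tree", "interval"),
    workers: Sequence[int] = (1, 2, 4),
    out_format: str = "tped",
    seed: int = 0,
) -> list[dict]:
    """Time an engine/worker grid on the same inputs.

    The first grid cell is the baseline. Worker counts are treated as the
    core count C of the efficiency formula (the scheduler itself is
    task-parallel over files/partitions). Returns one dict per run with
    label, engine, workers, seconds, rows and efficiency.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[dict] = []
    baseline: TimingRecord | None = None
    for engine in engines:
        for w in workers:
            if engine == "single" and w != workers[0]:
                continue  # the single engine has no worker knob
            label = f"{engine}-w{w}"
            job = MergeJob(
                inputs=list(inputs),
                output=out_dir / f"bench_{label}",
                out_format=out_format,
                engine=engine,
                workers=w,
                seed=seed,
            )
            t0 = time.perf_counter()
            res = run(job)
            elapsed = time.perf_counter() - t0
            record = TimingRecord(
                seconds=elapsed, cores=w, files=len(inputs), label=label
            )
            if baseline is None:
                baseline = record
            results.append(
                {
                    "label": label,
                    "engine": engine,
                    "workers": w,
                    "files": len(inputs),
                    "seconds": elapsed,
                    "rows": res.rows,
                    "efficiency": compute_efficiency(baseline, record),
                }
            )
    return results
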