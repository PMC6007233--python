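"""Deterministic synthetic single-sample VCF cohorts with known ground truth.

Emulates the shape of a whole-genome-sequencing cohort in which each
subject's variants are called into a separate single-sample VCF: variant
positions spread over chromosomes 1-22, X, Y, M in proportion to their
physical lengths, partial overlap of positions across subjects (a shared
site pool), per-record FILTER failures, multi-allelic sites, and an
occasional missing QUAL. The default desk scale — 20 samples of 50,000
variants each — reproduces, at roughly 1/1000 scale, the shape of a cohort
of a couple hundred files with 4-5 million rows each.

The reference allele at a position is a deterministic function of the
coordinate, so any two samples calling the same position agree on REF
(as real callers against one reference genome do). Generation is fully
reproducible from the cohort seed, and the expected merged table (the
ground truth) is accumulated by direct rule application while the files
are written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .merge_semantics import merge_site_tped, merge_site_vcf
from .vcf_io import (
    CHROM_RANK,
    CHROMOSOMES,
    SampleRoster,
    VariantKey,
    VcfRecord,
    parse_genotype,
)

__all__ = [
    "CHROM_LENGTHS",
    "CohortSpec",
    "GroundTruth",
    "CohortResult",
    "generate_cohort",
    "generate_worked_example",
]

#: Approximate physical chromosome lengths (bp), used as default weights.
CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "4": 190_214_555,
    "5": 181_538_259,
    "6": 170_805_979,
    "7": 159_345_973,
    "8": 145_138_636,
    "9": 138_394_717,
    "10": 133_797_422,
    "11": 135_086_622,
    "12": 133_275_309,
    "13": 114_364_328,
    "14": 107_043_718,
    "15": 101_991_189,
    "16": 90_338_345,
    "17": 83_257_441,
    "18": 80_373_285,
    "19": 58_617_616,
    "20": 64_444_167,
    "21": 46_709_983,
    "22": 50_818_468,
    "X": 156_040_895,
    "Y": 57_227_415,
    "M": 16_569,
}

_ACGT = "ACGT"

# Genotype draw weights (recorded in the cohort manifest).
_BIALLELIC_GTS = ("0/0", "0/1", "1/1")
_BIALLELIC_W = (0.10, 0.55, 0.35)
_MULTI_GTS = ("0/1", "1/1", "1/2", "0/2")
_MULTI_W = (0.30, 0.20, 0.30, 0.20)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; deterministic given ``seed``."""

    n_samples: int = 20
    variants_per_sample: int = 50_000
    overlap: float = 0.5
    filter_fail: float = 0.05
    multiallelic: float = 0.10
    qual_missing: float = 0.01
    chromosome_weights: Mapping[str, float] | None = None
    seed: int = 0
    with_duplicates: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.variants_per_sample < 1:
            raise ValueError("variants_per_sample must be >= 1")
        for name in ("overlap", "filter_fail", "multiallelic", "qual_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def weights(self) -> np.ndarray:
        if self.chromosome_weights is None:
            w = np.array([CHROM_LENGTHS[c] for c in CHROMOSOMES], dtype=float)
        else:
            w = np.array(
                [self.chromosome_weights.get(c, 0.0) for c in CHROMOSOMES],
                dtype=float,
            )
        if w.sum() <= 0:
            raise ValueError("chromosome weights must have positive mass")
        return w / w.sum()


#: One ground-truth contributor: everything needed to rebuild its VcfRecord.
# (ordinal, sample, id, ref, alts, qual, info, gt_text)
_Contribution = tuple[int, str, str, str, tuple[str, ...], float | None, tuple[str, ...], str]


@dataclass
class GroundTruth:
    """The expected merged table, keyed by ``(chromosome rank, position)``.

    Holds exactly the PASS contributors of every key that must appear in the
    merged output; expected TPED rows / merged sites are rendered through
    the same aggregation rules the engines apply.
    """

    roster: SampleRoster
    contributors: dict[tuple[int, int], list[_Contribution]] = field(
        default_factory=dict
    )

    def add(self, rank: int, pos: int, contrib: _Contribution) -> None:
        self.contributors.setdefault((rank, pos), []).append(contrib)

    @property
    def n_keys(self) -> int:
        return len(self.contributors)

    def sorted_keys(self) -> list[tuple[int, int]]:
        return sorted(self.contributors)

    def _records(self, sk: tuple[int, int]) -> list[VcfRecord]:
        rank, pos = sk
        key = VariantKey(CHROMOSOMES[rank], pos, rank)
        recs = []
        for ordinal, sample, vid, ref, alts, qual, info, gt in sorted(
            self.contributors[sk], key=lambda c: c[0]
        ):
            recs.append(
                VcfRecord(
                    key, vid, ref, alts, qual, "PASS", info, parse_genotype(gt), sample
                )
            )
        return recs

    def expected_tped_rows(self):
        for sk in self.sorted_keys():
            yield merge_site_tped(self._records(sk), self.roster, duplicates="lenient")

    def expected_sites(self):
        for sk in self.sorted_keys():
            yield merge_site_vcf(self._records(sk), self.roster, duplicates="lenient")

    def checksum(self) -> str:
        """SHA-256 over the expected TPED body (stable fingerprint)."""
        from .vcf_io import format_tped_row

        h = hashlib.sha256()
        n = len(self.roster)
        for row in self.expected_tped_rows():
            h.update(format_tped_row(row, n).encode())
            h.update(b"\n")
        return h.hexdigest()


@dataclass
class CohortResult:
    paths: list[Path]
    roster: SampleRoster
    truth: GroundTruth | None
    manifest_path: Path


def _site_alleles(rank: np.ndarray, pos: np.ndarray):
    """Deterministic REF/ALT assignment per coordinate (caller-independent).

    Returns index arrays: ref base, first ALT, second ALT, all distinct.
    """
    h = (pos.astype(np.uint64) * np.uint64(2654435761)) ^ (
        rank.astype(np.uint64) * np.uint64(0x9E3779B1)
    )
    h ^= h >> np.uint64(13)
    ref = (h & np.uint64(3)).astype(np.int64)
    pick1 = ((h >> np.uint64(2)) % np.uint64(3)).astype(np.int64)
    pick2_off = np.uint64(1) + ((h >> np.uint64(4)) % np.uint64(2))
    pick2 = ((pick1.astype(np.uint64) + pick2_off) % np.uint64(3)).astype(np.int64)
    # map picks into {0..3} \ {ref}
    alt1 = pick1 + (pick1 >= ref)
    alt2 = pick2 + (pick2 >= ref)
    return ref, alt1, alt2


def _distinct_positions(
    rng: np.random.Generator, length: int, count: int, exclude: set[int] | None = None
) -> np.ndarray:
    """Distinct 1-based positions in [1, length], optionally avoiding a set."""
    if count == 0:
        return np.empty(0, dtype=np.int64)
    if count > length:
        raise ValueError(f"cannot draw {count} distinct positions from [1, {length}]")
    out: list[int] = []
    seen: set[int] = set()
    need = count
    while need > 0:
        draw = rng.integers(1, length + 1, size=int(need * 1.4) + 8)
        for v in draw.tolist():
            if v in seen or (exclude is not None and v in exclude):
                continue
            seen.add(v)
            out.append(v)
            if len(out) == count:
                break
        need = count - len(out)
    return np.array(out, dtype=np.int64)


def _vcf_header(sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=vcfmerge-synthetic"]
    lines.extend(f"##contig=<ID={c}>" for c in CHROMOSOMES)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}"
    )
    return "\n".join(lines) + "\n"


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path, include_truth: bool = True
) -> CohortResult:
    """Write ``spec.n_samples`` sorted single-sample VCFs plus a manifest.

    Shared positions are drawn from a common per-chromosome pool at the
    overlap rate; the rest are private to each sample. Returns the file
    paths and (optionally) the ground-truth merged table accumulated during
    generation. Ground truth costs memory proportional to the total record
    count; disable it for large cohorts whose output is checked by other
    means.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    w = spec.weights()
    n_chrom = len(CHROMOSOMES)

    # Shared pool: one coordinate pool the samples overlap on.
    pool_size = spec.variants_per_sample
    pool_counts = rng.multinomial(pool_size, w)
    pool_rank_parts = []
    pool_pos_parts = []
    pool_sets: list[set[int]] = [set() for _ in range(n_chrom)]
    for r in range(n_chrom):
        length = CHROM_LENGTHS[CHROMOSOMES[r]]
        cnt = min(int(pool_counts[r]), length)
        positions = _distinct_positions(rng, length, cnt)
        pool_sets[r] = set(positions.tolist())
        pool_rank_parts.append(np.full(cnt, r, dtype=np.int64))
        pool_pos_parts.append(positions)
    pool_rank = np.concatenate(pool_rank_parts)
    pool_pos = np.concatenate(pool_pos_parts)
    pool_n = len(pool_pos)

    roster = SampleRoster(tuple(f"S{i:03d}" for i in range(spec.n_samples)))
    truth = GroundTruth(roster) if include_truth else None
    paths: list[Path] = []
    record_counts: list[int] = []

    for ordinal, sample in enumerate(roster.samples):
        n_shared = min(int(round(spec.overlap * spec.variants_per_sample)), pool_n)
        idx = rng.choice(pool_n, size=n_shared, replace=False)
        ranks = [pool_rank[idx]]
        positions = [pool_pos[idx]]

        n_private = spec.variants_per_sample - n_shared
        priv_counts = rng.multinomial(n_private, w) if n_private > 0 else np.zeros(
            n_chrom, dtype=np.int64
        )
        chosen_shared: list[set[int]] = [set() for _ in range(n_chrom)]
        for r, p in zip(pool_rank[idx].tolist(), pool_pos[idx].tolist()):
            chosen_shared[r].add(p)
        for r in range(n_chrom):
            cnt = int(priv_counts[r])
            if cnt == 0:
                continue
            length = CHROM_LENGTHS[CHROMOSOMES[r]]
            priv = _distinct_positions(rng, length, cnt, exclude=pool_sets[r])
            ranks.append(np.full(cnt, r, dtype=np.int64))
            positions.append(priv)

        rank_arr = np.concatenate(ranks)
        pos_arr = np.concatenate(positions)

        if spec.with_duplicates and len(pos_arr) >= 10:
            # duplicate ~1% of keys within the file (split multi-allelic style)
            n_dup = max(1, len(pos_arr) // 100)
            dup_idx = rng.choice(len(pos_arr), size=n_dup, replace=False)
            rank_arr = np.concatenate([rank_arr, rank_arr[dup_idx]])
            pos_arr = np.concatenate([pos_arr, pos_arr[dup_idx]])

        order = np.lexsort((pos_arr, rank_arr))
        rank_arr = rank_arr[order]
        pos_arr = pos_arr[order]
        n = len(pos_arr)

        ref_i, alt1_i, alt2_i = _site_alleles(rank_arr, pos_arr)
        multi = rng.random(n) < spec.multiallelic
        gt_bi = rng.choice(len(_BIALLELIC_GTS), size=n, p=_BIALLELIC_W)
        gt_mu = rng.choice(len(_MULTI_GTS), size=n, p=_MULTI_W)
        qual = np.round(rng.uniform(20.0, 99.0, size=n), 1)
        qmiss = rng.random(n) < spec.qual_missing
        fails = rng.random(n) < spec.filter_fail
        depth = rng.integers(5, 60, size=n)

        path = out_dir / f"{sample}.vcf"
        paths.append(path)
        dup_seen: set[tuple[int, int]] = set()
        with open(path, "w") as fh:
            fh.write(_vcf_header(sample))
            for i in range(n):
                r = int(rank_arr[i])
                p = int(pos_arr[i])
                chrom = CHROMOSOMES[r]
                ref = _ACGT[ref_i[i]]
                if multi[i]:
                    alts = (_ACGT[alt1_i[i]], _ACGT[alt2_i[i]])
                    gt = _MULTI_GTS[gt_mu[i]]
                else:
                    alts = (_ACGT[alt1_i[i]],)
                    gt = _BIALLELIC_GTS[gt_bi[i]]
                if spec.with_duplicates and (r, p) in dup_seen:
                    # second line of a within-file duplicate: flip to the other ALT
                    alts = (_ACGT[alt2_i[i]],)
                    gt = "0/1"
                dup_seen.add((r, p))
                q: float | None = None if qmiss[i] else float(qual[i])
                q_text = "." if q is None else f"{q:g}"
                filt = "q10" if fails[i] else "PASS"
                info = (f"DP={int(depth[i])}",)
                fh.write(
                    f"{chrom}\t{p}\t.\t{ref}\t{','.join(alts)}\t{q_text}\t{filt}"
                    f"\tDP={int(depth[i])}\tGT\t{gt}\n"
                )
                if truth is not None and filt == "PASS":
                    truth.add(r, p, (ordinal, sample, ".", ref, alts, q, info, gt))
        record_counts.append(n)

    manifest = {
        "spec": {
            k: v
            for k, v in asdict(spec).items()
            if k != "chromosome_weights" or v is not None
        },
        "samples": list(roster.samples),
        "files": [p.name for p in paths],
        "records_per_file": record_counts,
        "genotype_weights": {
            "biallelic": dict(zip(_BIALLELIC_GTS, _BIALLELIC_W)),
            "multiallelic": dict(zip(_MULTI_GTS, _MULTI_W)),
        },
        "truth_keys": truth.n_keys if truth is not None else None,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return CohortResult(paths, roster, truth, manifest_path)


# ---------------------------------------------------------------------------
# Worked example: three tiny input files and the TPED they must merge into
# ---------------------------------------------------------------------------

_WORKED_INPUTS: dict[str, list[str]] = {
    "NA001": [
        "1\t10123\t.\tA\tG\t50\tPASS\tDP=11\tGT\t0/1",
        "1\t10234\t.\tA\tC\t60\tPASS\tDP=14\tGT\t0/1",
        "1\t10501\t.\tC\tG,T\t60\tPASS\tDP=20\tGT\t1/2",
    ],
    "NA002": [
        "1\t10123\t.\tA\tG\t30\tPASS\tDP=9\tGT\t1/1",
        "1\t10147\t.\tG\tA\t15\tq10\tDP=4\tGT\t0/1",
        "1\t10501\t.\tC\tT\t20\tPASS\tDP=7\tGT\t0/1",
    ],
    "NA003": [
        "1\t10123\t.\tA\tG\t40\tPASS\tDP=12\tGT\t0/0",
        "1\t10234\t.\tA\tC\t45\tPASS\tDP=10\tGT\t1/1",
        "X\t500\t.\tT\tA\t55\tPASS\tDP=13\tGT\t1/1",
    ],
}

#: Expected TPED rows, derived by hand-applying the merge rules:
#: 10147 is dropped (FILTER q10); NA002 lacks 10234 and NA003 lacks 10501,
#: so both are filled with the site's homozygous-reference pair; 10501 is
#: multi-allelic (NA001 calls G/T, NA002's ALT T sits at merged index 2).
_WORKED_EXPECTED_TPED = [
    "1 1:10123 0 10123 A G G G A A",
    "1 1:10234 0 10234 A C A A C C",
    "1 1:10501 0 10501 G T C T C C",
    "X X:500 0 500 T T T T A A",
]


def generate_worked_example(out_dir: str | Path):
    """Write the three-sample toy cohort and its expected TPED.

    The cohort exercises exactly one non-PASS record (absent from the
    output), one position missing from one sample (homozygous-reference
    fill), and one multi-allelic site (allele-index remapping).
    Returns ``(paths, expected_tped_lines)``; the expected lines are also
    written to ``expected.tped`` beside the inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, lines in _WORKED_INPUTS.items():
        path = out_dir / f"{sample}.vcf"
        with open(path, "w") as fh:
            fh.write(_vcf_header(sample))
            for line in lines:
                fh.write(line + "\n")
        paths.append(path)
    expected = out_dir / "expected.tped"
    expected.write_text("\n".join(_WORKED_EXPECTED_TPED) + "\n")
    return paths, list(_WORKED_EXPECTED_TPED)
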