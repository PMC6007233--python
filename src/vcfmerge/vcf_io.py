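"""VCF input, the global genomic key order, and TPED / merged-VCF output.

Single-sample VCF files are the unit of input: each carries the eight
mandatory columns plus at most one FORMAT/sample genotype column. Records
are keyed by ``(chromosome, position)`` where chromosomes follow the fixed
rank order 1..22, X, Y, M; this order defines the one global sort order
that every merge engine must reproduce.

Outputs are PLINK TPED (with a companion TFAM stub) and multi-sample
VCF 4.x, both written as plain ``\\n``-terminated text so that independently
produced shards can be concatenated byte-for-byte.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "CHROMOSOMES",
    "CHROM_RANK",
    "VcfFormatError",
    "VariantKey",
    "GenotypeCall",
    "MISSING_CALL",
    "VcfRecord",
    "SampleRoster",
    "normalize_chrom",
    "compare_keys",
    "anonymize_position",
    "parse_genotype",
    "read_vcf",
    "read_sample_id",
    "write_tped",
    "write_merged_vcf",
    "format_tped_row",
    "format_vcf_record",
    "vcf_header_lines",
    "check_output_sorted",
]

#: The 25 accepted chromosome labels, in output (rank) order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "M")
CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

_ACGT = "ACGT"


class VcfFormatError(ValueError):
    """Malformed VCF content, an unknown chromosome label, or a bad coordinate."""


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label onto the 25-label set.

    Accepts an optional ``chr`` prefix and ``MT`` as a synonym for ``M``.
    Anything outside 1..22, X, Y, M is rejected.
    """
    c = label[3:] if label[:3] in ("chr", "CHR", "Chr") else label
    if c == "MT":
        c = "M"
    if c not in CHROM_RANK:
        raise VcfFormatError(
            f"unknown chromosome label {label!r}; accepted labels are "
            + ", ".join(CHROMOSOMES)
            + " (optionally 'chr'-prefixed; 'MT' accepted for 'M')"
        )
    return c


class VariantKey:
    """Totally ordered genomic coordinate: chromosome rank first, then position.

    Positions are 1-based. Comparison uses the precomputed ``sort_key``
    tuple so keys can be fed directly into heaps and sorts.
    """

    __slots__ = ("chrom", "pos", "sort_key")

    def __init__(self, chrom: str, pos: int, _rank: int | None = None):
        rank = CHROM_RANK.get(chrom) if _rank is None else _rank
        if rank is None:
            chrom = normalize_chrom(chrom)
            rank = CHROM_RANK[chrom]
        if pos < 1:
            raise VcfFormatError(f"position must be >= 1, got {pos}")
        self.chrom = chrom
        self.pos = pos
        self.sort_key = (rank, pos)

    def __eq__(self, other) -> bool:
        return isinstance(other, VariantKey) and self.sort_key == other.sort_key

    def __lt__(self, other: "VariantKey") -> bool:
        return self.sort_key < other.sort_key

    def __le__(self, other: "VariantKey") -> bool:
        return self.sort_key <= other.sort_key

    def __gt__(self, other: "VariantKey") -> bool:
        return self.sort_key > other.sort_key

    def __ge__(self, other: "VariantKey") -> bool:
        return self.sort_key >= other.sort_key

    def __hash__(self) -> int:
        return hash(self.sort_key)

    def __repr__(self) -> str:
        return f"VariantKey({self.chrom!r}, {self.pos})"


def compare_keys(a: VariantKey, b: VariantKey) -> int:
    """Three-way comparison on the global key order: -1, 0, or 1."""
    if a.sort_key < b.sort_key:
        return -1
    if a.sort_key > b.sort_key:
        return 1
    return 0


def anonymize_position(pos: int, c_real: float, c_int: int) -> int:
    """Order-preserving position scrambling: ``floor(pos * c_real) + c_int``.

    The constants are deliberately caller-supplied and carry no defaults;
    for any fixed pair the transform is monotone non-decreasing in ``pos``,
    so sorted inputs stay sorted. The result must remain a valid 1-based
    coordinate.
    """
    if pos < 1:
        raise VcfFormatError(f"position must be >= 1, got {pos}")
    if c_real <= 0:
        raise ValueError(f"scaling constant must be > 0, got {c_real}")
    out = math.floor(pos * c_real) + c_int
    if out < 1:
        raise VcfFormatError(
            f"anonymized position {out} < 1 for pos={pos}, c_real={c_real}, c_int={c_int}"
        )
    return out


class GenotypeCall:
    """A genotype as allele indices (0 = REF, k >= 1 = k-th ALT), or missing.

    ``alleles`` is a tuple of one (haploid) or two indices, or ``None`` for a
    missing call. Any ``.`` allele in the VCF text renders the whole call
    missing.
    """

    __slots__ = ("alleles", "phased")

    def __init__(self, alleles: tuple[int, ...] | None, phased: bool = False):
        self.alleles = alleles
        self.phased = phased

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def to_text(self) -> str:
        if self.alleles is None:
            return "./."
        sep = "|" if self.phased else "/"
        return sep.join(str(a) for a in self.alleles)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeCall)
            and self.alleles == other.alleles
            and self.phased == other.phased
        )

    def __hash__(self) -> int:
        return hash((self.alleles, self.phased))

    def __repr__(self) -> str:
        return f"GenotypeCall({self.alleles!r}, phased={self.phased})"


#: Shared missing-call singleton.
MISSING_CALL = GenotypeCall(None, False)


@lru_cache(maxsize=8192)
def parse_genotype(gt_text: str) -> GenotypeCall:
    """Parse a GT field (``a/b``, ``a|b``, ``a``, or missing forms).

    Any ``.`` allele makes the whole call missing; non-integer or negative
    tokens are errors.
    """
    phased = "|" in gt_text
    tokens = gt_text.replace("|", "/").split("/")
    if len(tokens) > 2:
        raise VcfFormatError(f"genotype {gt_text!r} has more than two alleles")
    alleles = []
    for tok in tokens:
        if tok == ".":
            return MISSING_CALL
        try:
            v = int(tok)
        except ValueError:
            raise VcfFormatError(
                f"genotype {gt_text!r}: allele token {tok!r} is not an integer"
            ) from None
        if v < 0:
            raise VcfFormatError(f"genotype {gt_text!r}: negative allele index {tok!r}")
        alleles.append(v)
    return GenotypeCall(tuple(alleles), phased)


@dataclass(slots=True)
class VcfRecord:
    """One parsed single-sample variant line."""

    key: VariantKey
    id: str
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    filter: str
    info: tuple[str, ...]
    call: GenotypeCall
    sample_id: str


@dataclass(frozen=True)
class SampleRoster:
    """Ordered sample identifiers fixing the column order of all outputs."""

    samples: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValueError(f"duplicate sample identifiers in roster: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently (magic-byte sniff)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode.replace("t", ""))
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def _header_samples(cols: Sequence[str], name: str) -> list[str]:
    samples = list(cols[9:]) if len(cols) > 9 else []
    if len(samples) > 1:
        raise VcfFormatError(
            f"{name}: found {len(samples)} sample columns; this reader accepts "
            "single-sample VCFs only (merge them with this package instead)"
        )
    return samples


def read_sample_id(source: str | Path) -> str | None:
    """Return the sample name declared on the ``#CHROM`` header line, if any."""
    with _open_text(source) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                cols = line.rstrip("\n").split("\t")
                samples = _header_samples(cols, str(source))
                return samples[0] if samples else None
            break
    return None


def read_vcf(
    source: str | Path | IO[str], sample_id: str | None = None
) -> Iterator[VcfRecord]:
    """Stream the records of a single-sample VCF in file order.

    ``sample_id`` overrides the header sample name; it is required for
    sites-only files (no FORMAT/sample column). Multi-sample input is an
    error. Malformed lines raise :class:`VcfFormatError` naming the file,
    line number, and column.
    """
    if hasattr(source, "read"):
        name = getattr(source, "name", "<stream>")
        yield from _parse_stream(source, name, sample_id)
    else:
        name = str(source)
        with _open_text(source) as fh:
            yield from _parse_stream(fh, name, sample_id)


def _parse_stream(fh: Iterable[str], name: str, sample_override: str | None):
    rank_of = CHROM_RANK
    sample = sample_override
    for lineno, line in enumerate(fh, 1):
        if line.startswith("#"):
            if not line.startswith("##"):
                samples = _header_samples(line.rstrip("\n").split("\t"), name)
                if sample_override is None and samples:
                    sample = samples[0]
            continue
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise VcfFormatError(
                f"{name}, line {lineno}: expected >= 8 tab-separated columns, "
                f"found {len(cols)}"
            )
        chrom = cols[0]
        rank = rank_of.get(chrom)
        if rank is None:
            try:
                chrom = normalize_chrom(chrom)
            except VcfFormatError as exc:
                raise VcfFormatError(
                    f"{name}, line {lineno}, column CHROM: {exc}"
                ) from None
            rank = rank_of[chrom]
        try:
            pos = int(cols[1])
        except ValueError:
            raise VcfFormatError(
                f"{name}, line {lineno}, column POS: {cols[1]!r} is not an integer"
            ) from None
        if pos < 1:
            raise VcfFormatError(
                f"{name}, line {lineno}, column POS: position {pos} < 1"
            )
        qual_text = cols[5]
        if qual_text == ".":
            qual: float | None = None
        else:
            try:
                qual = float(qual_text)
            except ValueError:
                raise VcfFormatError(
                    f"{name}, line {lineno}, column QUAL: {qual_text!r} is not numeric"
                ) from None
            if qual < 0:
                raise VcfFormatError(
                    f"{name}, line {lineno}, column QUAL: negative quality {qual_text}"
                )
        alt_text = cols[4]
        alts = () if alt_text == "." else tuple(alt_text.split(","))
        info_text = cols[7]
        info = () if info_text == "." else tuple(info_text.split(";"))
        if len(cols) >= 10:
            fmt = cols[8]
            if fmt == "GT":
                gt_text = cols[9]
            else:
                fields = fmt.split(":")
                try:
                    gt_idx = fields.index("GT")
                except ValueError:
                    gt_idx = -1
                gt_text = cols[9].split(":")[gt_idx] if gt_idx >= 0 else "."
            try:
                call = parse_genotype(gt_text)
            except VcfFormatError as exc:
                raise VcfFormatError(
                    f"{name}, line {lineno}, column {sample or 'SAMPLE'}: {exc}"
                ) from None
            if call.alleles is not None and max(call.alleles) > len(alts):
                raise VcfFormatError(
                    f"{name}, line {lineno}: allele index {max(call.alleles)} "
                    f"exceeds the {len(alts)} ALT allele(s) of the record"
                )
        else:
            call = MISSING_CALL
        if sample is None:
            raise VcfFormatError(
                f"{name}, line {lineno}: no sample column in the header and no "
                "sample_id override was given"
            )
        yield VcfRecord(
            VariantKey(chrom, pos, rank),
            cols[2],
            cols[3],
            alts,
            qual,
            cols[6],
            info,
            call,
            sample,
        )


# ---------------------------------------------------------------------------
# Output formatting and writers
# ---------------------------------------------------------------------------


def format_tped_row(row, n_samples: int) -> str:
    """Render one TPED line: chrom, id, genetic distance 0, pos, then alleles.

    Raises if the row does not carry exactly ``n_samples`` allele pairs or
    any pair member is empty.
    """
    if len(row.alleles) != n_samples:
        raise ValueError(
            f"TPED row at {row.key.chrom}:{row.key.pos} carries "
            f"{len(row.alleles)} allele pairs for a {n_samples}-sample roster"
        )
    parts = [row.key.chrom, row.id, "0", str(row.key.pos)]
    for a, b in row.alleles:
        if not a or not b:
            raise ValueError(
                f"TPED row at {row.key.chrom}:{row.key.pos} has an empty allele symbol"
            )
        parts.append(a)
        parts.append(b)
    return " ".join(parts)


def _format_qual(qual: float | None) -> str:
    return "." if qual is None else f"{qual:g}"


def format_vcf_record(site, roster: SampleRoster) -> str:
    """Render one merged-VCF data line (FORMAT is always ``GT``)."""
    if len(site.calls) != len(roster):
        raise ValueError(
            f"merged site at {site.key.chrom}:{site.key.pos} carries "
            f"{len(site.calls)} calls for a {len(roster)}-sample roster"
        )
    alt_text = ",".join(site.alts) if site.alts else "."
    info_text = ";".join(site.info) if site.info else "."
    cols = [
        site.key.chrom,
        str(site.key.pos),
        site.id,
        site.ref,
        alt_text,
        _format_qual(site.qual),
        site.filter,
        info_text,
        "GT",
    ]
    cols.extend(c.to_text() for c in site.calls)
    return "\t".join(cols)


def vcf_header_lines(roster: SampleRoster, source: str = "vcfmerge") -> list[str]:
    """Meta lines + column line for a merged multi-sample VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines.extend(f"##contig=<ID={c}>" for c in CHROMOSOMES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(roster.samples)
    )
    return lines


def _write_tfam(roster: SampleRoster, path: Path) -> None:
    # Family id = sample id; parents, sex, phenotype left unset (PLINK stub).
    with open(path, "w") as fh:
        for s in roster.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")


def write_tped(
    rows: Iterable,
    roster: SampleRoster,
    sink: str | Path | IO[str],
    *,
    tfam: bool = True,
) -> int:
    """Write sorted TPED rows; returns the row count.

    A TFAM stub (one line per roster sample) is written beside the TPED when
    ``sink`` is a path. Rows must arrive in non-decreasing key order.
    """
    n = len(roster)
    count = 0
    prev = None

    def _emit(fh) -> int:
        nonlocal count, prev
        for row in rows:
            if prev is not None and row.key.sort_key < prev:
                raise ValueError(
                    f"unsorted TPED input: {row.key.chrom}:{row.key.pos} follows "
                    f"{CHROMOSOMES[prev[0]]}:{prev[1]}"
                )
            prev = row.key.sort_key
            fh.write(format_tped_row(row, n))
            fh.write("\n")
            count += 1
        return count

    if hasattr(sink, "write"):
        return _emit(sink)
    sink = Path(sink)
    with open(sink, "w") as fh:
        _emit(fh)
    if tfam:
        _write_tfam(roster, sink.with_suffix(".tfam"))
    return count


def write_merged_vcf(
    sites: Iterable,
    roster: SampleRoster,
    sink: str | Path | IO[str],
) -> int:
    """Write a multi-sample VCF (header plus sorted sites); returns row count."""
    count = 0
    prev = None

    def _emit(fh) -> int:
        nonlocal count, prev
        for line in vcf_header_lines(roster):
            fh.write(line)
            fh.write("\n")
        for site in sites:
            if prev is not None and site.key.sort_key < prev:
                raise ValueError(
                    f"unsorted VCF input: {site.key.chrom}:{site.key.pos} follows "
                    f"{CHROMOSOMES[prev[0]]}:{prev[1]}"
                )
            prev = site.key.sort_key
            fh.write(format_vcf_record(site, roster))
            fh.write("\n")
            count += 1
        return count

    if hasattr(sink, "write"):
        return _emit(sink)
    with open(Path(sink), "w") as fh:
        return _emit(fh)


def check_output_sorted(path: str | Path) -> int:
    """One-pass validator for TPED or merged-VCF output.

    Checks that keys are non-decreasing in the global order and that every
    row has a consistent token width. Returns the data-row count; raises
    :class:`VcfFormatError` on the first violation.
    """
    path = Path(path)
    is_tped = path.suffix == ".tped"
    prev = None
    width = None
    rows = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split(" ") if is_tped else line.split("\t")
            if width is None:
                width = len(cols)
            elif len(cols) != width:
                raise VcfFormatError(
                    f"{path}, line {lineno}: {len(cols)} tokens, expected {width}"
                )
            chrom, pos_col = (cols[0], cols[3]) if is_tped else (cols[0], cols[1])
            key = VariantKey(chrom, int(pos_col))
            if prev is not None and key.sort_key < prev:
                raise VcfFormatError(
                    f"{path}, line {lineno}: key {chrom}:{pos_col} out of order"
                )
            prev = key.sort_key
            rows += 1
    return rows
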