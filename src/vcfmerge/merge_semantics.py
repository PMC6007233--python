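"""Per-record filtering and per-key aggregation rules.

Given the group of all records sharing one genomic key (already filtered to
FILTER == "PASS"), these functions produce either one TPED row — allele
indices translated to nucleotides, with a homozygous-reference pair filled
in for every roster sample lacking a record — or one merged-VCF site: ALT
and INFO lists concatenated in first-seen order with duplicates removed,
QUAL the weighted mean over contributing records, genotype indices remapped
into the merged ALT index space, and ``./.`` for absent samples.

Record groups must be supplied in deterministic contributor order
(input-file order, then record order within a file); first-seen
deduplication makes this order observable in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .vcf_io import (
    MISSING_CALL,
    GenotypeCall,
    SampleRoster,
    VariantKey,
    VcfRecord,
)

__all__ = [
    "MergeConflictError",
    "TpedRow",
    "MergedSite",
    "passes_filter",
    "translate_alleles",
    "remap_allele_indices",
    "merge_site_tped",
    "merge_site_vcf",
]


class MergeConflictError(ValueError):
    """Contradictory same-key records (duplicate sample, REF disagreement)."""


@dataclass(slots=True)
class TpedRow:
    """One output row of the TPED table: a nucleotide pair per roster sample."""

    key: VariantKey
    id: str
    alleles: tuple[tuple[str, str], ...]


@dataclass(slots=True)
class MergedSite:
    """One output row of the merged VCF, in merged allele index space."""

    key: VariantKey
    id: str
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    filter: str
    info: tuple[str, ...]
    calls: tuple[GenotypeCall, ...]


def passes_filter(record: VcfRecord) -> bool:
    """True iff the FILTER column equals ``PASS`` exactly (case-sensitive)."""
    return record.filter == "PASS"


def translate_alleles(
    call: GenotypeCall, ref: str, alts: Sequence[str]
) -> tuple[str, str]:
    """Translate allele indices to nucleotides: 0 -> REF, k >= 1 -> ALT[k-1].

    A haploid call contributes its single allele twice (TPED rows are
    diploid pairs). The call must be non-missing.
    """
    if call.alleles is None:
        raise ValueError("cannot translate a missing genotype call")
    out = []
    for idx in call.alleles:
        if idx > len(alts):
            raise MergeConflictError(
                f"allele index {idx} exceeds the {len(alts)} ALT allele(s)"
            )
        out.append(ref if idx == 0 else alts[idx - 1])
    if len(out) == 1:
        out.append(out[0])
    return (out[0], out[1])


def remap_allele_indices(
    call: GenotypeCall,
    local_ref: str,
    local_alts: Sequence[str],
    merged_alts: Sequence[str],
) -> GenotypeCall:
    """Re-express a call's ALT indices relative to the merged ALT list.

    Index 0 (reference) is invariant; local index k >= 1 becomes
    ``1 + position of local_alts[k-1] in merged_alts``. Phasing is
    preserved. ``local_ref`` is part of the site identity and is kept in
    the signature for symmetry with :func:`translate_alleles`.
    """
    del local_ref  # the reference allele never changes index
    if call.alleles is None:
        return call
    mapped = []
    for idx in call.alleles:
        if idx == 0:
            mapped.append(0)
            continue
        allele = local_alts[idx - 1]
        try:
            mapped.append(1 + merged_alts.index(allele))
        except ValueError:
            raise MergeConflictError(
                f"local ALT allele {allele!r} missing from merged ALT list "
                f"{list(merged_alts)!r}"
            ) from None
    new = tuple(mapped)
    if new == call.alleles:
        return call
    return GenotypeCall(new, call.phased)


def _merged_id(records: Sequence[VcfRecord], default: str) -> str:
    """Input ID kept only when every contributor agrees; else the default.

    The default is ``chrom:pos`` for TPED rows (the format needs a
    collision-free variant name) and ``.`` for merged-VCF sites (the VCF
    null).
    """
    ids = {r.id for r in records}
    if len(ids) == 1:
        (vid,) = ids
        if vid != ".":
            return vid
    return default


def _resolve_group(
    records: Sequence[VcfRecord],
    ref_conflict: str,
    duplicates: str,
) -> tuple[str, list[VcfRecord], dict[str, VcfRecord]]:
    """Validate one same-key group; returns (ref, usable records, per-sample pick).

    ``ref_conflict``: "error" rejects REF disagreement; "first" keeps the
    first-seen REF and drops records carrying any other.
    ``duplicates``: "error" rejects two records for one sample; "lenient"
    keeps all for ALT/INFO/QUAL aggregation and takes the genotype from the
    first line carrying a non-reference, non-missing call.
    """
    if not records:
        raise ValueError("empty record group")
    key = records[0].key
    ref = records[0].ref
    usable: list[VcfRecord] = []
    for rec in records:
        if rec.ref != ref:
            if ref_conflict == "error":
                raise MergeConflictError(
                    f"REF disagreement at {key.chrom}:{key.pos}: "
                    f"{ref!r} (first seen) vs {rec.ref!r} (sample {rec.sample_id})"
                )
            continue  # ref_conflict == "first": drop the disagreeing record
        usable.append(rec)

    by_sample: dict[str, VcfRecord] = {}
    for rec in usable:
        prev = by_sample.get(rec.sample_id)
        if prev is None:
            by_sample[rec.sample_id] = rec
        elif duplicates == "error":
            raise MergeConflictError(
                f"two records for sample {rec.sample_id!r} at {key.chrom}:{key.pos}"
            )
        else:  # lenient: prefer the line with a non-reference call
            def _nonref(r: VcfRecord) -> bool:
                return r.call.alleles is not None and any(a > 0 for a in r.call.alleles)

            if not _nonref(prev) and _nonref(rec):
                by_sample[rec.sample_id] = rec
    return ref, usable, by_sample


def merge_site_tped(
    records: Sequence[VcfRecord],
    roster: SampleRoster,
    *,
    ref_conflict: str = "error",
    duplicates: str = "error",
) -> TpedRow:
    """Aggregate one key's PASS records into a TPED row.

    Contributing samples get their call translated to nucleotides; every
    roster sample without a record (or with a missing call) gets the
    homozygous-reference pair for the site.
    """
    ref, usable, by_sample = _resolve_group(records, ref_conflict, duplicates)
    hom_ref = (ref, ref)
    alleles: list[tuple[str, str]] = [hom_ref] * len(roster)
    index = roster.index
    key = records[0].key
    for sample, rec in by_sample.items():
        try:
            i = index[sample]
        except KeyError:
            raise MergeConflictError(
                f"sample {sample!r} at {key.chrom}:{key.pos} is not in the roster"
            ) from None
        if rec.call.alleles is not None:
            try:
                alleles[i] = translate_alleles(rec.call, rec.ref, rec.alts)
            except MergeConflictError as exc:
                raise MergeConflictError(
                    f"at {key.chrom}:{key.pos}, sample {sample!r}: {exc}"
                ) from None
    return TpedRow(
        key, _merged_id(usable, f"{key.chrom}:{key.pos}"), tuple(alleles)
    )


def merge_site_vcf(
    records: Sequence[VcfRecord],
    roster: SampleRoster,
    *,
    ref_conflict: str = "error",
    duplicates: str = "error",
) -> MergedSite:
    """Aggregate one key's PASS records into a merged-VCF site.

    ALT and INFO are concatenated in first-seen order with duplicates
    removed; QUAL is the mean of non-missing qualities weighted by the
    number of individuals each record carries (1 for single-sample input);
    per-sample calls are remapped into the merged ALT index space; samples
    without a record are missing (``./.``).
    """
    ref, usable, by_sample = _resolve_group(records, ref_conflict, duplicates)
    key = records[0].key

    merged_alts: list[str] = []
    alt_seen: set[str] = set()
    merged_info: list[str] = []
    info_seen: set[str] = set()
    qual_sum = 0.0
    qual_weight = 0
    for rec in usable:
        for a in rec.alts:
            if a not in alt_seen:
                alt_seen.add(a)
                merged_alts.append(a)
        for tok in rec.info:
            if tok not in info_seen:
                info_seen.add(tok)
                merged_info.append(tok)
        if rec.qual is not None:
            qual_sum += rec.qual  # weight 1: one individual per input record
            qual_weight += 1
    qual = qual_sum / qual_weight if qual_weight else None

    calls: list[GenotypeCall] = [MISSING_CALL] * len(roster)
    index = roster.index
    for sample, rec in by_sample.items():
        try:
            i = index[sample]
        except KeyError:
            raise MergeConflictError(
                f"sample {sample!r} at {key.chrom}:{key.pos} is not in the roster"
            ) from None
        try:
            calls[i] = remap_allele_indices(rec.call, rec.ref, rec.alts, merged_alts)
        except MergeConflictError as exc:
            raise MergeConflictError(
                f"at {key.chrom}:{key.pos}, sample {sample!r}: {exc}"
            ) from None

    return MergedSite(
        key,
        _merged_id(usable, "."),
        ref,
        tuple(merged_alts),
        qual,
        "PASS",
        tuple(merged_info),
        tuple(calls),
    )
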