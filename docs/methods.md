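# Methods

## The operation

Merging `n` single-sample VCF files is a sorted full-outer join on the key
`(chromosome, position)`. The key order is fixed: chromosome rank in the
25-label sequence `1..22, X, Y, M` first, then 1-based position. Labels are
normalized on input (`chr` prefixes stripped, `MT -> M`); anything outside
the set is rejected rather than silently ordered, because a stable total
order across *every* engine and intermediate file is the property the whole
package is built on. Coordinates are 1-based inclusive; partition ranges
are half-open `[lo, hi)` on this order.

Per-record filtering keeps exactly the records with `FILTER == "PASS"`
(case-sensitive, exact; `.` is non-PASS). A location is kept iff at least
one record at that location passes — non-PASS records contribute nothing
and cannot veto a site. Per-site aggregation then follows the rules in the
README; the only genuinely open points were:

* **QUAL weights.** The weighted mean is weighted by the number of
  individuals a record carries, which is 1 for single-sample inputs, so the
  merged QUAL reduces to the plain mean of the contributing records'
  non-missing qualities. Records with QUAL `.` are excluded from numerator
  and denominator; if all contributors are missing, the merged QUAL is `.`.
  Semantic merging of INFO fields (e.g. summing `DP`) is out of scope; INFO
  entries are deduplicated as opaque tokens.
* **Deduplication order.** ALT and INFO keep first-seen order, where "seen"
  order is input-file order then record order within a file. This makes the
  output deterministic, but it also means every engine must carry the file
  ordinal alongside each record; ties at one key are always processed in
  ordinal order.
* **REF disagreement** between files at one position is a hard error by
  default (it indicates inputs called against different references); a
  `first` mode keeps the first-seen REF and drops disagreeing records with
  a warning.
* **Duplicate keys within one file** (split multi-allelic lines) are an
  error in strict mode; lenient mode keeps all lines for ALT/INFO/QUAL
  aggregation and takes the genotype from the first line carrying a
  non-reference call.
* **Variant id.** TPED needs a collision-free name, so it defaults to
  `chrom:pos` and preserves the input ID only when all contributors agree;
  merged VCF uses the VCF null `.` as the fallback instead.
* **Haploid calls** (`GT` = `1`) are doubled to a homozygous pair in TPED
  (the format is diploid) and written back verbatim in merged VCF.
* **Position anonymization** (`floor(pos * c_real) + c_int`) is provided as
  an explicit transform for privacy-preserving data release. It is monotone
  in the position for fixed constants, hence order-preserving; the
  constants are deliberately parameters with no defaults.

## Engines and their equivalence

All four engines produce byte-identical output; this is the central
invariant, enforced by construction and by test.

* Records travel as envelopes `(sort_key, file_ordinal, sequence, record)`.
  The triple `(sort_key, ordinal, seq)` is unique, so heap merges and sorts
  never compare record objects and every engine sees identical group
  contents in identical order.
* The **single** engine is a one-pass k-way merge (`heapq.merge`) over
  order-checked file streams, grouped by key.
* The **partitioned** engine scans each file once (one task per input
  file), writing per-chromosome sorted runs (gzip text, an internal
  versioned format) and drawing the first-round key sample; the second
  round subsamples at `1/n_files`, capping the expected boundary-sample
  size at `total_records * rate1 / n_files` independent of the file count.
  Phase 2 launches one logical job per *selected* chromosome — 25 when all
  are selected, regardless of which chromosomes carry data — routes records
  by binary search over the boundary list, sorts each partition, merges,
  and writes one shard per non-empty partition. Shards are concatenated by
  a single writer in (chromosome rank, partition index) order.
* The **tree** engine assigns contiguous, approximately equal file chunks
  to `p` workers (file order preserved, so global ordinals survive), merges
  locally, then runs the pairwise rounds of the `TreePlan`: in round
  `r >= 2` receivers are the workers divisible by `2^(r-1)` and senders sit
  `2^(r-2)` to their right; workers without a right neighbour carry their
  run forward, which extends the schedule to non-powers of two without
  changing the round count `1 + ceil(log2 p)`. The final pass re-groups
  worker 0's run and materializes the homozygous-reference / `./.` fill
  against the full roster — fill-in cannot happen earlier because a worker
  only knows its own samples.
* The **interval** engine computes per-chromosome `[min, max]` extents in a
  fast pre-scan, cuts the concatenated extent into `p` equal-coordinate
  spans, and runs a full multiway merge per interval with readers skipping
  records outside it (emulating an indexed region seek). Under skewed data
  the intervals are imbalanced — this is logged, never corrected, because
  correcting it would require the distribution scan the mode exists to
  avoid.

**Scheduling.** Workers are isolated tasks that communicate only through
files and returned summaries; any scheduler that finishes each phase before
the next starts is conformant. The built-in scheduler is a serial loop —
the worker count shapes the decomposition (partition cap `4 * workers`,
tree fan-in, interval count), not OS-level concurrency — which keeps the
engines trivially deterministic and portable; a process pool or MPI ranks
could be substituted behind the same task boundaries.

**Inputs** are expected coordinate-sorted per file (callers emit them that
way); disorder is detected and reported, and an opt-in `presort` loads and
stably sorts an offending file instead. Plain and gzip-compressed text are
read transparently (magic-byte sniff); block-compression indexes are
emulated by filtered scans, not required.

## Sampling and boundaries

First-round sampling is Bernoulli per key at rate `1e-4` by default
(overridable), with per-file child seeds `seed + file_ordinal` so parallel
scans are reproducible; the second round uses seeds derived from the
chromosome rank. Boundaries are evenly spaced order statistics: with `m`
sampled keys and `k = min(m + 1, max_partitions)` partitions, boundary `j`
is the sampled key of rank `ceil(j * m / k)` (1-based), duplicates
collapsed. The `ceil` convention reproduces the exact `{25, 50, 75}`
quantiles on a 1..99 sample with `k = 4`. The `max_partitions` cap
(default `4 * workers`) exists because the uncapped rule "partitions =
sample count + 1" creates pathological one-record partitions on small
inputs. The sampling seed moves boundaries only — never output content — 
and identical inputs and seed give byte-identical serialized plans.

A statistical note on balance: assigning `N` uniform records to `k` ranges
estimated from `m` sampled keys has per-range relative error on the order
of `sqrt(k/m)`, so a balance bound like max/mean <= 1.25 over 16 partitions
needs `m` in the low thousands; tests sample accordingly.

## The synthetic cohort generator

The generator emulates the shape of a per-subject variant-calling cohort:
chromosome choice weighted by physical chromosome length, positions drawn
without replacement per chromosome (no within-file duplicate keys unless
the duplicate-injection flag is set), a shared per-cohort position pool
giving partial overlap across samples (default 0.5), per-record FILTER
failures (`q10`, default 0.05), multi-allelic sites (default 0.10),
occasional missing QUAL (0.01), and genotypes drawn with fixed weights
recorded in the cohort manifest. REF/ALT at a position are a deterministic
hash of the coordinate, so samples never disagree on REF — as real callers
against one reference genome do not. The default desk scale, 20 samples x
50,000 variants, reproduces at roughly 1/1000 scale the shape of a cohort
of ~200 files with 4-5 million records each; generation is byte-reproducible
from the seed.

What the generator does **not** emulate: population-genetic allele
frequencies and LD structure, indel/symbolic alleles, genotype likelihoods,
unsorted or malformed inputs (exercised by hand-written fixtures instead),
and real chromosome-specific variant density. Passing tests therefore
demonstrate the correctness of the merge semantics and the equivalence of
the execution plans, not robustness to every artifact of production VCFs.

Ground truth is accumulated during generation by direct application of the
per-site rules and rendered through the same writers the engines use; the
independent check on the engines is the separate brute-force oracle in the
test suite (load everything into a map, filter, sort, aggregate).

## Numerical and formatting choices

QUAL means are computed in double precision and printed with `%g` (6
significant digits), which round-trips the one-decimal synthetic qualities
exactly; intermediate-run serialization uses `repr` for exact float
round-trips. TPED uses ASCII spaces, VCF tabs, `\n` line endings
everywhere. Wall-clock efficiency is `(T_b*C_b/N_b)/(T_i*C_i/N_i)`;
timing fields must be positive, and the metric is dimensionless.

## Problem sizes

The test suite and the acceptance script run cohorts from 2x30 up to the
default 20x50,000 (one million input records, ~525k merged rows), the scale
chosen for desk-speed reproducibility: the full equivalence matrix (ten
engine configurations, two formats) completes in a few minutes on one CPU.
Larger cohorts stress nothing new in the algorithms — every structure is
streaming or per-chromosome — but the generator and the pure-Python record
parsing scale linearly, so expect ~25-30 s per engine pass per million
records.

## Known limitations

* Only the `GT` FORMAT field is merged; PL/GL and other per-sample fields
  are out of scope.
* Multi-sample *inputs* are rejected by design (the tool produces them).
* Indel normalization / left-alignment is not performed; positions are
  compared as given.
* The QUAL weighting for multi-sample inputs and semantic INFO merging are
  documented gaps, not guesses.
* The serial scheduler means wall-clock speedups from `workers > 1` are not
  expected; the knob exists to exercise and test the decompositions.
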