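# vcfmerge

Sorted full-outer merging of many single-sample VCF files into one globally
sorted PLINK **TPED** (+TFAM) or multi-sample **VCF**, through four
interchangeable merge engines that produce byte-identical output.

## The problem

Whole-genome and whole-exome studies call variants per subject, leaving one
single-sample VCF per individual. Downstream association tools (PLINK and
friends) need one table in which every genomic location found in *any*
subject appears exactly once, in global coordinate order, with a value for
*every* subject — a sorted full-outer join on the key
`(chromosome, position)` with chromosomes ordered `1..22, X, Y, M`.

The merge applies a small set of rules:

* records whose `FILTER` is not exactly `PASS` are dropped;
* genotype allele indices (`0` = REF, `k >= 1` = k-th ALT) are translated to
  nucleotides for TPED output;
* a subject with no record at a kept location receives the homozygous
  reference pair (TPED) or a missing call `./.` (merged VCF);
* for merged VCF, ALT and INFO are the concatenation over inputs in
  first-seen order with duplicates removed, QUAL is the weighted mean of the
  contributing records' qualities, and each genotype is re-indexed into the
  merged ALT list (multi-allelic sites keep all alleles until the merge
  happens).

## The engines

All four engines implement the same join; they differ in how the work is
decomposed, and they must — and do — produce identical bytes:

| engine        | strategy |
|---------------|----------|
| `single`      | one-pass k-way multiway merge of all inputs through a priority queue |
| `partitioned` | two-phase divide and conquer: per-file scan + chromosome binning with two-round Bernoulli key sampling (rate 1e-4, then `1/n_files`) to compute balanced range-partition boundaries, then one merge job per chromosome (25 when all are selected), each routing records into half-open key ranges |
| `tree`        | task-parallel log-round schedule: every worker multiway-merges its share of the files, then pairwise merges (`1 + ceil(log2 p)` rounds) funnel everything to worker 0 |
| `interval`    | data-parallel: the concatenated genomic extent is cut into `p` equal-coordinate-span intervals (uniform-position assumption) and each worker merges its interval only |

The partitioned engine's boundary estimation is the load-balancing core:
with `m` sampled keys on a chromosome, boundary `j` of `k` partitions is the
sampled key of rank `ceil(j*m/k)`, so every range holds an approximately
equal share of the records. A `region_count(n) = max(1, n // 2)` helper
exposes the same pre-split heuristic used when bulk-loading a sorted
key-value store, and `interval_split` the uniform splitting of the
data-parallel mode.

Scalability is quantified by the per-core, per-file efficiency

```
Efficiency = (T_b * C_b / N_b) / (T_i * C_i / N_i)
```

(T wall seconds, C cores, N files; subscript `b` = baseline run), available
as `vcfmerge.compute_efficiency` and through the `bench` subcommand.

## Worked example

```bash
vcfmerge generate --out-dir toy --worked-example
vcfmerge merge --engine single --out-format tped -o merged toy/NA001.vcf toy/NA002.vcf toy/NA003.vcf
cat merged.tped
```

prints

```
1 1:10123 0 10123 A G G G A A
1 1:10234 0 10234 A C A A C C
1 1:10501 0 10501 G T C T C C
X X:500 0 500 T T T T A A
```

Reading the output: each row is one variant — chromosome, variant id
(`chrom:pos` unless all inputs agree on a name), the unused genetic
distance `0`, position, then two nucleotide columns per sample in input
order (NA001, NA002, NA003). Position `1:10147` existed in NA002 but its
`FILTER` was `q10`, so it is gone. At `1:10234` NA002 has no record and
shows the homozygous reference pair `A A`. At the multi-allelic site
`1:10501`, NA001's `1/2` call becomes `G T` while NA003, absent there, is
filled with `C C` (the site's REF). The same merge with
`--out-format vcf` writes one multi-sample VCF record per row, e.g. ALT
`G,T` at `1:10501` with NA002's local ALT `T` re-indexed to `0/2`, and
QUAL `40` (the mean of 60 and 20).

A synthetic cohort of any size can be generated with
`vcfmerge generate --out-dir cohort --samples 20 --variants 50000 --seed 7`;
`vcfmerge validate out.tped` checks global order and row width, and
`vcfmerge bench` times an engine/worker grid and prints the efficiency
table.

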