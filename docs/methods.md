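# Methods

## Model and procedure

`polyssr` treats cross-sample SSR length variation as directly observable in
de novo transcriptome assemblies. The underlying assumptions are:

* transcripts assembled independently from different samples of one species
  preserve the sequence flanking an SSR run exactly (no assembly error or
  allelic substitution within *k* bases of the run);
* repeat-count differences between samples at the same locus reflect length
  polymorphism rather than assembly artifacts;
* exact flank identity is specific enough that two different genomic loci
  essentially never share the same `left-flank + motif + right-flank` key.

Under these assumptions the pipeline is: per-transcript detection of maximal
repeat runs, flank-keyed aggregation of repeat counts over the merged
multi-sample dataset, a polymorphism flag for keys with ≥ 2 distinct counts,
and window extraction/verification for the candidates a user selects.

### Detection

A run of a primitive motif `m` (length 1–6) is *maximal* when its period can
be extended by neither a full copy nor a single base on the left, and full
copies are counted greedily to the right; a trailing partial copy belongs to
the flank, so the repeat number is always an integer. This convention makes
the repeat number usable as the "value" under the locus key. Primitivity
(`m` not a power of a shorter unit) plus maximality prevent double-counting
(a poly-A run is never also reported as an `AA` dimer run). Interrupted
repeats are reported as separate runs, each thresholded independently —
the method deliberately makes no perfect/imperfect distinction and relies on
thresholds alone. `N` terminates extension; runs containing `N` are never
reported. Overlapping runs of different unit lengths that each pass their
threshold are all reported; for the (theoretically unreachable, defensively
handled) case of two primitive units spanning an identical interval, the
shorter unit wins.

Canonical motif classes quotient a motif by cyclic rotation and reverse
complementation: the label `X/Y` uses the lexicographically smallest
rotation of each strand, smaller first, so `TA`, `AT` and their reverse
complements all tally as `AT/AT`.

### Aggregation

Keys are exact, case-normalized strings; matching is a single hash lookup,
so aggregation is one streaming pass with a key → record table (the dataset
never needs to fit in memory, only the records). Observation lists are
sorted by (transcript id, position) at finalization, which makes the result
independent of input record order without materializing the dataset.
Occurrences, not samples, are counted: two hits in one transcript contribute
two observations, matching the reports' "sum of all SSRs in the locus"
column. Reverse-complement key merging exists behind a flag but is off by
default: exact same-strand matching is the documented behavior, and the
mutation-splitting caveat below applies verbatim only then.

A consequence of exact matching, asserted in the tests as expected behavior:
one substitution inside a key flank of one sample splits the locus into two
records, and neither may reach the ≥ 2 distinct-counts bar. This is the
method's main source of false negatives.

### Report files

Both report files are three tab-separated columns: key string, observation
count, comma-separated repeat counts. The key is stored only as its
concatenated string form (flank boundaries are recoverable given *k*, since
`motif = key[k:-k]`); the reader therefore returns rows, not structured
keys, and round-trip losslessness means read→write byte-identity. Rows are
sorted by key string, so identical inputs give byte-identical reports.

### Extraction and verification

Windows expand symmetrically from the run until each side has ≥ 50 bases,
then grow one base per side (alternating, left first; an exhausted side
stops) toward the 300-base cap. A locus fails extraction when any sample's
transcript cannot supply 50 bases per side within a 300-base window — 100
and 300 bp being the usual amplicon bounds for fragment-analysis primer
design. Consistency comparison aligns left contexts at the run start
(compared right-to-left) and right contexts at the run end, comparing only
offsets covered by both windows and excluding the run itself: a repeat-count
difference is the signal being mined, never an inconsistency. Repeat counts
found at relocation time may differ from the aggregated record (the
transcript set may have changed); they are reported, not errored.

### Marker statistics

Allele frequencies are counted over the 2N gene copies of the genotyped
diploid individuals; an individual with a single detected fragment length is
treated as homozygous, the standard fragment-analysis convention. PIC uses
the Botstein form, computed as `1 − S₂ − (S₂² − S₄)` with `S₂ = Σp²`,
`S₄ = Σp⁴` (algebraically equal to the double sum, O(Na)); tests pin it to
an independent double-loop evaluation at 1e−12. Frequencies must sum to 1
within 1e−9. Informativeness categories use strict `>` at 0.25 and 0.5;
boundary values are vanishingly unlikely with empirical frequencies, but the
convention must be fixed. Reported statistics are formatted at 4 decimals.

## Parameters

| parameter | default | meaning |
|---|---|---|
| min repeats (mono…hexa) | 10, 6, 5, 5, 5, 5 | MISA-style detection thresholds, full copies |
| flank length *k* | 10 | bases per side forming the locus key; below ~8 the key loses specificity, larger *k* trades sensitivity (more skipped hits near transcript ends, more mutation splitting) for specificity |
| min_obs | 1 (off) | optional floor on observations per record; useful when many samples make singleton keys suspect |
| window | 100–300 bp, ≥ 50 bp/side | amplicon geometry for primer design |
| PIC categories | > 0.25, > 0.5 | conventional informativeness bands |

## Synthetic data

The transcript generator plants each locus as one transcript per sample:
`left flank + motif×reps + right flank`, flanks drawn once per locus and
reused verbatim across samples. Rejection sampling enforces the truth-table
guarantee: flanks are redrawn until the detector, run on each sample's
planted transcript, reports exactly the planted run — this simultaneously
excludes flank-internal SSRs and junction artifacts (a left flank ending in
the motif's last base would shift the detected run and rotate its motif,
changing the key; a right flank beginning with the motif's first base could
donate copies). Background transcripts are i.i.d. uniform ACGT, redrawn
until SSR-free and free of any planted key flank, so background contributes
zero records and flank keys are globally unique. Defaults — 6 samples, 20
loci (12 variable, 8 constant; every fourth locus given 30-base context and
hence not amplifiable), 15 background transcripts of 300–1200 bp per
sample — form the standard planted-study design used throughout the tests;
six samples because fewer than about six give too few repeat-count
observations for a meaningful polymorphism call.

What the generator does **not** emulate: assembly errors and chimeras,
allelic flank substitutions (except when tests introduce them explicitly),
imperfect/compound repeats, transcript fragmentation, paralogous loci with
near-identical flanks, and coverage-dependent transcript dropout. Passing
the planted-recovery tests therefore shows the bookkeeping is exact under
the model's assumptions, not that real assemblies satisfy those assumptions.

The genotype generator draws independent diploid genotypes from stated
allele-frequency vectors (Hardy–Weinberg sampling) with per-locus missing
individuals at a fixed rate; it does not model null alleles, stutter, or
allele-calling error.

## Numerical and design choices

* Coordinates are 0-based half-open internally; human-readable reports are
  1-based inclusive.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical FASTA and report files.
* Ranking of candidates: distinct repeat-count values desc, then
  observations desc, then key string asc — fully deterministic.
* Key string form is `left + motif + right`; the concatenation order is an
  implementation convention.
* Rejection sampling in the generator is bounded (200 tries) and raises
  rather than loops on infeasible constraints.
* Test problem sizes: the detector/oracle equivalence suite uses 1,000
  random 2-kb sequences; planted-recovery uses the 6-sample/20-locus
  design; frequency-recovery simulations use 500–2,000 individuals —
  scales at which binomial sampling error is tight enough for 4-decimal
  assertions to be meaningful where used.

## Known limitations

* Exact-match keys miss loci whose flanks carry any cross-sample variation;
  no inexact (similarity-based) clustering is attempted.
* Transcripts assembled on opposite strands appear as two loci unless
  `merge_revcomp` is enabled.
* Mononucleotide candidates are enriched for assembly/sequencing artifacts
  in real data; the pipeline reports them and leaves filtering to the user.
* No compound-SSR annotation, primer design, or population-structure
  statistics beyond the four validation columns.
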