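# polyssr

Mining **potentially polymorphic microsatellite (SSR) loci** directly from
multiple de novo-assembled transcriptomes, plus the marker statistics used
to validate them after genotyping.

## The problem

Microsatellites (simple sequence repeats, SSRs) are tandem repeats of 1–6 bp
DNA motifs whose copy number mutates rapidly, making them popular codominant
markers for population genetics. Developing *polymorphic* SSR markers for a
species without a reference genome is traditionally expensive: loci mined
from a single transcriptome assembly carry no polymorphism information, so
most candidates fail in the lab.

When **several** transcriptome assemblies of the same species are available,
polymorphism can be read directly from the data: transcripts from the same
SSR-bearing gene share conserved flanking sequence around the repeat run,
while the run's copy number may differ between samples. `polyssr` exploits
this:

1. **Detect** — find every maximal tandem-repeat run of a primitive 1–6 bp
   motif meeting MISA-style minimum-repeat thresholds (defaults: mono ≥ 10,
   di ≥ 6, tri/tetra/penta/hexa ≥ 5 copies). Motifs are classified into
   canonical rotation/strand classes (`AT/AT`, `AG/CT`, `AAT/ATT`, …).
2. **Aggregate** — key each run by its *k*-base flanks plus motif unit
   (default *k* = 10) and collect repeat counts under identical keys across
   the merged dataset. A locus whose key accumulates ≥ 2 distinct repeat
   counts is flagged *potentially polymorphic*. Two three-column reports are
   written: all loci (`FindStr.result.detail`) and the polymorphic subset
   (`FindStr.result`), each row `key ⟶ n_obs ⟶ repeat,counts`.
3. **Extract & verify** — relocate selected keys in the transcripts, cut
   100–300 bp candidate windows with ≥ 50 bp of context per side (the
   geometry primer design needs), and check that all samples agree on the
   sequence context around the run — repeat-count differences are the
   signal, context substitutions are not.
4. **Marker statistics** — from fragment-length genotype tables compute, per
   locus, N (individuals genotyped), Na (allele count), F_M (major-allele
   frequency) and the polymorphism information content

   PIC = 1 − Σᵢ pᵢ² − Σᵢ Σ_{j>i} 2 pᵢ² pⱼ²

   (Botstein et al. 1980), with dataset summaries and the conventional
   informativeness categories (PIC > 0.5 highly informative, 0.25–0.5
   reasonably informative).

A seeded synthetic-data generator produces multi-sample transcript sets with
planted loci and a truth table, and diploid genotype tables drawn from
stated allele-frequency vectors, so the whole pipeline is testable without
any external download.

## Worked example

```bash
python examples/mine_polymorphic_loci.py
```

```
samples: 6   transcripts in merged set: 210
loci found: 20   potentially polymorphic: 12

rank  key (flank+motif+flank, truncated)  n_obs  repeat counts
   1  CAGCGCTATAAAACGCCAGAGGTG                 6  9,7,6,10,8,10
   2  TCTCGGTCCAAGCTATGACGCA                   6  8,11,9,8,10,12
   ...
```

Six synthetic samples were scanned as one merged dataset; 20 flank-keyed
loci were found and exactly the 12 planted variable-repeat loci are flagged
polymorphic. Each row is one candidate: the flank+motif key shared by all
six samples and the six observed repeat counts — rank 1 shows five distinct
copy numbers (6–10), the strongest length-polymorphism signal.

`examples/extract_candidates.py` continues to window extraction and
verification, and `examples/marker_statistics.py` computes a genotyping
validation table:

```
    Locus       N     Na     FM    PIC
biallelic      19      2 0.5263 0.3743
     mono      18      1 1.0000 0.0000
    multi      14      5 0.3929 0.6836
     Mean 17.0000 2.6667 0.6397 0.3526
```

The monomorphic locus has PIC exactly 0; the five-allele locus is highly
informative (PIC > 0.5).

The same pipeline is scriptable from the shell:

```bash
polyssr simulate --out-dir sim --seed 42
polyssr scan --input sim/merged.fasta --flank-len 10 --out-dir out
polyssr extract --input sim/merged.fasta --result out/FindStr.result --out-dir out
polyssr stats --table genotypes.tsv
```

## Limitations

Key matching is exact string identity: a substitution in one sample's flank
splits a locus into two records, so some true polymorphic loci are missed.
Detection is threshold-only and does not distinguish perfect from imperfect
repeats; interrupted runs appear as separate loci. With fewer than about six
samples the repeat-count lists are too short for a meaningful polymorphism
call. See `docs/methods.md` for the full model description and design
choices.
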