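"""Synthetic multi-sample transcript sets and genotype tables with known truth.

The transcript generator emulates the situation the flank-keyed mining
method exploits: several independently assembled transcriptomes of one
organism each carry a transcript from the same SSR-bearing gene, with
conserved flanking sequence around a repeat run whose copy number
varies between samples. Planted loci are embedded in random
non-repetitive background transcripts, and the generator guarantees by
rejection sampling that

* each planted transcript yields exactly the planted run (and nothing
  else) under default detection thresholds — flanks can neither extend
  the run nor contain runs of their own;
* background transcripts contain no detectable SSR at all;
* no background transcript contains any planted locus's key flanks,
  so flank keys are unique and the pipeline's polymorphic-locus set
  can be compared against the truth table exactly.

The genotype generator draws independent diploid genotypes from stated
allele-frequency vectors, with per-locus missing individuals, emulating
fragment-length genotyping exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import Thresholds, find_ssrs
from .io import write_fasta
from .markers import GenotypeTable

__all__ = [
    "PlantedLocusSpec",
    "TruthRow",
    "TranscriptSet",
    "default_locus_specs",
    "make_transcript_set",
    "make_genotype_table",
    "write_transcript_set",
]

_BASES = np.array(list("ACGT"))
_MAX_TRIES = 200

#: fewer than about six samples give too few repeat-count observations
#: per locus for a meaningful polymorphism call
DEFAULT_N_SAMPLES = 6


@dataclass(frozen=True)
class PlantedLocusSpec:
    """Blueprint of one planted locus.

    ``repeats_per_sample`` gives the repeat count planted in each
    sample (list indexed by sample); every count must meet the
    detection threshold for the motif's unit length. ``flank_len`` is
    the conserved context generated once and reused verbatim in every
    sample; at least 50 makes the locus amplifiable (extraction-ready).
    """

    locus_id: str
    motif: str
    repeats_per_sample: tuple[int, ...]
    flank_len: int

    @property
    def polymorphic(self) -> bool:
        return len(set(self.repeats_per_sample)) >= 2


@dataclass(frozen=True)
class TruthRow:
    locus_id: str
    key_string: str
    left_flank: str
    motif: str
    right_flank: str
    repeats_per_sample: tuple[int, ...]
    polymorphic: bool
    amplifiable: bool


@dataclass
class TranscriptSet:
    """Generated per-sample transcript records plus the ground truth."""

    samples: dict[str, list[tuple[str, str]]]
    truth: list[TruthRow] = field(default_factory=list)

    def merged(self) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for name in sorted(self.samples):
            out.extend(self.samples[name])
        return out

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {row.locus_id: row for row in self.truth}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _clean_flanks(
    rng: np.random.Generator,
    spec: PlantedLocusSpec,
    thresholds: Thresholds,
) -> tuple[str, str]:
    """Draw flanks until every sample's transcript detects exactly the
    planted run. Junction-safety (no extension of the run into a flank)
    and flank-internal repeat freedom are both enforced by running the
    detector on the worst-case assembled transcripts."""
    check_reps = sorted(set(spec.repeats_per_sample))
    for _ in range(_MAX_TRIES):
        left = _random_dna(rng, spec.flank_len)
        right = _random_dna(rng, spec.flank_len)
        if left[-1] == spec.motif[-1] or right[0] == spec.motif[0]:
            continue  # run could extend into a flank, shifting the key
        ok = True
        for reps in check_reps:
            transcript = left + spec.motif * reps + right
            hits = find_ssrs(transcript, spec.locus_id, thresholds)
            if not (
                len(hits) == 1
                and hits[0].motif == spec.motif
                and hits[0].repeats == reps
                and hits[0].start == spec.flank_len
            ):
                ok = False
                break
        if ok:
            return left, right
    raise RuntimeError(
        f"could not generate clean flanks for locus {spec.locus_id} "
        f"after {_MAX_TRIES} tries"
    )


def _background_transcript(
    rng: np.random.Generator,
    length: int,
    thresholds: Thresholds,
    forbidden: list[str],
) -> str:
    """Random transcript with no detectable SSR and none of the
    *forbidden* substrings (planted key flanks)."""
    for _ in range(_MAX_TRIES):
        seq = _random_dna(rng, length)
        if find_ssrs(seq, "", thresholds):
            continue
        if any(f in seq for f in forbidden):
            continue
        return seq
    raise RuntimeError(
        f"could not generate SSR-free background of length {length} "
        f"after {_MAX_TRIES} tries"
    )


def default_locus_specs(
    n_samples: int = DEFAULT_N_SAMPLES,
    n_variable: int = 12,
    n_constant: int = 8,
    seed: int = 0,
) -> list[PlantedLocusSpec]:
    """The standard planted-study design: 20 loci over 6 samples.

    Twelve loci vary in repeat count across samples and eight are
    constant; a quarter of the loci (every fourth) get short 30-base
    context and are therefore not amplifiable, the rest get 60 bases.
    Motifs cycle through common di-/tri-/tetranucleotide units plus a
    poly-A; repeat counts sit a few copies above threshold, as typical
    of transcriptome SSRs.
    """
    rng = np.random.default_rng(seed)
    motifs = ["AT", "AG", "AC", "AAT", "AGC", "ACT", "AAG", "AAAC", "A", "CT"]
    base_reps = {1: 12, 2: 8, 3: 6, 4: 6, 5: 6, 6: 6}
    specs: list[PlantedLocusSpec] = []
    for i in range(n_variable + n_constant):
        motif = motifs[i % len(motifs)]
        base = base_reps[len(motif)]
        variable = i < n_variable
        if variable:
            while True:
                reps = tuple(
                    int(base + rng.integers(0, 5)) for _ in range(n_samples)
                )
                if len(set(reps)) >= 2:
                    break
        else:
            reps = (int(base + rng.integers(0, 3)),) * n_samples
        flank_len = 30 if i % 4 == 3 else 60
        specs.append(
            PlantedLocusSpec(
                locus_id=f"locus{i + 1:03d}",
                motif=motif,
                repeats_per_sample=reps,
                flank_len=flank_len,
            )
        )
    return specs


def make_transcript_set(
    specs: list[PlantedLocusSpec] | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_background: int = 15,
    background_length: tuple[int, int] = (300, 1200),
    seed: int = 0,
    key_k: int = 10,
    thresholds: Thresholds | None = None,
) -> TranscriptSet:
    """Generate per-sample transcript sets with planted SSR loci.

    Deterministic given *seed*. Each planted locus becomes one
    transcript per sample (conserved flanks, per-sample repeat count);
    *n_background* SSR-free random transcripts per sample are added and
    the per-sample record order is shuffled. The returned truth table
    records each locus's flank key (at flank length *key_k*), planted
    repeat counts, polymorphism flag and amplifiability flag.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if specs is None:
        specs = default_locus_specs(n_samples=n_samples, seed=seed)
    rng = np.random.default_rng(seed)

    for spec in specs:
        if len(spec.repeats_per_sample) != n_samples:
            raise ValueError(
                f"{spec.locus_id}: {len(spec.repeats_per_sample)} repeat "
                f"counts for {n_samples} samples"
            )
        if min(spec.repeats_per_sample) < thresholds[len(spec.motif)]:
            raise ValueError(
                f"{spec.locus_id}: planted repeat count below detection "
                f"threshold for unit length {len(spec.motif)}"
            )
        if spec.flank_len < key_k:
            raise ValueError(
                f"{spec.locus_id}: flank_len {spec.flank_len} < key flank "
                f"length {key_k}"
            )

    truth: list[TruthRow] = []
    planted: dict[str, tuple[str, str]] = {}
    forbidden: list[str] = []
    for spec in specs:
        left, right = _clean_flanks(rng, spec, thresholds)
        planted[spec.locus_id] = (left, right)
        forbidden.extend([left[-key_k:], right[:key_k]])
        min_run = min(spec.repeats_per_sample) * len(spec.motif)
        truth.append(
            TruthRow(
                locus_id=spec.locus_id,
                key_string=left[-key_k:] + spec.motif + right[:key_k],
                left_flank=left,
                motif=spec.motif,
                right_flank=right,
                repeats_per_sample=spec.repeats_per_sample,
                polymorphic=spec.polymorphic,
                amplifiable=spec.flank_len >= 50 and min_run + 100 <= 300,
            )
        )

    samples: dict[str, list[tuple[str, str]]] = {}
    for s in range(n_samples):
        sample_name = f"sample{s + 1}"
        records: list[tuple[str, str]] = []
        for spec in specs:
            left, right = planted[spec.locus_id]
            seq = left + spec.motif * spec.repeats_per_sample[s] + right
            records.append((f"{sample_name}_{spec.locus_id}", seq))
        for b in range(n_background):
            length = int(rng.integers(background_length[0], background_length[1] + 1))
            seq = _background_transcript(rng, length, thresholds, forbidden)
            records.append((f"{sample_name}_bg{b + 1:03d}", seq))
        order = rng.permutation(len(records))
        samples[sample_name] = [records[i] for i in order]

    return TranscriptSet(samples=samples, truth=truth)


def write_transcript_set(
    tset: TranscriptSet, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-sample FASTAs, a merged FASTA and the truth TSV.

    Returns a mapping of logical names ('sample1', ..., 'merged',
    'truth') to the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in sorted(tset.samples):
        p = out / f"{name}.fasta"
        write_fasta(tset.samples[name], p)
        paths[name] = p
    merged = out / "merged.fasta"
    write_fasta(tset.merged(), merged)
    paths["merged"] = merged

    truth_path = out / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write(
            "locus_id\tkey\tmotif\trepeats_per_sample\tpolymorphic\tamplifiable\n"
        )
        for row in tset.truth:
            reps = ",".join(str(r) for r in row.repeats_per_sample)
            fh.write(
                f"{row.locus_id}\t{row.key_string}\t{row.motif}\t{reps}\t"
                f"{int(row.polymorphic)}\t{int(row.amplifiable)}\n"
            )
    paths["truth"] = truth_path
    return paths


def make_genotype_table(
    allele_freqs: dict[str, dict[int, float]],
    n_individuals: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, dict[str, dict[int, float]]]:
    """Draw a diploid genotype table from stated allele frequencies.

    Individuals are independent; each contributes two allele copies per
    locus drawn from that locus's frequency vector, and is dropped at a
    locus with probability *missing_rate* (emulating failed
    genotyping). Returns the table together with the true frequencies
    (echoed for truth-table style use).
    """
    rng = np.random.default_rng(seed)
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for locus_id in sorted(allele_freqs):
        freqs = allele_freqs[locus_id]
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{locus_id}: frequencies sum to {p.sum()}, not 1")
        for i in range(n_individuals):
            if rng.random() < missing_rate:
                continue
            pair = rng.choice(alleles, size=2, p=p)
            calls[(locus_id, f"ind{i + 1:04d}")] = (int(pair[0]), int(pair[1]))
    return GenotypeTable(calls=calls), allele_freqs
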