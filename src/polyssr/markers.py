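"""Marker polymorphism statistics from fragment-length genotype tables.

Implements the per-locus statistics used to validate candidate SSR
markers after fragment-analysis genotyping: N (individuals successfully
genotyped), Na (number of distinct alleles), FM (major allele
frequency) and PIC, the polymorphism information content of Botstein
et al. (1980),

    PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2,

where p are allele frequencies counted over the 2N gene copies of the
genotyped diploid individuals. PIC is 0 for a monomorphic locus; values
above 0.5 are conventionally called highly informative and 0.25-0.5
reasonably informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "LocusStats",
    "DatasetSummary",
    "allele_frequencies",
    "pic",
    "locus_stats",
    "summarize",
    "pic_category_breakdown",
    "read_genotype_table",
    "write_genotype_table",
    "stats_table",
]

#: conventional informativeness thresholds for PIC
REASONABLY_INFORMATIVE = 0.25
HIGHLY_INFORMATIVE = 0.5


@dataclass
class GenotypeTable:
    """Diploid fragment-length allele calls per locus and individual.

    ``calls`` maps (locus_id, individual_id) to an allele pair — two
    positive fragment lengths, the same value twice for a homozygote.
    Individuals whose genotyping failed at a locus are simply absent.
    """

    calls: dict[tuple[str, str], tuple[int, int]]

    def loci(self) -> list[str]:
        return sorted({loc for loc, _ in self.calls})

    def genotypes_at(self, locus_id: str) -> dict[str, tuple[int, int]]:
        return {
            ind: pair for (loc, ind), pair in self.calls.items() if loc == locus_id
        }

    def __post_init__(self) -> None:
        for (loc, ind), pair in self.calls.items():
            if len(pair) != 2 or any(
                not isinstance(a, (int, np.integer)) or a <= 0 for a in pair
            ):
                raise ValueError(
                    f"locus {loc}, individual {ind}: allele pair must be two "
                    f"positive integer lengths, got {pair!r}"
                )


@dataclass(frozen=True)
class LocusStats:
    """Per-locus marker statistics (the standard validation columns)."""

    locus_id: str
    N: int
    Na: int
    FM: float
    PIC: float


@dataclass(frozen=True)
class DatasetSummary:
    mean_N: float
    mean_Na: float
    mean_FM: float
    mean_PIC: float
    n_loci: int
    n_monomorphic: int
    pct_polymorphic: float
    n_pic_gt_025: int
    n_pic_gt_05: int


def allele_frequencies(table: GenotypeTable, locus_id: str) -> dict[int, float]:
    """Allele frequencies at a locus from diploid gene counting.

    Each genotyped individual contributes two gene copies; frequencies
    are copy counts over 2N. Raises ValueError when no individual was
    genotyped at the locus.
    """
    genotypes = table.genotypes_at(locus_id)
    if not genotypes:
        raise ValueError(f"no data at locus {locus_id!r}")
    counts: dict[int, int] = {}
    for a1, a2 in genotypes.values():
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
    total = 2 * len(genotypes)
    return {allele: c / total for allele, c in sorted(counts.items())}


def pic(p: Mapping[int, float] | Iterable[float]) -> float:
    """Polymorphism information content of an allele-frequency vector.

    Accepts a mapping allele->frequency or a bare frequency iterable.
    Frequencies must be positive and sum to 1 (tolerance 1e-9).
    """
    freqs = np.asarray(
        list(p.values()) if isinstance(p, Mapping) else list(p), dtype=float
    )
    if freqs.size == 0 or (freqs <= 0).any():
        raise ValueError("all allele frequencies must be > 0")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {freqs.sum()!r}, not 1")
    sq = freqs**2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = sq.sum() ** 2 - (sq**2).sum()
    return float(1.0 - sq.sum() - cross)


def locus_stats(table: GenotypeTable, locus_id: str) -> LocusStats:
    """N, Na, major-allele frequency and PIC for one locus."""
    p = allele_frequencies(table, locus_id)
    return LocusStats(
        locus_id=locus_id,
        N=len(table.genotypes_at(locus_id)),
        Na=len(p),
        FM=max(p.values()),
        PIC=pic(p),
    )


def summarize(
    stats: Iterable[LocusStats],
    thresholds: tuple[float, float] = (REASONABLY_INFORMATIVE, HIGHLY_INFORMATIVE),
) -> DatasetSummary:
    """Dataset-level summary: arithmetic means plus category counts.

    A locus is monomorphic when Na == 1; the informativeness counts use
    strict "exceeds" comparisons against *thresholds*.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("no loci to summarize")
    lo, hi = thresholds
    n_mono = sum(1 for s in stats if s.Na == 1)
    n = len(stats)
    return DatasetSummary(
        mean_N=float(np.mean([s.N for s in stats])),
        mean_Na=float(np.mean([s.Na for s in stats])),
        mean_FM=float(np.mean([s.FM for s in stats])),
        mean_PIC=float(np.mean([s.PIC for s in stats])),
        n_loci=n,
        n_monomorphic=n_mono,
        pct_polymorphic=100.0 * (n - n_mono) / n,
        n_pic_gt_025=sum(1 for s in stats if s.PIC > lo),
        n_pic_gt_05=sum(1 for s in stats if s.PIC > hi),
    )


def pic_category_breakdown(
    stats: Iterable[LocusStats],
    motif_class_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-motif-class percentages of loci in three PIC bands.

    Bands are [0, 0.25], (0.25, 0.5] and (0.5, 1); per-class
    percentages sum to 100. Classes with no annotated locus are absent
    from the output. *motif_class_of* maps locus_id to its canonical
    motif class label (e.g. ``"AT/AT"``).
    """
    rows = []
    for s in stats:
        cls = motif_class_of.get(s.locus_id)
        if cls is None:
            raise ValueError(f"locus {s.locus_id!r} has no motif class annotation")
        if s.PIC <= REASONABLY_INFORMATIVE:
            band = "0-0.25"
        elif s.PIC <= HIGHLY_INFORMATIVE:
            band = "0.25-0.5"
        else:
            band = "0.5-1"
        rows.append({"motif_class": cls, "band": band})
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["motif_class", "band"]).size().unstack(fill_value=0)
    ).reindex(columns=["0-0.25", "0.25-0.5", "0.5-1"], fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def read_genotype_table(path: str | Path, sep: str = "\t") -> GenotypeTable:
    """Read a genotype table: locus_id, individual_id, allele1, allele2.

    Rows with both allele fields empty are failed genotypings and are
    dropped. Pass ``sep=','`` for CSV input. A malformed row raises
    ValueError naming the line.
    """
    df = pd.read_csv(
        path, sep=sep, header=None,
        names=["locus_id", "individual_id", "allele1", "allele2"],
        dtype={"locus_id": str, "individual_id": str},
        skip_blank_lines=True,
    )
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for i, row in df.iterrows():
        a1, a2 = row["allele1"], row["allele2"]
        if pd.isna(a1) and pd.isna(a2):
            continue
        if pd.isna(a1) or pd.isna(a2):
            raise ValueError(
                f"{path}: line {i + 1}: exactly one allele missing "
                f"(an individual contributes 0 or 2 allele copies)"
            )
        try:
            pair = (int(a1), int(a2))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 1}: {exc}") from exc
        calls[(row["locus_id"], row["individual_id"])] = pair
    return GenotypeTable(calls=calls)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table in the tab-delimited four-column layout."""
    with open(path, "w", encoding="utf-8") as fh:
        for (loc, ind), (a1, a2) in sorted(table.calls.items()):
            fh.write(f"{loc}\t{ind}\t{a1}\t{a2}\n")


def stats_table(stats: Iterable[LocusStats]) -> pd.DataFrame:
    """Per-locus rows plus a Mean row, floats at 4 decimals.

    Mirrors the conventional marker-validation table layout
    (Locus, N, Na, FM, PIC).
    """
    stats = list(stats)
    summary = summarize(stats)
    rows = [
        {"Locus": s.locus_id, "N": s.N, "Na": s.Na,
         "FM": f"{s.FM:.4f}", "PIC": f"{s.PIC:.4f}"}
        for s in stats
    ]
    rows.append(
        {"Locus": "Mean", "N": f"{summary.mean_N:.4f}",
         "Na": f"{summary.mean_Na:.4f}", "FM": f"{summary.mean_FM:.4f}",
         "PIC": f"{summary.mean_PIC:.4f}"}
    )
    return pd.DataFrame(rows, columns=["Locus", "N", "Na", "FM", "PIC"])
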