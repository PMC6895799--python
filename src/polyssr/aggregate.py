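"""Cross-sample aggregation of SSR runs into flank-keyed loci.

Each detected run is keyed by the exact k-base flanking sequences on
either side of it together with its motif unit. Identical keys observed
in different transcripts (typically from different per-sample
assemblies merged into one dataset) are treated as one putative locus;
the multiset of repeat numbers collected under a key is the locus's
polymorphism signal: two or more distinct repeat counts flag the locus
as potentially polymorphic.

Key matching is exact case-normalized string identity. A single flank
mutation therefore splits a locus into two records — an accepted
limitation of flank-keyed matching. An optional flag merges each key
with the reverse complement of its string form, for transcripts
assembled on opposite strands.

Two tab-delimited report files are produced: a *detail* file with every
locus and a *result* file restricted to the potentially polymorphic
ones. Both share the three-column schema
``key_sequence <TAB> n_obs <TAB> repeats,comma,separated``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .detect import SSRHit, Thresholds, find_ssrs, revcomp

__all__ = [
    "LocusKey",
    "LocusRecord",
    "ReportRow",
    "build_locus_key",
    "aggregate",
    "aggregate_sequences",
    "rank_candidates",
    "write_reports",
    "read_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusKey:
    """Identity of a putative SSR locus: left flank + motif + right flank."""

    left_flank: str
    motif: str
    right_flank: str

    @property
    def string_form(self) -> str:
        return self.left_flank + self.motif + self.right_flank

    @property
    def k(self) -> int:
        return len(self.left_flank)


@dataclass
class LocusRecord:
    """All repeat-count observations aggregated under one locus key."""

    key: LocusKey
    observations: list[tuple[str, int]] = field(default_factory=list)
    # (seq_id, start) per observation, parallel to `observations`; used
    # only to give the final record a dataset-order-independent sort
    _positions: list[tuple[str, int]] = field(default_factory=list, repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def repeats(self) -> list[int]:
        return [r for _, r in self.observations]

    @property
    def distinct_repeats(self) -> set[int]:
        return set(self.repeats)

    @property
    def polymorphic(self) -> bool:
        return len(self.distinct_repeats) >= 2


@dataclass(frozen=True)
class ReportRow:
    """One row of a three-column report file."""

    key_string: str
    n_obs: int
    repeats: tuple[int, ...]


def build_locus_key(hit: SSRHit, sequence: str, k: int) -> LocusKey | None:
    """Locus key for *hit*, or None when a full clean flank is unavailable.

    Requires exactly *k* bases on each side of the run within the
    transcript; a flank that is truncated by the sequence end or that
    contains ``N`` disqualifies the hit (the skip is logged).
    """
    if k < 1:
        raise ValueError("flank length k must be >= 1")
    seq = sequence.upper()
    if hit.start - k < 0 or hit.end + k > len(seq):
        logger.debug(
            "skip %s@%d: flank shorter than k=%d", hit.seq_id, hit.start, k
        )
        return None
    left = seq[hit.start - k : hit.start]
    right = seq[hit.end : hit.end + k]
    if "N" in left or "N" in right:
        logger.debug("skip %s@%d: N in flank", hit.seq_id, hit.start)
        return None
    return LocusKey(left_flank=left, motif=hit.motif, right_flank=right)


def _canonical_strand(key: LocusKey) -> LocusKey:
    """Strand-canonical form of a key: the lexicographically smaller of
    the key and its full reverse complement (flanks swap sides)."""
    rc = LocusKey(
        left_flank=revcomp(key.right_flank),
        motif=revcomp(key.motif),
        right_flank=revcomp(key.left_flank),
    )
    return key if key.string_form <= rc.string_form else rc


def aggregate(
    hits_with_sequences: Iterable[tuple[SSRHit, str]],
    k: int,
    min_obs: int = 1,
    merge_revcomp: bool = False,
) -> dict[LocusKey, LocusRecord]:
    """Aggregate (hit, source-sequence) pairs into flank-keyed loci.

    Single pass; the result is independent of input order (each
    record's observation list is finally sorted by (seq_id, position)).
    Hits whose flanks cannot supply *k* clean bases are skipped.
    Records with fewer than *min_obs* observations are dropped after
    aggregation (default 1: keep everything).
    """
    records: dict[LocusKey, LocusRecord] = {}
    for hit, sequence in hits_with_sequences:
        key = build_locus_key(hit, sequence, k)
        if key is None:
            continue
        if merge_revcomp:
            key = _canonical_strand(key)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = LocusRecord(key=key)
        rec.observations.append((hit.seq_id, hit.repeats))
        rec._positions.append((hit.seq_id, hit.start))

    for rec in records.values():
        order = sorted(
            range(rec.n_obs), key=lambda i: (rec._positions[i], rec.observations[i])
        )
        rec.observations = [rec.observations[i] for i in order]
        rec._positions = [rec._positions[i] for i in order]

    if min_obs > 1:
        records = {k_: r for k_, r in records.items() if r.n_obs >= min_obs}
    return records


def aggregate_sequences(
    sequences: Iterable[tuple[str, str]],
    k: int,
    thresholds: Thresholds | None = None,
    min_obs: int = 1,
    merge_revcomp: bool = False,
) -> dict[LocusKey, LocusRecord]:
    """Scan (seq_id, sequence) records and aggregate their SSR hits.

    Convenience wrapper chaining :func:`polyssr.detect.find_ssrs` into
    :func:`aggregate` in one streaming pass over the merged dataset.
    """

    def hit_stream() -> Iterator[tuple[SSRHit, str]]:
        for seq_id, sequence in sequences:
            for hit in find_ssrs(sequence, seq_id, thresholds):
                yield hit, sequence

    return aggregate(hit_stream(), k=k, min_obs=min_obs, merge_revcomp=merge_revcomp)


def rank_candidates(records: dict[LocusKey, LocusRecord]) -> list[LocusRecord]:
    """Polymorphic records ordered by decreasing evidence of polymorphism:
    distinct repeat-count values desc, then n_obs desc, then key asc."""
    poly = [r for r in records.values() if r.polymorphic]
    return sorted(
        poly,
        key=lambda r: (-len(r.distinct_repeats), -r.n_obs, r.key.string_form),
    )


def _rows(records: Iterable[LocusRecord]) -> list[ReportRow]:
    rows = [
        ReportRow(r.key.string_form, r.n_obs, tuple(r.repeats)) for r in records
    ]
    rows.sort(key=lambda row: row.key_string)
    return rows


def write_reports(
    records: dict[LocusKey, LocusRecord],
    detail_path: str | Path,
    result_path: str | Path,
    header: bool = False,
) -> None:
    """Write the detail (all loci) and result (polymorphic loci) files.

    Rows are sorted by key string for reproducibility. No header by
    default; ``header=True`` prepends ``key\\tn_obs\\trepeats``.
    """
    all_rows = _rows(records.values())
    poly_keys = {r.key.string_form for r in records.values() if r.polymorphic}
    for path, rows in (
        (detail_path, all_rows),
        (result_path, [r for r in all_rows if r.key_string in poly_keys]),
    ):
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("key\tn_obs\trepeats\n")
            for row in rows:
                reps = ",".join(str(x) for x in row.repeats)
                fh.write(f"{row.key_string}\t{row.n_obs}\t{reps}\n")


def read_report(path: str | Path, header: bool = False) -> list[ReportRow]:
    """Read a three-column report file back into rows.

    The key is returned as its concatenated string form; flank/motif
    boundaries are not delimited in the file format.
    """
    rows: list[ReportRow] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if header and lines:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1 + int(header)):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        key_string, n_obs_s, reps_s = parts
        repeats = tuple(int(x) for x in reps_s.split(",")) if reps_s else ()
        n_obs = int(n_obs_s)
        if n_obs != len(repeats):
            raise ValueError(
                f"{path}:{lineno}: n_obs {n_obs} != {len(repeats)} repeat values"
            )
        rows.append(ReportRow(key_string, n_obs, repeats))
    return rows
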