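"""Microsatellite (SSR) detection in transcript sequences.

Finds maximal tandem-repeat runs of primitive 1-6 bp motifs under
per-unit-length minimum-repeat thresholds (MISA-style), and classifies
motifs into canonical strand/rotation classes such as ``AT/AT`` or
``AAT/ATT`` so that a motif, all its cyclic rotations, and all rotations
of its reverse complement share one label.

Only full tandem copies count toward the repeat number; a trailing
partial copy belongs to the flank. Runs containing ``N`` are never
reported. Interrupted (imperfect) repeats appear as separate maximal
runs, each thresholded independently — the scanner makes no
perfect/imperfect distinction.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_THRESHOLDS",
    "Thresholds",
    "SSRHit",
    "MotifSummary",
    "find_ssrs",
    "canonical_motif_class",
    "summarize_motifs",
    "revcomp",
    "is_primitive",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: MISA default minimum repeat counts per motif unit length.
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_VALID_SEQ_RE = re.compile(r"[^ACGTN]")
_VALID_MOTIF_RE = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class Thresholds:
    """Minimum repeat count required for a run of each motif unit length.

    Parameters
    ----------
    min_repeats
        Mapping from unit length (1..6) to the minimum number of full
        tandem copies a run must contain to be reported. All six unit
        lengths must be present and every value must be >= 2.
    """

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValueError(
                "min_repeats must have exactly the unit lengths 1..6, "
                f"got {sorted(self.min_repeats)}"
            )
        bad = {k: v for k, v in self.min_repeats.items() if v < 2}
        if bad:
            raise ValueError(f"minimum repeat counts must be >= 2, got {bad}")

    def __getitem__(self, unit_length: int) -> int:
        return self.min_repeats[unit_length]


@dataclass(frozen=True)
class SSRHit:
    """One maximal tandem-repeat run in one transcript.

    Coordinates are 0-based half-open; ``end - start`` equals
    ``repeats * len(motif)`` (partial trailing copies are excluded).
    """

    seq_id: str
    motif: str
    repeats: int
    start: int
    end: int
    motif_class: str

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def run_sequence(self) -> str:
        return self.motif * self.repeats


@dataclass
class MotifSummary:
    """Tally of hits per canonical motif class and per unit length."""

    counts: dict[str, int]
    counts_by_unit_length: dict[int, int]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a whole-number power of a shorter string.

    Uses the classic rotation trick: a string is a nontrivial power iff
    it occurs in its own doubling with both end characters removed.
    """
    return (motif + motif).find(motif, 1) == len(motif)


def _min_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def canonical_motif_class(motif: str) -> str:
    """Canonical strand/rotation class label for a repeat unit.

    The label is ``X/Y`` where X is the lexicographically smallest
    cyclic rotation of the motif or of its reverse complement
    (whichever is smaller) and Y the smallest rotation of the other
    strand, so e.g. ``TA``, ``AT`` and ``TTA`` map to ``AT/AT`` and
    ``AAT/ATT`` respectively.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6 or _VALID_MOTIF_RE.search(motif):
        raise ValueError(f"motif must be 1-6 bases over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    fwd = _min_rotation(motif)
    rev = _min_rotation(revcomp(motif))
    a, b = sorted((fwd, rev))
    return f"{a}/{b}"


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    m = _VALID_SEQ_RE.search(seq)
    if m:
        raise ValueError(
            f"non-DNA character {m.group()!r} at position {m.start()}"
        )
    return seq


def _scan_segment(seq: str, offset: int, k: int, min_rep: int):
    """Yield (start, copies) of maximal period-k runs in an N-free segment.

    A run is reported from the earliest position at which the period-k
    property holds, so left-maximality is automatic; only full copies
    count, so the reported span can never be extended by one more copy.
    """
    n = len(seq)
    i = 0
    while i + k * min_rep <= n:
        j = i + k
        while j < n and seq[j] == seq[j - k]:
            j += 1
        # seq[i:j] is the maximal region with period k starting at i
        copies = (j - i) // k
        if copies >= min_rep and is_primitive(seq[i : i + k]):
            yield offset + i, copies
        if copies >= 2:
            # next candidate region cannot start inside this one
            i = j - k + 1
        else:
            i += 1


def find_ssrs(
    sequence: str,
    seq_id: str = "",
    thresholds: Thresholds | None = None,
) -> list[SSRHit]:
    """Find every maximal SSR run in *sequence* meeting its threshold.

    Parameters
    ----------
    sequence
        DNA over A/C/G/T/N, case-insensitive. ``N`` terminates run
        extension and never occurs inside a reported run.
    seq_id
        Identifier recorded on each hit.
    thresholds
        Per-unit-length minimum repeat counts; MISA defaults if omitted.

    Returns
    -------
    list of SSRHit, sorted by start position (ties: shorter unit first).
    Overlapping runs of different unit lengths are all reported, except
    that two runs spanning the identical interval keep only the shorter
    unit length.
    """
    seq = _validate_sequence(sequence)
    if thresholds is None:
        thresholds = Thresholds()

    hits: dict[tuple[int, int], SSRHit] = {}
    # scan each N-free segment independently
    seg_start = 0
    for segment in seq.split("N"):
        if segment:
            for k in range(1, 7):
                min_rep = thresholds[k]
                for start, copies in _scan_segment(segment, seg_start, k, min_rep):
                    motif = seq[start : start + k]
                    span = (start, start + copies * k)
                    prev = hits.get(span)
                    if prev is None or k < prev.unit_length:
                        hits[span] = SSRHit(
                            seq_id=seq_id,
                            motif=motif,
                            repeats=copies,
                            start=span[0],
                            end=span[1],
                            motif_class=canonical_motif_class(motif),
                        )
        seg_start += len(segment) + 1

    return sorted(hits.values(), key=lambda h: (h.start, h.unit_length, h.end))


def summarize_motifs(hits: list[SSRHit]) -> MotifSummary:
    """Tally hits by canonical motif class and by unit length."""
    by_class = Counter(h.motif_class for h in hits)
    by_len = Counter(h.unit_length for h in hits)
    return MotifSummary(counts=dict(by_class), counts_by_unit_length=dict(by_len))
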