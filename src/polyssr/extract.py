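"""Candidate-sequence extraction and verification for selected loci.

Given a locus key (left flank + motif + right flank), this module
relocates its occurrences in the transcript dataset, cuts a
primer-design-ready window around each run (100-300 bp, at least 50 bp
of context on each side), and checks two things across the windows of
one putative locus: that every window supplies enough flank for primer
design, and that the non-repeat context around the run is identical
across samples wherever two windows both cover it. A repeat-count
difference between samples is the polymorphism signal, never an
inconsistency; a substitution in the shared context is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .aggregate import LocusKey
from .detect import DEFAULT_THRESHOLDS

__all__ = [
    "KeyMatch",
    "CandidateAmplicon",
    "VerificationReport",
    "locate_key",
    "extract_window",
    "verify_locus",
    "write_amplicon_fasta",
]

logger = logging.getLogger(__name__)

MIN_FLANK = 50
MIN_WINDOW = 100
MAX_WINDOW = 300


@dataclass(frozen=True)
class KeyMatch:
    """One exact occurrence of a locus key in one transcript."""

    seq_id: str
    run_start: int  # 0-based start of the repeat run (after the left flank)
    run_end: int  # half-open end of the full copies
    repeats: int


@dataclass(frozen=True)
class CandidateAmplicon:
    """A 100-300 bp window around one SSR run, ready for primer design."""

    locus_key: LocusKey
    seq_id: str
    window_sequence: str
    left_context_len: int
    right_context_len: int
    repeats: int

    @property
    def run_sequence(self) -> str:
        stop = len(self.window_sequence) - self.right_context_len
        return self.window_sequence[self.left_context_len : stop]


@dataclass
class VerificationReport:
    """Outcome of the two checks for one locus's candidate windows."""

    locus_key: LocusKey
    flank_length_ok: bool
    consistency_ok: bool
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.flank_length_ok and self.consistency_ok


def _min_repeats_for(motif: str) -> int:
    return DEFAULT_THRESHOLDS[len(motif)]


def locate_key(
    key: LocusKey,
    transcripts: Iterable[tuple[str, str]],
    min_repeats: int | None = None,
) -> list[KeyMatch]:
    """Exact occurrences of *key* across (seq_id, sequence) records.

    A match is the left flank, followed by at least *min_repeats* full
    copies of the motif (greedy count), followed immediately by the
    right flank. Records are searched independently — a key never
    matches across a transcript boundary. The repeat count found at
    each occurrence may differ from the aggregate record (new data);
    it is reported, not treated as an error.
    """
    if min_repeats is None:
        min_repeats = _min_repeats_for(key.motif)
    left, motif, right = key.left_flank, key.motif, key.right_flank
    m = len(motif)
    matches: list[KeyMatch] = []
    for seq_id, sequence in transcripts:
        seq = sequence.upper()
        pos = seq.find(left)
        while pos != -1:
            run_start = pos + len(left)
            j = run_start
            while seq.startswith(motif, j):
                j += m
            copies = (j - run_start) // m
            if copies >= min_repeats and seq.startswith(right, j):
                matches.append(
                    KeyMatch(
                        seq_id=seq_id,
                        run_start=run_start,
                        run_end=j,
                        repeats=copies,
                    )
                )
            pos = seq.find(left, pos + 1)
    if not matches:
        logger.warning("locus key %s...: no occurrences found", key.string_form[:20])
    return matches


def extract_window(
    match: KeyMatch,
    sequence: str,
    key: LocusKey,
    min_flank: int = MIN_FLANK,
    max_window: int = MAX_WINDOW,
) -> CandidateAmplicon | None:
    """Cut a candidate window around *match*, or None when impossible.

    The window expands symmetrically from the run until each side has
    *min_flank* bases, then keeps growing one base per side (alternating,
    left first; a side that hits the transcript end stops) until the
    window reaches *max_window* or the transcript is exhausted. Returns
    None, with the reason logged, when the transcript cannot provide
    *min_flank* bases on each side within a *max_window*-base window.
    """
    seq = sequence.upper()
    run_len = match.run_end - match.run_start
    if run_len + 2 * min_flank > max_window:
        logger.info(
            "%s: run of %d bases leaves no room for %d-base flanks in a "
            "%d-base window", match.seq_id, run_len, min_flank, max_window,
        )
        return None
    if match.run_start < min_flank or len(seq) - match.run_end < min_flank:
        logger.info(
            "%s: context %d/%d bases, need >= %d per side",
            match.seq_id, match.run_start, len(seq) - match.run_end, min_flank,
        )
        return None

    left = right = min_flank
    budget = max_window - run_len - left - right
    grow_left = True
    while budget > 0:
        can_left = match.run_start - left > 0
        can_right = match.run_end + right < len(seq)
        if not can_left and not can_right:
            break
        if grow_left and can_left:
            left += 1
            budget -= 1
        elif not grow_left and can_right:
            right += 1
            budget -= 1
        elif can_left:
            left += 1
            budget -= 1
        else:
            right += 1
            budget -= 1
        grow_left = not grow_left

    window = seq[match.run_start - left : match.run_end + right]
    return CandidateAmplicon(
        locus_key=key,
        seq_id=match.seq_id,
        window_sequence=window,
        left_context_len=left,
        right_context_len=right,
        repeats=match.repeats,
    )


def verify_locus(
    windows: list[CandidateAmplicon],
    key: LocusKey,
    min_flank: int = MIN_FLANK,
) -> VerificationReport:
    """Run the flank-length and cross-sample consistency checks.

    ``flank_length_ok``: every window carries at least *min_flank*
    context bases on each side of the run.

    ``consistency_ok``: for every pair of windows, the context
    sequences — left contexts aligned at the run start (compared
    right-to-left), right contexts aligned at the run end — agree at
    every offset both windows cover. The repeat run itself is excluded
    from the comparison, so windows differing only in repeat count are
    consistent. A single window is vacuously consistent.
    """
    notes: list[str] = []
    flank_ok = True
    for w in windows:
        if w.left_context_len < min_flank or w.right_context_len < min_flank:
            flank_ok = False
            notes.append(
                f"{w.seq_id}: flanks {w.left_context_len}/{w.right_context_len}"
                f" < {min_flank}"
            )

    contexts = []
    for w in windows:
        left_ctx = w.window_sequence[: w.left_context_len]
        right_ctx = w.window_sequence[len(w.window_sequence) - w.right_context_len :]
        contexts.append((w.seq_id, left_ctx, right_ctx))

    consistent = True
    for i in range(len(contexts)):
        for j in range(i + 1, len(contexts)):
            id_a, la, ra = contexts[i]
            id_b, lb, rb = contexts[j]
            n_left = min(len(la), len(lb))
            if n_left and la[-n_left:] != lb[-n_left:]:
                consistent = False
                notes.append(f"left context differs: {id_a} vs {id_b}")
            n_right = min(len(ra), len(rb))
            if n_right and ra[:n_right] != rb[:n_right]:
                consistent = False
                notes.append(f"right context differs: {id_a} vs {id_b}")

    return VerificationReport(
        locus_key=key,
        flank_length_ok=flank_ok,
        consistency_ok=consistent,
        notes=notes,
    )


def write_amplicon_fasta(
    amplicons: Iterable[CandidateAmplicon],
    path: str | Path,
    locus_ids: dict[str, str] | None = None,
) -> None:
    """Write candidate amplicons as FASTA, one record per (locus, sample).

    Record IDs follow ``<locus_id>|<seq_id>|repeats=<n>``; *locus_ids*
    maps key string forms to short locus labels (defaults to the key
    string itself).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for amp in amplicons:
            ks = amp.locus_key.string_form
            locus_id = (locus_ids or {}).get(ks, ks)
            fh.write(f">{locus_id}|{amp.seq_id}|repeats={amp.repeats}\n")
            fh.write(amp.window_sequence + "\n")
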