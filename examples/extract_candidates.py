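"""Extract primer-ready candidate windows for mined polymorphic loci.

Takes the top-ranked polymorphic loci from a scanned synthetic dataset,
relocates each locus key in the transcripts, cuts 100-300 bp windows
with at least 50 bp of context per side, and runs the verification
checks (flank length sufficiency and cross-sample context consistency).
"""

from polyssr import (
    aggregate_sequences,
    extract_window,
    locate_key,
    make_transcript_set,
    rank_candidates,
    verify_locus,
)

tset = make_transcript_set(seed=42)
transcripts = tset.merged()
seqs = dict(transcripts)
records = aggregate_sequences(transcripts, k=10)

print("locus key (truncated)            matches windows flank_ok consistent")
for rec in rank_candidates(records)[:8]:
    matches = locate_key(rec.key, transcripts)
    windows = [
        w for m in matches
        if (w := extract_window(m, seqs[m.seq_id], rec.key)) is not None
    ]
    report = verify_locus(windows, rec.key)
    ok = report.flank_length_ok and len(windows) == len(matches)
    print(
        f"{rec.key.string_form[:30]:<32} {len(matches):>7} {len(windows):>7} "
        f"{str(ok):>8} {str(report.consistency_ok):>10}"
    )

# a locus passes when every sample's window provides >= 50 bases of
# context per side (enough for primer design) and all windows agree on
# the sequence around the run; repeat-count differences are the
# polymorphism signal and never count as inconsistency
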