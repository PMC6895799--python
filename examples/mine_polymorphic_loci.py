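"""Mine potentially polymorphic SSR loci from a multi-sample transcript set.

Generates a synthetic six-sample dataset with 20 planted SSR loci (12
of them with repeat counts that vary between samples), scans the merged
dataset, aggregates flank-keyed loci, and prints the polymorphic
candidates ranked by how many distinct repeat counts they show — the
loci a lab would take forward to primer design first.
"""

from polyssr import aggregate_sequences, make_transcript_set, rank_candidates

tset = make_transcript_set(seed=42)
merged = tset.merged()
print(f"samples: {len(tset.samples)}   transcripts in merged set: {len(merged)}")

records = aggregate_sequences(merged, k=10)
n_poly = sum(1 for r in records.values() if r.polymorphic)
print(f"loci found: {len(records)}   potentially polymorphic: {n_poly}\n")

print("rank  key (flank+motif+flank, truncated)  n_obs  repeat counts")
for i, rec in enumerate(rank_candidates(records), start=1):
    reps = ",".join(str(r) for r in rec.repeats)
    print(f"{i:>4}  {rec.key.string_form[:34]:<36} {rec.n_obs:>5}  {reps}")

# each row is one putative locus: identical flanking sequence in several
# samples with >= 2 distinct repeat counts, i.e. a length polymorphism
# visible directly in the assemblies before any wet-lab work
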