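"""Cleavage-site profile and isoacceptor frequencies of 5' tRNA halves.

After aligning and classifying one library, prints (a) the fraction of 5'
halves ending at each offset upstream of the anticodon -- the cleavage-site
usage that produces 30/31/32/33 nt halves -- and (b) the isotype shares of
half reads next to gene copy number, showing the two are unrelated.
"""

from trnahalf import (
    AlignPolicy, Annotator, MixtureSpec, PreprocessParams, ReportMode,
    align_and_report, build_index, build_synthetic_reference, cleavage_profile,
    default_reference_spec, isoacceptor_frequencies, preprocess_reads,
    simulate_sample,
)

genome, track = build_synthetic_reference(default_reference_spec(seed=0))
sim = simulate_sample(genome, track, MixtureSpec(n_reads=20_000), seed=1)
clean, _ = preprocess_reads(sim.reads, PreprocessParams())
index = build_index(genome, 14)
reported, seqs = align_and_report(clean, index, AlignPolicy(), ReportMode("best_one"))
annotator = Annotator(track, chrom_sizes={c: len(s) for c, s in genome.items()})
frame = annotator.annotate_batch(reported, seqs)

prof = cleavage_profile(frame, track.gene_lookup())
by_off = prof.groupby("offset").n_reads.sum()
print("cleavage offsets upstream of the anticodon (fraction of 5' halves):")
print((by_off / by_off.sum()).round(3).to_string())
print("-> offset 1 ends one base before the anticodon (33 nt half),"
      " offset 4 four bases before (30 nt half)\n")

iso = isoacceptor_frequencies(frame, track.gene_lookup())
print(iso.assign(fraction=iso.fraction.round(3)).to_string(index=False))
print("-> Gly and Val dominate the circulating halves while copy number"
      " does not track abundance")
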