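"""The 30-33 nt peak depends on how multireads are reported.

Aligns one simulated library under both alignment policies (5'-seed based
and end-to-end k-difference) crossed with both reporting policies, and
prints the read count in the 30-33 nt window for each combination.  The
peak -- 5' tRNA halves from multi-copy gene families -- survives best-one
reporting and collapses when multireads are suppressed.
"""

from trnahalf import (
    AlignPolicy, Annotator, MixtureSpec, PreprocessParams, ReportMode,
    build_index, build_synthetic_reference, default_reference_spec,
    length_histogram, preprocess_reads, simulate_sample,
)
from trnahalf.align import align_read, report

genome, track = build_synthetic_reference(default_reference_spec(seed=0))
sim = simulate_sample(genome, track, MixtureSpec(n_reads=20_000), seed=0)
clean, _ = preprocess_reads(sim.reads, PreprocessParams())
index = build_index(genome, 14)
annotator = Annotator(track, chrom_sizes={c: len(s) for c, s in genome.items()})
seqs = {rid: s for rid, s, _ in clean}

print(f"{'policy':<10} {'reporting':<12} {'mapped':>7} {'30-33 nt':>9}")
for pol_label, pol in (("maq_like", AlignPolicy()), ("kdiff", AlignPolicy(mode="kdiff"))):
    valid = [align_read(rid, s, index, pol) for rid, s, _ in clean]
    for mode in ("best_one", "unique_only"):
        reported = [a for v in valid for a in report(v, ReportMode(mode))]
        frame = annotator.annotate_batch(reported, seqs)
        hist = length_histogram(frame).set_index("length").total
        print(f"{pol_label:<10} {mode:<12} {len(reported):>7} {hist.loc[30:33].sum():>9}")

print("\nThe 30-33 nt window holds thousands of reads under best_one and"
      " almost none under unique_only: the peak is made of multireads from"
      " identical tRNA gene copies.")
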