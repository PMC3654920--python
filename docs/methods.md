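# Methods

## Scope and coordinate conventions

The pipeline analyses circulating 5′ tRNA halves from small RNA-seq: 30–33
nt fragments generated by cleavage of mature tRNAs in the anticodon loop.
Genomic intervals are 0-based half-open (BED convention) everywhere;
positions inside a mature tRNA are 1-based with position 1 at the mature 5′
nucleotide, matching the cloverleaf numbering in which a typical anticodon
occupies positions 33–35. `trna_coordinate` maps a genomic position to the
mature frame strand-awarely and is a bijection between the gene interval
and 1..length on either strand.

## Synthetic reference

`build_synthetic_reference` embeds tRNA gene families into random
chromosome backgrounds. All copies of a family are sequence-identical by
default — this is deliberate: identical copies are exactly what makes 5′
half reads multireads, the phenomenon the aligner stages are designed to
expose. An option (`copy_substitutions`) introduces ≤2 substitutions per
copy to exercise mismatch policies instead. Mature tRNAs are the genomic
gene sequences (no intron or CCA modelling; the analysis aligns reads to
genomic loci, so post-transcriptional tails are out of frame). Family 5′
ends (first 20 nt) are kept distinct between families so halves multimap
only within their own family.

The default spec carries seven families with the copy numbers of the
genomic tRNA families dominating circulating halves — Gly-GCC ×29,
Val-AAC ×23, Glu-CTC ×21, His-GTG ×11 — plus Lys-CTT ×8, Cys-GCA ×5 and
Arg-CCG ×4 for the differential analysis, with mature length 76 and
anticodon start at mature position 34, so cleavage 1–4 nt upstream of the
anticodon yields 30–33 nt halves. Features (tRNA loci, miRNA loci, rRNA,
other small RNAs, repeat regions) are placed without overlap by rejection
sampling; an explicit capacity error is raised if the chromosomes are too
small. Builds are byte-deterministic given the spec seed. On disk the
reference is FASTA plus BED6 with five extra columns (class, isotype,
anticodon, anticodon position, family id), chosen over GFF attributes for
bit-exact round-tripping.

## Read simulator

`MixtureSpec` defines a library as a mixture over five origin classes with
default fractions 0.546 / 0.002 / 0.002 / 0.25 / 0.20 for 5′ halves, 3′
halves, full-length tRNA, miRNA, and genomic noise. The defaults encode
the serum conditions: ~99.3 % of tRNA-derived reads are 5′ halves, and
after alignment roughly 80 % of mapped reads annotate as small RNAs with
tRNA and miRNA dominating.

* **5′ halves** end at mature position `anticodon_pos − offset`, with
  offset ∈ {1..4} drawn from site-usage probabilities
  0.2568/0.3455/0.1693/0.2284, the exact count-derived fractions whose
  integer rounding gives the published 26/35/17/23 % usage (equivalently
  23/17/35/26 % of halves at 30/31/32/33 nt). The printed percentages sum
  to 101 due to rounding, so the exact fractions are used. Each half
  picks its genomic locus uniformly among the family's copies.
* **3′ halves** begin immediately after the cleavage site; **full-length**
  reads carry the whole mature sequence (and are subsequently removed by
  the ≤48 nt insert filter, as in real libraries where they exceed the
  read length).
* **miRNA** reads take 20–24 nt (peaked at 22) from single-copy loci;
  **noise** reads are uniform genomic fragments of 5–48 nt on either
  strand, reproducing the mapped-length floor of real libraries.
* Family abundance weights default to Gly 0.46, Val 0.44, Glu 0.08,
  His 0.01 and <1 % for the rest — the observed isoacceptor shares, which
  deliberately do not track copy number.
* Inserts get the TruSeq small-RNA 3′ adapter appended, are padded and cut
  to 50 nt, and receive per-base substitution errors at rate 0.001.
  Qualities are flat Q40 by default; an option degrades a configurable
  read fraction to exercise the quality filter.

`simulate_experiment` adds the 3×3 design (three animals per group:
young control, old control, old CR). Per-family 5′-half counts are drawn
gamma–Poisson — NB with dispersion 0.1, the model family the testing stage
assumes — around `n_reads × fraction × weight × group_effect`. Counts are
absolute (library totals vary between groups) rather than renormalised, so
a family's simulated old/young mean-count ratio converges to its group
effect; TMM normalisation downstream absorbs the induced library-size
shifts. Default group effects are the mean-count ratios of the published
age/CR table (e.g. His-GTG 3.75× up with age, Gly-GCC 4.5× down).
Per-sample seeds are spawned from one experiment seed; identical seeds give
byte-identical FASTQ.

What the simulator does **not** model: ligation bias, RT stops at modified
nucleotides, per-cycle error profiles, isomiR heterogeneity, or any
sequencing bias shaping isoacceptor frequencies. Passing tests therefore
demonstrate that the pipeline recovers the structure the generator encodes,
not that real serum libraries are free of such biases.

## Preprocessing

Adapter trimming removes the leftmost occurrence of the adapter — full
internal match or 3′-terminal prefix of ≥5 bases — tolerating a mismatch
rate of 0.1 per overlap (so ≥10-base overlaps admit one mismatch), plus
everything 3′ of it; reads without a detectable adapter are kept whole.
Trimming is idempotent. Quality filtering keeps reads whose insert length
lies in [5, 48] nt and where ≥80 % of bases have Phred ≥20, both bounds
inclusive. The exact parameters of the original study's FASTX step are not
recoverable; these defaults are conventional and fully configurable.

## Aligner

Two policies are implemented over an exact k-mer position index of the
forward genome:

* `maq_like` (default): candidates come from an exact match of the read's
  first 14 bases (its high-quality 5′ end) on either strand; candidates
  are verified end-to-end with at most `max_total_mismatches` (default 2)
  mismatches overall and at most `seed_mismatches` (default 0, others via
  Hamming-ball seed enumeration) within the seed. The quality-weighted
  mismatch ceiling of classical aligners is replaced by this plain count:
  simulated qualities are flat and the phenomenon under test depends on
  placement multiplicity, not quality arithmetic.
* `kdiff`: every end-to-end placement with ≤v mismatches anywhere
  (default v=0, configurable; the original study does not state its
  budget). Candidates are generated by pigeonhole seeding — the read is
  cut into v+1 disjoint chunks, one of which must match exactly — using
  lazily built k-mer tables, so the verified set is provably complete.

`n_valid` is the exact size of the valid set by full enumeration (genomes
here are desk-scale; no capping). Palindromic placements on both strands
count separately. Reporting is `best_one` (fewest mismatches, ties broken
deterministically by (chrom, start, strand), or seeded-random on request)
or `unique_only` (emit only if `n_valid == 1`). Deterministic tie-breaking
replaces the pseudo-random placement of production aligners for
testability; its visible consequence is that a family's multiread counts
concentrate on the lexicographically first copy rather than spreading over
copies. Output is minimal SAM with `NM` (mismatches) and `NH` (valid-set
size) tags. Indels, quality-sum ceilings, and compressed indexes are out
of scope.

The test suite verifies the aligner against an independent brute-force
oracle (numpy sliding-window scoring of every genomic position, both
strands) for both policies at mismatch budgets 0–3.

## Annotation and classification

Reported alignments are intersected with the feature track (interval
trees); a read takes the highest-priority class among strand-compatible
overlaps of ≥1 base, with priority tRNA > miRNA > rRNA > other small RNA >
repeat (repeats are strandless; reads whose best class is repeat are
excluded from tRNA statistics downstream). On tRNA loci, a read whose 5′
terminus lies within 2 nt of mature position 1 is `tRNA_5p`; within 2 nt of
the mature 3′ end, `tRNA_3p`; otherwise internal; 5′ takes precedence on
degenerate short genes. The ±2 nt tolerance absorbs simulated 5′-end
raggedness while keeping classes crisp. For 5′ halves the mature position
of the 3′-terminal base is the cleavage position, reported as the offset
`anticodon_pos − cleavage_pos` (≥1 means cleavage upstream of the
anticodon). Derived tables: per-length histograms by class and policy
combination, per-family cleavage-site fractions, and isoacceptor
frequencies joined with family copy numbers.

## Counting, filtering, and testing

Counting uses best-one reports, so each read increments exactly one locus;
the default library size is the sample's total mapped reads. TMM factors
follow the standard construction (M-trim 30 %, A-trim 5 %, delta-method
weights, reference = sample with the median library size, factors centred
at geometric mean 1); a no-normalisation flag uses raw libraries. The
abundance filter keeps loci whose group-mean CPM (counts per million,
`count / library × 10⁶`) reaches 500 in at least one of the three groups —
the group statistic is not specified in the study's description, so the
group mean is the default with a per-sample-maximum variant behind a flag.

Dispersions: the common φ maximises the Cox–Reid adjusted profile
likelihood (APL) summed over non-zero loci, evaluated on a 25-point log
grid over [1e-4, 10] with quadratic refinement; per-locus fits underneath
are vectorised Newton iterations on per-group log-means with library
offsets. Tagwise φ_g maximises `APL_g + (prior_df / residual_df) ·
mean-APL`, i.e. weighted-likelihood shrinkage toward the common value with
prior df 10 — the model class of the standard count-based framework
without its full empirical-Bayes machinery. One sample per group leaves no
residual df and raises; a fixed user dispersion is then accepted by the
testing step.

Each contrast is a 1-df likelihood-ratio test of the three-group model
against the model merging the contrasted groups. Results carry raw group
mean counts, the signed mean-ratio fold change (the table convention: r if
r ≥ 1 else −1/r, printed to one decimal), the model-based fold change from
fitted coefficients, raw LRT p-values (ranked as published), and BH
q-values per contrast. The two fold-change flavours agree on some
published rows and differ by one rounding step on others (e.g. His-GTG:
mean-ratio 3.7 vs printed model-based 3.8); both are reported. Tests
cross-check the implementation against two independent routes: per-locus
statsmodels NB-GLM log-likelihoods, and Bioconductor edgeR (`glmLRT` at
fixed dispersion; `calcNormFactors` for TMM), which agree to ~1e-6.

Whether the original analysis counted per locus or per identical-sequence
family is ambiguous (its table lists many identical-FC loci per family);
deterministic tie-breaking makes the per-locus choice explicit here.

## Numerical choices and degenerate inputs

Newton fits clamp coefficients to ±30 on the log scale and converge in
≤50 damped steps; all-zero groups fit μ→0 and contribute zero likelihood;
all-zero loci are excluded from dispersion estimation and inherit the
common value. NB log-likelihoods switch to the Poisson limit below
φ=1e-8. Non-converged fits flag their p-values as NA and are excluded
from BH adjustment. `signed_fold_change` is NaN when both means are zero
and ±∞ when exactly one is.

## Problem sizes

Default scales are chosen for desk-scale, fully enumerable analysis:
80 kb × 3 chromosomes, 101 tRNA loci, 10⁵-read libraries for
distributional checks and 1.5–20 k reads for end-to-end demos, 200–1000
loci for statistical calibration, and 25 replicates for power estimates.
These sizes make every valid alignment set exactly enumerable and keep the
whole suite reproducible from seeds.
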