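"""Recompute the study's printed summary numbers from its printed counts.

The original raw data were never deposited, but every derived percentage
and fold change in the published summary tables can be recomputed from the
printed counts with the reporting operations.
"""

from trnahalf import signed_fold_change, size_share_table, summarize_mapping
from trnahalf.published import MAPPING_COUNTS, TRNA_SIZE_COUNTS, diff_group_means

s = summarize_mapping(
    MAPPING_COUNTS["preprocessed"], MAPPING_COUNTS["mapped"],
    class_counts={"tRNA": MAPPING_COUNTS["trna"]},
    n_small_rna=MAPPING_COUNTS["small_rna"],
)
print(f"mapped: {s.mapped_pct}% of preprocessed reads")
print(f"small-RNA: {s.small_rna_pct}% of mapped reads")
print(f"tRNA: {s.class_pct_of_small_rna['tRNA']}% of small-RNA reads\n")

print("tRNA read-length shares:")
print(size_share_table(TRNA_SIZE_COUNTS).to_string(index=False))

print("\nsigned fold changes from group mean counts:")
means = diff_group_means()
for locus in ("chr1:171074302-171074372", "chr17:23533962-23534034",
              "chr13:23401073-23401145"):
    row = means.loc[locus]
    age = signed_fold_change(row.young_control, row.old_control)
    cr = signed_fold_change(row.old_control, row.old_CR)
    print(f"  {row.family:<8} {locus:<28} age FC {age:+.1f}   CR FC {cr:+.1f}")
print("\nage FC compares old vs young controls; CR FC compares old"
      " calorie-restricted vs old controls.")
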