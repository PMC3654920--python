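"""Printed summary values from the original mouse serum small-RNA survey.

The study's raw sequencing data were never deposited, but its published
summary tables are usable as inputs: overall mapping totals, the size
distribution of tRNA-mapping reads, and per-locus group mean counts from
the age / calorie-restriction differential-abundance table.  The reporting
operations recompute every derived percentage and fold change from these
counts; nothing here stores a derived number that the package computes.
"""

from __future__ import annotations

import pandas as pd

#: overall read-accounting totals (combined over the 9 serum libraries)
MAPPING_COUNTS = {
    "preprocessed": 196_083_881,
    "mapped": 163_078_230,
    "small_rna": 128_703_415,
    "trna": 86_343_437,
}

#: number of tRNA-mapping reads by read length (nt)
TRNA_SIZE_COUNTS = {30: 16_649_224, 31: 12_343_893, 32: 25_190_160, 33: 18_724_475}

#: isoacceptor shares of circulating 5' halves vs gene copy number
ISOACCEPTOR_TABLE = pd.DataFrame(
    {
        "isotype": ["Gly", "Val", "Glu", "His", "Others"],
        "copy_number": [29, 23, 21, 11, 351],
        "share": [0.46, 0.44, 0.08, 0.01, 0.01],
    }
)

#: per-locus group mean counts (young control, old control, old CR) from the
#: differential-abundance table, keyed by genomic locus, with the printed
#: fold changes and p-values kept alongside for comparison only
_DIFF_ROWS = [
    # family, locus, young, old, old_cr, printed_age_fc, printed_age_p,
    # printed_cr_fc, printed_cr_p
    ("His-GTG", "chr4:82619623-82619694", 797, 2988, 1554, 3.8, 3.1e-11, -2.0, 6.8e-4),
    ("His-GTG", "chr2:122377363-122377434", 798, 2994, 1549, 3.8, 3.7e-11, -2.0, 6.4e-4),
    ("His-GTG", "chr3:96452495-96452566", 307, 1140, 590, 3.8, 3.8e-11, -2.0, 6.1e-4),
    ("His-GTG", "chr2:122375494-122375565", 808, 2990, 1533, 3.8, 3.9e-11, -2.0, 5.0e-4),
    ("His-GTG", "chr2:122377968-122378039", 309, 1163, 600, 3.8, 4.2e-11, -2.0, 6.6e-4),
    ("His-GTG", "chr3:96458070-96458141", 802, 2993, 1523, 3.8, 4.3e-11, -2.0, 4.8e-4),
    ("His-GTG", "chr3:96500366-96500437", 796, 2954, 1524, 3.8, 4.5e-11, -2.0, 5.9e-4),
    ("His-GTG", "chr3:96410069-96410140", 301, 1148, 590, 3.9, 2.0e-11, -2.0, 5.5e-4),
    ("Arg-CCG", "chr11:107012866-107012938", 1243, 256, 302, -5.0, 9.9e-12, 1.2, 4.7e-1),
    ("Cys-GCA", "chr11:97798906-97798977", 933, 370, 688, -2.6, 2.5e-6, 1.8, 2.4e-3),
    ("Cys-GCA", "chr11:97988246-97988317", 928, 376, 700, -2.5, 3.9e-6, 1.8, 2.2e-3),
    ("Cys-GCA", "chr11:97988923-97988994", 930, 360, 684, -2.6, 1.3e-6, 1.9, 1.5e-3),
    ("Gly-GCC", "chr1:171074302-171074372", 16868, 3739, 3807, -4.5, 3.5e-14, -1.0, 9.6e-1),
    ("Gly-GCC", "chr1:171066631-171066701", 16820, 3730, 3790, -4.5, 4.3e-14, -1.0, 9.6e-1),
    ("Gly-GCC", "chr1:171081876-171081946", 16779, 3725, 3788, -4.4, 5.3e-14, -1.0, 9.6e-1),
    ("Lys-CTT", "chr17:23533962-23534034", 4175, 1939, 3286, -2.2, 8.8e-6, 1.7, 3.7e-3),
    ("Lys-CTT", "chr3:96428235-96428307", 4215, 1964, 3353, -2.2, 1.0e-5, 1.7, 3.3e-3),
    ("Lys-CTT", "chr17:23547360-23547432", 4098, 1923, 3272, -2.2, 1.1e-5, 1.7, 3.4e-3),
    ("Lys-CTT", "chr17:23535332-23535404", 14085, 6569, 11132, -2.2, 1.2e-5, 1.7, 4.1e-3),
    ("Lys-CTT", "chr13:23436340-23436412", 4181, 1962, 3321, -2.2, 1.2e-5, 1.7, 3.9e-3),
    ("Lys-CTT", "chr3:96499512-96499584", 13865, 6507, 11017, -2.2, 1.3e-5, 1.7, 3.9e-3),
    ("Lys-CTT", "chr11:48833883-48833955", 13905, 6539, 11051, -2.2, 1.4e-5, 1.7, 4.1e-3),
    ("Val-AAC", "chr13:23401073-23401145", 1247, 451, 814, -2.8, 3.3e-7, 1.8, 4.1e-3),
    ("Val-AAC", "chr13:23413248-23413320", 1246, 467, 836, -2.7, 5.4e-7, 1.8, 4.0e-3),
]


def diff_group_means() -> pd.DataFrame:
    """Group mean counts per locus from the published differential table."""
    return pd.DataFrame(
        _DIFF_ROWS,
        columns=[
            "family", "locus", "young_control", "old_control", "old_CR",
            "printed_age_fc", "printed_age_p", "printed_cr_fc", "printed_cr_p",
        ],
    ).set_index("locus")
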