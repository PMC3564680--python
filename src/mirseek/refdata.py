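"""Published summary statistics of the six-library olive small-RNA
experiment (GEO GSE42978) that this pipeline's accounting conventions
follow.

These numbers are inputs, not results: the cleaning-report identity
(clean = high-quality − Σ artifact categories) and the mapping-statistics
rounding conventions can be checked against them without access to the
raw reads. Libraries: UF/RF = unripe/ripe fruit, JON/NON = "on-year"
July/November leaf, JOFF/NOFF = "off-year" July/November leaf.
"""

from __future__ import annotations

# Per-library raw cleaning accounting. Keys per library:
# total_reads, high_quality, then the five artifact categories.
CLEANING_STATS: dict[str, dict[str, int]] = {
    "UF": {
        "total_reads": 15_364_727,
        "high_quality": 15_340_544,
        "3'adapter_null": 4_407,
        "insert_null": 6_029,
        "5'adapter_contaminants": 46_316,
        "smaller_than_18nt": 23_051,
        "polyA": 727,
    },
    "RF": {
        "total_reads": 13_895_311,
        "high_quality": 13_868_830,
        "3'adapter_null": 4_141,
        "insert_null": 1_148,
        "5'adapter_contaminants": 12_104,
        "smaller_than_18nt": 33_526,
        "polyA": 590,
    },
    "NON": {
        "total_reads": 15_310_134,
        "high_quality": 15_288_291,
        "3'adapter_null": 3_703,
        "insert_null": 3_681,
        "5'adapter_contaminants": 93_196,
        "smaller_than_18nt": 32_945,
        "polyA": 1_298,
    },
    "JON": {
        "total_reads": 17_043_189,
        "high_quality": 17_018_648,
        "3'adapter_null": 3_941,
        "insert_null": 2_750,
        "5'adapter_contaminants": 18_866,
        "smaller_than_18nt": 42_170,
        "polyA": 712,
    },
    "NOFF": {
        "total_reads": 15_849_260,
        "high_quality": 15_825_515,
        "3'adapter_null": 4_334,
        "insert_null": 2_995,
        "5'adapter_contaminants": 40_797,
        "smaller_than_18nt": 66_057,
        "polyA": 911,
    },
    "JOFF": {
        "total_reads": 16_064_294,
        "high_quality": 16_041_414,
        "3'adapter_null": 3_937,
        "insert_null": 4_423,
        "5'adapter_contaminants": 38_204,
        "smaller_than_18nt": 62_461,
        "polyA": 529,
    },
}

# Published clean-read totals (the TPM denominators of the experiment).
CLEAN_READ_TOTALS: dict[str, int] = {
    "UF": 15_260_014,
    "RF": 13_817_321,
    "JON": 16_950_209,
    "NON": 15_153_468,
    "JOFF": 15_931_860,
    "NOFF": 15_710_421,
}

# Genome-mapping statistics: unique tags mapped / unique tags, and
# mapped reads / total reads, per library.
MAPPING_STATS: dict[str, dict[str, int]] = {
    "UF": {"unique_mapped": 26_242, "unique_total": 7_933_475,
           "total_mapped": 850_744, "total_reads": 15_260_014},
    "RF": {"unique_mapped": 26_711, "unique_total": 7_423_620,
           "total_mapped": 1_219_147, "total_reads": 13_817_321},
    "JON": {"unique_mapped": 26_735, "unique_total": 6_003_166,
            "total_mapped": 1_876_682, "total_reads": 16_950_209},
    "NON": {"unique_mapped": 22_769, "unique_total": 5_479_750,
            "total_mapped": 1_353_664, "total_reads": 15_153_468},
    "JOFF": {"unique_mapped": 28_383, "unique_total": 6_001_443,
             "total_mapped": 1_412_100, "total_reads": 15_931_860},
    "NOFF": {"unique_mapped": 27_589, "unique_total": 5_535_758,
             "total_mapped": 2_126_303, "total_reads": 15_710_421},
}
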