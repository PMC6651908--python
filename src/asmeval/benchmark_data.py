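"""Published read-accounting tables for the UHRR platform-comparison libraries.

These are the printed per-library numbers from the public DNBseq/HiSeq
Universal Human Reference RNA benchmark (SRA accessions ERR1831362-70,
SRR1261168/70, SRR950078/80/84). They serve as ready-made inputs for the
step-report arithmetic: per-library read counts surviving each
preprocessing step (raw -> quality-filtered -> genome-mapped ->
PCR-deduplicated) and the per-category filtered-out counts.

Counts are in read pairs ("spots" in SRA accounting).
"""

from __future__ import annotations

import pandas as pd

QC_STEPS = ["raw", "filtered", "mapped", "deduplicated"]

# Reads surviving each preprocessing step, per library.
_STEP_ROWS = [
    # platform, library, raw, filtered, mapped, deduplicated
    ("DNBseq", "ERR1831362", 48148821, 45828900, 44015469, 32497907),
    ("DNBseq", "ERR1831363", 29782959, 28352783, 27237354, 21102998),
    ("DNBseq", "ERR1831364", 54940056, 52466727, 50421993, 36693200),
    ("DNBseq", "ERR1831365", 36073210, 34329221, 32932438, 24745818),
    ("DNBseq", "ERR1831366", 43664065, 41782043, 40108615, 29250048),
    ("DNBseq", "ERR1831367", 55025946, 52410892, 50302197, 36153502),
    ("DNBseq", "ERR1831368", 53296161, 50698009, 48688107, 34475744),
    ("DNBseq", "ERR1831369", 65455754, 62428710, 59984288, 41622545),
    ("DNBseq", "ERR1831370", 29774053, 28307062, 27164676, 20606457),
    ("HiSeq", "SRR1261168", 134921154, 104132308, 101903998, 70430950),
    ("HiSeq", "SRR1261170", 72897482, 33367214, 32597422, 27498074),
    ("HiSeq", "SRR950078", 100387010, 77761236, 73979293, 50505406),
    ("HiSeq", "SRR950080", 91781477, 69875633, 66896955, 49310706),
    ("HiSeq", "SRR950084", 125083194, 93367543, 89192069, 61653799),
]

# Reads removed by the quality filter, by removal category, per library.
_CATEGORY_ROWS = [
    # platform, library, adapter, low_quality, ambiguous
    ("DNBseq", "ERR1831362", 125926, 1424492, 769503),
    ("DNBseq", "ERR1831363", 79533, 871008, 479635),
    ("DNBseq", "ERR1831364", 127069, 1476496, 869764),
    ("DNBseq", "ERR1831365", 103994, 1051568, 588427),
    ("DNBseq", "ERR1831366", 110324, 1060462, 711236),
    ("DNBseq", "ERR1831367", 132461, 1581470, 901123),
    ("DNBseq", "ERR1831368", 133444, 1588843, 875865),
    ("DNBseq", "ERR1831369", 152027, 1825708, 1049309),
    ("DNBseq", "ERR1831370", 83674, 898776, 484541),
    ("HiSeq", "SRR1261168", 3497, 30319019, 466900),
    ("HiSeq", "SRR1261170", 509, 33381937, 6147822),
    ("HiSeq", "SRR950078", 1313463, 20004668, 1307643),
    ("HiSeq", "SRR950080", 2022559, 18689016, 1194269),
    ("HiSeq", "SRR950084", 4443842, 25596160, 1675649),
]

# Complete-transcript counts per subset size (Gbp), per library, filled
# in order along the published size grid; libraries smaller than a size
# have no entry there.
COMPLETENESS_SIZE_GRID = [1, 2, 3, 4, 5, 6, 8, 10, 12, 20]

_COMPLETENESS_ROWS: dict[tuple[str, str], list[int]] = {
    ("DNBseq", "COMBINED"): [2483, 3891, 4720, 5276, 5705, 5994, 6458,
                             6716, 6979, 7472],
    ("DNBseq", "ERR1831362"): [2049, 3306, 4140, 4719, 5189, 5530],
    ("DNBseq", "ERR1831363"): [1981, 3235, 4026, 4641],
    ("DNBseq", "ERR1831364"): [2052, 3393, 4253, 4805, 5187, 5527],
    ("DNBseq", "ERR1831365"): [1997, 3295, 4125, 4667],
    ("DNBseq", "ERR1831366"): [1995, 3293, 4111, 4739, 5193],
    ("DNBseq", "ERR1831367"): [2061, 3351, 4173, 4775, 5216, 5511],
    ("DNBseq", "ERR1831368"): [1951, 3304, 4131, 4707, 5164, 5471],
    ("DNBseq", "ERR1831369"): [2032, 3323, 4170, 4772, 5178, 5575, 5989],
    ("DNBseq", "ERR1831370"): [1920, 3260, 4091, 4622],
    ("HiSeq", "SRR1261168"): [2363, 3696, 4483, 4987, 5439, 5720, 6304,
                              6688, 6933],
    ("HiSeq", "SRR1261170"): [1908, 3135, 3908, 4478, 4916, 5107],
    ("HiSeq", "SRR950078"): [809, 1402, 1820, 2190, 2444, 2673, 3024, 3362],
    ("HiSeq", "SRR950080"): [982, 1620, 2126, 2504, 2816, 3094, 3471],
    ("HiSeq", "SRR950084"): [936, 1573, 2068, 2433, 2722, 2985, 3379, 3666],
}

# Abundance-ratio regression inclusion counts (TPM >= 10 in both
# libraries) and their published share of the transcript universe.
ABUNDANCE_INCLUSION = pd.DataFrame(
    [
        ("ERR1831367", "SRR1261168", 9687, 4.75),
        ("ERR1831367", "SRR950078", 11753, 5.77),
    ],
    columns=["library_a", "library_b", "n_included", "pct_of_transcripts"],
)


def step_counts() -> pd.DataFrame:
    """Per-library reads surviving each preprocessing step."""
    return pd.DataFrame(
        _STEP_ROWS, columns=["platform", "library"] + QC_STEPS
    )


def filter_category_counts() -> pd.DataFrame:
    """Per-library reads removed at the quality-filter step, by category."""
    return pd.DataFrame(
        _CATEGORY_ROWS,
        columns=["platform", "library", "adapter", "low_quality", "ambiguous"],
    )


def completeness_counts() -> pd.DataFrame:
    """Complete-transcript counts per library and subset size (long form)."""
    rows = []
    for (platform, library), values in _COMPLETENESS_ROWS.items():
        for size, n in zip(COMPLETENESS_SIZE_GRID, values):
            rows.append((platform, library, size, n))
    return pd.DataFrame(
        rows, columns=["platform", "library", "size_gbp", "n_complete"]
    )
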