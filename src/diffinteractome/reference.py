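"""Reference study-design constants.

Sample counts of the 12 TCGA cohorts (cohorts with at least 30 matched
normal and tumor RNA-seq samples) that the differential-interactome
methodology targets. Used for cohort-size bookkeeping and as realistic
defaults when sizing synthetic cohorts.
"""

from __future__ import annotations

#: cohort abbreviation -> (n_normal, n_tumor)
TCGA_COHORT_SIZES: dict[str, tuple[int, int]] = {
    "BRCA": (113, 1102),
    "COAD": (41, 478),
    "HNSC": (44, 500),
    "KIRC": (72, 538),
    "KIRP": (32, 289),
    "LIHC": (50, 371),
    "LUAD": (59, 533),
    "LUSC": (49, 502),
    "PRAD": (52, 498),
    "STAD": (32, 375),
    "THCA": (58, 502),
    "UCEC": (35, 551),
}


def total_samples() -> tuple[int, int]:
    """(total normal, total tumor) across the 12 cohorts."""
    normals = sum(n for n, _ in TCGA_COHORT_SIZES.values())
    tumors = sum(t for _, t in TCGA_COHORT_SIZES.values())
    return normals, tumors
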