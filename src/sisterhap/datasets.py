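"""Published case-control haplotype tables bundled for examples and tests.

Two classic datasets travel with the package:

* ``il13_breast_cancer`` — haplotype counts over three IL-13 promoter/coding
  variants (−1512 A/C, −1055 C/T, 2044 G/A) in 560 breast-cancer cases and
  354 controls.
* ``ad_apoe`` — EM-estimated haplotype frequencies for four three-SNP
  combinations drawn from markers C19M1/C19M3/C19M4/C19M6 in the ApoE region
  on chromosome 19 (C19M4 tags ApoE-ε4), from 210 Alzheimer-disease cases
  and 159 non-demented controls (420 / 318 haplotypes).

``*_PUBLISHED_CLASSES`` hold the originally reported crossover-class
frequency vectors (P1..P4) per population, usable directly with
:func:`sisterhap.rd_test.rd_statistic`; they differ in the last digits from
vectors recomputed off the bundled tables because the source rounded
frequencies and, for the IL-13 control column, used a slightly smaller
denominator.
"""

from __future__ import annotations

from .hap_table_io import HaplotypeTable

__all__ = [
    "il13_breast_cancer",
    "ad_apoe",
    "AD_COMBINATIONS",
    "IL13_PUBLISHED_CLASSES",
    "AD_PUBLISHED_CLASSES",
]

_IL13_SITES = ("IL13_-1512", "IL13_-1055", "IL13_2044")
_IL13_ROWS = [
    ("ACA", 78, 69),
    ("ATA", 15, 4),
    ("ACG", 302, 182),
    ("ATG", 29, 15),
    ("CCA", 7, 0),
    ("CTA", 72, 50),
    ("CCG", 15, 7),
    ("CTG", 42, 27),
]


def il13_breast_cancer() -> HaplotypeTable:
    """IL-13 three-variant haplotype counts: 560 cases / 354 controls."""
    return HaplotypeTable.from_counts(_IL13_SITES, _IL13_ROWS)


AD_COMBINATIONS = ("M1M3M4*", "M1M4*M6", "M3M4*M6", "M1M3M6")

_AD_SITES = {
    "M1M3M4*": ("C19M1", "C19M3", "C19M4"),
    "M1M4*M6": ("C19M1", "C19M4", "C19M6"),
    "M3M4*M6": ("C19M3", "C19M4", "C19M6"),
    "M1M3M6": ("C19M1", "C19M3", "C19M6"),
}

# (haplotype, case frequency, control frequency); EM-estimated, rounded at
# source (columns are renormalized at load).
_AD_ROWS = {
    "M1M3M4*": [
        ("TCC", 0.013, 0.0),
        ("CCC", 0.023, 0.0),
        ("TTC", 0.110, 0.063),
        ("CTC", 0.141, 0.042),
        ("TCT", 0.285, 0.417),
        ("CCT", 0.288, 0.447),
        ("TTT", 0.124, 0.017),
        ("CTT", 0.014, 0.014),
    ],
    "M1M4*M6": [
        ("CCA", 0.063, 0.0),
        ("CCG", 0.101, 0.042),
        ("CTA", 0.173, 0.221),
        ("CTG", 0.129, 0.240),
        ("TCA", 0.019, 0.007),
        ("TCG", 0.105, 0.056),
        ("TTA", 0.175, 0.258),
        ("TTG", 0.235, 0.176),
    ],
    "M3M4*M6": [
        ("CCA", 0.030, 0.0),
        ("CCG", 0.006, 0.0),
        ("CTA", 0.343, 0.477),
        ("CTG", 0.230, 0.387),
        ("TCA", 0.052, 0.007),
        ("TCG", 0.200, 0.098),
        ("TTA", 0.005, 0.002),
        ("TTG", 0.133, 0.029),
    ],
    "M1M3M6": [
        ("CCA", 0.211, 0.219),
        ("CCG", 0.139, 0.228),
        ("CTA", 0.055, 0.002),
        ("CTG", 0.120, 0.054),
        ("TCA", 0.209, 0.258),
        ("TCG", 0.127, 0.159),
        ("TTA", 0.009, 0.007),
        ("TTG", 0.255, 0.073),
    ],
}

# Case/control sizes in haplotypes (two per subject).
AD_N_CASE = 420.0
AD_N_CONTROL = 318.0


def ad_apoe(combination: str) -> HaplotypeTable:
    """One of the four three-SNP ApoE-region combinations (frequency mode)."""
    if combination not in AD_COMBINATIONS:
        raise KeyError(
            f"unknown combination {combination!r}; expected one of {AD_COMBINATIONS}"
        )
    return HaplotypeTable.from_frequencies(
        _AD_SITES[combination],
        _AD_ROWS[combination],
        n_case=AD_N_CASE,
        n_control=AD_N_CONTROL,
    )


# Originally reported crossover-class frequency vectors (P1, P2, P3, P4).
IL13_PUBLISHED_CLASSES = {
    "overall": (0.67016, 0.246273, 0.042728, 0.053882),
    "control": (0.672464, 0.278261, 0.031884, 0.043478),
    "case": (0.667857, 0.214286, 0.053571, 0.064286),
}

AD_PUBLISHED_CLASSES = {
    ("M1M3M4*", "overall"): (0.475, 0.032, 0.472, 0.023),
    ("M1M3M4*", "case"): (0.398, 0.148, 0.427, 0.028),
    ("M1M3M4*", "control"): (0.510, 0.017, 0.459, 0.014),
    ("M1M4*M6", "overall"): (0.305, 0.199, 0.292, 0.206),
    ("M1M4*M6", "case"): (0.276, 0.297, 0.278, 0.146),
    ("M1M4*M6", "control"): (0.300, 0.176, 0.277, 0.247),
    ("M3M4*M6", "overall"): (0.589, 0.358, 0.008, 0.047),
    ("M3M4*M6", "case"): (0.5431, 0.2818, 0.0116, 0.1636),
    ("M3M4*M6", "control"): (0.575, 0.394, 0.002, 0.029),
    ("M1M3M6", "overall"): (0.320, 0.175, 0.316, 0.191),
    ("M1M3M6", "case"): (0.329, 0.182, 0.466, 0.148),
    ("M1M3M6", "control"): (0.312, 0.161, 0.292, 0.235),
}

# Originally reported RD values matching the vectors above, for cross-checks.
AD_PUBLISHED_RD = {
    ("M1M3M4*", "overall"): -0.0042,
    ("M1M3M4*", "case"): -0.052,
    ("M1M3M4*", "control"): -0.0007,
    ("M1M4*M6", "overall"): 0.0047,
    ("M1M4*M6", "case"): -0.042,
    ("M1M4*M6", "control"): 0.0253,
    ("M3M4*M6", "overall"): 0.0248,
    ("M3M4*M6", "case"): 0.086,
    ("M3M4*M6", "control"): 0.0159,
    ("M1M3M6", "overall"): 0.0058,
    ("M1M3M6", "case"): -0.036,
    ("M1M3M6", "control"): 0.0263,
}

IL13_PUBLISHED_RD = {"overall": 0.02591, "control": 0.020365, "case": 0.031454}
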