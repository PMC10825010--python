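"""Recombination-disequilibrium (RD) statistic and its chi-square test.

With the four crossover-class frequencies P1 (parental), P2, P3 (single
crossovers) and P4 (double crossover), the interval recombination fractions
are R1 = P3 + P4 and R2 = P2 + P4, and the RD statistic is

    Dr = P1·P4 − P2·P3 = P4 − R1·R2 ,

the departure of the double-crossover frequency from its expectation under
independent crossing-over in the two intervals. Dr = 0 means no interference
(coefficient of coincidence c = 1); Dr < 0 positive interference (c < 1);
Dr > 0 negative interference (c > 1). In fact Dr = (c − 1)·R1·R2 exactly.

The test is the df=1 chi-square for independence of crossover events in the
two intervals: a goodness-of-fit over the four classes against expected
counts E1 = n(1−R1)(1−R2), E2 = n(1−R1)R2, E3 = nR1(1−R2), E4 = nR1R2,
algebraically identical to n·Dr² / (R1(1−R1)·R2(1−R2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .hap_table_io import HaplotypeTable, validate_table
from .sister_recode import (
    CollapsedClasses,
    collapse_classes,
    enumerate_sister_pairs,
    recode,
    select_parental,
)

__all__ = [
    "RDResult",
    "RDTestUndefinedError",
    "NotRDTestableError",
    "rd_statistic",
    "rd_chisq",
    "rd_result_from_classes",
    "rd_analysis",
]


class RDTestUndefinedError(ValueError):
    """Degenerate margins: an interval has no recombinants or no non-recombinants."""


class NotRDTestableError(ValueError):
    """Fewer than 7 haplotype classes observed; sister pairs cannot be formed."""


@dataclass
class RDResult:
    """RD statistic and df=1 chi-square test for one population."""

    population: str
    P: np.ndarray
    Dr: float
    R1: float
    R2: float
    chisq: float
    p_value: float
    n: float
    df: int = 1


def rd_statistic(P: Sequence[float], factor4: bool = False) -> float:
    """RD statistic from the 4 crossover-class frequencies (P1, P2, P3, P4).

    Default is Dr = P1·P4 − P2·P3 on sister-collapsed class frequencies, the
    form under which Dr = P4 − R1·R2 and Dr = (c−1)·R1·R2. ``factor4`` selects
    the variant 4·P1·P4 − P2·P3 for comparison with legacy reports; it does
    not satisfy those identities and is off by default.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (4,):
        raise ValueError("P must have exactly 4 class frequencies")
    if factor4:
        return float(4.0 * P[0] * P[3] - P[1] * P[2])
    return float(P[0] * P[3] - P[1] * P[2])


def recombination_fractions(P: Sequence[float]) -> tuple[float, float]:
    """Interval recombination fractions (R1, R2) = (P3+P4, P2+P4)."""
    P = np.asarray(P, dtype=float)
    return float(P[2] + P[3]), float(P[1] + P[3])


def rd_chisq(classes: CollapsedClasses) -> tuple[float, float]:
    """df=1 chi-square testing independence of crossovers in the two intervals.

    Computed as the goodness-of-fit statistic over the four observed class
    counts against expectations from the marginal recombination fractions.
    Raises :class:`RDTestUndefinedError` when either interval has margin 0 or
    1 (no recombinants, or no non-recombinants).
    """
    n = classes.n
    if n <= 0:
        raise ZeroDivisionError("zero total count")
    R1, R2 = recombination_fractions(classes.P)
    if R1 <= 0 or R1 >= 1 or R2 <= 0 or R2 >= 1:
        raise RDTestUndefinedError(
            "RD test undefined: no recombinants/non-recombinants in an interval"
        )
    expected = n * np.array(
        [(1 - R1) * (1 - R2), (1 - R1) * R2, R1 * (1 - R2), R1 * R2]
    )
    observed = classes.counts
    chisq = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chisq, df=1))
    return chisq, p


def rd_result_from_classes(classes: CollapsedClasses) -> RDResult:
    """Full RD result (statistic + test) for one collapsed population."""
    R1, R2 = recombination_fractions(classes.P)
    chisq, p = rd_chisq(classes)
    return RDResult(
        population=classes.population,
        P=classes.P.copy(),
        Dr=rd_statistic(classes.P),
        R1=R1,
        R2=R2,
        chisq=chisq,
        p_value=p,
        n=classes.n,
    )


def rd_analysis(
    table: HaplotypeTable,
    populations: Sequence[str] = ("case", "control", "overall"),
) -> list[RDResult]:
    """Run the RD test in each population of a three-site haplotype table.

    The pipeline is: parental selection → letter recoding → sister pairing →
    class collapse → chi-square, with ``overall`` computed on pooled counts.
    Tables with fewer than 7 observed haplotype classes are rejected.
    """
    report = validate_table(table)
    if not report.rd_testable:
        raise NotRDTestableError(
            f"only {report.n_classes_observed} haplotype classes observed; "
            "at least 7 are required for the RD test"
        )
    parental = select_parental(table)
    recoded = recode(table, parental)
    pairing = enumerate_sister_pairs(recoded)
    return [
        rd_result_from_classes(collapse_classes(recoded, pairing, pop))  # type: ignore[arg-type]
        for pop in populations
    ]
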