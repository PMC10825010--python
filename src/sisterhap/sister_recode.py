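"""Translate DNA haplotypes to genetic (capital/lower) notation and pair sisters.

For three biallelic SNP sites, the haplotypes are recoded with one letter pair
per site (A/a, B/b, C/c), uppercase for the allele carried by the *parental*
haplotype — the most frequent one — and lowercase for the alternate allele.
Two haplotypes are *sisters* when they carry opposite alleles at every site
(full case complement), like the two gamete types of a single meiosis.

The 8 three-site genotype strings then partition into 4 sister pairs, the
classical three-point-cross classes anchored on parental ABC:

====  ============  =========================================
P1    {ABC, abc}    parental (non-recombinant)
P2    {ABc, abC}    single crossover in interval 2 (sites 2-3)
P3    {Abc, aBC}    single crossover in interval 1 (sites 1-2)
P4    {AbC, aBc}    double crossover
====  ============  =========================================
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .hap_table_io import HaplotypeTable, NoDataError

GENO_LETTERS = string.ascii_uppercase

CLASS_LABELS = (
    "parental",
    "single_crossover_2",
    "single_crossover_1",
    "double_crossover",
)

Population = Literal["case", "control", "overall"]

__all__ = [
    "RecodedTable",
    "RecodedRow",
    "SisterPairing",
    "CollapsedClasses",
    "RecodeError",
    "MonomorphicSiteError",
    "MultiAllelicSiteError",
    "ParentalNotFoundError",
    "PairingError",
    "ZeroTotalError",
    "select_parental",
    "recode",
    "complement",
    "enumerate_sister_pairs",
    "collapse_classes",
]


class RecodeError(ValueError):
    """Base class for recoding failures."""


class MonomorphicSiteError(RecodeError):
    """A site shows a single observed allele; no letter pair can be assigned."""


class MultiAllelicSiteError(RecodeError):
    """A site shows more than two observed alleles."""


class ParentalNotFoundError(RecodeError):
    """The designated parental haplotype is not in the table."""


class PairingError(ValueError):
    """Sister-pair enumeration requested for m != 3."""


class ZeroTotalError(ValueError):
    """A population has zero total haplotype count."""


@dataclass(frozen=True)
class SiteLetters:
    """Per-site allele → letter assignment (upper = parental allele)."""

    upper_allele: str
    lower_allele: str


@dataclass(frozen=True)
class RecodedRow:
    dna: str
    geno: str
    case_count: float
    control_count: float


@dataclass
class RecodedTable:
    """A haplotype table in genotype-letter notation, anchored on the parental."""

    site_ids: list[str]
    site_letters: list[SiteLetters]
    parental: str
    rows: list[RecodedRow]

    @property
    def m(self) -> int:
        return len(self.site_letters)

    def geno_to_dna(self, geno: str) -> str:
        """Map any genotype string (observed or not) back to DNA bases."""
        if len(geno) != self.m:
            raise RecodeError(f"genotype string {geno!r} has wrong length")
        bases = []
        for i, ch in enumerate(geno):
            letters = self.site_letters[i]
            if ch == GENO_LETTERS[i]:
                bases.append(letters.upper_allele)
            elif ch == GENO_LETTERS[i].lower():
                bases.append(letters.lower_allele)
            else:
                raise RecodeError(f"invalid letter {ch!r} at site {i + 1} in {geno!r}")
        return "".join(bases)

    def counts(self, population: Population) -> dict[str, float]:
        """Per-genotype counts for one population (overall = pooled)."""
        if population == "case":
            return {r.geno: r.case_count for r in self.rows}
        if population == "control":
            return {r.geno: r.control_count for r in self.rows}
        if population == "overall":
            return {r.geno: r.case_count + r.control_count for r in self.rows}
        raise ValueError(f"unknown population {population!r}")


@dataclass
class SisterPairing:
    """The four sister pairs of a three-site system, in class order P1..P4.

    Each pair is (unprimed, primed) where the unprimed member is the one whose
    first letter is uppercase; the primed member is its full complement.
    """

    pairs: list[tuple[str, str]]
    class_labels: dict[tuple[str, str], str]
    dna_pairs: list[tuple[str, str]]

    def pair_for(self, geno: str) -> tuple[int, tuple[str, str]]:
        for i, pair in enumerate(self.pairs):
            if geno in pair:
                return i, pair
        raise PairingError(f"genotype {geno!r} not in any sister pair")


@dataclass
class CollapsedClasses:
    """Crossover-class frequencies P1..P4 for one population."""

    P: np.ndarray  # shape (4,), frequencies summing to 1
    counts: np.ndarray  # shape (4,), class counts
    n: float
    population: str


def select_parental(table: HaplotypeTable) -> str:
    """Return the parental haplotype: largest pooled (case+control) count.

    Ties are broken toward the lexicographically smallest haplotype.
    """
    if not table.rows:
        raise NoDataError("empty table")
    return min(table.rows, key=lambda r: (-r.pooled, r.haplotype)).haplotype


def recode(table: HaplotypeTable, parental: str) -> RecodedTable:
    """Recode DNA haplotypes to per-site letter notation anchored on ``parental``.

    At site *i*, the parental base maps to the uppercase letter (A, B, C, ...)
    and the alternate base to the lowercase letter; the parental haplotype is
    therefore all-uppercase. Raises on monomorphic or multi-allelic sites.
    """
    if parental not in table.haplotypes:
        raise ParentalNotFoundError(f"parental haplotype {parental!r} not in table")
    if table.m > len(GENO_LETTERS):
        raise RecodeError("too many sites to letter-code")
    alleles = table.site_alleles()
    site_letters: list[SiteLetters] = []
    for i, (sid, site_al) in enumerate(zip(table.site_ids, alleles)):
        if len(site_al) > 2:
            raise MultiAllelicSiteError(f"site {sid} has alleles {sorted(site_al)}")
        others = site_al - {parental[i]}
        if not others:
            raise MonomorphicSiteError(f"site {sid} is monomorphic: only {parental[i]!r} observed")
        site_letters.append(SiteLetters(upper_allele=parental[i], lower_allele=others.pop()))
    rows = []
    for row in table.rows:
        geno = "".join(
            GENO_LETTERS[i] if base == site_letters[i].upper_allele else GENO_LETTERS[i].lower()
            for i, base in enumerate(row.haplotype)
        )
        rows.append(RecodedRow(row.haplotype, geno, row.case_count, row.control_count))
    return RecodedTable(
        site_ids=list(table.site_ids),
        site_letters=site_letters,
        parental=parental,
        rows=rows,
    )


def complement(geno: str) -> str:
    """Sister (full complement) of a genotype string: flip case at every site."""
    for i, ch in enumerate(geno):
        if ch.upper() != GENO_LETTERS[i]:
            raise RecodeError(f"invalid character {ch!r} at position {i} in {geno!r}")
    return geno.swapcase()


def enumerate_sister_pairs(recoded: RecodedTable) -> SisterPairing:
    """Enumerate the four sister pairs of a three-site system in class order.

    The pairs partition all 8 genotype strings; the class of a pair is read
    off the unprimed member's case pattern relative to parental ABC.
    """
    if recoded.m != 3:
        raise PairingError(f"sister pairing requires exactly 3 sites, got {recoded.m}")
    unprimed = ["ABC", "ABc", "Abc", "AbC"]  # P1, P2, P3, P4
    pairs = [(h, complement(h)) for h in unprimed]
    class_labels = dict(zip(pairs, CLASS_LABELS))
    dna_pairs = [(recoded.geno_to_dna(h), recoded.geno_to_dna(hp)) for h, hp in pairs]
    return SisterPairing(pairs=pairs, class_labels=class_labels, dna_pairs=dna_pairs)


def collapse_classes(
    recoded: RecodedTable,
    pairing: SisterPairing,
    population: Population,
) -> CollapsedClasses:
    """Collapse sister pairs into crossover-class frequencies P1..P4.

    P_i = (count(h_i) + count(complement(h_i))) / n for the requested
    population; ``overall`` pools case and control counts. Unobserved
    haplotypes contribute zero.
    """
    counts = recoded.counts(population)
    class_counts = np.array(
        [counts.get(h, 0.0) + counts.get(hp, 0.0) for h, hp in pairing.pairs]
    )
    n = float(class_counts.sum())
    if n <= 0:
        raise ZeroTotalError(f"zero total count in population {population!r}")
    return CollapsedClasses(
        P=class_counts / n,
        counts=class_counts,
        n=n,
        population=population,
    )
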