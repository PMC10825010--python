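"""2×2 haplotype-pair association tests: odds ratio, Wald Z, Yates chi-square.

A haplotype pair and the case/control split form a 2×2 table

              h1   h2
    case       a    b
    control    c    d

Three pairing schemes are supported:

``sister``
    the biologically motivated scheme: the four sister (full-complement)
    pairs of a three-site system, h1 being the pair member with more
    parental (uppercase) alleles;
``individual_common``
    a target haplotype against the single most frequent haplotype;
``individual_others``
    a target haplotype against the pooled sum of all remaining haplotypes.

The latter two are implemented for comparison: only one haplotype is a
genuine biological partner (the full complement) of the common haplotype, so
those schemes can manufacture spurious associations.

The default 2×2 chi-square uses the Yates continuity correction with the
correction term clamped at zero; the uncorrected statistic is also reported
for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .hap_table_io import HaplotypeTable
from .sister_recode import SisterPairing, enumerate_sister_pairs, recode, select_parental

__all__ = [
    "Counts2x2",
    "AssocResult",
    "ZeroMarginError",
    "SchemeError",
    "build_2x2",
    "odds_ratio",
    "wald_z",
    "plain_chisq",
    "yates_chisq",
    "associate",
]


class ZeroMarginError(ValueError):
    """A row or column margin of the 2×2 table is zero."""


class SchemeError(ValueError):
    """Invalid pairing-scheme request (e.g. target equals the common haplotype)."""


@dataclass(frozen=True)
class Counts2x2:
    """One 2×2 table in fixed orientation (rows case/control, cols h1/h2)."""

    a: float
    b: float
    c: float
    d: float
    h1: str = "h1"
    h2: str = "h2"
    label: str = ""


@dataclass
class AssocResult:
    """Association statistics for one haplotype pair."""

    scheme: str
    h1: str
    h2: str
    label: str
    a: float
    b: float
    c: float
    d: float
    odds_ratio: float | None
    z: float | None
    p_z: float | None
    chisq_yates: float | None
    p_chisq: float | None
    chisq_plain: float | None
    p_chisq_plain: float | None
    p_adj: float | None = None


def _abcd(counts: Counts2x2 | Sequence[float]) -> tuple[float, float, float, float]:
    if isinstance(counts, Counts2x2):
        return counts.a, counts.b, counts.c, counts.d
    a, b, c, d = counts
    return float(a), float(b), float(c), float(d)


def odds_ratio(
    counts: Counts2x2 | Sequence[float], haldane: bool = False
) -> float | None:
    """Odds ratio (a·d)/(b·c); ``None`` (reported NA) when a·d or b·c is zero.

    ``haldane`` applies the Haldane–Anscombe +0.5 to every cell first, making
    the ratio always defined; off by default to mirror NA-style reporting.
    """
    a, b, c, d = _abcd(counts)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0 or a * d == 0:
        return None
    return (a * d) / (b * c)


def wald_z(counts: Counts2x2 | Sequence[float]) -> tuple[float | None, float | None]:
    """Wald test of log-OR: Z = |ln OR| / sqrt(1/a+1/b+1/c+1/d), two-sided p.

    Undefined (None, None) when any cell is zero.
    """
    a, b, c, d = _abcd(counts)
    if min(a, b, c, d) <= 0:
        return None, None
    z = abs(math.log((a * d) / (b * c))) / math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return z, float(2.0 * stats.norm.sf(z))


def _margins(a: float, b: float, c: float, d: float):
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ZeroMarginError("2x2 table has a zero margin")
    return n, r1, r2, c1, c2


def plain_chisq(counts: Counts2x2 | Sequence[float]) -> tuple[float, float]:
    """Uncorrected Pearson chi-square of the 2×2 table, df=1 upper-tail p."""
    a, b, c, d = _abcd(counts)
    n, r1, r2, c1, c2 = _margins(a, b, c, d)
    chisq = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


def yates_chisq(counts: Counts2x2 | Sequence[float]) -> tuple[float, float]:
    """Yates-corrected chi-square: N·(max(0, |ad−bc| − N/2))² / (r1·r2·c1·c2)."""
    a, b, c, d = _abcd(counts)
    n, r1, r2, c1, c2 = _margins(a, b, c, d)
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    chisq = n * num**2 / (r1 * r2 * c1 * c2)
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


def _sister_orientation(pair: tuple[str, str]) -> tuple[str, str]:
    """h1 = pair member with more parental (uppercase) alleles."""
    h, hp = pair
    return (h, hp) if sum(ch.isupper() for ch in h) >= sum(ch.isupper() for ch in hp) else (hp, h)


def build_2x2(
    table: HaplotypeTable,
    pairing: SisterPairing | None = None,
    scheme: str = "sister",
    target: str | None = None,
) -> Counts2x2:
    """Build one 2×2 table under a pairing scheme.

    For ``sister``, ``target`` names either member of the pair (DNA or
    genotype string). For ``individual_common`` and ``individual_others``,
    ``target`` is the DNA haplotype of interest; the reference is the most
    frequent haplotype, or the pooled remainder, respectively.
    """
    case = table.case_counts()
    ctrl = table.control_counts()
    if scheme == "sister":
        if pairing is None:
            raise SchemeError("sister scheme requires a SisterPairing")
        if target is None:
            raise SchemeError("sister scheme requires a target haplotype")
        for pair, dna_pair in zip(pairing.pairs, pairing.dna_pairs):
            if target in pair or target in dna_pair:
                geno_by_dna = dict(zip(dna_pair, pair))
                dna_by_geno = dict(zip(pair, dna_pair))
                g1, g2 = _sister_orientation(pair)
                h1, h2 = dna_by_geno[g1], dna_by_geno[g2]
                return Counts2x2(
                    a=case.get(h1, 0.0), b=case.get(h2, 0.0),
                    c=ctrl.get(h1, 0.0), d=ctrl.get(h2, 0.0),
                    h1=h1, h2=h2, label=f"{g1}/{g2}",
                )
        raise SchemeError(f"target {target!r} not in any sister pair")
    if target is None or target not in case:
        raise SchemeError(f"unknown target haplotype {target!r}")
    if scheme == "individual_common":
        common = select_parental(table)
        if target == common:
            raise SchemeError(
                f"target {target!r} is itself the common haplotype"
            )
        return Counts2x2(
            a=case[target], b=case[common], c=ctrl[target], d=ctrl[common],
            h1=target, h2=common, label=f"{target}/common:{common}",
        )
    if scheme == "individual_others":
        return Counts2x2(
            a=case[target], b=table.total_case - case[target],
            c=ctrl[target], d=table.total_control - ctrl[target],
            h1=target, h2="others", label=f"{target}/others",
        )
    raise SchemeError(f"unknown scheme {scheme!r}")


def _result(scheme: str, counts: Counts2x2, haldane: bool) -> AssocResult:
    orr = odds_ratio(counts, haldane=haldane)
    z, p_z = wald_z(counts)
    try:
        chisq_y, p_y = yates_chisq(counts)
        chisq_p, p_p = plain_chisq(counts)
    except ZeroMarginError:
        chisq_y = p_y = chisq_p = p_p = None
    return AssocResult(
        scheme=scheme, h1=counts.h1, h2=counts.h2, label=counts.label,
        a=counts.a, b=counts.b, c=counts.c, d=counts.d,
        odds_ratio=orr, z=z, p_z=p_z,
        chisq_yates=chisq_y, p_chisq=p_y,
        chisq_plain=chisq_p, p_chisq_plain=p_p,
    )


def associate(
    table: HaplotypeTable,
    pairing: SisterPairing | None = None,
    scheme: str = "sister",
    target: str | None = None,
    haldane: bool = False,
    bh_adjust: bool = False,
) -> list[AssocResult]:
    """Association results for every pair under a scheme.

    ``sister`` yields 4 results in class order P1..P4 (deriving the pairing
    from the table when not supplied); the individual schemes yield one
    result per non-reference haplotype, or a single result when ``target``
    is given. ``bh_adjust`` adds Benjamini–Hochberg adjusted chi-square
    p-values (raw p is the default report).
    """
    results: list[AssocResult] = []
    if scheme == "sister":
        if pairing is None:
            pairing = enumerate_sister_pairs(recode(table, select_parental(table)))
        targets = [dna for dna, _ in pairing.dna_pairs]
        if target is not None:
            targets = [target]
        for t in targets:
            results.append(_result(scheme, build_2x2(table, pairing, scheme, t), haldane))
    elif scheme in ("individual_common", "individual_others"):
        common = select_parental(table)
        if target is not None:
            targets = [target]
        elif scheme == "individual_common":
            targets = [h for h in table.haplotypes if h != common]
        else:
            targets = list(table.haplotypes)
        for t in targets:
            results.append(_result(scheme, build_2x2(table, None, scheme, t), haldane))
    else:
        raise SchemeError(f"unknown scheme {scheme!r}")
    if bh_adjust:
        ps = [r.p_chisq for r in results]
        defined = [i for i, p in enumerate(ps) if p is not None]
        if defined:
            adj = stats.false_discovery_control([ps[i] for i in defined], method="bh")
            for i, p in zip(defined, adj):
                results[i].p_adj = float(p)
    return results
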