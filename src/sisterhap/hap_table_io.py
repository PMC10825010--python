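"""Reading, validating and writing case/control haplotype tables and result reports.

A haplotype table is the universal input record of this package: one row per
haplotype string over *m* biallelic SNP sites, with real-valued case and
control counts (real-valued because haplotype frequencies are usually
EM-estimated upstream and arrive as frequency × sample size).

Input is delimited text (TSV or CSV)::

    #sites: rs123,rs456,rs789
    haplotype	case_count	control_count
    ACA	78	69
    ...

Frequency input uses columns ``case_freq``/``control_freq`` and requires the
haplotype sample sizes ``n_case``/``n_control``; each frequency column is
normalized to sum to one and converted once to pseudo-counts freq × n, so all
downstream code sees counts only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

__all__ = [
    "HaplotypeTable",
    "HapRow",
    "ValidationReport",
    "HaplotypeTableError",
    "NoDataError",
    "RowLengthMismatchError",
    "DuplicateHaplotypeError",
    "NegativeCountError",
    "MissingSampleSizeError",
    "InvalidAlleleError",
    "EmptyResultsError",
    "read_haplotype_table",
    "write_haplotype_table",
    "validate_table",
    "write_report",
    "format_number",
]


class HaplotypeTableError(ValueError):
    """Base class for malformed haplotype-table input."""


class NoDataError(HaplotypeTableError):
    """The input contains no data rows."""


class RowLengthMismatchError(HaplotypeTableError):
    """A haplotype string's length disagrees with the number of sites."""


class DuplicateHaplotypeError(HaplotypeTableError):
    """The same haplotype string appears in more than one row."""


class NegativeCountError(HaplotypeTableError):
    """A count or frequency is negative."""


class MissingSampleSizeError(HaplotypeTableError):
    """Frequency-mode input without explicit n_case / n_control."""


class InvalidAlleleError(HaplotypeTableError):
    """A haplotype contains a character outside {A, C, G, T}."""


class EmptyResultsError(ValueError):
    """write_report called with no results."""


@dataclass(frozen=True)
class HapRow:
    """One haplotype with its case and control counts."""

    haplotype: str
    case_count: float
    control_count: float

    @property
    def pooled(self) -> float:
        return self.case_count + self.control_count


@dataclass
class HaplotypeTable:
    """Case/control haplotype counts over ``m`` biallelic SNP sites.

    ``counts_are_frequencies`` records provenance only: when True the counts
    were derived from a frequency table as normalized frequency × n.
    """

    site_ids: list[str]
    rows: list[HapRow]
    n_case: float
    n_control: float
    counts_are_frequencies: bool = False

    @property
    def m(self) -> int:
        return len(self.site_ids)

    @property
    def haplotypes(self) -> list[str]:
        return [r.haplotype for r in self.rows]

    def case_counts(self) -> dict[str, float]:
        return {r.haplotype: r.case_count for r in self.rows}

    def control_counts(self) -> dict[str, float]:
        return {r.haplotype: r.control_count for r in self.rows}

    @property
    def total_case(self) -> float:
        return sum(r.case_count for r in self.rows)

    @property
    def total_control(self) -> float:
        return sum(r.control_count for r in self.rows)

    def site_alleles(self) -> list[set[str]]:
        """Distinct bases observed at each site (rows with positive pooled count)."""
        alleles: list[set[str]] = [set() for _ in self.site_ids]
        for row in self.rows:
            if row.pooled > 0:
                for i, base in enumerate(row.haplotype):
                    alleles[i].add(base)
        return alleles

    @classmethod
    def from_counts(
        cls,
        site_ids: Sequence[str],
        rows: Iterable[tuple[str, float, float]],
        n_case: float | None = None,
        n_control: float | None = None,
    ) -> "HaplotypeTable":
        hap_rows = [HapRow(h, float(a), float(b)) for h, a, b in rows]
        table = cls(
            site_ids=list(site_ids),
            rows=hap_rows,
            n_case=float(n_case) if n_case is not None else sum(r.case_count for r in hap_rows),
            n_control=float(n_control) if n_control is not None else sum(r.control_count for r in hap_rows),
        )
        _check_table(table)
        return table

    @classmethod
    def from_frequencies(
        cls,
        site_ids: Sequence[str],
        rows: Iterable[tuple[str, float, float]],
        n_case: float,
        n_control: float,
    ) -> "HaplotypeTable":
        """Build a table from per-population frequencies.

        Each frequency column is renormalized to sum to one (published tables
        are often rounded and sum slightly off) and converted to pseudo-counts
        frequency × n.
        """
        rows = list(rows)
        if not rows:
            raise NoDataError("no data rows")
        case = np.array([r[1] for r in rows], dtype=float)
        ctrl = np.array([r[2] for r in rows], dtype=float)
        if (case < 0).any() or (ctrl < 0).any():
            raise NegativeCountError("negative frequency")
        if case.sum() <= 0 or ctrl.sum() <= 0:
            raise NoDataError("a frequency column sums to zero")
        case = case / case.sum() * float(n_case)
        ctrl = ctrl / ctrl.sum() * float(n_control)
        hap_rows = [HapRow(r[0], a, b) for r, a, b in zip(rows, case, ctrl)]
        table = cls(
            site_ids=list(site_ids),
            rows=hap_rows,
            n_case=float(n_case),
            n_control=float(n_control),
            counts_are_frequencies=True,
        )
        _check_table(table)
        return table


@dataclass
class ValidationReport:
    """Report-only quality summary of a haplotype table."""

    site_alleles: list[set[str]]
    removed_sites: list[str]
    n_classes_observed: int
    rd_testable: bool
    messages: list[str] = field(default_factory=list)


def _check_table(table: HaplotypeTable) -> None:
    if not table.rows:
        raise NoDataError("no data rows")
    m = table.m
    seen: set[str] = set()
    for row in table.rows:
        if len(row.haplotype) != m:
            raise RowLengthMismatchError(
                f"row length mismatch: {row.haplotype!r} has {len(row.haplotype)} sites, expected {m}"
            )
        bad = set(row.haplotype) - VALID_BASES
        if bad:
            raise InvalidAlleleError(
                f"invalid allele(s) {sorted(bad)} in haplotype {row.haplotype!r}"
            )
        if row.haplotype in seen:
            raise DuplicateHaplotypeError(f"duplicate haplotype {row.haplotype!r}")
        seen.add(row.haplotype)
        if row.case_count < 0 or row.control_count < 0:
            raise NegativeCountError(f"negative count in row {row.haplotype!r}")


def read_haplotype_table(
    path: str | Path,
    *,
    n_case: float | None = None,
    n_control: float | None = None,
    sep: str | None = None,
) -> HaplotypeTable:
    """Read a delimited haplotype table (see module docstring for the format).

    Parameters
    ----------
    path
        TSV or CSV file; the delimiter is sniffed unless ``sep`` is given.
    n_case, n_control
        Total haplotype sample sizes. Required for frequency-mode input
        (columns ``case_freq``/``control_freq``); optional for count input,
        where they default to the column sums.
    """
    text = Path(path).read_text()
    site_ids: list[str] | None = None
    data_lines: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.lower().startswith("#sites:"):
            spec = stripped.split(":", 1)[1]
            site_ids = [s.strip() for s in spec.replace("\t", ",").split(",") if s.strip()]
        elif stripped.startswith("#") or not stripped:
            continue
        else:
            data_lines.append(line)
    if len(data_lines) <= 1:
        raise NoDataError(f"no data rows in {path}")
    df = pd.read_csv(
        io.StringIO("\n".join(data_lines)),
        sep=sep,
        engine="python",
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "haplotype" not in df.columns:
        raise HaplotypeTableError("missing required column 'haplotype'")

    freq_mode = "case_freq" in df.columns or "control_freq" in df.columns
    if freq_mode:
        for col in ("case_freq", "control_freq"):
            if col not in df.columns:
                raise HaplotypeTableError(f"missing required column {col!r}")
        if n_case is None or n_control is None:
            raise MissingSampleSizeError(
                "frequency input requires explicit n_case and n_control"
            )
        case_col, ctrl_col = "case_freq", "control_freq"
    else:
        for col in ("case_count", "control_count"):
            if col not in df.columns:
                raise HaplotypeTableError(f"missing required column {col!r}")
        case_col, ctrl_col = "case_count", "control_count"

    haps = [str(h).strip() for h in df["haplotype"]]
    if any(h != h.upper() for h in haps):
        warnings.warn("lowercase haplotype input upcased", stacklevel=2)
        haps = [h.upper() for h in haps]
    if site_ids is None:
        m = len(haps[0]) if haps else 0
        site_ids = [f"S{i + 1}" for i in range(m)]
    rows = list(zip(haps, df[case_col].astype(float), df[ctrl_col].astype(float)))
    if freq_mode:
        assert n_case is not None and n_control is not None
        return HaplotypeTable.from_frequencies(site_ids, rows, n_case, n_control)
    return HaplotypeTable.from_counts(site_ids, rows, n_case, n_control)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a table as TSV, round-trip readable via :func:`read_haplotype_table`."""
    with open(path, "w") as fh:
        fh.write("#sites: " + ",".join(table.site_ids) + "\n")
        fh.write("haplotype\tcase_count\tcontrol_count\n")
        for row in table.rows:
            fh.write(f"{row.haplotype}\t{row.case_count!r}\t{row.control_count!r}\n")


def validate_table(table: HaplotypeTable) -> ValidationReport:
    """Quality-check a table without mutating it.

    Flags multi-allelic sites for removal (the removal itself is performed by
    triplet dissection or the caller), counts observed haplotype classes
    (pooled count > 0), and decides RD testability: fewer than 7 observed
    classes cannot form a valid sister-pair system.
    """
    alleles = table.site_alleles()
    removed = [sid for sid, al in zip(table.site_ids, alleles) if len(al) > 2]
    n_classes = sum(1 for r in table.rows if r.pooled > 0)
    messages = []
    for sid, al in zip(table.site_ids, alleles):
        if len(al) > 2:
            messages.append(f"site {sid} is multi-allelic ({'/'.join(sorted(al))}): flagged for removal")
        elif len(al) < 2:
            messages.append(f"site {sid} is monomorphic ({'/'.join(sorted(al))})")
    if n_classes < 7:
        messages.append(
            f"only {n_classes} haplotype classes observed: fewer than 7 classes "
            "cannot construct valid sister pairs, RD test unavailable"
        )
    return ValidationReport(
        site_alleles=alleles,
        removed_sites=removed,
        n_classes_observed=n_classes,
        rd_testable=n_classes >= 7,
        messages=messages,
    )


def format_number(x: object) -> str:
    """Render a report value: 6 significant digits, NA for undefined."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


_RD_COLUMNS = [
    "population", "P1", "P2", "P3", "P4", "R1", "R2",
    "Dr", "chisq", "df", "p_value", "n",
]
_ASSOC_COLUMNS = [
    "scheme", "pair", "a", "b", "c", "d", "OR", "Z", "p_Z",
    "chisq_yates", "chisq_plain", "p_chisq",
]


def report_frames(results: Iterable[object]) -> dict[str, pd.DataFrame]:
    """Split mixed RD / association results into per-section data frames."""
    rd_rows, assoc_rows = [], []
    for res in results:
        if hasattr(res, "Dr"):
            rd_rows.append({
                "population": res.population,
                "P1": res.P[0], "P2": res.P[1], "P3": res.P[2], "P4": res.P[3],
                "R1": res.R1, "R2": res.R2, "Dr": res.Dr,
                "chisq": res.chisq, "df": res.df, "p_value": res.p_value,
                "n": res.n,
            })
        elif hasattr(res, "chisq_yates"):
            assoc_rows.append({
                "scheme": res.scheme, "pair": res.label,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "OR": res.odds_ratio, "Z": res.z, "p_Z": res.p_z,
                "chisq_yates": res.chisq_yates, "chisq_plain": res.chisq_plain,
                "p_chisq": res.p_chisq,
            })
        else:
            raise TypeError(f"unknown result type {type(res).__name__}")
    frames: dict[str, pd.DataFrame] = {}
    if rd_rows:
        frames["RD"] = pd.DataFrame(rd_rows, columns=_RD_COLUMNS)
    if assoc_rows:
        frames["ASSOCIATION"] = pd.DataFrame(assoc_rows, columns=_ASSOC_COLUMNS)
    return frames


def write_report(results: Iterable[object], path: str | Path) -> None:
    """Write RD and/or association results as a sectioned TSV report.

    Sections appear in fixed order (RD then ASSOCIATION), rows in input
    order; numbers are printed with 6 significant digits and undefined
    statistics as ``NA``.
    """
    results = list(results)
    if not results:
        raise EmptyResultsError("no results to write")
    frames = report_frames(results)
    with open(path, "w") as fh:
        for name in ("RD", "ASSOCIATION"):
            if name not in frames:
                continue
            df = frames[name]
            fh.write(f"# {name}\n")
            fh.write("\t".join(df.columns) + "\n")
            for _, row in df.iterrows():
                fh.write("\t".join(format_number(v) for v in row) + "\n")
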