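"""Dissect m-SNP haplotype tables into all three-SNP combinations.

Sister-pair analysis is defined for three sites, so wider haplotypes are
reduced to every C(m, 3) site triplet. Each projected triplet table goes
through quality control first:

* multi-allelic sites are dropped before enumeration (biallelic-only method);
* a triplet with all 8 haplotype classes observed is analysed as-is (``ok``);
* a triplet with exactly 7 classes gets the single missing class imputed
  with the per-population minimum positive count — a rare-haplotype stand-in
  — and is flagged ``imputed``;
* a triplet with 6 or fewer classes is ``excluded``: six haplotypes cannot
  form a valid sister-pair system.

Each retained triplet is then run through the RD test (case, control,
overall) and sister-pair association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

from .hap_table_io import HaplotypeTable, HapRow, validate_table
from .pair_association import AssocResult, associate
from .rd_test import RDResult, RDTestUndefinedError, rd_analysis
from .sister_recode import ZeroTotalError

__all__ = [
    "TripletReport",
    "DissectError",
    "triplets",
    "project_to_triplet",
    "impute_missing_class",
    "run_all",
    "qc_summary",
]


class DissectError(ValueError):
    """Invalid dissection request (unknown site, too few sites)."""


@dataclass
class TripletReport:
    """QC status and analysis results for one three-site combination."""

    triplet: tuple[str, str, str]
    qc_status: str  # ok | imputed | excluded
    n_classes_observed: int
    rd_results: list[RDResult] = field(default_factory=list)
    assoc_results: list[AssocResult] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def triplets(site_ids: Sequence[str]) -> list[tuple[str, ...]]:
    """All C(m,3) site triplets in lexicographic index order."""
    if len(site_ids) < 3:
        raise DissectError(f"need at least 3 sites, got {len(site_ids)}")
    return list(combinations(site_ids, 3))


def project_to_triplet(
    table: HaplotypeTable, triplet: Sequence[str]
) -> HaplotypeTable:
    """Restrict a table to three sites, merging rows that become identical.

    Site order follows the parent table; total counts per population are
    conserved.
    """
    try:
        idx = sorted(table.site_ids.index(s) for s in triplet)
    except ValueError as exc:
        raise DissectError(f"unknown site id in triplet {tuple(triplet)!r}") from exc
    if len(set(idx)) != 3:
        raise DissectError(f"triplet must name 3 distinct sites, got {tuple(triplet)!r}")
    merged: dict[str, list[float]] = {}
    order: list[str] = []
    for row in table.rows:
        key = "".join(row.haplotype[i] for i in idx)
        if key not in merged:
            merged[key] = [0.0, 0.0]
            order.append(key)
        merged[key][0] += row.case_count
        merged[key][1] += row.control_count
    return HaplotypeTable(
        site_ids=[table.site_ids[i] for i in idx],
        rows=[HapRow(h, merged[h][0], merged[h][1]) for h in order],
        n_case=table.n_case,
        n_control=table.n_control,
        counts_are_frequencies=table.counts_are_frequencies,
    )


def _missing_classes(table: HaplotypeTable) -> list[str]:
    """Possible-but-unobserved haplotypes over the observed per-site alleles."""
    alleles = table.site_alleles()
    if any(len(a) != 2 for a in alleles):
        return []
    observed = {r.haplotype for r in table.rows if r.pooled > 0}
    return [
        "".join(combo)
        for combo in product(*(sorted(a) for a in alleles))
        if "".join(combo) not in observed
    ]


def impute_missing_class(table: HaplotypeTable) -> tuple[HaplotypeTable, str]:
    """Apply the 7-class imputation / 6-class exclusion rule to a triplet table.

    Returns ``(table, status)``: unchanged with ``ok`` at 8 observed classes;
    at exactly 7, the absent class receives the per-population minimum
    positive count (count tables grow their totals; frequency-derived tables
    are renormalized back to the original sample sizes) and status is
    ``imputed``; at 6 or fewer the input is returned with ``excluded``.
    """
    n_classes = sum(1 for r in table.rows if r.pooled > 0)
    if n_classes >= 8:
        return table, "ok"
    if n_classes < 7:
        return table, "excluded"
    missing = _missing_classes(table)
    if len(missing) != 1:  # 7 observed classes determine the 8th uniquely
        return table, "excluded"
    case_min = min((r.case_count for r in table.rows if r.case_count > 0), default=0.0)
    ctrl_min = min((r.control_count for r in table.rows if r.control_count > 0), default=0.0)
    rows = [r for r in table.rows if r.pooled > 0] + [HapRow(missing[0], case_min, ctrl_min)]
    if table.counts_are_frequencies:
        case_tot = sum(r.case_count for r in rows)
        ctrl_tot = sum(r.control_count for r in rows)
        rows = [
            HapRow(
                r.haplotype,
                r.case_count / case_tot * table.n_case,
                r.control_count / ctrl_tot * table.n_control,
            )
            for r in rows
        ]
        n_case, n_control = table.n_case, table.n_control
    else:
        n_case = table.n_case + case_min
        n_control = table.n_control + ctrl_min
    return (
        HaplotypeTable(
            site_ids=list(table.site_ids),
            rows=rows,
            n_case=n_case,
            n_control=n_control,
            counts_are_frequencies=table.counts_are_frequencies,
        ),
        "imputed",
    )


def run_all(table: HaplotypeTable) -> list[TripletReport]:
    """Analyse every three-SNP combination of an m-SNP haplotype table.

    Multi-allelic sites are dropped first; each triplet is projected,
    QC'd/imputed, and — unless excluded — run through RD analysis and
    sister-pair association. Reports come back in deterministic triplet
    order.
    """
    report = validate_table(table)
    keep = [s for s in table.site_ids if s not in report.removed_sites]
    if len(keep) < 3:
        raise DissectError(
            f"only {len(keep)} biallelic sites after quality control; need 3"
        )
    reports: list[TripletReport] = []
    for trip in triplets(keep):
        sub = project_to_triplet(table, trip)
        sub, status = impute_missing_class(sub)
        n_classes = sum(1 for r in sub.rows if r.pooled > 0)
        trip_report = TripletReport(
            triplet=tuple(sub.site_ids),  # type: ignore[arg-type]
            qc_status=status,
            n_classes_observed=n_classes,
        )
        if status == "excluded":
            trip_report.messages.append(
                "excluded: 6 or fewer haplotype classes cannot construct valid sister pairs"
            )
        else:
            if status == "imputed":
                trip_report.messages.append(
                    "one absent haplotype class imputed with per-population minimum positive count"
                )
            try:
                trip_report.rd_results = rd_analysis(sub)
            except (RDTestUndefinedError, ZeroTotalError) as exc:
                trip_report.messages.append(f"RD test unavailable: {exc}")
            trip_report.assoc_results = associate(sub, scheme="sister")
        reports.append(trip_report)
    return reports


def qc_summary(reports: Sequence[TripletReport]) -> dict[str, int]:
    """Counts of ok / imputed / excluded triplets."""
    summary = {"ok": 0, "imputed": 0, "excluded": 0}
    for rep in reports:
        summary[rep.qc_status] += 1
    return summary
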