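import numpy as np
import pytest

from sisterhap.dissect import (
    DissectError,
    impute_missing_class,
    project_to_triplet,
    qc_summary,
    run_all,
    triplets,
)
from sisterhap.hap_table_io import HaplotypeTable
from sisterhap.pair_association import associate
from sisterhap.rd_test import rd_analysis


class TestTriplets:
    @pytest.mark.parametrize("m,count", [(3, 1), (4, 4), (6, 20)])
    def test_counts(self, m, count):
        sites = [f"s{i}" for i in range(m)]
        out = triplets(sites)
        assert len(out) == count
        assert len(set(out)) == count

    def test_four_site_combinations_deterministic(self):
        assert triplets(["M1", "M3", "M4", "M6"]) == [
            ("M1", "M3", "M4"), ("M1", "M3", "M6"),
            ("M1", "M4", "M6"), ("M3", "M4", "M6"),
        ]

    def test_too_few_sites(self):
        with pytest.raises(DissectError):
            triplets(["a", "b"])


class TestProjection:
    def test_conserves_totals_and_merges(self, four_site_table):
        for trip in triplets(four_site_table.site_ids):
            sub = project_to_triplet(four_site_table, trip)
            assert sub.total_case == pytest.approx(four_site_table.total_case)
            assert sub.total_control == pytest.approx(four_site_table.total_control)
            assert len(sub.rows) == 8  # 16 four-site rows merge pairwise

    def test_rows_differing_only_at_dropped_site_merge(self):
        table = HaplotypeTable.from_counts(
            ["a", "b", "c", "d"],
            [("ACGT", 10, 5), ("ACGA", 7, 3), ("CTAT", 2, 1), ("CTAA", 2, 1)],
        )
        sub = project_to_triplet(table, ("a", "b", "c"))
        assert {r.haplotype: r.case_count for r in sub.rows} == {"ACG": 17, "CTA": 4}

    def test_unknown_site(self, four_site_table):
        with pytest.raises(DissectError, match="unknown site"):
            project_to_triplet(four_site_table, ("s1", "s2", "nope"))


class TestImputation:
    def test_eight_classes_untouched(self, il13):
        out, status = impute_missing_class(il13)
        assert status == "ok"
        assert out is il13

    def test_seven_classes_min_positive_count(self):
        table = HaplotypeTable.from_counts(
            ["a", "b", "c"],
            [
                ("ACG", 100, 90), ("CTA", 60, 55), ("ACA", 20, 18),
                ("CTG", 15, 12), ("ATA", 3, 6), ("CCG", 9, 2),
                ("ATG", 5, 4),  # missing sister class: CCA
            ],
        )
        out, status = impute_missing_class(table)
        assert status == "imputed"
        added = {r.haplotype: r for r in out.rows}["CCA"]
        assert (added.case_count, added.control_count) == (3, 2)
        assert out.n_case == table.n_case + 3
        assert out.total_case == pytest.approx(215)

    def test_imputation_preserves_parental_ranking(self):
        table = HaplotypeTable.from_counts(
            ["a", "b", "c"],
            [
                ("ACG", 100, 90), ("CTA", 60, 55), ("ACA", 20, 18),
                ("CTG", 15, 12), ("ATA", 3, 6), ("CCG", 9, 2), ("ATG", 5, 4),
            ],
        )
        from sisterhap.sister_recode import select_parental

        out, _ = impute_missing_class(table)
        assert select_parental(out) == select_parental(table) == "ACG"

    def test_six_classes_excluded(self, six_class_table):
        out, status = impute_missing_class(six_class_table)
        assert status == "excluded"
        assert out is six_class_table

    def test_frequency_table_renormalized(self):
        rows = [
            ("ACG", 0.40, 0.42), ("CTA", 0.25, 0.24), ("ACA", 0.12, 0.11),
            ("CTG", 0.10, 0.10), ("ATA", 0.05, 0.06), ("CCG", 0.05, 0.04),
            ("ATG", 0.03, 0.03),
        ]
        table = HaplotypeTable.from_frequencies(["a", "b", "c"], rows, 200, 100)
        out, status = impute_missing_class(table)
        assert status == "imputed"
        assert out.total_case == pytest.approx(200)
        assert out.total_control == pytest.approx(100)


class TestRunAll:
    def test_four_site_table_all_ok(self, four_site_table):
        reports = run_all(four_site_table)
        assert len(reports) == 4
        assert qc_summary(reports) == {"ok": 4, "imputed": 0, "excluded": 0}
        for rep in reports:
            assert len(rep.rd_results) == 3
            assert len(rep.assoc_results) == 4

    def test_m3_matches_direct_analysis(self, il13):
        report = run_all(il13)[0]
        direct_rd = rd_analysis(il13)
        assert [r.Dr for r in report.rd_results] == pytest.approx(
            [r.Dr for r in direct_rd]
        )
        assert [r.odds_ratio for r in report.assoc_results if r.odds_ratio] == (
            pytest.approx(
                [r.odds_ratio for r in associate(il13, scheme="sister") if r.odds_ratio]
            )
        )

    def test_sparse_six_site_mixture(self):
        # 6 sites built by concatenating two independent 3-site systems,
        # leaving many triplets with missing classes
        rng = np.random.default_rng(99)
        base = ["ACG", "CTA", "ACA", "CTG", "ATA", "CCG", "ATG", "CCA"]
        rows = {}
        for i, h1 in enumerate(base):
            for h2 in base[:3]:
                rows[h1 + h2] = (float(rng.integers(0, 40)), float(rng.integers(0, 40)))
        table = HaplotypeTable.from_counts(
            [f"s{i}" for i in range(6)], [(h, a, b) for h, (a, b) in rows.items()]
        )
        reports = run_all(table)
        assert len(reports) == 20
        summary = qc_summary(reports)
        assert sum(summary.values()) == 20
        assert summary["excluded"] > 0  # site s5 patterns only span 3 haplotypes
        for rep in reports:
            if rep.qc_status == "excluded":
                assert not rep.rd_results and not rep.assoc_results

    def test_multiallelic_site_dropped_first(self, four_site_table):
        rows = [(r.haplotype + b, r.case_count, r.control_count)
                for r, b in zip(four_site_table.rows, "ACG" * 6)]
        table = HaplotypeTable.from_counts(
            four_site_table.site_ids + ["bad"], rows)
        reports = run_all(table)
        assert all("bad" not in rep.triplet for rep in reports)
        assert len(reports) == 4

    def test_too_few_biallelic_sites(self):
        table = HaplotypeTable.from_counts(
            ["a", "b", "c"],
            [("ACG", 5, 5), ("CTG", 4, 4), ("GCG", 3, 3), ("ATG", 2, 2)],
        )  # site a has alleles A/C/G; only 2 biallelic sites remain
        with pytest.raises(DissectError, match="biallelic"):
            run_all(table)


class TestSiteOrderInvariance:
    def test_reversed_site_order_preserves_dr_magnitudes(self, il13):
        reversed_table = HaplotypeTable.from_counts(
            list(reversed(il13.site_ids)),
            [(r.haplotype[::-1], r.case_count, r.control_count) for r in il13.rows],
        )
        fwd = run_all(il13)[0]
        rev = run_all(reversed_table)[0]
        # reversal swaps the two intervals (P2<->P3); Dr and chisq are symmetric
        for a, b in zip(fwd.rd_results, rev.rd_results):
            assert a.Dr == pytest.approx(b.Dr, abs=1e-12)
            assert a.chisq == pytest.approx(b.chisq, abs=1e-9)
            assert (a.R1, a.R2) == pytest.approx((b.R2, b.R1))

    def test_permuted_site_order_preserves_qc(self, four_site_table):
        perm = [2, 0, 3, 1]
        permuted = HaplotypeTable.from_counts(
            [four_site_table.site_ids[i] for i in perm],
            [
                ("".join(r.haplotype[i] for i in perm), r.case_count, r.control_count)
                for r in four_site_table.rows
            ],
        )
        a = {frozenset(r.triplet): (r.qc_status, r.n_classes_observed)
             for r in run_all(four_site_table)}
        b = {frozenset(r.triplet): (r.qc_status, r.n_classes_observed)
             for r in run_all(permuted)}
        assert a == b
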