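import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sisterhap import datasets
from sisterhap.hap_table_io import HaplotypeTable
from sisterhap.rd_test import (
    NotRDTestableError,
    RDTestUndefinedError,
    rd_analysis,
    rd_chisq,
    rd_result_from_classes,
    rd_statistic,
    recombination_fractions,
)
from sisterhap.sister_recode import CollapsedClasses


def _classes(counts, population="case"):
    counts = np.asarray(counts, dtype=float)
    return CollapsedClasses(
        P=counts / counts.sum(), counts=counts, n=float(counts.sum()),
        population=population,
    )


def _printed_decimals(x: float) -> int:
    s = f"{x!r}"
    return len(s.split(".")[1]) if "." in s else 0


class TestStatistic:
    def test_il13_case(self):
        P = (0.667857, 0.214286, 0.053571, 0.064286)
        assert rd_statistic(P) == pytest.approx(0.031454, abs=5e-7)

    def test_ad_m3m4m6_overall(self):
        assert rd_statistic((0.589, 0.358, 0.008, 0.047)) == pytest.approx(
            0.024819, abs=1e-6
        )

    def test_independence_gives_zero(self):
        # P4 = R1*R2 exactly: (0.56, 0.24, 0.14, 0.06) has R1=0.2, R2=0.3
        assert rd_statistic((0.56, 0.24, 0.14, 0.06)) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("key", sorted(datasets.AD_PUBLISHED_CLASSES))
    def test_all_published_ad_vectors(self, key):
        """Every published AD class vector reproduces its published RD value."""
        dr = rd_statistic(datasets.AD_PUBLISHED_CLASSES[key])
        printed = datasets.AD_PUBLISHED_RD[key]
        assert dr == pytest.approx(printed, abs=0.51 * 10 ** -_printed_decimals(printed))

    @pytest.mark.parametrize("pop", ["control", "case"])
    def test_published_il13_vectors(self, pop):
        dr = rd_statistic(datasets.IL13_PUBLISHED_CLASSES[pop])
        printed = datasets.IL13_PUBLISHED_RD[pop]
        assert dr == pytest.approx(printed, abs=0.51 * 10 ** -_printed_decimals(printed))

    def test_published_il13_overall_column_averages_populations(self):
        """The source's 'overall' column is the mean of the case and control
        columns (not a pooled computation): its RD equals the mean of the two
        per-population RDs. This package pools counts instead."""
        mean_vec = np.mean(
            [
                datasets.IL13_PUBLISHED_CLASSES["control"],
                datasets.IL13_PUBLISHED_CLASSES["case"],
            ],
            axis=0,
        )
        np.testing.assert_allclose(
            mean_vec, datasets.IL13_PUBLISHED_CLASSES["overall"], atol=5e-6
        )
        mean_rd = np.mean(
            [datasets.IL13_PUBLISHED_RD["control"], datasets.IL13_PUBLISHED_RD["case"]]
        )
        assert mean_rd == pytest.approx(datasets.IL13_PUBLISHED_RD["overall"], abs=5e-5)

    def test_factor4_compat_variant(self):
        P = (0.5, 0.2, 0.2, 0.1)
        assert rd_statistic(P, factor4=True) == pytest.approx(4 * 0.05 - 0.04)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(derandomize=True)
    def test_identities_and_symmetry(self, raw):
        """Dr = P1*P4 - P2*P3 = P4 - R1*R2, invariant under P2<->P3 exchange."""
        P = np.array(raw) / np.sum(raw)
        R1, R2 = recombination_fractions(P)
        dr = rd_statistic(P)
        assert dr == pytest.approx(P[3] - R1 * R2, abs=1e-12)
        assert dr == pytest.approx(rd_statistic(P[[0, 2, 1, 3]]), abs=1e-12)
        assert abs(dr) <= 0.25 + 1e-12


class TestChisq:
    def test_il13_case_counts(self):
        chisq, p = rd_chisq(_classes([374, 120, 30, 36]))
        assert chisq == pytest.approx(26.52, abs=0.01)
        assert p == pytest.approx(2.6e-07, rel=0.05)

    def test_uniform_classes_zero(self):
        chisq, p = rd_chisq(_classes([100, 100, 100, 100]))
        assert chisq == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_independent_counts_zero(self):
        chisq, _ = rd_chisq(_classes([560, 240, 140, 60]))
        assert chisq == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_margin_raises(self):
        with pytest.raises(RDTestUndefinedError, match="no recombinants"):
            rd_chisq(_classes([500, 0, 100, 0]))  # R2 = 0

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4),
        st.integers(50, 5000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_goodness_of_fit_equals_closed_form(self, raw, n):
        """GOF over 4 classes == n*Dr^2 / (R1(1-R1)R2(1-R2)) to 1e-9."""
        counts = np.array(raw) / np.sum(raw) * n
        classes = _classes(counts)
        chisq, _ = rd_chisq(classes)
        R1, R2 = recombination_fractions(classes.P)
        closed = n * rd_statistic(classes.P) ** 2 / (R1 * (1 - R1) * R2 * (1 - R2))
        assert chisq == pytest.approx(closed, abs=1e-9 * max(1.0, closed))

    def test_sister_priming_irrelevant(self):
        """Relabelling which sister is primed cannot change the collapsed test."""
        res_a = rd_result_from_classes(_classes([374, 120, 30, 36]))
        res_b = rd_result_from_classes(_classes([374, 120, 30, 36], "control"))
        assert res_a.Dr == res_b.Dr and res_a.chisq == res_b.chisq


class TestAnalysis:
    def test_il13_three_populations(self, il13):
        results = {r.population: r for r in rd_analysis(il13)}
        assert set(results) == {"case", "control", "overall"}
        assert results["case"].Dr == pytest.approx(0.031454, abs=5e-7)
        # count-based control Dr: the published table used a slightly smaller
        # denominator, giving 0.020365 from its frequency vector instead
        assert results["control"].Dr == pytest.approx(0.019344, abs=1e-5)
        assert results["overall"].n == pytest.approx(914)

    def test_ad_case_dr(self):
        results = {r.population: r for r in rd_analysis(datasets.ad_apoe("M1M3M4*"))}
        assert results["case"].Dr == pytest.approx(-0.052, abs=5e-4)

    def test_not_testable_table_raises(self, six_class_table):
        with pytest.raises(NotRDTestableError, match="7"):
            rd_analysis(six_class_table)

    def test_result_invariants(self, il13):
        for res in rd_analysis(il13):
            assert res.df == 1
            assert 0 <= res.p_value <= 1
            assert res.R1 == pytest.approx(res.P[2] + res.P[3])
            assert res.R2 == pytest.approx(res.P[1] + res.P[3])
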