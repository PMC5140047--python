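"""Expected-MAF model, clonality test, and FSM statistics."""

from fractions import Fraction

import numpy as np
import pytest

from clonescape import (
    SomaticSnv,
    call_clonality,
    clonality_test,
    enrichment_2x2,
    expected_maf,
    fsm,
    fsm_gene_test,
)
from oracles import fisher_two_sided_by_enumeration, maf_by_cell_enumeration

STATE_CONFIGS = [
    ("CN2", "none"),
    ("CN1", "mutant_retained"),
    ("CN1", "mutant_lost"),
    ("LOH", "mutant_duplicated"),
    ("LOH", "wildtype_duplicated"),
]


class TestExpectedMaf:
    @pytest.mark.parametrize("alpha, beta, state, config, expected", [
        (1.0, 1.0, "CN1", "mutant_retained", 1.0),
        (0.7, 0.0, "CN1", "mutant_retained", 0.35),
        (0.7, 0.0, "LOH", "mutant_duplicated", 0.35),
        (0.6, 0.3, "CN2", "none", 0.3),
        (0.5, 0.5, "CN1", "mutant_retained", 2 / 7),   # 0.2857
        (0.5, 0.5, "LOH", "mutant_duplicated", 0.375),
    ])
    def test_worked_examples(self, alpha, beta, state, config, expected):
        assert expected_maf(alpha, beta, state, config) == pytest.approx(expected)

    @pytest.mark.parametrize("state, config", STATE_CONFIGS)
    def test_matches_cell_enumeration_oracle(self, state, config):
        """Closed forms agree with exact allele counting over a 20x20 grid."""
        for i in range(1, 21):
            for j in range(0, 21):
                alpha, beta = Fraction(i, 20), Fraction(j, 20)
                want = maf_by_cell_enumeration(alpha, beta, state, config)
                got = expected_maf(float(alpha), float(beta), state, config)
                assert abs(got - float(want)) < 1e-9, (alpha, beta, state, config)

    def test_unsupported_state_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            expected_maf(0.5, 0.5, "AMP", "none")

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            expected_maf(0.0, 0.5, "CN2")
        with pytest.raises(ValueError):
            expected_maf(0.5, 1.5, "CN2")


class TestClonalityTest:
    def test_zero_alt_closed_form(self):
        assert clonality_test(0, 30, 0.25) == pytest.approx(0.75 ** 30, rel=1e-9)

    def test_all_alt_is_uninformative(self):
        assert clonality_test(50, 50, 0.3) == pytest.approx(1.0)

    def test_degenerate_maf_raises(self):
        with pytest.raises(ValueError):
            clonality_test(5, 10, 0.0)
        with pytest.raises(ValueError):
            clonality_test(5, 10, 1.0)

    def test_type_i_error_conservative(self, rng):
        """Clonal SNVs at depth 100 reject at p<0.05 at a rate in [0.02, 0.06]."""
        n = 10_000
        alpha = rng.uniform(0.2, 0.9, n)
        maf = alpha / 2.0
        alt = rng.binomial(100, maf)
        from scipy.stats import binom
        p = binom.cdf(alt, 100, maf)
        rate = float(np.mean(p < 0.05))
        assert 0.02 <= rate <= 0.06

    def test_pvalues_stochastically_dominate_uniform(self, rng):
        """Under the clonal null, P(p <= t) <= t for every t (conservative)."""
        alt = rng.binomial(80, 0.3, 5000)
        from scipy.stats import binom
        p = np.sort(binom.cdf(alt, 80, 0.3))
        ecdf = np.arange(1, p.size + 1) / p.size
        assert np.all(ecdf - p <= 0.02)  # small MC slack

    def test_rejection_rate_non_increasing_in_ccf(self, rng):
        """Power to detect subclonality falls as the cancer-cell fraction rises."""
        depth, alpha = 100, 0.6
        null_maf = alpha / 2
        rates = []
        for ccf in (0.2, 0.4, 0.6, 0.8, 1.0):
            alt = rng.binomial(depth, ccf * null_maf, 4000)
            from scipy.stats import binom
            rates.append(float(np.mean(binom.cdf(alt, depth, null_maf) < 0.05)))
        assert all(a >= b - 0.02 for a, b in zip(rates, rates[1:]))


class TestCallClonality:
    def _snv(self, **kw):
        base = dict(chrom="chr1", pos=100, ref="C", alt="T", depth=100, alt_count=30)
        base.update(kw)
        return SomaticSnv(**base)

    def test_amplified_and_cn0_regions_excluded(self):
        for state in ("AMP", "CN0"):
            assert call_clonality(self._snv(segment_state=state), alpha=0.6) == "excluded"

    def test_cutoff_decision(self):
        subclonal = self._snv(alt_count=5)
        assert call_clonality(subclonal, alpha=0.8) == "subclonal"
        clonal = self._snv(alt_count=40)
        assert call_clonality(clonal, alpha=0.8) == "clonal"

    def test_unknown_config_takes_conservative_max_p(self):
        snv = self._snv(segment_state="CN1", beta=0.5, allele_config="none",
                        alt_count=20)
        call_clonality(snv, alpha=0.6)
        p_retained = clonality_test(20, 100, expected_maf(0.6, 0.5, "CN1", "mutant_retained"))
        p_lost = clonality_test(20, 100, expected_maf(0.6, 0.5, "CN1", "mutant_lost"))
        assert snv.p_clonal == pytest.approx(max(p_retained, p_lost))

    def test_fully_deleted_mutant_config_skipped(self):
        """With beta=1 CN1, the mutant-lost null is degenerate; the retained
        configuration is used instead of failing."""
        snv = self._snv(segment_state="CN1", beta=1.0, allele_config="none")
        label = call_clonality(snv, alpha=0.5)
        assert label in ("clonal", "subclonal")
        assert snv.allele_config == "mutant_retained"


class TestFsm:
    @pytest.mark.parametrize("calls, expected", [
        (["clonal", "subclonal", "subclonal", "clonal"], 0.5),
        (["clonal", "clonal"], 0.0),
        (["subclonal", "excluded", "subclonal"], 1.0),
    ])
    def test_examples(self, calls, expected):
        assert fsm(calls) == pytest.approx(expected)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            fsm(["excluded", "excluded"])

    def test_pooled_fsm_is_count_weighted_mean(self, rng):
        samples = []
        for _ in range(10):
            n = int(rng.integers(5, 40))
            calls = list(rng.choice(["clonal", "subclonal"], n))
            samples.append(calls)
        pooled = fsm([c for s in samples for c in s])
        weights = np.array([len(s) for s in samples])
        per_sample = np.array([fsm(s) for s in samples])
        assert pooled == pytest.approx(np.average(per_sample, weights=weights))


class TestFisherStatistics:
    def test_identical_proportions_p_one(self):
        assert fsm_gene_test((5, 5), (50, 50)) == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle(self):
        for table in [(10, 0, 50, 50), (3, 9, 14, 2), (1, 1, 1, 1), (0, 5, 5, 0)]:
            a, b, c, d = table
            assert fsm_gene_test((a, b), (c, d)) == pytest.approx(
                fisher_two_sided_by_enumeration(a, b, c, d), rel=1e-9)

    def test_row_swap_symmetry(self):
        assert fsm_gene_test((3, 9), (14, 2)) == pytest.approx(fsm_gene_test((14, 2), (3, 9)))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fsm_gene_test((0, 0), (0, 0))

    def test_enrichment_reports_fractions(self):
        (fa, fb), p = enrichment_2x2((13, 87), (8, 92))
        assert (fa, fb) == pytest.approx((0.13, 0.08))
        assert 0 < p <= 1

    def test_enrichment_equal_columns_p_one(self):
        (_, _), p = enrichment_2x2((10, 20), (10, 20))
        assert p == pytest.approx(1.0)

    def test_planted_apobec_enrichment_detected(self, rng):
        """A 2:1 subclonal/clonal APOBEC odds ratio is detected at p<0.05 in
        at least 90% of seeded cohorts of 2,000 mutations."""
        hits = 0
        runs = 20
        for _ in range(runs):
            n_sub, n_clo = 1000, 1000
            p_clo = 0.08
            odds = 2.0 * p_clo / (1 - p_clo)
            p_sub = odds / (1 + odds)
            a = int(rng.binomial(n_sub, p_sub))
            c = int(rng.binomial(n_clo, p_clo))
            _, p = enrichment_2x2((a, n_sub - a), (c, n_clo - c))
            hits += p < 0.05
        assert hits / runs >= 0.9
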