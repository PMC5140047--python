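"""BAF peak fitting, cell-fraction inversion, purity, and copy-state tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonescape import (
    CnaSegment,
    PurityEstimate,
    analyze_sample_cnas,
    assign_copy_state,
    cell_fraction_from_peaks,
    classify_cna_clonality,
    estimate_purity,
    fit_baf_peaks,
    fold_baf,
)
from clonescape.cna import EstimationError


class TestFoldBaf:
    @pytest.mark.parametrize("values, expected", [
        ([0.2, 0.8], [0.2, 0.2]),
        ([0.5], [0.5]),
        ([1 / 3, 2 / 3, 0.5], [1 / 3, 1 / 3, 0.5]),
    ])
    def test_examples(self, values, expected):
        assert fold_baf(values) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fold_baf([1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_symmetry_and_range(self, values):
        folded = fold_baf(values)
        assert np.all(folded <= 0.5 + 1e-12)
        assert np.allclose(folded, fold_baf(1.0 - np.asarray(values)))


class TestFitBafPeaks:
    def test_noise_free_two_band_segment(self):
        values = np.tile([1 / 3, 2 / 3], 50)
        fit = fit_baf_peaks(values)
        assert fit.mu1 == pytest.approx(1 / 3, abs=1e-4)
        assert fit.mu2 == pytest.approx(2 / 3, abs=1e-4)
        assert not fit.degenerate

    def test_grid_search_likelihood_agrees(self):
        """EM lands on the same mu as a direct grid search of the likelihood."""
        rng = np.random.default_rng(3)
        b = np.clip(np.concatenate([rng.normal(0.35, 0.03, 300),
                                    rng.normal(0.65, 0.03, 300)]), 0, 1)
        fit = fit_baf_peaks(b)

        def loglik(mu, sd):
            from scipy.stats import norm
            return np.sum(np.log(0.5 * norm.pdf(b, mu, sd) + 0.5 * norm.pdf(b, 1 - mu, sd)))

        grid = np.linspace(0.01, 0.5, 491)
        best = grid[np.argmax([loglik(m, fit.sd) for m in grid])]
        assert fit.mu1 == pytest.approx(best, abs=2e-3)

    def test_degenerate_single_band(self):
        fit = fit_baf_peaks(np.full(100, 0.5))
        assert fit.degenerate
        assert fit.mu1 == pytest.approx(0.5, abs=1e-6)
        assert fit.mu2 == pytest.approx(0.5, abs=1e-6)

    def test_monte_carlo_recovery_and_monotone_loglik(self, rng):
        b = np.clip(np.concatenate([rng.normal(0.4, 0.03, 250),
                                    rng.normal(0.6, 0.03, 250)]), 0, 1)
        fit = fit_baf_peaks(b)
        assert abs(fit.mu1 - 0.4) < 0.01
        diffs = np.diff(fit.loglik)
        assert np.all(diffs >= -1e-8)

    def test_too_few_probes_returns_none(self):
        assert fit_baf_peaks([0.4, 0.6] * 10) is None


class TestCellFraction:
    @pytest.mark.parametrize("mu1, mu2, state, expected", [
        (1 / 3, 2 / 3, "CN1", 0.5),
        (0.4, 0.6, "LOH", 0.2),
        (0.5, 0.5, "CN1", 0.0),
        (0.5, 0.5, "LOH", 0.0),
    ])
    def test_examples(self, mu1, mu2, state, expected):
        assert cell_fraction_from_peaks(mu1, mu2, state) == pytest.approx(expected)

    @pytest.mark.parametrize("state", ["CN1", "LOH"])
    def test_round_trip_exact_on_grid(self, state):
        """Peak positions implied by c invert back to c to 1e-9."""
        for c in np.linspace(0.0, 1.0, 101):
            if state == "CN1":
                mu1, mu2 = (1 - c) / (2 - c), 1 / (2 - c)
            else:
                mu1, mu2 = (1 - c) / 2, (1 + c) / 2
            assert cell_fraction_from_peaks(mu1, mu2, state) == pytest.approx(c, abs=1e-9)

    def test_unsupported_states_raise(self):
        with pytest.raises(ValueError):
            cell_fraction_from_peaks(0.3, 0.7, "AMP")
        with pytest.raises(ValueError):
            cell_fraction_from_peaks(0.3, 0.7, "CN0")


class TestEstimatePurity:
    def test_identical_values_single_peak(self):
        est = estimate_purity([0.6] * 8)
        assert est.alpha == pytest.approx(0.6)
        assert len(est.density_peaks) == 1

    def test_bimodal_rightmost_peak(self, rng):
        pis = np.concatenate([rng.normal(0.3, 0.02, 25), rng.normal(0.7, 0.02, 25)])
        est = estimate_purity(np.clip(pis, 0, 1))
        assert len(est.density_peaks) == 2
        assert est.alpha == pytest.approx(0.7, abs=0.05)

    def test_permutation_invariance(self, rng):
        pis = rng.uniform(0.2, 0.8, 40)
        a = estimate_purity(pis).alpha
        b = estimate_purity(rng.permutation(pis)).alpha
        assert a == b

    def test_empty_raises(self):
        with pytest.raises(EstimationError, match="no usable CNAs"):
            estimate_purity([])


class TestClassifyClonality:
    @pytest.mark.parametrize("c, alpha, rel_tol, expected", [
        (0.58, 0.6, 0.1, "clonal"),
        (0.30, 0.6, 0.1, "subclonal"),
        (0.6, 0.6, 0.0, "clonal"),
    ])
    def test_decision_rule(self, c, alpha, rel_tol, expected):
        seg = CnaSegment(chrom="chr1", start=0, end=100, state="CN1",
                         cell_fraction_c=c)
        purity = PurityEstimate(alpha=alpha, pi_values=np.array([c]),
                                density_peaks=np.array([alpha]), bandwidth=0.1)
        assert classify_cna_clonality(seg, purity, rel_tol=rel_tol) == expected


class TestAssignCopyState:
    @pytest.mark.parametrize("ratio, peaks, expected", [
        (1.0, (0.5, 0.5), "CN2"),
        (1.0, (0.3, 0.7), "LOH"),
        (0.75, (0.35, 0.65), "CN1"),
        (0.1, (0.5, 0.5), "CN0"),
        (1.6, (0.4, 0.6), "AMP"),
    ])
    def test_examples(self, ratio, peaks, expected):
        assert assign_copy_state(ratio, peaks) == expected

    def test_nonpositive_ratio_raises(self):
        with pytest.raises(ValueError):
            assign_copy_state(0.0, (0.5, 0.5))


class TestSampleDriver:
    def test_cna_labels_recovered_on_synthetic_sample(self):
        """Clonal/subclonal labels are >=90% correct with well-separated betas."""
        from clonescape import SimulationConfig, simulate_tumor_sample

        cfg = SimulationConfig(n_segments=40, probes_per_segment=200,
                               subclonal_cna_prob=0.5, beta_range=(0.2, 0.6),
                               purity_range=(0.5, 0.8), seed=11)
        correct = total = 0
        for idx in range(3):
            sample, truth = simulate_tumor_sample(cfg, idx)
            analyze_sample_cnas(sample.segments)
            for seg, row in zip(sample.segments, truth.segment_truth.itertuples()):
                if seg.clonality in ("clonal", "subclonal"):
                    total += 1
                    correct += seg.clonality == row.clonality
        assert total > 30
        assert correct / total >= 0.9
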