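"""Frequency computation and Gaussian peak fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkscan import deconvolve as dec
from hkscan import simulate as sim
from hkscan.deconvolve import (
    BinCountTable,
    GaussianFit,
    aggregate_replicates,
    bin_centers,
    compute_bin_frequencies,
    fit_gaussian_profile,
    fold_induction,
)


def _table_from_reads(reads: dict[str, list[int]], cells: list[float],
                      edges=None) -> BinCountTable:
    n_bins = len(cells)
    if edges is None:
        edges = np.linspace(1.0, 1.0 + 0.5 * n_bins, n_bins + 1)
    df = pd.DataFrame(reads, index=pd.RangeIndex(1, n_bins + 1, name="bin")).T
    df.columns = pd.RangeIndex(1, n_bins + 1, name="bin")
    key = ("OmpR", "on", 1)
    return BinCountTable(
        reads={key: df}, cells_sorted={key: np.array(cells, float)},
        bin_edges={key: np.asarray(edges, float)},
    )


class TestBinFrequencies:
    def test_direct_formula(self):
        # 500 of 1000 reads in a bin holding 2e5 of 1e6 sorted cells -> 0.1
        cells = [2e5] + [8e5 / 7] * 7
        table = _table_from_reads(
            {"v": [500, 0, 0, 0, 0, 0, 0, 0], "w": [500, 100, 100, 100, 100, 100, 100, 100]},
            cells,
        )
        freqs = compute_bin_frequencies(table, "OmpR", "on")[1]
        assert freqs.loc["v", 1] == pytest.approx(0.5 * 0.2)

    def test_absent_variant_has_all_zero_profile(self):
        table = _table_from_reads(
            {"v": [0] * 8, "w": [10, 20, 40, 80, 40, 20, 10, 5]}, [100.0] * 8
        )
        freqs = compute_bin_frequencies(table, "OmpR", "on")[1]
        assert (freqs.loc["v"] == 0).all()

    def test_empty_bin_contributes_zero(self):
        table = _table_from_reads(
            {"v": [0, 10, 10, 10, 10, 10, 10, 10]}, [0.0] + [100.0] * 7
        )
        freqs = compute_bin_frequencies(table, "OmpR", "on")[1]
        assert freqs.loc["v", 1] == 0.0

    def test_per_bin_frequency_sums_match_cell_fractions(self, small_table):
        """Sum over variants of freq(v, b) equals cells_sorted(b) / cells_total."""
        for reporter in small_table.reporters:
            per_rep = compute_bin_frequencies(small_table, reporter, "on")
            for rep, freqs in per_rep.items():
                cells = small_table.cells_sorted[(reporter, "on", rep)]
                expected = cells / cells.sum()
                np.testing.assert_allclose(
                    freqs.to_numpy().sum(axis=0), expected, atol=1e-12
                )


class TestAggregateReplicates:
    def test_identical_replicates_have_zero_sd(self):
        df = pd.DataFrame({1: [0.1], 2: [0.3]}, index=["v"])
        prof = aggregate_replicates({1: df, 2: df.copy(), 3: df.copy()}, np.array([1.0, 2.0]))
        np.testing.assert_allclose(prof.sd_freq.to_numpy(), 0.0, atol=1e-15)

    def test_mean_and_sample_sd(self):
        frames = {
            r: pd.DataFrame({1: [x]}, index=["v"]) for r, x in zip((1, 2, 3), (0.1, 0.2, 0.3))
        }
        prof = aggregate_replicates(frames, np.array([1.0]))
        assert prof.mean_freq.loc["v", 1] == pytest.approx(0.2)
        assert prof.sd_freq.loc["v", 1] == pytest.approx(0.1)

    def test_single_replicate_gets_floor_and_flag(self):
        prof = aggregate_replicates(
            {1: pd.DataFrame({1: [0.5]}, index=["v"])}, np.array([1.0])
        )
        assert prof.sd_freq.loc["v", 1] == dec.SD_FLOOR
        assert "single_replicate" in prof.qc_flags

    def test_mean_profile_converges_with_many_replicates(self):
        """Law of large numbers: 50-replicate mean approaches expected bin mass."""
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        edges = np.linspace(1.0, 4.0, 9)
        mu_true, sigma, n_cells = 2.6, 0.4, 5000
        expected = np.diff(norm.cdf(edges, mu_true, sigma))
        expected[0] += norm.cdf(edges[0], mu_true, sigma)
        expected[-1] += norm.sf(edges[-1], mu_true, sigma)
        frames = {}
        for r in range(50):
            x = rng.normal(mu_true, sigma, n_cells)
            counts = np.bincount(np.digitize(x, edges[1:-1]), minlength=8)
            # single-variant library: reads mirror cells exactly
            frames[r] = pd.DataFrame(
                (counts / counts.sum())[None, :], index=["v"],
                columns=pd.RangeIndex(1, 9, name="bin"),
            )
        prof = aggregate_replicates(frames, bin_centers(edges))
        np.testing.assert_allclose(prof.mean_freq.loc["v"], expected, atol=0.005)


class TestGaussianFit:
    def test_noiseless_self_consistency(self):
        x = bin_centers(np.linspace(2.0, 5.0, 9))
        a, mu, sigma = 0.02, 3.4, 0.6
        y = a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
        fit = fit_gaussian_profile(y, np.full(8, 1e-4), x)
        assert fit.converged
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.mu == pytest.approx(mu, abs=1e-6)
        assert fit.sigma == pytest.approx(sigma, abs=1e-6)

    def test_symmetric_profile_peaks_at_the_midpoint(self):
        x = np.arange(8, dtype=float)
        y = np.array([0.0, 0.1, 0.4, 0.9, 0.9, 0.4, 0.1, 0.0])
        fit = fit_gaussian_profile(y, np.full(8, 1e-3), x)
        assert fit.converged
        assert fit.mu == pytest.approx(3.5, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        delta=st.floats(-2.0, 2.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_shift_and_scale_invariance(self, delta, scale):
        """Shifting centers by d shifts mu by d; rescaling y leaves mu, sigma."""
        x = bin_centers(np.linspace(2.0, 5.0, 9))
        y = 0.01 * np.exp(-((x - 3.2) ** 2) / (2 * 0.5**2))
        sd = np.full(8, 1e-4)
        base = fit_gaussian_profile(y, sd, x)
        shifted = fit_gaussian_profile(y, sd, x + delta)
        assert shifted.mu == pytest.approx(base.mu + delta, abs=1e-6)
        scaled = fit_gaussian_profile(scale * y, scale * sd, x)
        assert scaled.mu == pytest.approx(base.mu, abs=1e-6)
        assert scaled.sigma == pytest.approx(base.sigma, abs=1e-6)
        assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-6)

    def test_all_zero_profile_does_not_converge(self):
        fit = fit_gaussian_profile(np.zeros(8), np.zeros(8), np.arange(8, dtype=float))
        assert not fit.converged
        assert "too_few_bins" in fit.qc_flags

    def test_too_few_nonzero_bins_does_not_converge(self):
        y = np.array([0.0, 0.0, 0.5, 0.7, 0.3, 0.0, 0.0, 0.0])
        fit = fit_gaussian_profile(y, np.full(8, 1e-3), np.arange(8, dtype=float))
        assert not fit.converged


class TestFoldInduction:
    def _fit(self, mu):
        return GaussianFit(mu=mu, sigma=0.4, amplitude=1.0, converged=True)

    def test_equal_peaks_give_unity(self):
        assert fold_induction(self._fit(3.0), self._fit(3.0)) == pytest.approx(1.0)

    def test_linear_mode_matches_wild_type_induction_magnitude(self):
        on = self._fit(3.0 + np.log10(14.0))
        assert fold_induction(on, self._fit(3.0)) == pytest.approx(14.0)

    def test_literal_vs_linear_modes(self):
        on, off = self._fit(4.0), self._fit(2.0)
        assert fold_induction(on, off, mode="literal") == pytest.approx(2.0)
        assert fold_induction(on, off, mode="linear") == pytest.approx(100.0)

    def test_non_converged_input_is_nan(self):
        bad = GaussianFit(np.nan, np.nan, np.nan, converged=False)
        assert np.isnan(fold_induction(self._fit(3.0), bad))

    def test_unknown_mode_is_an_error(self):
        with pytest.raises(ValueError):
            fold_induction(self._fit(1.0), self._fit(1.0), mode="log")


class TestEndToEnd:
    def test_reduced_library_recovery(self, small_truth, small_table, small_measurements):
        """Deconvolved peaks track planted truth on the reduced library."""
        meas = small_measurements
        errs = []
        for reporter in sim.REPORTERS:
            sub = meas[meas.reporter == reporter].set_index("variant")
            for cond in ("on", "off"):
                true = small_truth.true_mu[(reporter, cond)].reindex(sub.index)
                errs.append((sub[f"mu_{cond}"] - true).abs())
        allerr = pd.concat(errs).dropna()
        assert (allerr < 0.1).mean() > 0.95
        # planted class structure separates cleanly on the cognate reporter
        sub = meas[meas.reporter == "OmpR"].set_index("variant")
        lof = small_truth.class_label.index[small_truth.class_label == "loss_of_function"]
        rest = small_truth.class_label.index.difference(lof)
        assert sub.loc[lof, "mu_on"].max() < sub.loc[rest, "mu_on"].min()
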