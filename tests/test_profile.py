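"""Tests of spectrum peak detection and the genome estimates."""
import math

import numpy as np
import pytest

from genoprof import (
    KmerHistogram,
    NoPeakError,
    ReadSimConfig,
    SimulationConfig,
    count_canonical_kmers,
    detect_peaks,
    estimate_base_coverage,
    estimate_genome_size,
    estimate_heterozygosity,
    estimate_single_copy,
    plot_spectrum,
    profile,
    simulate_reads,
    synthesize_diploid,
)


def gaussian_bump(center, sigma, area, depths):
    return area * np.exp(-0.5 * ((depths - center) / sigma) ** 2) / (
        sigma * math.sqrt(2 * math.pi)
    )


def make_hist(freq, k=19, total_bases=0, L=0.0):
    return KmerHistogram(k=k, freq=freq, total_bases=total_bases, mean_read_length=L)


class TestDetectPeaks:
    def test_bimodal_spectrum_with_error_spike(self):
        depths = np.arange(1, 600)
        f = gaussian_bump(150, 20, 1e5, depths) + gaussian_bump(300, 30, 9e5, depths)
        f += np.where(depths <= 10, 1e6 * np.exp(-depths), 0)
        freq = {int(d): int(round(v)) for d, v in zip(depths, f) if round(v) > 0}
        peaks = detect_peaks(make_hist(freq))
        assert abs(peaks.alpha_depth - 150) <= 3
        assert abs(peaks.beta_depth - 300) <= 3
        assert 10 < peaks.error_cutoff < 100
        assert peaks.high_cutoff == round(1.5 * peaks.beta_depth)

    def test_unimodal_spectrum_has_no_alpha(self):
        depths = np.arange(1, 300)
        f = gaussian_bump(100, 12, 5e5, depths)
        freq = {int(d): int(round(v)) for d, v in zip(depths, f) if round(v) > 0}
        peaks = detect_peaks(make_hist(freq))
        assert peaks.alpha_depth is None
        assert abs(peaks.beta_depth - 100) <= 2

    def test_error_only_spectrum_raises(self):
        with pytest.raises(NoPeakError):
            detect_peaks(make_hist({1: 1_000_000}))

    def test_monotone_decreasing_spectrum_raises(self):
        freq = {c: int(1e6 * math.exp(-c)) for c in range(1, 12)}
        freq = {c: v for c, v in freq.items() if v > 0}
        with pytest.raises(NoPeakError):
            detect_peaks(make_hist(freq))

    def test_alpha_within_search_window(self):
        depths = np.arange(1, 600)
        f = gaussian_bump(150, 20, 3e5, depths) + gaussian_bump(300, 30, 9e5, depths)
        freq = {int(d): int(round(v)) for d, v in zip(depths, f) if round(v) > 0}
        peaks = detect_peaks(make_hist(freq))
        assert 0.35 * peaks.beta_depth <= peaks.alpha_depth <= 0.65 * peaks.beta_depth


class TestFormulas:
    @pytest.mark.parametrize(
        "M,L,k,expected",
        [(132, 150, 19, 150.0), (50, 100, 1, 50.0), (10, 36, 31, 60.0)],
    )
    def test_base_coverage_formula(self, M, L, k, expected):
        assert estimate_base_coverage(M, L, k) == pytest.approx(expected)

    def test_base_coverage_domain_error(self):
        with pytest.raises(ValueError):
            estimate_base_coverage(10, 18, 19)

    @pytest.mark.parametrize("T,N,expected", [(1000, 10, 100.0), (6.0e10, 60, 1.0e9)])
    def test_genome_size_formula(self, T, N, expected):
        assert estimate_genome_size(T, N) == pytest.approx(expected)

    def test_genome_size_domain_error(self):
        with pytest.raises(ValueError):
            estimate_genome_size(1000, 0)

    def test_single_copy_single_bin_at_peak(self):
        assert estimate_single_copy(make_hist({300: 1000}), 300, 150, 450) == 1000

    def test_single_copy_weighted_sum(self):
        hist = make_hist({200: 100, 300: 200, 400: 100})
        assert estimate_single_copy(hist, 300, 150, 450) == pytest.approx(400.0)

    def test_single_copy_excludes_out_of_bounds_bins(self):
        hist = make_hist({100: 999, 300: 10})
        assert estimate_single_copy(hist, 300, 150, 450) == pytest.approx(10.0)


class TestHeterozygosityEstimate:
    def test_absent_alpha_gives_zeroes(self):
        depths = np.arange(1, 300)
        f = gaussian_bump(100, 12, 5e5, depths)
        freq = {int(d): int(round(v)) for d, v in zip(depths, f) if round(v) > 0}
        hist = make_hist(freq)
        peaks = detect_peaks(hist)
        assert estimate_heterozygosity(peaks, hist, 19) == (0.0, 0.0)

    def test_zero_alpha_area_gives_zero_rate(self):
        from genoprof.profile import SpectrumPeaks

        peaks = SpectrumPeaks(
            error_cutoff=5, alpha_depth=150, alpha_height=10.0,
            beta_depth=300, beta_height=100.0, beta_depth_refined=300.0,
            high_cutoff=450,
        )
        hist = make_hist({300: 1000})  # no mass in the alpha window
        ratio, rate = estimate_heterozygosity(peaks, hist, 19)
        assert rate == 0.0
        assert ratio == pytest.approx(0.1)


@pytest.fixture(scope="module")
def small_sim_hist():
    """300 kb diploid, 50x error-free coverage, k=19."""
    genome = synthesize_diploid(
        SimulationConfig(haploid_length=300_000, seed=21)
    )
    reads = simulate_reads(genome, ReadSimConfig(coverage=50, error_rate=0.0, seed=22))
    return genome, count_canonical_kmers(reads, 19)


class TestProfileRecovery:
    def test_genome_size_and_repeat_recovery(self, small_sim_hist):
        genome, hist = small_sim_hist
        prof = profile(hist)
        assert abs(prof.genome_size - len(genome)) / len(genome) < 0.05
        assert abs(prof.repeat_fraction - 0.45) < 0.10

    def test_het_rate_recovered_within_factor_two(self, small_sim_hist):
        _, hist = small_sim_hist
        prof = profile(hist)
        assert 0.0007 <= prof.het_rate <= 0.0028

    def test_fraction_identity_and_bounds(self, small_sim_hist):
        _, hist = small_sim_hist
        prof = profile(hist)
        assert prof.single_copy_fraction + prof.repeat_fraction == pytest.approx(1.0)
        assert 0 <= prof.single_copy_fraction <= 1
        assert prof.single_copy_size <= prof.genome_size * 1.05

    def test_repeat_free_genome_mostly_single_copy(self):
        genome = synthesize_diploid(
            SimulationConfig(haploid_length=200_000, repeat_fraction=0.0, seed=31)
        )
        reads = simulate_reads(genome, ReadSimConfig(coverage=50, error_rate=0.0, seed=32))
        prof = profile(count_canonical_kmers(reads, 19))
        assert prof.single_copy_fraction >= 0.9
        assert abs(prof.genome_size - len(genome)) / len(genome) < 0.05

    def test_het_ratio_monotone_in_true_het_rate(self):
        ratios = []
        for het in (0.0, 0.001, 0.005, 0.01):
            genome = synthesize_diploid(
                SimulationConfig(
                    haploid_length=150_000, repeat_fraction=0.0, het_rate=het, seed=41
                )
            )
            reads = simulate_reads(
                genome, ReadSimConfig(coverage=50, error_rate=0.0, seed=42)
            )
            ratios.append(profile(count_canonical_kmers(reads, 19)).het_ratio)
        assert ratios == sorted(ratios)
        assert ratios[0] == 0.0

    def test_profile_requires_totals(self):
        hist = KmerHistogram(k=19, freq={50: 100, 51: 120, 52: 100})
        with pytest.raises(Exception, match="total_bases"):
            profile(hist)


def test_plot_spectrum_writes_png(small_sim_hist, tmp_path):
    _, hist = small_sim_hist
    peaks = detect_peaks(hist)
    out = tmp_path / "spectrum.png"
    plot_spectrum(hist, peaks, out)
    assert out.stat().st_size > 0
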