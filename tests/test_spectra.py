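"""Histogram/quantile motion spectra, q_s skewness, peak position and Q_mf."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestmotion import (
    MotionSpectrum,
    base_motion_ratio,
    count_modes,
    histogram_spectrum,
    peak_position,
    quantile_spectrum,
    scale_episode,
    skewness_qs,
)


def make_spectrum(rel_counts, peak_bin=None):
    """Hand-built spectrum on a unit log-range abscissa."""
    rel = np.asarray(rel_counts, dtype=float)
    edges = np.linspace(0.0, 3.0, len(rel) + 1)
    if peak_bin is None:
        peak_bin = int(np.argmax(rel))
    return MotionSpectrum(
        bin_edges=edges,
        rel_counts=rel,
        peak_bin=peak_bin,
        n_frames=1000,
        episode_max=999,
    )


class TestHistogramSpectrum:
    def test_identical_counts_occupy_single_bin(self):
        spec = histogram_spectrum(np.full(200, 37), episode_max=100)
        assert np.count_nonzero(spec.rel_counts) == 1
        assert spec.rel_counts.max() == 1.0

    def test_matches_brute_force_binning(self, rng):
        counts = rng.integers(0, 2_000, 1_000)
        emax = int(counts.max())
        spec = histogram_spectrum(counts, episode_max=emax)
        edges = spec.bin_edges
        brute = np.zeros(50)
        for c in counts:
            y = np.log10(c + 1.0)
            for b in range(50):
                upper_ok = y <= edges[b + 1] if b == 49 else y < edges[b + 1]
                if edges[b] <= y and upper_ok:
                    brute[b] += 1
                    break
        assert np.allclose(spec.rel_counts, brute / len(counts))

    def test_lognormal_counts_give_near_gaussian_spectrum(self, rng):
        counts = rng.lognormal(np.log(200), 0.35, 20_000).astype(int)
        spec = histogram_spectrum(counts, episode_max=int(counts.max()))
        assert count_modes(spec) == 1
        qs = skewness_qs(spec)
        assert not qs.degenerate
        assert 0.5 < qs.q_s < 2.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 3_000))
    def test_rel_counts_always_sum_to_one(self, seed, n):
        counts = np.random.default_rng(seed).integers(0, 5_000, n)
        spec = histogram_spectrum(counts)
        assert spec.rel_counts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_counts_flagged_degenerate(self):
        spec = histogram_spectrum(np.zeros(100, dtype=int))
        assert spec.degenerate
        assert spec.rel_counts[0] == 1.0

    def test_episode_max_below_session_max_rejected(self):
        with pytest.raises(ValueError):
            histogram_spectrum([1, 2, 500], episode_max=100)

    def test_episode_scaling_reaches_unit_maximum(self, rng):
        specs = [
            histogram_spectrum(rng.integers(0, 900, 300), episode_max=900)
            for _ in range(6)
        ]
        scale_episode(specs)
        assert max(s.episode_scaled.max() for s in specs) == pytest.approx(1.0)


class TestSkewness:
    def test_symmetric_spectrum_has_unit_skewness(self):
        rel = np.zeros(50)
        rel[25] = 0.3
        for d in range(1, 10):
            rel[25 - d] = rel[25 + d] = 0.035
        spec = make_spectrum(rel / rel.sum())
        assert skewness_qs(spec).q_s == pytest.approx(1.0)

    def test_constructed_tail_areas_give_two(self):
        # uT_a = 0.2 (bins >= peak+5), lT_a = 0.1 (bins <= peak-5)
        rel = np.zeros(50)
        rel[25] = 0.7
        rel[31] = 0.2
        rel[19] = 0.1
        res = skewness_qs(make_spectrum(rel))
        assert res.upper_tail_area == pytest.approx(0.2)
        assert res.lower_tail_area == pytest.approx(0.1)
        assert res.q_s == pytest.approx(2.0)

    def test_empty_tails_flagged_degenerate(self):
        rel = np.zeros(50)
        rel[24:27] = [0.3, 0.4, 0.3]
        res = skewness_qs(make_spectrum(rel))
        assert res.degenerate
        assert res.q_s == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mirroring_inverts_the_quotient(self, seed):
        rng = np.random.default_rng(seed)
        rel = rng.random(50) * 0.01
        rel[0] = 0.0  # support on bins 1..49 so bin i mirrors to bin 50-i
        rel[25] = 1.0  # unambiguous central peak, fixed under the mirror
        rel = rel / rel.sum()
        mirrored = np.zeros(50)
        mirrored[1:] = rel[1:][::-1]
        q = skewness_qs(make_spectrum(rel, peak_bin=25))
        q_m = skewness_qs(make_spectrum(mirrored, peak_bin=25))
        assert q_m.q_s == pytest.approx(1.0 / q.q_s, rel=1e-9)

    def test_burst_cohort_creates_right_dominance_and_removal_restores(self, rng):
        # quiescent cohort built symmetric (in log space) about a bin center,
        # so its spectrum alone is balanced; a small high-magnitude burst
        # cohort must tip q_s above 1, and removing it must restore balance.
        emax = 3_000
        edges = np.linspace(0.0, np.log10(emax + 1.0), 51)
        center = 0.5 * (edges[25] + edges[26])
        offsets = np.abs(rng.normal(0.0, 0.35, 9_000))
        y = np.concatenate([center + offsets, center - offsets])
        quiescent = np.round(10.0**y - 1.0).astype(int).clip(0)
        bursts = (
            np.round(10.0 ** rng.normal(3.1, 0.12, 2_000) - 1.0).astype(int).clip(0, emax)
        )
        mixture = np.concatenate([quiescent, bursts])
        q_mix = skewness_qs(histogram_spectrum(mixture, episode_max=emax))
        q_base = skewness_qs(histogram_spectrum(quiescent, episode_max=emax))
        assert q_mix.q_s > 1.0
        assert q_base.q_s == pytest.approx(1.0, abs=0.15)


class TestPeakPosition:
    def test_extreme_point_masses(self):
        lo = np.zeros(50)
        lo[0] = 1.0
        hi = np.zeros(50)
        hi[49] = 1.0
        assert peak_position(make_spectrum(lo)) == 0.0
        assert peak_position(make_spectrum(hi)) == 1.0

    def test_mass_flight_shifts_peak_right(self, rng):
        quiet = rng.lognormal(np.log(50), 0.3, 5_000).astype(int)
        mfa = rng.lognormal(np.log(500), 0.3, 5_000).astype(int)
        emax = int(max(quiet.max(), mfa.max()))
        p_quiet = peak_position(histogram_spectrum(quiet, episode_max=emax))
        p_mfa = peak_position(histogram_spectrum(mfa, episode_max=emax))
        assert p_mfa > p_quiet


class TestBaseMotionRatio:
    def _spectra(self, rng, scale=1.0):
        out = {}
        for z in ("sz1", "sz2", "sz3", "sz4", "sz5"):
            counts = (rng.lognormal(np.log(400), 0.4, 6_000) * scale).astype(int)
            out[z] = histogram_spectrum(counts, episode_max=max(int(counts.max()), 2_000))
        return out

    def test_identity_comparison_gives_unity(self, rng):
        a = self._spectra(rng)
        res = base_motion_ratio(a, a)
        assert all(v == pytest.approx(1.0) for v in res.per_zone.values())

    def test_halved_counts_give_half_ratio(self, rng):
        a = {}
        b = {}
        for z in ("sz1", "sz2", "sz3", "sz4", "sz5"):
            counts = rng.lognormal(np.log(400), 0.4, 6_000).astype(int)
            emax = int(counts.max())
            a[z] = histogram_spectrum(counts, episode_max=emax)
            b[z] = histogram_spectrum(counts // 2, episode_max=emax)
        res = base_motion_ratio(a, b)
        assert res.mean == pytest.approx(0.5, abs=0.05)

    def test_mean_is_arithmetic_mean_of_zone_ratios(self, rng):
        a = self._spectra(rng)
        b = self._spectra(rng, scale=0.7)
        res = base_motion_ratio(a, b)
        assert res.mean == pytest.approx(np.mean(list(res.per_zone.values())))


class TestQuantileSpectrum:
    def test_constant_counts(self):
        qs = quantile_spectrum(np.full(500, 120), episode_max=240)
        assert qs.slope_030_090 == 0.0
        assert qs.low_base == pytest.approx(0.5)

    def test_uniform_counts_closed_form(self, rng):
        counts = rng.integers(0, 10_001, 10_000)
        qs = quantile_spectrum(counts, episode_max=10_000)
        assert qs.slope_030_090 == pytest.approx(1.0, abs=0.05)
        assert qs.low_base == pytest.approx(0.05, abs=0.02)

    def test_burst_cohort_raises_slope_but_not_low_base(self, rng):
        base = rng.uniform(0.0, 0.3, 9_000)
        burst = rng.uniform(0.7, 1.0, 1_000)
        plain = quantile_spectrum((base * 1_000).astype(int), episode_max=1_000)
        mixed = quantile_spectrum(
            (np.concatenate([base, burst]) * 1_000).astype(int), episode_max=1_000
        )
        assert mixed.slope_030_090 > plain.slope_030_090
        assert abs(mixed.low_base - plain.low_base) < 0.01

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            quantile_spectrum(np.arange(50))

    def test_median_agrees_with_histogram_spectrum(self, rng):
        counts = rng.lognormal(np.log(150), 0.5, 5_000).astype(int)
        emax = int(counts.max())
        spec = histogram_spectrum(counts, episode_max=emax)
        qs = quantile_spectrum(counts, episode_max=emax)
        # histogram bin containing the median of the distribution
        cum = np.cumsum(spec.rel_counts)
        med_bin = int(np.searchsorted(cum, 0.5))
        med_log = np.log10(np.quantile(qs.values, 0.5) * emax + 1.0)
        width = spec.bin_edges[1] - spec.bin_edges[0]
        assert spec.bin_edges[med_bin] - width <= med_log <= spec.bin_edges[med_bin + 1] + width
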