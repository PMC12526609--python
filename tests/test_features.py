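"""Feature-bank oracles: closed forms, hand arithmetic and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import somnostage as ss
from somnostage import features as F

from .conftest import FS, sine


class TestTimeDomain:
    def test_sine_closed_forms(self):
        x = sine(10.0, seconds=5.0)          # integer number of periods
        td = F.time_domain_features(x, FS)
        assert td["rms"] == pytest.approx(1 / math.sqrt(2), abs=1e-3)
        assert td["mean"] == pytest.approx(0.0, abs=1e-6)
        assert td["zcr"] == pytest.approx(20.0, abs=0.5)

    def test_constant_signal(self):
        td = F.time_domain_features(np.full(100, 2.5), FS)
        assert td["variance"] == 0 and td["zcr"] == 0 and td["aac"] == 0
        assert td["ssi"] == pytest.approx(100 * 2.5 ** 2)
        assert td["skewness"] == 0 and td["kurtosis"] == 0

    def test_hand_arithmetic_on_four_samples(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        td = F.time_domain_features(x, 1.0)
        assert td["max"] == 2 and td["min"] == -2
        assert td["aac"] == pytest.approx((2 + 3 + 4) / 3)
        assert td["iqr"] == pytest.approx(td["p75"] - td["p25"])
        assert td["ssi"] == pytest.approx(1 + 1 + 4 + 4)
        assert td["rms"] == pytest.approx(math.sqrt(10 / 4))

    def test_gaussian_kurtosis_is_three(self, rng):
        """Kurtosis is non-excess: a long Gaussian sample gives ≈3."""
        x = rng.standard_normal(200_000)
        td = F.time_domain_features(x, FS)
        assert td["kurtosis"] == pytest.approx(3.0, abs=0.1)
        assert td["skewness"] == pytest.approx(0.0, abs=0.05)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
    def test_scaling_and_offset_laws(self, k, c):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(640)
        base = F.time_domain_features(x, FS)
        scaled = F.time_domain_features(k * x, FS)
        assert scaled["variance"] == pytest.approx(k ** 2 * base["variance"],
                                                   rel=1e-9)
        assert scaled["ssi"] == pytest.approx(k ** 2 * base["ssi"], rel=1e-9)
        assert scaled["zcr"] == base["zcr"]
        assert scaled["skewness"] == pytest.approx(base["skewness"], rel=1e-7)
        assert scaled["kurtosis"] == pytest.approx(base["kurtosis"], rel=1e-7)
        shifted = F.time_domain_features(x + c, FS)
        assert shifted["variance"] == pytest.approx(base["variance"], rel=1e-7)
        assert shifted["zcr"] == base["zcr"]


class TestHjorth:
    def test_sine_mobility_matches_angular_frequency(self):
        f0 = 2.0
        x = sine(f0, seconds=10.0)
        h = F.hjorth_parameters(x, FS)
        assert h["mobility"] == pytest.approx(2 * math.pi * f0, rel=0.02)
        assert h["complexity"] == pytest.approx(1.0, rel=0.05)

    def test_activity_equals_sample_variance(self, rng):
        x = rng.standard_normal(640)
        h = F.hjorth_parameters(x, FS)
        assert h["activity"] == np.var(x, ddof=1)

    def test_matches_independent_two_pass_implementation(self, rng):
        x = rng.standard_normal(640)
        h = F.hjorth_parameters(x, FS)
        # independent recomputation from the definitions
        d1 = np.diff(x) * FS
        d2 = np.diff(d1) * FS
        mob = math.sqrt(np.var(d1, ddof=1) / np.var(x, ddof=1))
        mob_d = math.sqrt(np.var(d2, ddof=1) / np.var(d1, ddof=1))
        assert h["mobility"] == pytest.approx(mob, abs=1e-10)
        assert h["complexity"] == pytest.approx(mob_d / mob, abs=1e-10)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(F.DegenerateSegmentError):
            F.hjorth_parameters(np.ones(100), FS)


class TestWelchPsd:
    def test_tone_peaks_at_its_frequency(self):
        psd = F.welch_psd(sine(10.0), FS)
        assert psd.freqs[int(np.argmax(psd.density))] == pytest.approx(
            10.0, abs=psd.df)

    def test_parseval_for_white_noise(self, rng):
        x = 2.0 * rng.standard_normal(int(FS * 5))
        psd = F.welch_psd(x, FS)
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_zero_signal_gives_zero_density(self):
        psd = F.welch_psd(np.zeros(640), FS)
        assert np.all(psd.density == 0)

    def test_subwindow_longer_than_segment_rejected(self):
        with pytest.raises(ValueError):
            F.welch_psd(np.ones(100), FS, subwin_sec=2.0)


class TestBandPowers:
    def test_alpha_tone_concentrates_in_alpha(self):
        psd = F.welch_psd(sine(10.0), FS)
        bp = F.band_powers(psd)
        assert bp["rsp_alpha"] >= 0.95

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        # long signal so per-band estimates are stable
        x = rng.standard_normal(int(FS * 60))
        psd = F.welch_psd(x, FS)
        bp = F.band_powers(psd)
        scheme = F.BandScheme()
        per_hz = {}
        for b, (lo, hi) in scheme.bands.items():
            grid = psd.freqs[(psd.freqs >= lo) & (psd.freqs <= hi)]
            per_hz[b] = bp[f"power_{b}"] / (grid[-1] - grid[0])
        ref = np.mean(list(per_hz.values()))
        for b, v in per_hz.items():
            assert v == pytest.approx(ref, rel=0.15), b

    def test_total_power_bounds_band_sum(self, night_segments):
        seg = night_segments[0]
        psd = F.welch_psd(seg.samples, seg.fs)
        bp = F.band_powers(psd)
        band_sum = sum(bp[f"power_{b}"] for b in F.BandScheme().bands)
        assert bp["total_power"] >= band_sum - 1e-9

    def test_rsp_within_unit_interval_and_sums_below_one(self, night_segments):
        for seg in night_segments[:20]:
            bp = F.band_powers(F.welch_psd(seg.samples, seg.fs))
            rsps = [bp[f"rsp_{b}"] for b in F.BandScheme().bands]
            assert all(0.0 <= r <= 1.0 for r in rsps)
            assert sum(rsps) <= 1.0 + 1e-9


class TestRatiosAndIndices:
    _powers = {
        "power_delta": 4.0, "power_theta": 2.0, "power_alpha": 1.0,
        "power_beta": 1.0, "power_gamma": 0.5,
    }

    def test_ratio_arithmetic(self):
        r = F.power_ratios(self._powers)
        assert r["dar"] == 4.0 and r["dtr"] == 2.0
        assert r["dtabr"] == pytest.approx((4 + 2) / (1 + 1))

    def test_equal_band_powers_give_unit_ratios(self):
        eq = {f"power_{b}": 2.0 for b in
              ("delta", "theta", "alpha", "beta", "gamma")}
        r = F.power_ratios(eq)
        assert r["dar"] == r["dtr"] == r["dtabr"] == 1.0

    def test_theta_delta_is_reciprocal_of_dtr(self):
        r = F.power_ratios(self._powers)
        assert r["dtr"] * r["theta_delta"] == pytest.approx(1.0)

    def test_slow_wave_index_arithmetic(self):
        p = {"power_delta": 8.0, "power_theta": 1.0, "power_alpha": 1.0}
        swi = F.slow_wave_indices(p)
        assert swi["dsi"] == pytest.approx(4.0)
        assert swi["tsi"] == pytest.approx(1 / 9)
        assert swi["asi"] == pytest.approx(1 / 9)

    def test_equal_powers_give_half(self):
        p = {"power_delta": 3.0, "power_theta": 3.0, "power_alpha": 3.0}
        swi = F.slow_wave_indices(p)
        assert swi == pytest.approx({"dsi": 0.5, "tsi": 0.5, "asi": 0.5})

    def test_zero_denominator_is_degenerate(self):
        bad = dict(self._powers, power_alpha=0.0)
        with pytest.raises(F.DegenerateSegmentError):
            F.power_ratios(bad)


class TestSpectralShape:
    def test_flat_density_has_zero_slope(self):
        psd = F.PSDEstimate(freqs=np.arange(1.0, 40.0),
                            density=np.ones(39))
        assert F.spectral_slope(psd, 1.0, 39.0) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_density_recovers_slope(self):
        f = np.arange(1.0, 40.0)
        psd = F.PSDEstimate(freqs=f, density=100.0 - 1.7 * f)
        assert F.spectral_slope(psd, 1.0, 40.0) == pytest.approx(-1.7,
                                                                 abs=1e-10)

    def test_slope_matches_normal_equations_oracle(self, rng):
        f = np.arange(0.5, 44.5, 0.5)
        d = rng.random(f.size)
        psd = F.PSDEstimate(freqs=f, density=d)
        lo, hi = 4.0, 30.0
        m = (f >= lo) & (f <= hi)
        X = np.vstack([np.ones(m.sum()), f[m]]).T
        beta = np.linalg.solve(X.T @ X, X.T @ d[m])
        assert F.spectral_slope(psd, lo, hi) == pytest.approx(beta[1],
                                                              abs=1e-10)

    def test_dominant_frequency_of_tone(self):
        psd = F.welch_psd(sine(6.0), FS)
        assert F.dominant_frequency(psd) == pytest.approx(6.0, abs=psd.df)

    def test_dominant_frequency_tie_goes_low(self):
        f = np.arange(0.5, 44.5, 0.5)
        d = np.zeros(f.size)
        d[np.searchsorted(f, 5.0)] = 1.0
        d[np.searchsorted(f, 15.0)] = 1.0
        psd = F.PSDEstimate(freqs=f, density=d)
        assert F.dominant_frequency(psd) == pytest.approx(5.0, abs=0.51)

    def test_harmonic_parameters_of_two_equal_lines(self):
        f = np.arange(0.5, 44.5, 0.5)
        d = np.zeros(f.size)
        i1, i2 = np.searchsorted(f, [5.0, 15.0])
        d[i1] = d[i2] = 1.0
        h = F.harmonic_parameters(F.PSDEstimate(freqs=f, density=d))
        assert h["harmonic_center"] == pytest.approx(10.0)
        assert h["harmonic_bandwidth"] == pytest.approx(5.0)

    def test_harmonic_center_of_single_line(self):
        f = np.arange(0.5, 44.5, 0.5)
        d = np.zeros(f.size)
        d[np.searchsorted(f, 20.0)] = 3.0
        h = F.harmonic_parameters(F.PSDEstimate(freqs=f, density=d))
        assert h["harmonic_center"] == pytest.approx(20.0)
        assert h["harmonic_bandwidth"] == pytest.approx(0.0, abs=1e-9)


class TestSef:
    def test_single_tone_has_small_sefd(self):
        """A pure tone concentrates the cumulative spectrum at one line;
        SEFd collapses to the width of the spectral peak (grid + leakage)."""
        out = F.sef_difference(sine(10.0), FS)
        assert out["sef50"] == pytest.approx(10.0, abs=1.0)
        assert 0.0 <= out["sefd"] <= 2.0

    def test_sef95_never_below_sef50(self, night_segments):
        for seg in night_segments[:20]:
            out = F.sef_difference(seg.samples, seg.fs)
            assert out["sef95"] >= out["sef50"]

    def test_white_noise_approaches_uniform_spectrum_values(self, rng):
        """For a flat spectrum on [0.5, 44], SEFq ≈ 0.5 + q×43.5."""
        vals = [F.sef_difference(rng.standard_normal(int(FS * 5)), FS)["sefd"]
                for _ in range(20)]
        expected = (0.95 - 0.50) * 43.5
        assert np.mean(vals) == pytest.approx(expected, rel=0.12)


class TestEntropies:
    def test_single_line_spectral_entropy_is_zero(self):
        f = np.arange(0.5, 44.5, 0.5)
        d = np.zeros(f.size)
        d[20] = 5.0
        assert F.spectral_entropy(F.PSDEstimate(freqs=f, density=d)) == 0.0

    def test_uniform_density_entropy_is_one(self):
        f = np.arange(0.5, 44.5, 0.5)
        psd = F.PSDEstimate(freqs=f, density=np.ones(f.size))
        assert F.spectral_entropy(psd) == pytest.approx(1.0)

    def test_white_noise_spectral_entropy_is_high(self, rng):
        psd = F.welch_psd(rng.standard_normal(int(FS * 5)), FS)
        assert F.spectral_entropy(psd) >= 0.9

    def test_svd_entropy_of_constant_is_zero(self):
        assert F.svd_entropy(np.full(200, 3.0)) == 0.0

    def test_svd_entropy_matches_full_decomposition_oracle(self, rng):
        x = rng.standard_normal(400)
        m, tau = 10, 1
        rows = [x[i: i + m] for i in range(x.size - (m - 1) * tau)]
        s = np.linalg.svd(np.array(rows), compute_uv=False)
        sb = s / s.sum()
        expected = float(-(sb * np.log2(sb)).sum() / np.log2(m))
        assert F.svd_entropy(x, m, tau) == pytest.approx(expected, abs=1e-8)

    def test_svd_entropy_bounded(self, night_segments):
        for seg in night_segments[:10]:
            assert 0.0 <= F.svd_entropy(seg.samples) <= 1.0

    def test_renyi_uniform_16_bins_is_4_bits(self):
        x = np.repeat(np.arange(16.0), 10)
        assert F.renyi_entropy(x, 2.0, 16) == pytest.approx(4.0)

    def test_renyi_one_bin_is_zero(self):
        assert F.renyi_entropy(np.full(50, 1.0)) == 0.0

    def test_renyi_matches_histogram_oracle(self, rng):
        x = rng.standard_normal(1000)
        counts, _ = np.histogram(x, bins=16)
        p = counts / counts.sum()
        expected = float(-np.log2(np.sum(p[p > 0] ** 2)))
        assert F.renyi_entropy(x, 2.0, 16) == pytest.approx(expected,
                                                            abs=1e-10)


class TestLempelZiv:
    @pytest.mark.parametrize("bits, expected", [
        ("0001", 2),
        ("0101010101", 3),
        ("0", 1),
        ("01", 2),
    ])
    def test_hand_parsed_phrase_counts(self, bits, expected):
        arr = np.array([int(b) for b in bits], dtype=np.int8)
        assert F._lz76_count(arr) == expected

    def test_normalized_complexity_of_random_sequence_near_one(self, rng):
        x = rng.standard_normal(10_000)
        out = F.lempel_ziv_complexity(x)
        assert 0.8 <= out["lzc"] <= 1.2

    def test_phrase_count_grows_with_novel_content(self, rng):
        """Appending new material to a fixed binary prefix can only add
        phrases (monotonicity of the exhaustive-history parse)."""
        bits = (rng.random(600) >= 0.5).astype(np.int8)
        c_prefix = F._lz76_count(bits[:500])
        c_full = F._lz76_count(bits)
        assert c_full >= c_prefix


class TestExtractFeatures:
    def test_default_bank_has_100_finite_values(self, night_segments):
        fv = F.extract_features(night_segments[0])
        assert len(fv.values) == 100
        assert set(fv.values) == set(F.DEFAULT_BANK)
        assert all(np.isfinite(v) for v in fv.values.values())
        assert not fv.degenerate

    def test_constant_segment_is_flagged_degenerate(self):
        seg = ss.Segment(samples=np.full(int(FS * 5), 1.0), fs=FS,
                         start_index=0)
        fv = F.extract_features(seg)
        assert fv.degenerate

    def test_extraction_is_deterministic(self, night_segments):
        a = F.extract_features(night_segments[3])
        b = F.extract_features(night_segments[3])
        assert a.values == b.values

    def test_unknown_feature_name_rejected(self, night_segments):
        with pytest.raises(KeyError):
            F.extract_features(night_segments[0], bank=["rms", "nope"])

    def test_dataframe_carries_labels_and_manifest_order(self, night_segments):
        df = F.features_dataframe(night_segments[:12], recording_id="r0")
        assert list(df.columns[:100]) == F.DEFAULT_BANK
        assert set(df["label"]) <= set(ss.STAGES) | {ss.UNSCORED}
        assert (df["recording_id"] == "r0").all()
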