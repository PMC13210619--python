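"""Spectral and coherence feature extraction: scalar primitives, the named
vectors, scale invariances and brute-force estimator oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegscreen.containers import MONTAGE, Segment
from eegscreen.features import (
    BANDS, EstimatorConfig, asymmetry, band_power, coherence_spectrum,
    connectivity_feature_names, connectivity_vector, extract_features, fuse,
    fused_feature_names, log_abs_power, psd, relative_power,
    spectral_feature_names, spectral_vector,
)

FS = 256.0
EPOCH = 1024


def _segment(samples, key="H_S1"):
    return Segment(subject_key=key, condition="EO", samples=samples,
                   sampling_rate=FS, index=0, channels=MONTAGE)


def _tone(freq, n=EPOCH, amp=1.0, phase=0.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestPsdAndBandPower:
    def test_tone_peak_bin(self):
        freqs, dens = psd(_tone(10.0, n=4096), FS)
        assert freqs[np.argmax(dens)] == pytest.approx(10.0, abs=0.5)

    def test_parseval_white_noise(self):
        """Integrated PSD over (0, Nyquist) recovers the signal variance
        (10% on the average over 100 realizations)."""
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(100):
            x = rng.standard_normal(2048) * 3.0
            freqs, dens = psd(x, FS)
            total = np.trapezoid(dens, freqs)
            ratios.append(total / x.var())
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.1)

    def test_zero_signal_zero_psd(self):
        _, dens = psd(np.zeros(2048), FS)
        assert np.all(dens == 0)

    def test_signal_shorter_than_window(self):
        with pytest.raises(ValueError):
            psd(np.zeros(100), FS)

    def test_tone_concentrates_in_alpha(self):
        freqs, dens = psd(_tone(10.0, n=4096), FS)
        powers = {b.name: band_power(freqs, dens, b) for b in BANDS}
        for name, p in powers.items():
            if name != "alpha":
                assert powers["alpha"] > 100 * max(p, 1e-12)

    def test_flat_psd_rectangle_integral(self):
        freqs = np.arange(0, 128.5, 0.5)
        dens = np.full_like(freqs, 2.0)
        beta = next(b for b in BANDS if b.name == "beta")
        assert band_power(freqs, dens, beta) \
            == pytest.approx(2.0 * (beta.high - beta.low))

    def test_band_outside_range(self):
        freqs = np.arange(0, 10.5, 0.5)
        with pytest.raises(ValueError):
            band_power(freqs, np.ones_like(freqs),
                       next(b for b in BANDS if b.name == "gamma"))

    def test_welch_matches_periodogram_oracle(self):
        """Brute-force oracle: band power by direct periodogram integration
        agrees with the Welch path on 100 random short signals."""
        from scipy.signal import periodogram

        rng = np.random.default_rng(7)
        beta = next(b for b in BANDS if b.name == "beta")
        rel_errs, ratios = [], []
        for _ in range(100):
            x = rng.standard_normal(EPOCH)
            fw, dw = psd(x, FS)
            welch_bp = band_power(fw, dw, beta)
            fp, dp = periodogram(x, fs=FS)
            df = fp[1] - fp[0]
            mask = (fp >= beta.low) & (fp < beta.high)
            oracle_bp = dp[mask].sum() * df
            rel_errs.append(abs(welch_bp - oracle_bp) / oracle_bp)
            ratios.append(welch_bp / oracle_bp)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)
        assert np.median(rel_errs) < 0.15


class TestScalars:
    @pytest.mark.parametrize("powers,expected", [
        ((1, 1, 1, 1, 1), (0.2,) * 5),
        ((0, 0, 4, 0, 0), (0, 0, 1, 0, 0)),
        ((1, 2, 3, 4, 10), (0.05, 0.10, 0.15, 0.20, 0.50)),
    ])
    def test_relative_power(self, powers, expected):
        assert relative_power(np.array(powers, float)) \
            == pytest.approx(expected)

    def test_relative_power_all_zero_errors(self):
        with pytest.raises(ValueError):
            relative_power(np.zeros(5))

    @pytest.mark.parametrize("power,expected", [
        (np.e, 1.0), (1.0, 0.0), (0.0, np.log(1e-12)),
    ])
    def test_log_abs_power(self, power, expected):
        assert log_abs_power(power) == pytest.approx(expected)

    @pytest.mark.parametrize("r,l,expected", [
        (2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (0.0, 2.0, -1.0),
    ])
    def test_asymmetry(self, r, l, expected):
        assert asymmetry(r, l) == pytest.approx(expected)

    def test_asymmetry_both_zero_errors(self):
        with pytest.raises(ValueError):
            asymmetry(0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_asymmetry_bounded(self, r, l):
        assert -1.0 <= asymmetry(r, l) <= 1.0


class TestSpectralVector:
    def _noise_segment(self, seed=0):
        rng = np.random.default_rng(seed)
        return _segment(rng.standard_normal((8, EPOCH)) * 10.0)

    def test_ninety_finite_named_values(self):
        v = spectral_vector(self._noise_segment())
        assert list(v.index) == spectral_feature_names()
        assert len(v) == 90
        assert np.all(np.isfinite(v.to_numpy()))

    def test_block_sizes(self):
        names = spectral_feature_names()
        assert sum("_rel_" in n for n in names) == 40
        assert sum("_logabs_" in n for n in names) == 40
        assert sum("_asym_" in n for n in names) == 10

    def test_relative_powers_sum_to_one_per_channel(self):
        v = spectral_vector(self._noise_segment(1))
        for ch in MONTAGE:
            total = sum(v[f"{b.name}_rel_{ch}"] for b in BANDS)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_hemispheres_zero_asymmetry(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, EPOCH))
        for left, right in (("Fp1", "Fp2"), ("F3", "F4"),
                            ("C3", "C4"), ("P3", "P4")):
            x[MONTAGE.index(right)] = x[MONTAGE.index(left)]
        v = spectral_vector(_segment(x))
        for name in v.index:
            if "_asym_" in name:
                assert v[name] == pytest.approx(0.0, abs=1e-12)

    def test_planted_beta_effect_recovered(self, default_run):
        """Patient-class mean relative beta at F3 exceeds the control mean
        (well over 200 segments per class)."""
        from eegscreen.cohort import parse_subject_key

        ds = default_run.dataset
        labels = np.array([parse_subject_key(k)[0] for k in ds.subject_keys])
        assert (labels == "MDD").sum() > 200 and (labels == "H").sum() > 200
        col = ds.features["beta_rel_F3"]
        assert col[labels == "MDD"].mean() > col[labels == "H"].mean()


class TestCoherence:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(0).standard_normal(EPOCH)
        _, coh = coherence_spectrum(x, x, FS)
        assert np.allclose(coh, 1.0, atol=1e-9)

    def test_affine_invariance(self):
        x = np.random.default_rng(1).standard_normal(EPOCH)
        _, c1 = coherence_spectrum(x, x, FS)
        _, c2 = coherence_spectrum(x, 2.0 * x + 5.0, FS)
        assert np.allclose(c1, c2, atol=1e-6)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, EPOCH))
        _, cxy = coherence_spectrum(x, y, FS)
        _, cyx = coherence_spectrum(y, x, FS)
        assert np.allclose(cxy, cyx)

    def test_independent_noise_floor(self):
        """100 independent pairs: mean coherence stays under 0.2."""
        rng = np.random.default_rng(3)
        means = []
        for _ in range(100):
            x, y = rng.standard_normal((2, EPOCH))
            _, coh = coherence_spectrum(x, y, FS)
            means.append(coh.mean())
        assert np.mean(means) < 0.2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            coherence_spectrum(np.zeros(512), np.zeros(256), FS)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            coherence_spectrum(np.zeros(256), np.zeros(256), FS)


class TestConnectivityVector:
    def test_56_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        v = connectivity_vector(_segment(rng.standard_normal((8, EPOCH))))
        assert list(v.index) == connectivity_feature_names()
        assert len(v) == 56
        assert np.all((v.to_numpy() >= 0) & (v.to_numpy() <= 1))

    def test_28_pairs_enumerated(self):
        names = connectivity_feature_names()
        alpha = [n for n in names if n.startswith("alpha_coh_")]
        beta = [n for n in names if n.startswith("beta_coh_")]
        assert len(alpha) == len(beta) == 28

    def test_shared_alpha_source_pair_coheres(self):
        """Two channels fed the same latent alpha source (weight 1, tiny
        independent noise) show alpha coherence > 0.9."""
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(4)
        sos = butter(4, [8, 12], btype="bandpass", fs=FS, output="sos")
        shared = sosfiltfilt(sos, rng.standard_normal(EPOCH))
        shared /= shared.std()
        x = rng.standard_normal((8, EPOCH)) * 0.05
        x[0] += shared
        x[1] += shared
        v = connectivity_vector(_segment(x))
        assert v["alpha_coh_Fp1_Fp2"] > 0.9


class TestFusionAndInvariances:
    def test_fusion_order_and_slice(self):
        rng = np.random.default_rng(0)
        seg = _segment(rng.standard_normal((8, EPOCH)) * 10)
        s, c = spectral_vector(seg), connectivity_vector(seg)
        f = fuse(s, c)
        assert list(f.index) == fused_feature_names()
        assert len(f) == 146
        assert np.array_equal(f.iloc[:90].to_numpy(), s.to_numpy())
        assert len(set(f.index)) == 146

    def test_fusion_rejects_wrong_vocabulary(self):
        rng = np.random.default_rng(0)
        seg = _segment(rng.standard_normal((8, EPOCH)))
        s = spectral_vector(seg)
        with pytest.raises(ValueError):
            fuse(s, s)

    @pytest.mark.parametrize("c", [0.1, 3.0, 100.0])
    def test_amplitude_scale_invariance(self, c):
        """Scaling a whole segment by c>0 leaves relative, asymmetry and
        coherence features unchanged and shifts every log-absolute feature
        by exactly 2 ln c."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((8, EPOCH)) * 10
        seg, seg_c = _segment(x), _segment(c * x)
        s1, s2 = spectral_vector(seg), spectral_vector(seg_c)
        c1, c2 = connectivity_vector(seg), connectivity_vector(seg_c)
        for name in s1.index:
            if "_logabs_" in name:
                assert s2[name] - s1[name] \
                    == pytest.approx(2.0 * np.log(c), abs=1e-9)
            else:
                assert s2[name] == pytest.approx(s1[name], abs=1e-9)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-9)

    def test_extract_features_table_shape(self):
        rng = np.random.default_rng(6)
        segs = [_segment(rng.standard_normal((8, EPOCH)), key=f"H_S{i}")
                for i in range(3)]
        table = extract_features(segs)
        assert table.shape == (3, 3 + 146)
        assert list(table.columns[:3]) \
            == ["subject_key", "condition", "segment_index"]
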