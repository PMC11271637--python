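"""Amplitude/phase decomposition, substitution laws, and the batch enhancer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from stainadapt.fourier import (
    EnhancerPolicy,
    Patch,
    decompose,
    enhance_batch,
    recombine,
)

from conftest import random_patch_pixels


def direct_dft2(channel):
    """O(N^4) double-sum DFT oracle, independent of numpy.fft."""
    h, w = channel.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            acc = 0.0 + 0.0j
            for y in range(h):
                for x in range(w):
                    acc += channel[y, x] * np.exp(-2j * np.pi * (u * y / h + v * x / w))
            out[u, v] = acc
    return out


def direct_idft2(spectrum):
    h, w = spectrum.shape
    out = np.zeros((h, w), dtype=complex)
    for y in range(h):
        for x in range(w):
            acc = 0.0 + 0.0j
            for u in range(h):
                for v in range(w):
                    acc += spectrum[u, v] * np.exp(2j * np.pi * (u * y / h + v * x / w))
            out[y, x] = acc / (h * w)
    return out


class TestDecompose:
    def test_constant_patch_has_only_dc(self):
        c, H, W = 0.3, 6, 4
        dec = decompose(Patch(np.full((H, W, 3), c)))
        assert dec.amplitude[0, 0, 0] == pytest.approx(c * H * W, rel=1e-12)
        assert dec.phase[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        off_dc = dec.amplitude.copy()
        off_dc[0, 0, :] = 0
        assert np.abs(off_dc).max() < 1e-10

    def test_delta_patch_flat_spectrum(self):
        pix = np.zeros((4, 4, 3))
        pix[0, 0, :] = 1.0
        dec = decompose(Patch(pix))
        np.testing.assert_allclose(dec.amplitude, 1.0, atol=1e-12)
        np.testing.assert_allclose(dec.phase, 0.0, atol=1e-12)

    def test_non_finite_pixels_rejected(self):
        pix = np.zeros((4, 4, 3))
        patch = Patch(pix)
        patch.pixels[1, 1, 0] = np.nan
        with pytest.raises(ValueError):
            decompose(patch)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pix = random_patch_pixels(rng)
            dec = decompose(Patch(pix))
            np.testing.assert_allclose(recombine(dec, dec), pix, atol=1e-6)


class TestRecombine:
    def test_self_substitution_identity(self):
        rng = np.random.default_rng(1)
        pix = random_patch_pixels(rng, 16, 16)
        dec = decompose(Patch(pix))
        assert np.abs(recombine(dec, dec) - pix).max() < 1e-6

    def test_constant_amplitude_wins(self):
        amp = decompose(Patch(np.full((8, 8, 3), 0.8)))
        pha = decompose(Patch(np.full((8, 8, 3), 0.1)))
        np.testing.assert_allclose(recombine(amp, pha), 0.8, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        a = decompose(Patch(np.zeros((4, 4, 3))))
        b = decompose(Patch(np.zeros((8, 8, 3))))
        with pytest.raises(ValueError):
            recombine(a, b)

    def test_matches_direct_summation_oracle(self):
        # fixed integer-valued 4x4 patches, scaled into [0, 1]
        a16 = np.array([[3, 7, 1, 9], [2, 8, 5, 4], [11, 0, 6, 13], [10, 15, 12, 14]])
        b16 = np.array([[5, 2, 14, 7], [9, 1, 3, 12], [4, 15, 8, 0], [6, 10, 13, 11]])
        pa = np.stack([a16 / 16, (a16.T) / 16, (a16[::-1]) / 16], axis=2)
        pb = np.stack([b16 / 16, (b16.T) / 16, (b16[::-1]) / 16], axis=2)
        ours = recombine(decompose(Patch(pa)), decompose(Patch(pb)), clip=False)
        for ch in range(3):
            sa = direct_dft2(pa[:, :, ch])
            sb = direct_dft2(pb[:, :, ch])
            hybrid = np.abs(sa) * np.exp(1j * np.angle(sb))
            expected = direct_idft2(hybrid).real
            np.testing.assert_allclose(ours[:, :, ch], expected, atol=1e-10)


class TestSubstitutionLaws:
    def _pair(self, seed):
        rng = np.random.default_rng(seed)
        # mid-range pixels keep the hybrid inside [0, 1]: no clipping
        src = Patch(random_patch_pixels(rng, 16, 16, 0.35, 0.65))
        tgt = Patch(random_patch_pixels(rng, 16, 16, 0.35, 0.65))
        return src, tgt

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_amplitude_substitution_law(self, seed):
        src, tgt = self._pair(seed)
        z = recombine(decompose(tgt), decompose(src), clip=False)
        assert z.min() >= 0 and z.max() <= 1, "no clipping in this construction"
        amp_z = decompose(Patch(z)).amplitude
        amp_t = decompose(tgt).amplitude
        np.testing.assert_allclose(amp_z, amp_t, rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_phase_preservation_law(self, seed):
        src, tgt = self._pair(seed)
        z = recombine(decompose(tgt), decompose(src), clip=False)
        dec_z = decompose(Patch(z))
        dec_s = decompose(src)
        sel = decompose(tgt).amplitude > 1e-9
        dphi = np.angle(np.exp(1j * (dec_z.phase - dec_s.phase)))  # mod 2pi
        assert np.abs(dphi[sel]).max() < 1e-5

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        pix = random_patch_pixels(rng, h, w)
        dec = decompose(Patch(pix))
        np.testing.assert_allclose(recombine(dec, dec), pix, atol=1e-6)


class TestEnhanceBatch:
    def _batch(self, n, seed=0, h=8):
        rng = np.random.default_rng(seed)
        return [Patch(random_patch_pixels(rng, h, h), slide_id=f"s{i}",
                      domain="source", label=i % 2) for i in range(n)]

    def test_probability_zero_is_identity(self):
        batch = self._batch(5)
        out = enhance_batch(batch, [], EnhancerPolicy(probability=0.0, rng_seed=1))
        assert all(o is p for o, p in zip(out, batch))

    def test_self_pool_identity_pairing(self):
        batch = self._batch(2, seed=3)
        # find a seed whose pairing is the identity permutation
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rng.random(2)
            if np.array_equal(rng.integers(0, 2, 2), [0, 1]):
                break
        else:
            pytest.fail("no identity-pairing seed found")
        out = enhance_batch(batch, batch, EnhancerPolicy(probability=1.0, rng_seed=seed))
        for o, p in zip(out, batch):
            np.testing.assert_allclose(o.pixels, p.pixels, atol=1e-6)
            assert o.label == p.label and o.domain == "source"

    def test_enhanced_count_within_binomial_interval(self):
        n = 1000
        batch = self._batch(n, h=4)
        pool = self._batch(3, seed=99, h=4)
        policy = EnhancerPolicy(probability=0.5, rng_seed=42)
        out = enhance_batch(batch, pool, policy)
        changed = sum(o is not p for o, p in zip(out, batch))
        lo = binom.ppf(0.0005, n, 0.5)   # central 99.9% interval
        hi = binom.isf(0.0005, n, 0.5)
        assert lo <= changed <= hi

    def test_byte_deterministic_per_seed(self):
        batch = self._batch(8)
        pool = self._batch(4, seed=5)
        policy = EnhancerPolicy(probability=0.7, rng_seed=11)
        a = enhance_batch(batch, pool, policy)
        b = enhance_batch(batch, pool, policy)
        for pa, pb in zip(a, b):
            assert pa.pixels.tobytes() == pb.pixels.tobytes()

    def test_enhanced_keeps_label_and_range(self):
        batch = self._batch(6)
        pool = [Patch(random_patch_pixels(np.random.default_rng(8), 8, 8),
                      domain="target")]
        out = enhance_batch(batch, pool, EnhancerPolicy(probability=1.0, rng_seed=0))
        for o, p in zip(out, batch):
            assert o.label == p.label and o.domain == "source"
            assert o.pixels.min() >= 0 and o.pixels.max() <= 1

    def test_errors(self):
        batch = self._batch(2)
        with pytest.raises(ValueError):
            enhance_batch(batch, [], EnhancerPolicy(probability=0.5))
        small = [Patch(np.zeros((4, 4, 3)), domain="target")]
        with pytest.raises(ValueError):
            enhance_batch(batch, small, EnhancerPolicy(probability=1.0))
        with pytest.raises(ValueError):
            EnhancerPolicy(probability=1.5)
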