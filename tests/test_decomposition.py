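import numpy as np
import pytest

from fracband.decomposition import (
    BAND_ORDER,
    SubbandCoefficients,
    WaveletSpec,
    daubechies_lowpass,
    decompose,
    default_grouping,
    dwt2_analysis,
    subband_energy,
    subband_reconstruct,
    svd_decompose_channel,
)

FAMILIES = ("haar", "db4", "db5", "db8")

# Published db4 decomposition low-pass taps (reference values, 6 d.p.).
DB4_TAPS = [0.230378, 0.714847, 0.630881, -0.027984, -0.187035, 0.030841,
            0.032883, -0.010597]


# ---------------------------------------------------------------------------
# independent reference implementation: direct filter-and-downsample sums
# ---------------------------------------------------------------------------

def _filter_downsample(vec, taps):
    n = len(vec)
    return np.array([
        sum(taps[t] * vec[(2 * k + t) % n] for t in range(len(taps)))
        for k in range(n // 2)
    ])


def reference_analysis(channel, spec):
    """Row filtering + downsampling, then column filtering + downsampling,
    evaluated by explicit loops."""
    h, g = spec.dec_lo, spec.dec_hi
    rows_lo = np.array([_filter_downsample(row, h) for row in channel])
    rows_hi = np.array([_filter_downsample(row, g) for row in channel])
    out = {}
    for name, (rows, taps) in {
        "LL": (rows_lo, h), "LH": (rows_lo, g), "HL": (rows_hi, h), "HH": (rows_hi, g),
    }.items():
        out[name] = np.array([_filter_downsample(col, taps) for col in rows.T]).T
    return out


def reference_operator(n, spec):
    """One-level transform matrix materialised tap by tap."""
    w = np.zeros((n, n))
    for k in range(n // 2):
        for t, tap in enumerate(spec.dec_lo):
            w[k, (2 * k + t) % n] += tap
        for t, tap in enumerate(spec.dec_hi):
            w[n // 2 + k, (2 * k + t) % n] += tap
    return w


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilters:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_lowpass_sums_to_sqrt2(self, family):
        spec = WaveletSpec.create(family)
        assert spec.dec_lo.sum() == pytest.approx(np.sqrt(2.0), abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_double_shift_orthonormality(self, family):
        h = WaveletSpec.create(family).dec_lo
        for m in range(len(h) // 2):
            value = sum(h[n] * h[n + 2 * m] for n in range(len(h) - 2 * m))
            assert value == pytest.approx(1.0 if m == 0 else 0.0, abs=1e-10)

    def test_db4_matches_published_taps(self):
        np.testing.assert_allclose(daubechies_lowpass(4), DB4_TAPS, atol=5e-7)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_perfect_reconstruction_validates(self, family):
        WaveletSpec.create(family).validate()

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown wavelet family"):
            WaveletSpec.create("sym5")


# ---------------------------------------------------------------------------
# decimated analysis
# ---------------------------------------------------------------------------

class TestAnalysis:
    def test_constant_image_haar(self):
        coeffs = dwt2_analysis(np.full((6, 6), 2.5), WaveletSpec.create("haar"))
        np.testing.assert_allclose(coeffs.LL, 5.0, atol=1e-12)
        for band in ("LH", "HL", "HH"):
            np.testing.assert_allclose(getattr(coeffs, band), 0.0, atol=1e-12)

    def test_2x2_haar_direct_evaluation(self):
        spec = WaveletSpec.create("haar")
        coeffs = dwt2_analysis(np.array([[1.0, 2.0], [3.0, 4.0]]), spec)
        expected = reference_analysis(np.array([[1.0, 2.0], [3.0, 4.0]]), spec)
        assert coeffs.LL[0, 0] == pytest.approx(5.0)
        for band in BAND_ORDER:
            np.testing.assert_allclose(getattr(coeffs, band), expected[band], atol=1e-12)

    def test_subband_sizes_are_half(self):
        coeffs = dwt2_analysis(np.zeros((128, 128)), WaveletSpec.create("haar"))
        for band in BAND_ORDER:
            assert getattr(coeffs, band).shape == (64, 64)

    def test_haar_energy_conservation(self, rng):
        x = rng.standard_normal((16, 16))
        coeffs = dwt2_analysis(x, WaveletSpec.create("haar"))
        total = sum(np.sum(np.square(getattr(coeffs, b))) for b in BAND_ORDER)
        assert total == pytest.approx(np.sum(np.square(x)), abs=1e-8)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError, match="even"):
            dwt2_analysis(np.zeros((7, 8)), WaveletSpec.create("haar"))

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("shape", [(8, 8), (16, 12), (16, 16)])
    def test_matches_reference_loops(self, family, shape, rng):
        spec = WaveletSpec.create(family)
        x = rng.standard_normal(shape)
        coeffs = dwt2_analysis(x, spec)
        expected = reference_analysis(x, spec)
        for band in BAND_ORDER:
            np.testing.assert_allclose(getattr(coeffs, band), expected[band], atol=1e-8)


# ---------------------------------------------------------------------------
# per-subband reconstruction
# ---------------------------------------------------------------------------

class TestReconstruction:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_subbands_sum_to_original(self, family, rng):
        spec = WaveletSpec.create(family)
        x = rng.standard_normal((20, 14))
        subbands = subband_reconstruct(dwt2_analysis(x, spec), spec)
        np.testing.assert_allclose(subbands.total(), x, atol=1e-6)
        for band in BAND_ORDER:
            assert subbands[band].shape == x.shape

    def test_constant_image_lives_in_ll(self):
        spec = WaveletSpec.create("haar")
        x = np.full((8, 8), 3.0)
        subbands = subband_reconstruct(dwt2_analysis(x, spec), spec)
        np.testing.assert_allclose(subbands["LL"], x, atol=1e-10)
        for band in ("LH", "HL", "HH"):
            np.testing.assert_allclose(subbands[band], 0.0, atol=1e-10)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_impulse_against_operator_matrix(self, family):
        spec = WaveletSpec.create(family)
        x = np.zeros((8, 8))
        x[3, 5] = 1.0
        w = reference_operator(8, spec)
        coeffs = w @ x @ w.T
        blocks = {"LL": (slice(0, 4), slice(0, 4)), "LH": (slice(4, 8), slice(0, 4)),
                  "HL": (slice(0, 4), slice(4, 8)), "HH": (slice(4, 8), slice(4, 8))}
        subbands = subband_reconstruct(dwt2_analysis(x, spec), spec)
        for band, (rs, cs) in blocks.items():
            keep = np.zeros_like(coeffs)
            keep[rs, cs] = coeffs[rs, cs]
            np.testing.assert_allclose(subbands[band], w.T @ keep @ w, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree in shape"):
            SubbandCoefficients(LL=np.zeros((4, 4)), LH=np.zeros((4, 4)),
                                HL=np.zeros((4, 4)), HH=np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# top-level decompose
# ---------------------------------------------------------------------------

class TestDecompose:
    @pytest.mark.parametrize("method", ["dwt2", "swt2"])
    @pytest.mark.parametrize("family", FAMILIES)
    def test_wavelet_paths_reconstruct(self, method, family, rng):
        x = rng.standard_normal((16, 12, 3))
        subbands = decompose(x, method=method, wavelet=family)
        np.testing.assert_allclose(subbands.total(), x, atol=1e-6)
        assert subbands.shape == x.shape

    def test_channel_independence(self, rng):
        x = rng.standard_normal((8, 8, 3))
        whole = decompose(x, "dwt2", "db4")
        for c in range(3):
            single = decompose(x[..., c], "dwt2", "db4")
            for band in BAND_ORDER:
                np.testing.assert_allclose(whole[band][..., c], single[band], atol=1e-12)

    def test_dwt2_oracle_on_random_8x8x3(self, rng):
        spec = WaveletSpec.create("haar")
        x = rng.standard_normal((8, 8, 3))
        got = decompose(x, "dwt2", "haar")
        w = reference_operator(8, spec)
        for c in range(3):
            coeffs = w @ x[..., c] @ w.T
            ref = reference_analysis(x[..., c], spec)
            np.testing.assert_allclose(coeffs[:4, :4], ref["LL"], atol=1e-8)
            total = w.T @ coeffs @ w
            np.testing.assert_allclose(got.total()[..., c], total, atol=1e-8)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown decomposition method"):
            decompose(rng.standard_normal((8, 8)), method="fft")


class TestSVD:
    def test_rank1_captured_by_first_mode(self, rng):
        u = rng.standard_normal(128)
        v = rng.standard_normal(128)
        x = np.outer(u, v)
        subbands = svd_decompose_channel(x)
        np.testing.assert_allclose(subbands["LL"], x, atol=1e-8)
        for band in ("LH", "HL", "HH"):
            np.testing.assert_allclose(subbands[band], 0.0, atol=1e-8)

    def test_modes_sum_exactly(self, rng):
        x = rng.standard_normal((128, 128))
        subbands = decompose(x, method="svd")
        np.testing.assert_allclose(subbands.total(), x, atol=1e-8)

    def test_nonsquare_truncates_last_interval(self, rng):
        x = rng.standard_normal((128, 64, 2))
        subbands = decompose(x, method="svd")
        np.testing.assert_allclose(subbands.total(), x, atol=1e-8)
        assert subbands.shape == x.shape

    def test_grouping_must_cover_rank(self, rng):
        x = rng.standard_normal((128, 128))
        with pytest.raises(ValueError, match="rank"):
            svd_decompose_channel(x, grouping=[(1, 5), (6, 15), (16, 40), (41, 100)])

    def test_grouping_must_be_contiguous(self, rng):
        x = rng.standard_normal((16, 16))
        with pytest.raises(ValueError, match="contiguous"):
            svd_decompose_channel(x, grouping=[(1, 5), (7, 10), (11, 12), (13, 16)])

    def test_default_grouping_partitions_128(self):
        ranges = default_grouping()
        flat = [i for lo, hi in ranges for i in range(lo, hi + 1)]
        assert flat == list(range(1, 129))


class TestEnergy:
    def test_constant_image_detail_energy_zero(self):
        subbands = decompose(np.full((16, 16), 4.0), "dwt2", "haar")
        energies = subband_energy(subbands)
        for band in ("LH", "HL", "HH"):
            assert energies[band] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_is_diagonal_detail(self):
        # 0/1 checkerboard = constant 0.5 (LL) + alternating +-0.5 (HH):
        # both carry energy 0.25, the oriented detail bands exactly 0
        x = np.indices((16, 16)).sum(axis=0) % 2
        energies = subband_energy(decompose(x.astype(float), "dwt2", "haar"))
        assert energies["HH"] == pytest.approx(0.25, abs=1e-12)
        assert energies["LL"] == pytest.approx(0.25, abs=1e-12)
        assert energies["LH"] == pytest.approx(0.0, abs=1e-12)
        assert energies["HL"] == pytest.approx(0.0, abs=1e-12)
        # among the detail bands the diagonal one strictly dominates
        assert energies["HH"] > max(energies["LH"], energies["HL"])

    def test_haar_band_energies_sum_to_image_energy(self, rng):
        x = rng.standard_normal((16, 16))
        energies = subband_energy(decompose(x, "dwt2", "haar"))
        assert sum(energies.values()) == pytest.approx(np.mean(np.square(x)), abs=1e-8)

    def test_energies_nonnegative(self, rng):
        energies = subband_energy(decompose(rng.standard_normal((8, 8, 3)), "dwt2", "db5"))
        assert all(v >= 0 for v in energies.values())
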