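"""One-level multiband decomposition of images into four full-size subbands.

Three interchangeable methods are provided:

``dwt2``
    Decimated separable two-dimensional wavelet analysis followed by a
    per-subband inverse transform (the other three coefficient blocks
    zeroed), yielding four image tensors the same size as the source.
``swt2``
    The stationary (undecimated, shift-invariant) variant.
``svd``
    Per-channel singular value decomposition with contiguous grouping of
    eigentriples (singular value + singular vector pairs) into additive
    image modes.

All methods use periodic boundary handling on even-sized inputs, under
which the four subband images sum exactly back to the source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.special import comb

__all__ = [
    "BAND_ORDER",
    "WAVELET_FAMILIES",
    "SubbandCoefficients",
    "SubbandImageSet",
    "WaveletSpec",
    "decompose",
    "default_grouping",
    "dwt2_analysis",
    "save_subband_npz",
    "save_subband_pngs",
    "subband_energy",
    "subband_reconstruct",
    "swt2_decompose_channel",
    "svd_decompose_channel",
]

#: Canonical subband ordering used everywhere downstream.
BAND_ORDER = ("LL", "LH", "HL", "HH")

#: Supported wavelet families (number of vanishing moments).
WAVELET_FAMILIES = {"haar": 1, "db4": 4, "db5": 5, "db8": 8}


# ---------------------------------------------------------------------------
# Wavelet filters
# ---------------------------------------------------------------------------

def daubechies_lowpass(p: int) -> np.ndarray:
    """Orthonormal Daubechies low-pass analysis filter with ``p`` vanishing
    moments (``2p`` taps), built by spectral factorisation.

    ``p=1`` gives the Haar filter.  The taps satisfy ``sum(h) = sqrt(2)``
    and the double-shift orthonormality ``sum_n h[n] h[n+2m] = delta_m``.
    """
    if p < 1:
        raise ValueError("vanishing moments must be >= 1")
    if p == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # Half-band residual polynomial P(y) = sum_k C(p-1+k, k) y^k.
    coeffs = [float(comb(p - 1 + k, k, exact=True)) for k in range(p)]
    yroots = np.roots(coeffs[::-1])
    # Map each root through z + 1/z = 2 - 4y and keep the root inside the
    # unit circle (minimum-phase factor).
    poly = np.poly1d([1.0])
    for _ in range(p):
        poly = poly * np.poly1d([1.0, 1.0])  # (z + 1)^p
    for y in yroots:
        b = 2.0 - 4.0 * y
        disc = np.sqrt(b * b - 4.0 + 0j)
        z1, z2 = (b + disc) / 2.0, (b - disc) / 2.0
        z = z1 if abs(z1) < 1.0 else z2
        poly = poly * np.poly1d([1.0, -z])
    h = np.real(poly.coeffs)
    return h / h.sum() * np.sqrt(2.0)


def quadrature_mirror(h: np.ndarray) -> np.ndarray:
    """High-pass filter paired with low-pass ``h``: g[n] = (-1)^n h[L-1-n]."""
    n = np.arange(len(h))
    return ((-1.0) ** n) * h[::-1]


@dataclass(frozen=True)
class WaveletSpec:
    """Analysis/synthesis filter bank for one wavelet family.

    Synthesis filters are the time-reversed analysis filters (orthogonal
    bank), applied here through the transpose of the analysis operator.
    """

    family: str
    dec_lo: np.ndarray = field(repr=False)
    dec_hi: np.ndarray = field(repr=False)
    rec_lo: np.ndarray = field(repr=False)
    rec_hi: np.ndarray = field(repr=False)
    boundary_mode: str = "periodization"

    @classmethod
    def create(cls, family: str) -> "WaveletSpec":
        key = family.lower()
        if key not in WAVELET_FAMILIES:
            raise ValueError(
                f"unknown wavelet family {family!r}; "
                f"choose one of {sorted(WAVELET_FAMILIES)}"
            )
        h = daubechies_lowpass(WAVELET_FAMILIES[key])
        g = quadrature_mirror(h)
        return cls(family=key, dec_lo=h, dec_hi=g, rec_lo=h[::-1], rec_hi=g[::-1])

    def validate(self, n: int = 16, tol: float = 1e-8) -> None:
        """Numerically confirm perfect reconstruction on a length-``n`` probe."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        w = analysis_matrix(n, self.family)
        if not np.allclose(w.T @ (w @ x), x, atol=tol):
            raise ValueError(f"filter bank for {self.family!r} fails perfect reconstruction")


@lru_cache(maxsize=64)
def _matrices(n: int, family: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decimated (L, H) and undecimated (Lf, Hf) circulant analysis operators.

    Row ``k`` of L places the low-pass taps at circular positions
    ``(2k + t) mod n``; the undecimated rows advance by one instead of two.
    Periodic wrapping keeps the decimated pair orthonormal for every even
    ``n``, so the inverse transform is the transpose.
    """
    if n % 2:
        raise ValueError(f"signal length must be even, got {n}")
    spec = WaveletSpec.create(family)
    h, g = spec.dec_lo, spec.dec_hi
    taps = np.arange(len(h))
    low = np.zeros((n // 2, n))
    high = np.zeros((n // 2, n))
    low_f = np.zeros((n, n))
    high_f = np.zeros((n, n))
    for k in range(n):
        idx = (k + taps) % n
        np.add.at(low_f[k], idx, h)
        np.add.at(high_f[k], idx, g)
        if k < n // 2:
            idx2 = (2 * k + taps) % n
            np.add.at(low[k], idx2, h)
            np.add.at(high[k], idx2, g)
    return low, high, low_f, high_f


def analysis_matrix(n: int, family: str) -> np.ndarray:
    """Full orthogonal one-level transform operator, low-pass rows stacked
    over high-pass rows."""
    low, high, _, _ = _matrices(n, family)
    return np.vstack([low, high])


# ---------------------------------------------------------------------------
# Subband containers
# ---------------------------------------------------------------------------

@dataclass
class SubbandCoefficients:
    """Decimated coefficient blocks of one channel; each (M/2, N/2)."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def __post_init__(self) -> None:
        shapes = {band: getattr(self, band).shape for band in BAND_ORDER}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"coefficient blocks disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.LL.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {band: getattr(self, band) for band in BAND_ORDER}


@dataclass
class SubbandImageSet:
    """Four full-size subband image tensors of one image (or channel)."""

    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.bands) != BAND_ORDER:
            raise ValueError(f"bands must be ordered {BAND_ORDER}, got {tuple(self.bands)}")
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"subband tensors disagree in shape: {shapes}")

    def __getitem__(self, band: str) -> np.ndarray:
        return self.bands[band]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.bands["LL"].shape

    def total(self) -> np.ndarray:
        """Elementwise sum of the four subband tensors (equals the source
        image for the wavelet and SVD paths)."""
        return sum(self.bands.values())


# ---------------------------------------------------------------------------
# Decimated wavelet path
# ---------------------------------------------------------------------------

def _check_channel(channel: np.ndarray) -> None:
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {channel.shape}")
    m, n = channel.shape
    if m % 2 or n % 2:
        raise ValueError(f"channel dimensions must be even, got {m}x{n}")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")


def dwt2_analysis(channel: np.ndarray, spec: WaveletSpec) -> SubbandCoefficients:
    """One-level separable decimated analysis of a single channel.

    Rows are filtered and downsampled, then columns, producing the four
    (M/2, N/2) coefficient blocks.  For orthonormal filters the transform
    conserves energy exactly.
    """
    _check_channel(channel)
    m, n = channel.shape
    lr, hr, _, _ = _matrices(n, spec.family)   # operate along rows (width n)
    lc, hc, _, _ = _matrices(m, spec.family)   # operate along columns (height m)
    row_lo = channel @ lr.T
    row_hi = channel @ hr.T
    return SubbandCoefficients(
        LL=lc @ row_lo,
        LH=hc @ row_lo,
        HL=lc @ row_hi,
        HH=hc @ row_hi,
    )


def subband_reconstruct(coeffs: SubbandCoefficients, spec: WaveletSpec) -> SubbandImageSet:
    """Inverse-transform each coefficient block with the other three zeroed,
    giving four full-size (M, N) images whose sum is the original channel."""
    half_m, half_n = coeffs.shape
    m, n = 2 * half_m, 2 * half_n
    lr, hr, _, _ = _matrices(n, spec.family)
    lc, hc, _, _ = _matrices(m, spec.family)
    ops = {"LL": (lc, lr), "LH": (hc, lr), "HL": (lc, hr), "HH": (hc, hr)}
    bands = {
        band: col_op.T @ getattr(coeffs, band) @ row_op
        for band, (col_op, row_op) in ops.items()
    }
    return SubbandImageSet(bands={b: bands[b] for b in BAND_ORDER})


# ---------------------------------------------------------------------------
# Stationary (undecimated) wavelet path
# ---------------------------------------------------------------------------

def swt2_decompose_channel(channel: np.ndarray, spec: WaveletSpec) -> SubbandImageSet:
    """Undecimated analysis + per-band inverse for one channel.

    The undecimated analysis pair forms a tight frame with redundancy two
    per axis, so the per-band synthesis divides by four; the four
    reconstructions again sum exactly to the channel.
    """
    _check_channel(channel)
    m, n = channel.shape
    _, _, lr, hr = _matrices(n, spec.family)
    _, _, lc, hc = _matrices(m, spec.family)
    row_lo = channel @ lr.T
    row_hi = channel @ hr.T
    coeffs = {
        "LL": lc @ row_lo,
        "LH": hc @ row_lo,
        "HL": lc @ row_hi,
        "HH": hc @ row_hi,
    }
    ops = {"LL": (lc, lr), "LH": (hc, lr), "HL": (lc, hr), "HH": (hc, hr)}
    bands = {
        band: (col_op.T @ coeffs[band] @ row_op) / 4.0
        for band, (col_op, row_op) in ops.items()
    }
    return SubbandImageSet(bands={b: bands[b] for b in BAND_ORDER})


# ---------------------------------------------------------------------------
# SVD eigentriple grouping
# ---------------------------------------------------------------------------

def default_grouping() -> list[tuple[int, int]]:
    """Default contiguous eigentriple index intervals (1-based, inclusive)."""
    return [(1, 5), (6, 15), (16, 40), (41, 128)]


def _validated_grouping(ranges, rank: int) -> list[tuple[int, int]]:
    ranges = [tuple(int(v) for v in r) for r in ranges]
    if len(ranges) != len(BAND_ORDER):
        raise ValueError(f"grouping must contain {len(BAND_ORDER)} intervals, got {len(ranges)}")
    prev_hi = 0
    clipped = []
    for lo, hi in ranges:
        if lo != prev_hi + 1 or hi < lo:
            raise ValueError(
                f"grouping intervals must be contiguous ascending 1-based; bad interval ({lo}, {hi})"
            )
        clipped.append((lo, min(hi, rank)))
        prev_hi = hi
    if prev_hi < rank:
        raise ValueError(f"grouping covers 1..{prev_hi} but rank is {rank}")
    # Intervals that fall entirely beyond the rank contribute empty modes.
    return clipped


def svd_decompose_channel(channel: np.ndarray, grouping=None) -> SubbandImageSet:
    """Split one channel into additive low-rank modes by grouping its
    eigentriples (sigma_k, u_k, v_k) into contiguous index intervals."""
    _check_channel(channel)
    rank = min(channel.shape)
    ranges = _validated_grouping(grouping if grouping is not None else default_grouping(), rank)
    u, s, vt = np.linalg.svd(channel, full_matrices=False)
    bands = {}
    for band, (lo, hi) in zip(BAND_ORDER, ranges):
        if hi < lo:
            bands[band] = np.zeros_like(channel)
        else:
            sl = slice(lo - 1, hi)
            bands[band] = (u[:, sl] * s[sl]) @ vt[sl, :]
    return SubbandImageSet(bands=bands)


# ---------------------------------------------------------------------------
# Top-level dispatch
# ---------------------------------------------------------------------------

def _per_channel(image: np.ndarray, fn) -> SubbandImageSet:
    if image.ndim == 2:
        return fn(image)
    if image.ndim != 3:
        raise ValueError(f"expected HxW or HxWxC image, got shape {image.shape}")
    per_ch = [fn(image[..., c]) for c in range(image.shape[-1])]
    bands = {
        band: np.stack([s[band] for s in per_ch], axis=-1) for band in BAND_ORDER
    }
    return SubbandImageSet(bands=bands)


def decompose(
    image: np.ndarray,
    method: str = "dwt2",
    wavelet: str | WaveletSpec = "haar",
    grouping=None,
) -> SubbandImageSet:
    """Decompose an image (H x W or H x W x C) into four full-size subband
    tensors; channels are processed independently and restacked."""
    image = np.asarray(image, dtype=float)
    if method == "dwt2":
        spec = wavelet if isinstance(wavelet, WaveletSpec) else WaveletSpec.create(wavelet)
        return _per_channel(image, lambda ch: subband_reconstruct(dwt2_analysis(ch, spec), spec))
    if method == "swt2":
        spec = wavelet if isinstance(wavelet, WaveletSpec) else WaveletSpec.create(wavelet)
        return _per_channel(image, lambda ch: swt2_decompose_channel(ch, spec))
    if method == "svd":
        return _per_channel(image, lambda ch: svd_decompose_channel(ch, grouping))
    raise ValueError(f"unknown decomposition method {method!r}; choose dwt2, swt2 or svd")


def subband_energy(subbands: SubbandImageSet) -> dict[str, float]:
    """Mean squared intensity of each subband tensor."""
    return {band: float(np.mean(np.square(arr))) for band, arr in subbands.bands.items()}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _display_normalise(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def save_subband_pngs(subbands: SubbandImageSet, out_dir: str | Path, prefix: str = "subband") -> list[Path]:
    """Write one display-normalised 8-bit PNG per band; returns the paths."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for band, arr in subbands.bands.items():
        scaled = (_display_normalise(arr) * 255.0).round().astype(np.uint8)
        path = out_dir / f"{prefix}_{band}.png"
        Image.fromarray(scaled).save(path)
        paths.append(path)
    return paths


def save_subband_npz(subbands: SubbandImageSet, path: str | Path) -> Path:
    """Lossless numeric archive of the raw subband tensors."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **subbands.bands)
    return path
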