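"""Texture-feature battery: 250 named radiomics features in nine groups.

Every extractor consumes a plain 2-D numpy array of non-negative gray-level
intensities ("GrayImage") and returns an ordered ``{name: value}`` mapping
whose keys come from :mod:`echotexture.registry`.  :func:`extract_all`
concatenates the nine groups in canonical order and always emits exactly 250
finite values.

Conventions adopted throughout (documented here once):

* Moments are population (biased) moments; kurtosis is excess kurtosis
  (a Gaussian scores 0); zero-variance inputs yield skewness = kurtosis = 0.
* Percentiles use the nearest-rank method.
* Gradients are central differences over interior pixels, without the 1/2
  factor.
* Orientation angles are measured with x = column index increasing rightward
  and y = row index increasing downward; the direction letters map to
  H = 0 deg, Z = 45 deg, V = 90 deg, N = 135 deg.
* Co-occurrence and run-length statistics operate on an image quantized to
  ``Ng`` gray levels (default 64, mean +/- 3 sigma window, the convention of
  the texture-analysis lineage this feature set follows).
* Logarithms in entropy-type features are base 2 with 0*log(0) = 0.
"""

from __future__ import annotations

import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as _fft

from .registry import (
    AR_NAMES,
    DIRECTIONS,
    DIRECTION_DEGREES,
    FEATURE_NAMES,
    GABOR_SIZES,
    GLCM_NAMES,
    GLRLM_STATS,
    GRADIENT_NAMES,
    HISTOGRAM_NAMES,
    WAVELET_CHANNELS,
    WAVELET_LEVELS,
)

__all__ = [
    "FeatureConfig",
    "QuantizedImage",
    "quantize",
    "histogram_features",
    "ar_model_features",
    "gradient_features",
    "hog_features",
    "gabor_features",
    "wavelet_energy_features",
    "glrlm_features",
    "glcm_features",
    "lbp_features",
    "extract_all",
]


# --------------------------------------------------------------------------
# configuration and validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the extraction battery.

    quant_levels
        Number of gray levels Ng for the co-occurrence / run-length matrices.
    quant_method
        ``"mu_3sigma"`` (mean +/- 3 sigma window, default) or ``"full_range"``.
    gabor_sizes
        Gaussian-envelope sizes (pixels) of the Gabor bank; the carrier
        wavelength is tied to the envelope as lambda = 2 * size.
    """

    quant_levels: int = 64
    quant_method: str = "mu_3sigma"
    gabor_sizes: tuple[int, ...] = GABOR_SIZES


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    return a


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance/skewness/excess-kurtosis with the
    zero-variance convention (skewness = kurtosis = 0)."""
    mean = float(values.mean())
    var = float(values.var())
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    z = (values - mean) / math.sqrt(var)
    return mean, var, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


# --------------------------------------------------------------------------
# (a) histogram
# --------------------------------------------------------------------------

def histogram_features(img) -> "OrderedDict[str, float]":
    """First-order statistics of the intensity histogram (9 features)."""
    a = _as_image(img).ravel()
    mean, var, skew, kurt = _moments(a)
    srt = np.sort(a)
    n = srt.size

    def nearest_rank(k: float) -> float:
        idx = max(int(math.ceil(k / 100.0 * n)) - 1, 0)
        return float(srt[idx])

    return OrderedDict(
        zip(
            HISTOGRAM_NAMES,
            [
                mean,
                var,
                skew,
                kurt,
                nearest_rank(1),
                nearest_rank(10),
                nearest_rank(50),
                nearest_rank(90),
                nearest_rank(99),
            ],
        )
    )


# --------------------------------------------------------------------------
# (b) causal 2-D autoregressive model
# --------------------------------------------------------------------------

def ar_model_features(img) -> "OrderedDict[str, float]":
    """Least-squares fit of the causal first-order 2-D AR model.

    f(x, y) = t1*f(x-1, y) + t2*f(x-1, y-1) + t3*f(x, y-1)
              + t4*f(x+1, y-1) + e

    fitted on the mean-subtracted image over all pixels whose four causal
    neighbours exist; ``Sigma`` is the residual standard deviation.  A
    constant image follows the degenerate convention theta = 0, Sigma = 0.
    """
    a = _as_image(img)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("AR model needs an image of at least 3x3 pixels")
    z = a - a.mean()
    if z.var() == 0.0:
        return OrderedDict(zip(AR_NAMES, [0.0] * 5))
    target = z[1:, 1:-1].ravel()
    design = np.column_stack(
        [
            z[1:, :-2].ravel(),   # f(x-1, y)
            z[:-1, :-2].ravel(),  # f(x-1, y-1)
            z[:-1, 1:-1].ravel(), # f(x, y-1)
            z[:-1, 2:].ravel(),   # f(x+1, y-1)
        ]
    )
    theta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ theta
    sigma = float(resid.std())
    return OrderedDict(zip(AR_NAMES, [*map(float, theta), sigma]))


# --------------------------------------------------------------------------
# (c) gradient
# --------------------------------------------------------------------------

def _central_gradients(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = a[1:-1, 2:] - a[1:-1, :-2]
    gy = a[2:, 1:-1] - a[:-2, 1:-1]
    return gx, gy


def gradient_features(img) -> "OrderedDict[str, float]":
    """Moments of the gradient-magnitude map plus the percentage of
    interior pixels with non-zero gradient (5 features)."""
    a = _as_image(img)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("gradient features need an image of at least 3x3")
    gx, gy = _central_gradients(a)
    gm = np.hypot(gx, gy)
    mean, var, skew, kurt = _moments(gm)
    nonzeros = 100.0 * float(np.mean(gm > 0))
    return OrderedDict(zip(GRADIENT_NAMES, [mean, var, skew, kurt, nonzeros]))


# --------------------------------------------------------------------------
# (d) histogram of oriented gradients
# --------------------------------------------------------------------------

def hog_features(img) -> "OrderedDict[str, float]":
    """Whole-ROI magnitude-weighted orientation histograms with 4, 8 and 16
    signed bins over [0, 360) degrees, each L1-normalized (28 features).

    Zero-magnitude pixels cast no vote; if no pixel votes, the histograms
    stay identically zero (degenerate flat image).
    """
    a = _as_image(img)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("HOG needs an image of at least 3x3")
    gx, gy = _central_gradients(a)
    gm = np.hypot(gx, gy).ravel()
    ang = np.degrees(np.arctan2(gy, gx)).ravel() % 360.0
    voting = gm > 0
    out: "OrderedDict[str, float]" = OrderedDict()
    for nbins in (4, 8, 16):
        hist = np.zeros(nbins)
        if voting.any():
            idx = np.minimum(
                (ang[voting] / (360.0 / nbins)).astype(np.intp), nbins - 1
            )
            np.add.at(hist, idx, gm[voting])
            total = hist.sum()
            if total > 0:
                hist /= total
        for b in range(nbins):
            out[f"O{nbins}b{b}"] = float(hist[b])
    return out


# --------------------------------------------------------------------------
# (e) Gabor magnitude bank
# --------------------------------------------------------------------------

_GABOR_KERNELS: dict[tuple[int, str], np.ndarray] = {}
_GABOR_FFTS: dict[tuple, np.ndarray] = {}


def gabor_kernel(size: int, direction: str) -> np.ndarray:
    """Complex Gabor kernel: isotropic Gaussian envelope sigma = ``size``,
    carrier wavelength lambda = 2 * ``size`` along ``direction``; truncated
    at 3 sigma and L1-normalized by the envelope."""
    key = (size, direction)
    if key not in _GABOR_KERNELS:
        half = 3 * size
        y, x = np.mgrid[-half : half + 1, -half : half + 1]
        theta = math.radians(DIRECTION_DEGREES[direction])
        u = x * math.cos(theta) + y * math.sin(theta)
        env = np.exp(-(x**2 + y**2) / (2.0 * size**2))
        kern = env * np.exp(2j * np.pi * u / (2.0 * size))
        _GABOR_KERNELS[key] = kern / env.sum()
    return _GABOR_KERNELS[key]


def gabor_features(img, sizes: tuple[int, ...] = GABOR_SIZES) -> "OrderedDict[str, float]":
    """Mean magnitude of the Gabor-filtered interior for every envelope size
    and the four orientations H/Z/V/N (24 features with the default sizes).

    The image is mean-subtracted before filtering to suppress the DC
    response; only the fully-supported ("valid") region enters the mean.
    All filters share one padded FFT of the image.
    """
    a = _as_image(img)
    h, w = a.shape
    max_support = 6 * max(sizes) + 1
    if min(h, w) < max_support:
        raise ValueError(
            f"image {h}x{w} smaller than the largest Gabor support "
            f"({max_support}); reduce the envelope sizes or enlarge the ROI"
        )
    z = a - a.mean()
    pad = (
        _fft.next_fast_len(h + max_support - 1),
        _fft.next_fast_len(w + max_support - 1),
    )
    fimg = _fft.fft2(z, pad)
    out: "OrderedDict[str, float]" = OrderedDict()
    for s in sizes:
        k = 6 * s + 1
        for d in DIRECTIONS:
            fkey = (s, d, pad)
            if fkey not in _GABOR_FFTS:
                _GABOR_FFTS[fkey] = _fft.fft2(gabor_kernel(s, d), pad)
            resp = _fft.ifft2(fimg * _GABOR_FFTS[fkey])
            valid = resp[k - 1 : h, k - 1 : w]
            out[f"Gab{s}{d}"] = float(np.abs(valid).mean())
    return out


# --------------------------------------------------------------------------
# (f) Haar wavelet subband energies
# --------------------------------------------------------------------------

def wavelet_energy_features(img) -> "OrderedDict[str, float]":
    """Mean squared Haar detail coefficients for levels S1..S8 (finest to
    coarsest) and channels LH/HL/HH (24 features).

    Images too small for all 8 dyadic levels get the missing energies filled
    with 0 and a warning is emitted (the fill-and-flag rule).
    """
    a = _as_image(img)
    max_level = pywt.dwt_max_level(min(a.shape), "haar")
    level = min(8, max_level)
    names = [f"HaarS{k}{c}" for k in WAVELET_LEVELS for c in WAVELET_CHANNELS]
    out = OrderedDict((n, 0.0) for n in names)
    if level >= 1:
        coeffs = pywt.wavedec2(a, "haar", level=level)
        # coeffs[1] is the coarsest detail tuple (level ``level``),
        # coeffs[-1] the finest (level 1)
        for k in range(1, level + 1):
            ch, cv, cd = coeffs[level - k + 1]
            out[f"HaarS{k}LH"] = float(np.mean(ch**2))
            out[f"HaarS{k}HL"] = float(np.mean(cv**2))
            out[f"HaarS{k}HH"] = float(np.mean(cd**2))
    if level < 8:
        warnings.warn(
            f"image supports only {level} Haar levels; energies for levels "
            f"{level + 1}..8 filled with 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# --------------------------------------------------------------------------
# quantization (precondition of GLRLM / GLCM)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantizedImage:
    """Gray-level image re-binned to ``levels`` integer levels."""

    pixels: np.ndarray
    levels: int
    method: str
    mu: float = field(default=float("nan"))
    sigma: float = field(default=float("nan"))


def quantize(img, levels: int = 64, method: str = "mu_3sigma") -> QuantizedImage:
    """Linear re-binning of an intensity window into ``levels`` bins.

    ``full_range`` bins the observed [min, max]; ``mu_3sigma`` bins
    [mu - 3 sigma, mu + 3 sigma] with out-of-window intensities clipped.
    A constant image (sigma = 0) falls back to ``full_range``.
    """
    if levels not in (16, 32, 64, 128):
        raise ValueError("levels must be one of 16, 32, 64, 128")
    a = _as_image(img)
    mu = float(a.mean())
    sigma = float(a.std())
    eff = method
    if method == "mu_3sigma" and sigma == 0.0:
        eff = "full_range"
    if eff == "full_range":
        lo, hi = float(a.min()), float(a.max())
    elif eff == "mu_3sigma":
        lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    else:
        raise ValueError(f"unknown quantization method {method!r}")
    if hi <= lo:
        q = np.zeros(a.shape, dtype=np.intp)
    else:
        x = np.clip(a, lo, hi)
        q = ((x - lo) * (levels / (hi - lo))).astype(np.intp)
        np.minimum(q, levels - 1, out=q)
    return QuantizedImage(pixels=q, levels=levels, method=method, mu=mu, sigma=sigma)


def _as_quantized(qimg) -> QuantizedImage:
    if isinstance(qimg, QuantizedImage):
        return qimg
    a = np.asarray(qimg)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a 2-D quantized image")
    if not np.issubdtype(a.dtype, np.integer):
        raise TypeError("a raw array passed as quantized image must be integer")
    return QuantizedImage(pixels=a.astype(np.intp), levels=int(a.max()) + 1,
                          method="raw")


# --------------------------------------------------------------------------
# (g) gray-level run-length matrix
# --------------------------------------------------------------------------

def _direction_lines(q: np.ndarray, direction: str) -> list[np.ndarray]:
    """Pixel sequences along a direction: rows (H), columns (V),
    45-degree anti-diagonals (Z), 135-degree main diagonals (N)."""
    h, w = q.shape
    if direction == "H":
        return list(q)
    if direction == "V":
        return list(q.T)
    if direction == "Z":
        fl = np.fliplr(q)
        return [fl.diagonal(k) for k in range(-(h - 1), w)]
    if direction == "N":
        return [q.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"unknown direction {direction!r}; expected one of H, Z, V, N")


def _run_lengths(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run gray levels and lengths over a set of 1-D lines."""
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(np.array([-1], dtype=np.int64))  # separator
    arr = np.concatenate(parts)
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [arr.size - 1]))
    levels = arr[starts]
    keep = levels >= 0
    return levels[keep], (ends - starts + 1)[keep]


def glrlm_features(qimg, directions: tuple[str, ...] = DIRECTIONS) -> "OrderedDict[str, float]":
    """Seven run-length statistics per direction (28 features).

    With run-length matrix p(i, j) (gray level i, run length j), C total
    runs, P total pixels, r_j = sum_i p(i, j) and g_i = sum_j p(i, j):

    ShrtREmph = sum p/j^2 / C,  LngREmph = sum p*j^2 / C,
    GLevNonUn = sum g_i^2 / C,  RLNonUni = sum r_j^2 / C,
    Fraction = C / P,  NRLNonUni = RLNonUni / C,  NGLevNonUni = GLevNonUn / C.
    """
    qi = _as_quantized(qimg)
    q = qi.pixels
    n_pixels = q.size
    out: "OrderedDict[str, float]" = OrderedDict()
    for d in directions:
        levels, lengths = _run_lengths(_direction_lines(q, d))
        c = levels.size
        lengths_f = lengths.astype(np.float64)
        g = np.bincount(levels).astype(np.float64)
        r = np.bincount(lengths).astype(np.float64)
        glev = float((g**2).sum() / c)
        rln = float((r**2).sum() / c)
        stats = {
            "RLNonUni": rln,
            "GLevNonUn": glev,
            "LngREmph": float((lengths_f**2).sum() / c),
            "ShrtREmph": float((1.0 / lengths_f**2).sum() / c),
            "Fraction": float(c / n_pixels),
            "NRLNonUni": rln / c,
            "NGLevNonUni": glev / c,
        }
        for s in GLRLM_STATS:
            out[f"{d}{s}"] = stats[s]
    return out


# --------------------------------------------------------------------------
# (h) gray-level co-occurrence matrix
# --------------------------------------------------------------------------

_GLCM_OFFSETS = {"H": (0, 1), "Z": (-1, 1), "V": (1, 0), "N": (1, 1)}


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(qimg) -> "OrderedDict[str, float]":
    """Eleven Haralick statistics of a single symmetric co-occurrence matrix
    at offset distance 1, pooled over the four directions H/Z/V/N.

    Gray levels are indexed 0..Ng-1; entropies are base 2; the correlation
    of a one-level (degenerate) matrix is 1 by convention.
    """
    qi = _as_quantized(qimg)
    q = qi.pixels
    ng = qi.levels
    h, w = q.shape
    counts = np.zeros(ng * ng, dtype=np.float64)
    for dy, dx in _GLCM_OFFSETS.values():
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        a = q[ys2, xs2].ravel()
        b = q[ys, xs].ravel()
        if a.size == 0:
            continue
        counts += np.bincount(a * ng + b, minlength=ng * ng)
        counts += np.bincount(b * ng + a, minlength=ng * ng)
    p = counts.reshape(ng, ng)
    total = p.sum()
    if total == 0:
        raise ValueError("image too small for distance-1 co-occurrence pairs")
    p /= total
    i = np.arange(ng, dtype=np.float64)
    px = p.sum(axis=1)
    mu_x = float(i @ px)
    sig_x = math.sqrt(float(((i - mu_x) ** 2) @ px))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    if sig_x > 0:
        correlat = float((((ii - mu_x) * (jj - mu_x) * p).sum()) / (sig_x * sig_x))
    else:
        correlat = 1.0
    # distributions of i+j and |i-j|
    ksum = np.arange(2 * ng - 1, dtype=np.float64)
    p_sum = np.bincount((ii + jj).astype(np.intp).ravel(), weights=p.ravel(),
                        minlength=2 * ng - 1)
    kdif = np.arange(ng, dtype=np.float64)
    p_dif = np.bincount(np.abs(ii - jj).astype(np.intp).ravel(),
                        weights=p.ravel(), minlength=ng)
    sum_avg = float(ksum @ p_sum)
    dif_avg = float(kdif @ p_dif)
    out = OrderedDict(
        zip(
            GLCM_NAMES,
            [
                float((p**2).sum()),                                  # AngScMom
                float((((ii - jj) ** 2) * p).sum()),                  # Contrast
                correlat,                                             # Correlat
                float((((ii - mu_x) ** 2) * p).sum()),                # SumOfSqs
                float((p / (1.0 + (ii - jj) ** 2)).sum()),            # InvDfMom
                sum_avg,                                              # SumAverg
                float(((ksum - sum_avg) ** 2 @ p_sum)),               # SumVarnc
                float(-_xlog2(p_sum).sum()),                          # SumEntrp
                float(-_xlog2(p).sum()),                              # Entropy
                float(((kdif - dif_avg) ** 2 @ p_dif)),               # DifVarnc
                float(-_xlog2(p_dif).sum()),                          # DifEntrp
            ],
        )
    )
    return out


# --------------------------------------------------------------------------
# (i) local binary pattern variants
# --------------------------------------------------------------------------

def _sample_offset(a: np.ndarray, dy: float, dx: float, margin: int) -> np.ndarray:
    """Bilinear sample of ``a`` at (i + dy, j + dx) for every interior pixel
    (i, j) with the given border margin; exact for integer offsets."""
    h, w = a.shape
    fy, fx = math.floor(dy), math.floor(dx)
    ry, rx = dy - fy, dx - fx
    if ry < 1e-9:
        ry = 0.0
    elif ry > 1 - 1e-9:
        fy, ry = fy + 1, 0.0
    if rx < 1e-9:
        rx = 0.0
    elif rx > 1 - 1e-9:
        fx, rx = fx + 1, 0.0

    def block(oy: int, ox: int) -> np.ndarray:
        return a[margin + oy : h - margin + oy, margin + ox : w - margin + ox]

    out = (1 - ry) * (1 - rx) * block(fy, fx)
    if rx:
        out = out + (1 - ry) * rx * block(fy, fx + 1)
    if ry:
        out = out + ry * (1 - rx) * block(fy + 1, fx)
    if ry and rx:
        out = out + ry * rx * block(fy + 1, fx + 1)
    return out


def _circle_offsets(n: int, radius: float) -> list[tuple[float, float]]:
    """(dy, dx) of n points on a circle, starting at angle 0 (east) and
    proceeding counter-clockwise in image coordinates (y down)."""
    offs = []
    for t in range(n):
        theta = 2.0 * math.pi * t / n
        offs.append((-radius * math.sin(theta), radius * math.cos(theta)))
    return offs


def _hist(codes: np.ndarray, nbins: int) -> np.ndarray:
    h = np.bincount(codes.ravel(), minlength=nbins).astype(np.float64)
    return h / h.sum()


def lbp_features(img) -> "OrderedDict[str, float]":
    """Overcomplete (Oc4), transition (Tr4) and center-symmetric (Cs4/8/12)
    local-binary-pattern code histograms, each L1-normalized (116 features).

    * Oc4: classic LBP over the 4-connected neighbours (E, N, W, S order,
      bit = neighbour >= center).
    * Tr4: bit b set when consecutive neighbours (circular E-N-W-S order)
      disagree in their >=-center sign.
    * CsN: each of the N/2 opposing neighbour pairs on a circle compared
      directly (first >= second); N = 4, 8, 12 on radii 1, 1, 2 with
      bilinear interpolation of off-grid samples.

    Ties (equality) count as ">=", i.e. bit 1.
    """
    a = _as_image(img)
    if a.shape[0] < 5 or a.shape[1] < 5:
        raise ValueError("LBP needs an image of at least 5x5 (radius-2 circle)")
    out: "OrderedDict[str, float]" = OrderedDict()

    # --- 4-connected neighbourhood codes (margin 1) --------------------
    center = a[1:-1, 1:-1]
    nbrs4 = [
        a[1:-1, 2:],   # E
        a[:-2, 1:-1],  # N
        a[1:-1, :-2],  # W
        a[2:, 1:-1],   # S
    ]
    signs = [(nb >= center) for nb in nbrs4]
    oc = np.zeros(center.shape, dtype=np.intp)
    tr = np.zeros(center.shape, dtype=np.intp)
    for b in range(4):
        oc |= signs[b].astype(np.intp) << b
        tr |= (signs[b] ^ signs[(b + 1) % 4]).astype(np.intp) << b
    for i, v in enumerate(_hist(oc, 16)):
        out[f"Oc4n{i}"] = float(v)
    for i, v in enumerate(_hist(tr, 16)):
        out[f"Tr4n{i}"] = float(v)

    # --- center-symmetric codes ---------------------------------------
    for n, radius, margin in ((4, 1.0, 1), (8, 1.0, 1), (12, 2.0, 2)):
        offs = _circle_offsets(n, radius)
        half = n // 2
        code = np.zeros(
            (a.shape[0] - 2 * margin, a.shape[1] - 2 * margin), dtype=np.intp
        )
        for b in range(half):
            first = _sample_offset(a, *offs[b], margin)
            second = _sample_offset(a, *offs[b + half], margin)
            code |= (first >= second).astype(np.intp) << b
        for i, v in enumerate(_hist(code, 1 << half)):
            out[f"Cs{n}n{i}"] = float(v)
    return out


# --------------------------------------------------------------------------
# full battery
# --------------------------------------------------------------------------

def extract_all(img, config: FeatureConfig | None = None) -> "OrderedDict[str, float]":
    """Extract the full 250-feature vector, groups concatenated in canonical
    registry order.  Deterministic; all values finite 64-bit floats."""
    cfg = config or FeatureConfig()
    a = _as_image(img)
    q = quantize(a, levels=cfg.quant_levels, method=cfg.quant_method)
    vec: "OrderedDict[str, float]" = OrderedDict()
    vec.update(histogram_features(a))
    vec.update(ar_model_features(a))
    vec.update(gradient_features(a))
    vec.update(hog_features(a))
    vec.update(gabor_features(a, sizes=cfg.gabor_sizes))
    vec.update(wavelet_energy_features(a))
    vec.update(glrlm_features(q))
    vec.update(glcm_features(q))
    vec.update(lbp_features(a))
    if tuple(vec) != FEATURE_NAMES:
        raise RuntimeError("feature vector does not match the registry order")
    values = np.fromiter(vec.values(), dtype=np.float64, count=len(vec))
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in vec.items() if not math.isfinite(v)]
        raise RuntimeError(f"non-finite feature values: {bad}")
    return vec
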