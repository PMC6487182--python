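"""Log-Gabor filter bank texture features.

Filters are defined directly in the frequency domain as Gaussians in the
log-polar coordinates (rho, theta):

    G_{s,t}(rho, theta) = exp(-((rho - rho_s)^2) / (2 sigma_rho^2))
                        * exp(-((theta - theta_t)^2) / (2 sigma_theta^2))

with rho the log radial frequency.  Each filter has unit peak at its centre
and exactly zero DC response, so features are invariant to constant
intensity offsets.  The angular Gaussian covers a single half-plane, making
the complex spatial response an analytic (quadrature) signal whose modulus
is the sub-band magnitude.

For each of the S*O sub-bands the magnitude response is summarized over the
valve mask with six first-order statistics (mean, std, skewness, kurtosis,
energy, entropy) and eight second-order gray-level co-occurrence statistics
(contrast, correlation, homogeneity, uniformity at 1-px offsets of 0 and 90
degrees, 32 gray levels), 14 per band.  A correlation-based reducer then
drops redundant columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "LogGaborBank",
    "GaborFeatureBlock",
    "build_loggabor_bank",
    "gabor_raw_features",
    "fit_correlation_reducer",
    "apply_reducer",
    "FIRST_ORDER_STATS",
    "SECOND_ORDER_STATS",
    "DEFAULT_STAT_NAMES",
]

FIRST_ORDER_STATS = ("mean", "std", "skew", "kurt", "energy", "entropy")
SECOND_ORDER_STATS = ("contrast", "correlation", "homogeneity", "uniformity")
_GLCM_ANGLES = ("0", "90")
DEFAULT_STAT_NAMES = tuple(
    list(FIRST_ORDER_STATS)
    + [f"{s}{a}" for a in _GLCM_ANGLES for s in SECOND_ORDER_STATS]
)
_GLCM_LEVELS = 32


@dataclass(frozen=True)
class LogGaborBank:
    """Frequency-domain log-Gabor filters for a fixed image shape."""

    shape: tuple[int, int]
    S: int
    O: int
    wavelengths: np.ndarray          # per scale, px
    orientations: np.ndarray         # per orientation, radians
    transfer: np.ndarray             # (S, O, rows, cols), real in [0, 1]

    @property
    def n_filters(self) -> int:
        return self.S * self.O


@dataclass(frozen=True)
class GaborFeatureBlock:
    raw: np.ndarray
    stat_names: tuple[str, ...]
    reduced: np.ndarray | None = None
    selection: np.ndarray | None = None


def build_loggabor_bank(
    shape: tuple[int, int],
    S: int = 4,
    O: int = 6,
    min_wavelength: float = 4.0,
    scale_mult: float = 2.0,
    sigma_rho: float = 0.65,
    sigma_theta: float = np.pi / 7.2,
) -> LogGaborBank:
    """Build the S x O frequency-domain log-Gabor bank for an image shape.

    ``sigma_rho`` is the standard ratio sigma/f0 of the radial log-Gaussian
    (bandwidth factor, ~0.65 gives about two octaves); ``sigma_theta`` is
    the angular standard deviation in radians.
    """
    if S < 1 or O < 1:
        raise ValueError("S and O must be >= 1")
    if min_wavelength < 2:
        raise ValueError("min_wavelength must be >= 2 px")
    rows, cols = shape
    max_wavelength = min_wavelength * scale_mult ** (S - 1)
    if max_wavelength > max(rows, cols):
        raise ValueError("largest wavelength exceeds the image size")

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); DC forced to zero below
    # display orientation: x = +col, y = -row
    theta_grid = np.arctan2(-fy, fx)

    wavelengths = min_wavelength * scale_mult ** np.arange(S)
    orientations = np.arange(O) * np.pi / O
    log_sigma = abs(np.log(sigma_rho))

    transfer = np.empty((S, O, rows, cols))
    for s, lam in enumerate(wavelengths):
        f0 = 1.0 / lam
        radial = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma ** 2))
        radial[0, 0] = 0.0
        for t, theta0 in enumerate(orientations):
            d = np.arctan2(np.sin(theta_grid - theta0), np.cos(theta_grid - theta0))
            angular = np.exp(-(d ** 2) / (2.0 * sigma_theta ** 2))
            transfer[s, t] = radial * angular
    return LogGaborBank(
        shape=(rows, cols), S=S, O=O,
        wavelengths=wavelengths, orientations=orientations, transfer=transfer,
    )


@lru_cache(maxsize=8)
def cached_loggabor_bank(
    shape: tuple[int, int],
    S: int = 4,
    O: int = 6,
    min_wavelength: float = 4.0,
    scale_mult: float = 2.0,
    sigma_rho: float = 0.65,
    sigma_theta: float = np.pi / 7.2,
) -> LogGaborBank:
    """Memoized bank construction; banks are immutable and shape-keyed."""
    return build_loggabor_bank(shape, S, O, min_wavelength, scale_mult,
                               sigma_rho, sigma_theta)


def filter_responses(image: np.ndarray, bank: LogGaborBank) -> np.ndarray:
    """Complex analytic responses, shape (S, O, rows, cols).

    Real part = even-symmetric response, imaginary part = odd-symmetric.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != bank.shape:
        raise ValueError("image shape does not match the bank")
    F = np.fft.fft2(img)
    out = np.empty((bank.S, bank.O) + bank.shape, dtype=np.complex128)
    for s in range(bank.S):
        for t in range(bank.O):
            out[s, t] = np.fft.ifft2(F * bank.transfer[s, t])
    return out


def _entropy32(values: np.ndarray) -> float:
    hist, _ = np.histogram(values, bins=_GLCM_LEVELS)
    p = hist[hist > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def _glcm(quantized: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over in-mask pixel pairs.

    ``quantized`` holds levels 0.._GLCM_LEVELS-1 inside the mask and the
    sentinel _GLCM_LEVELS outside; sentinel pairs are discarded.
    """
    dr, dc = offset  # non-negative offsets only (0 deg and 90 deg used here)
    rows, cols = quantized.shape
    src = quantized[: rows - dr, : cols - dc]
    dst = quantized[dr:, dc:]
    pairs_i = src.ravel()
    pairs_j = dst.ravel()
    keep = (pairs_i < _GLCM_LEVELS) & (pairs_j < _GLCM_LEVELS)
    codes = pairs_i[keep] * _GLCM_LEVELS + pairs_j[keep]
    P = np.bincount(codes, minlength=_GLCM_LEVELS ** 2).reshape(
        _GLCM_LEVELS, _GLCM_LEVELS
    ).astype(np.float64)
    P = P + P.T  # symmetric
    total = P.sum()
    if total > 0:
        P /= total
    return P


def _glcm_stats(P: np.ndarray) -> tuple[float, float, float, float]:
    i = np.arange(_GLCM_LEVELS)[:, None]
    j = np.arange(_GLCM_LEVELS)[None, :]
    contrast = float(np.sum(P * (i - j) ** 2))
    homogeneity = float(np.sum(P / (1.0 + (i - j) ** 2)))
    uniformity = float(np.sum(P ** 2))
    pi = P.sum(axis=1)
    mu_i = float(np.sum(np.arange(_GLCM_LEVELS) * pi))
    var_i = float(np.sum(((np.arange(_GLCM_LEVELS) - mu_i) ** 2) * pi))
    if var_i < 1e-12:
        correlation = 0.0
    else:
        correlation = float(np.sum(P * (i - mu_i) * (j - mu_i)) / var_i)
    return contrast, correlation, homogeneity, uniformity


def gabor_raw_features(
    image: np.ndarray,
    mask: np.ndarray,
    bank: LogGaborBank,
    stat_names: tuple[str, ...] = DEFAULT_STAT_NAMES,
) -> GaborFeatureBlock:
    """Per-sub-band statistics of the masked valve texture.

    The background is replaced by the valve-interior mean before filtering to
    suppress mask-edge ringing; statistics then run over mask pixels only.
    Raw length is S * O * len(stat_names).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bank.shape:
        raise ValueError("mask shape does not match the bank")
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(image, dtype=np.float64)
    filled = np.where(mask, img, img[mask].mean())
    responses = filter_responses(filled, bank)

    feats: list[float] = []
    for s in range(bank.S):
        for t in range(bank.O):
            mag = np.abs(responses[s, t])
            vals = mag[mask]
            mu = float(vals.mean())
            centered = vals - mu
            var = float(np.mean(centered ** 2))
            std = float(np.sqrt(var))
            degenerate = std < 1e-12
            # quantize in-mask magnitudes to 32 levels; sentinel outside
            lo, hi = vals.min(), vals.max()
            if hi - lo < 1e-12:
                q_in = np.zeros(vals.shape, dtype=np.intp)
            else:
                q_in = np.minimum(
                    ((vals - lo) / (hi - lo) * _GLCM_LEVELS).astype(np.intp),
                    _GLCM_LEVELS - 1,
                )
            quant = np.full(mask.shape, _GLCM_LEVELS, dtype=np.intp)
            quant[mask] = q_in
            per_band = {
                "mean": mu,
                "std": std,
                # biased sample skewness and excess kurtosis
                "skew": 0.0 if degenerate else float(np.mean(centered ** 3) / std ** 3),
                "kurt": 0.0 if degenerate else float(np.mean(centered ** 4) / var ** 2 - 3.0),
                "energy": float(np.mean(vals ** 2)),
                "entropy": _entropy32(vals),
            }
            for angle, offset in (("0", (0, 1)), ("90", (1, 0))):
                c, r, h, u = _glcm_stats(_glcm(quant, offset))
                per_band[f"contrast{angle}"] = c
                per_band[f"correlation{angle}"] = r
                per_band[f"homogeneity{angle}"] = h
                per_band[f"uniformity{angle}"] = u
            feats.extend(per_band[name] for name in stat_names)
    return GaborFeatureBlock(raw=np.asarray(feats), stat_names=tuple(stat_names))


def feature_names(bank: LogGaborBank, stat_names=DEFAULT_STAT_NAMES) -> list[str]:
    return [
        f"gab_s{s + 1}_o{t + 1}_{name}"
        for s in range(bank.S)
        for t in range(bank.O)
        for name in stat_names
    ]


def fit_correlation_reducer(
    table: np.ndarray,
    threshold: float | None = 0.95,
    target_dim: int | None = None,
) -> np.ndarray:
    """Indices of columns retained after correlation-based redundancy removal.

    Threshold mode: a greedy pass in column order drops any column whose
    absolute Pearson correlation with an already-retained column exceeds
    ``threshold``.  Target-dim mode: repeatedly drops the later member of the
    most-correlated remaining pair until ``target_dim`` columns remain.
    Constant columns have undefined correlation and are treated as r = 0
    (retained).  Column 0 is never dropped.  Fit on training rows only.
    """
    X = np.asarray(table, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("table contains non-finite values")
    n_cols = X.shape[1]
    sd = X.std(axis=0)
    safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - X.mean(axis=0)) / safe
    corr = np.abs(Z.T @ Z) / X.shape[0]
    corr[sd <= 1e-12, :] = 0.0
    corr[:, sd <= 1e-12] = 0.0
    np.fill_diagonal(corr, 0.0)

    if target_dim is not None:
        if not 1 <= target_dim <= n_cols:
            raise ValueError("target_dim out of range")
        alive = np.ones(n_cols, dtype=bool)
        work = corr.copy()
        while alive.sum() > target_dim:
            flat = np.argmax(work)
            i, j = divmod(int(flat), n_cols)
            if work[i, j] <= 0:
                # all remaining pairs uncorrelated: drop the highest index
                drop = int(np.nonzero(alive)[0][-1])
            else:
                drop = max(i, j)  # later member goes; column 0 is never max
            alive[drop] = False
            work[drop, :] = -1.0
            work[:, drop] = -1.0
        return np.nonzero(alive)[0]

    if threshold is None or not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    kept: list[int] = []
    for j in range(n_cols):
        # strict comparison so exact duplicates (|r| = 1) drop at threshold 1
        if all(corr[j, k] < threshold for k in kept):
            kept.append(j)
    return np.asarray(kept, dtype=np.intp)


def apply_reducer(raw: np.ndarray | GaborFeatureBlock, selection: np.ndarray) -> np.ndarray:
    """Select the retained feature columns (or vector entries) in order."""
    vec = raw.raw if isinstance(raw, GaborFeatureBlock) else np.asarray(raw)
    selection = np.asarray(selection, dtype=np.intp)
    n = vec.shape[-1]
    if selection.size and (selection.min() < 0 or selection.max() >= n):
        raise IndexError("selection index out of range")
    return vec[..., selection]
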