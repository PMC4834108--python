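"""Optic-disc localisation from two weighted feature maps.

``F1`` enhances the disc (sum of gradient magnitudes plus a fast radial
symmetry transform at plausible disc radii); ``F2`` enhances the vasculature
(mean oriented matched-filter response).  The disc centre is then found by an
exhaustive two-stage search: horizontally in ``F2`` (the arcades cross the
disc vertically, so the column band of width ``w_max`` with the most vessel
response marks the disc column) and vertically in ``F1`` (the ``d_max``
window with the most disc response marks the row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .io import RetinalImage, minmax_or_zeros, to_luma


@dataclass
class LocalizationConfig:
    """Stage parameters; defaults are per-modality.

    ``sigma`` is the matched-filter vessel profile width (px): 4 for fundus,
    1.5 for SLO.  ``d_max`` is the maximum disc dimension (400 / 150 px) and
    ``w_max`` the maximum vessel width (50 / 12 px).
    """

    frst_radii: tuple
    sigma: float
    d_max: int
    w_max: int
    w_gradient: float = 0.5
    w_frst: float = 0.5
    n_orientations: int = 12

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.d_max <= 0 or self.w_max <= 0:
            raise ValueError("d_max and w_max must be positive")

    @classmethod
    def fundus(cls) -> "LocalizationConfig":
        return cls(frst_radii=_default_radii(400), sigma=4.0, d_max=400, w_max=50)

    @classmethod
    def slo(cls) -> "LocalizationConfig":
        return cls(frst_radii=_default_radii(150), sigma=1.5, d_max=150, w_max=12)

    @classmethod
    def for_disc_diameter(
        cls, diameter: float, sigma: float = 2.0, w_max: int = 10
    ) -> "LocalizationConfig":
        """Config scaled to a known nominal disc diameter (synthetic data)."""
        d_max = int(round(1.2 * diameter))
        radii = tuple(sorted({max(2, int(round(diameter * f)))
                              for f in (0.35, 0.5, 0.65)}))
        return cls(frst_radii=radii, sigma=sigma, d_max=d_max, w_max=w_max)


def _default_radii(d_max: int) -> tuple:
    # plausible disc radii: half of {d_max/4, d_max/3, d_max/2}
    return tuple(
        sorted({max(2, int(round(d_max * f * 0.5))) for f in (0.25, 1 / 3, 0.5)})
    )


@dataclass
class DiscLocation:
    x: int
    y: int
    score: float


def gradient_sum(y_map: np.ndarray) -> np.ndarray:
    """|dY/dx| + |dY/dy| (central differences), min-max normalised."""
    gy, gx = np.gradient(np.asarray(y_map, float))
    return minmax_or_zeros(np.abs(gx) + np.abs(gy))


def frst(y_map: np.ndarray, radii, alpha: float = 2.0) -> np.ndarray:
    """Fast radial symmetry transform (bright radial symmetry only).

    For each radius every pixel with non-negligible gradient votes at the
    *positively affected* pixel one radius along its gradient direction;
    orientation and magnitude projection images are combined as
    ``(|O|/k)^alpha * (M/k)``, smoothed with a Gaussian of width ``r/4``,
    averaged over radii and min-max normalised.  Maxima sit at the centres
    of bright blobs whose radius matches ``r``.
    """
    y_map = np.asarray(y_map, float)
    radii = tuple(int(r) for r in radii)
    if len(radii) == 0:
        raise ValueError("radius set must be non-empty")
    if max(radii) >= min(y_map.shape) / 2:
        raise ValueError("radius exceeds half the image size")
    gy, gx = np.gradient(y_map)
    mag = np.hypot(gx, gy)
    h, w = y_map.shape
    rows, cols = np.nonzero(mag > 1e-12)
    if rows.size == 0:
        return np.zeros_like(y_map)
    gxv = gx[rows, cols] / mag[rows, cols]
    gyv = gy[rows, cols] / mag[rows, cols]
    mv = mag[rows, cols]
    total = np.zeros_like(y_map)
    for r in radii:
        pr = rows + np.round(gyv * r).astype(int)
        pc = cols + np.round(gxv * r).astype(int)
        ok = (pr >= 0) & (pr < h) & (pc >= 0) & (pc < w)  # discard, not clip
        flat = pr[ok] * w + pc[ok]
        orient = np.bincount(flat, minlength=h * w).astype(float).reshape(h, w)
        magim = np.bincount(flat, weights=mv[ok], minlength=h * w).reshape(h, w)
        kappa = 8.0 if r == 1 else 9.9
        orient = np.minimum(orient, kappa)
        s = (orient / kappa) ** alpha * (magim / kappa)
        total += gaussian_filter(s, sigma=max(r / 4.0, 0.5))
    return minmax_or_zeros(total / len(radii))


def matched_filter_kernel(sigma: float, theta_deg: float) -> np.ndarray:
    """Zero-mean oriented matched-filter kernel for dark vessels.

    Gaussian valley profile ``-exp(-u^2 / 2 sigma^2)`` across the vessel,
    constant along it (length 6 sigma), rotated by ``theta``, DC-subtracted.
    """
    # grid must hold the rotated support square at any angle
    half_len = max(int(np.ceil(3.0 * sigma * np.sqrt(2.0))), 2)
    rng = np.arange(-half_len, half_len + 1)
    xx, yy = np.meshgrid(rng, rng)
    th = np.deg2rad(theta_deg)
    # u: distance across the vessel axis; v: along it
    u = xx * np.sin(th) + yy * np.cos(th)
    v = -xx * np.cos(th) + yy * np.sin(th)
    kern = -np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    # rotated-square support keeps the kernel rotation-covariant
    kern[(np.abs(v) > 3.0 * sigma) | (np.abs(u) > 3.0 * sigma)] = 0.0
    support = kern < 0
    kern[support] -= kern[support].mean()  # zero mean over the support
    return kern


def matched_filter_vessels(
    y_map: np.ndarray, sigma: float, n_orientations: int = 12,
    normalize: bool = True,
) -> np.ndarray:
    """Mean of oriented matched-filter responses, min-max normalised.

    Orientations cover 0..180 degrees in steps of 180/n (30 degrees per step
    for the default 12 taken pairwise with kernel symmetry).  Boundaries are
    reflect-padded so image borders do not fire the filter.
    """
    y_map = np.asarray(y_map, float)
    kernels = [matched_filter_kernel(sigma, 180.0 * k / n_orientations)
               for k in range(n_orientations)]
    pad = kernels[0].shape[0] // 2 + 1
    padded = np.pad(y_map, pad, mode="reflect")
    resp = np.zeros_like(padded)
    for kern in kernels:
        resp += fftconvolve(padded, kern[::-1, ::-1], mode="same")
    resp = resp[pad:-pad, pad:-pad] / n_orientations
    if not normalize:
        return resp
    if np.ptp(resp) < 1e-9:  # featureless input: numerically flat response
        return np.zeros_like(resp)
    return minmax_or_zeros(resp)


@dataclass
class FeatureMapPair:
    f1: np.ndarray  # disc-enhancing
    f2: np.ndarray  # vessel-enhancing


def build_feature_maps(img: RetinalImage, cfg: LocalizationConfig) -> FeatureMapPair:
    """F1 = minmax(w_g * gradient_sum + w_f * FRST); F2 = matched filter."""
    y = to_luma(img)
    f1 = minmax_or_zeros(
        cfg.w_gradient * gradient_sum(y) + cfg.w_frst * frst(y, cfg.frst_radii)
    )
    f2 = matched_filter_vessels(y, cfg.sigma, cfg.n_orientations)
    return FeatureMapPair(f1=f1, f2=f2)


def _band_sums(col_sums: np.ndarray, width: int) -> np.ndarray:
    """Sum of ``col_sums`` over a centred window of ``width`` per column."""
    c = np.concatenate([[0.0], np.cumsum(col_sums)])
    n = col_sums.size
    half = width // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return c[hi] - c[lo]


def localize_disc(maps: FeatureMapPair, cfg: LocalizationConfig) -> DiscLocation:
    """Two-stage exhaustive search for the disc centre.

    Stage 1 scans columns of ``F2``: the best column is the centre of the
    vertical band of width ``w_max`` with the largest total vessel response.
    Stage 2 scans rows of ``F1`` inside the ``d_max``-wide column slab at
    that x: the best row centres the ``d_max x d_max`` window with the
    largest disc response.  A contiguous run of tied window positions
    resolves to its centre (windows wider than the structure tie over a
    whole run; the centred position is the unbiased choice).
    """
    f1, f2 = maps.f1, maps.f2
    if f1.shape != f2.shape:
        raise ValueError("feature maps must share a shape")
    h, w = f1.shape
    if h < cfg.d_max // 2 or w < cfg.d_max // 2:
        raise ValueError("image is too small for the configured d_max")
    band = _band_sums(f2.sum(axis=0), cfg.w_max)
    x_hat = _argmax_run_center(band)
    half = cfg.d_max // 2
    x0, x1 = max(0, x_hat - half), min(w, x_hat + half + 1)
    row_slab = f1[:, x0:x1].sum(axis=1)
    rows = _band_sums(row_slab, cfg.d_max)
    y_hat = _argmax_run_center(rows)
    score = float(rows[y_hat] + band[x_hat])
    return DiscLocation(x=x_hat, y=y_hat, score=score)


def _argmax_run_center(values: np.ndarray, rel_eps: float = 1e-12) -> int:
    """Index of the maximum; a contiguous tied run yields its (lower)
    middle element."""
    values = np.asarray(values, float)
    first = int(np.argmax(values))
    tol = rel_eps * max(abs(values[first]), 1.0)
    last = first
    while last + 1 < values.size and values[last + 1] >= values[first] - tol:
        last += 1
    return (first + last) // 2


def localize(img: RetinalImage, cfg: LocalizationConfig | None = None) -> DiscLocation:
    """Convenience wrapper: feature maps + search with per-modality defaults."""
    if cfg is None:
        cfg = (
            LocalizationConfig.fundus()
            if img.modality == "fundus"
            else LocalizationConfig.slo()
        )
    return localize_disc(build_feature_maps(img, cfg), cfg)
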