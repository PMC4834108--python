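"""Regional feature extraction: six feature families over five regions.

For every disc-centred crop the model computes, per region (OD, I, S, N, T)
and per optical channel (red, green):

* ``g``        — means of the 48 Gaussian-filter-bank responses (240 cols);
* ``texoff``   — 20 grey-level co-occurrence (GLCM) texture statistics at
                 pixel offsets d = 1..10 (2000 cols);
* ``texscale`` — the same 20 statistics at offset 1 after Gaussian blurring
                 at sigma = 2, 4, 8, 16 (800 cols);
* ``dg``       — centre-surround dyadic Gaussian-pyramid responses of the
                 intensity, red-green opponency and yellow channels at nine
                 (centre, surround) level pairs (135 cols);
* ``gab``      — mean Gabor magnitude over a 4 sigma x 5 gamma x
                 7 frequency x 4 orientation filter grid (5600 cols);
* ``wav``      — one-level DWT subband average/energy for five wavelet
                 families (400 cols).

Assembled in the block order [dg, texoff, texscale, g, gab, wav] this gives
9175 regional columns; "global" mode treats the whole crop as one region
(1835 columns).  Every column carries provenance metadata
(family, region, channel, parameter string).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .io import RetinalImage
from .segmentation import DEFAULT_SIGMAS, FilterBank, gaussian_bank_maps

CHANNELS = ("red", "green")
REGION_ORDER = ("OD", "I", "S", "N", "T")


@dataclass(frozen=True)
class ColumnMeta:
    family: str   # dg | texoff | texscale | g | gab | wav
    region: str   # OD | I | S | N | T | whole
    channel: str
    params: str

    @property
    def key(self) -> str:
        return f"{self.family}|{self.region}|{self.channel}|{self.params}"

    @classmethod
    def from_key(cls, key: str) -> "ColumnMeta":
        family, region, channel, params = key.split("|", 3)
        return cls(family, region, channel, params)


@dataclass
class FeatureMatrix:
    """Samples x features with per-column provenance."""

    values: np.ndarray
    columns: list  # of ColumnMeta

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match value width")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def family_counts(self) -> dict:
        out: dict = {}
        for c in self.columns:
            out[c.family] = out.get(c.family, 0) + 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[c.key for c in self.columns])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        cols = [ColumnMeta.from_key(k) for k in df.columns]
        return cls(df.to_numpy(float), cols)

    def subset(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, int)
        return FeatureMatrix(self.values[:, idx], [self.columns[i] for i in idx])


# ---------------------------------------------------------------------------
# gaussian (filter-bank mean) features
# ---------------------------------------------------------------------------

_BANK_KERNELS = ("N", "Nx", "Ny", "Nxx", "Nxy", "Nyy")


def gaussian_features(crop: RetinalImage, region_masks: dict,
                      bank: FilterBank | None = None,
                      maps: np.ndarray | None = None):
    """Mean filter-bank response per region: 6 kernels x 4 scales x
    2 channels x regions."""
    bank = bank or FilterBank()
    if maps is None:
        maps = gaussian_bank_maps(crop, bank, inpaint=False)
    vals, meta = [], []
    idx = 0
    for chan in bank.channels:
        for s in bank.sigmas:
            for kern in _BANK_KERNELS:
                m = maps[idx]
                idx += 1
                for rname in _region_iter(region_masks):
                    mask = region_masks[rname]
                    vals.append(float(m[mask].mean()) if mask.any() else 0.0)
                    meta.append(ColumnMeta("g", rname, chan, f"{kern},s{s:g}"))
    return np.array(vals), meta


def _region_iter(region_masks: dict):
    known = [r for r in REGION_ORDER if r in region_masks]
    extra = [r for r in region_masks if r not in REGION_ORDER]
    return known + extra


# ---------------------------------------------------------------------------
# GLCM texture features
# ---------------------------------------------------------------------------

def glcm(values: np.ndarray, mask: np.ndarray, d: int, levels: int = 16,
         orientations=((1, 0), (1, 1), (0, 1), (-1, 1)),
         symmetric: bool = True) -> np.ndarray:
    """Region-restricted grey-level co-occurrence probability matrix.

    The region is min-max quantised to ``levels`` grey bins; pairs are
    counted only when *both* pixels fall inside the region, accumulated over
    the four orientations at displacement magnitude ``d`` and (optionally)
    both directions, then normalised to sum 1.
    """
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty region")
    region = values[mask]
    lo, hi = region.min(), region.max()
    if hi > lo:
        q = np.zeros_like(values, dtype=int)
        q[mask] = np.minimum(
            ((values[mask] - lo) / (hi - lo) * levels).astype(int), levels - 1
        )
    else:
        q = np.zeros_like(values, dtype=int)
    counts = np.zeros((levels, levels))
    h, w = values.shape
    found = False
    for ox, oy in orientations:
        dx, dy = ox * d, oy * d
        src = np.zeros((h, w), bool)
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        src[ys, xs] = True
        valid = src & mask
        rows, cols = np.nonzero(valid)
        r2, c2 = rows + dy, cols + dx
        inside = mask[r2, c2]
        if not inside.any():
            continue
        found = True
        i = q[rows[inside], cols[inside]]
        j = q[r2[inside], c2[inside]]
        np.add.at(counts, (i, j), 1.0)
    if not found:
        raise ValueError("no valid pixel pairs for this offset")
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


GLCM_FEATURE_NAMES = (
    "autocorrelation", "contrast", "correlation", "cluster_prominence",
    "cluster_shade", "dissimilarity", "energy", "entropy", "homogeneity",
    "max_probability", "sum_of_squares", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy", "imc1",
    "imc2", "idn", "idmn",
)


def glcm_features(p: np.ndarray) -> np.ndarray:
    """The 20-statistic extended Haralick set from a GLCM ``p``.

    Entropies are in bits (log base 2); 0 log 0 is taken as 0.
    """
    p = np.asarray(p, float)
    n = p.shape[0]
    i = np.arange(n)[:, None] * np.ones((1, n))
    j = np.ones((n, 1)) * np.arange(n)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (np.arange(n) * px).sum()
    mu_y = (np.arange(n) * py).sum()
    sd_x = np.sqrt(((np.arange(n) - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((np.arange(n) - mu_y) ** 2 * py).sum())
    mu = p.mean() * 0 + (i * p).sum()  # mean of i under p (== mu_x)

    def xlog2(v):
        v = np.asarray(v, float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    # sum / difference distributions
    ksum = np.arange(2 * n - 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), p.ravel())
    kdiff = np.arange(n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), p.ravel())

    autocorrelation = (i * j * p).sum()
    contrast = (((i - j) ** 2) * p).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((i - mu_x) * (j - mu_y) * p).sum() / (sd_x * sd_y)
    else:
        correlation = 0.0
    cluster_prominence = (((i + j - mu_x - mu_y) ** 4) * p).sum()
    cluster_shade = (((i + j - mu_x - mu_y) ** 3) * p).sum()
    dissimilarity = (np.abs(i - j) * p).sum()
    energy = (p ** 2).sum()
    entropy = -xlog2(p).sum()
    homogeneity = (p / (1.0 + (i - j) ** 2)).sum()  # inverse difference moment
    max_probability = p.max()
    sum_of_squares = (((i - mu) ** 2) * p).sum()
    sum_average = (ksum * p_sum).sum()
    sum_entropy = -xlog2(p_sum).sum()
    sum_variance = (((ksum - sum_average) ** 2) * p_sum).sum()
    diff_average = (kdiff * p_diff).sum()
    difference_variance = (((kdiff - diff_average) ** 2) * p_diff).sum()
    difference_entropy = -xlog2(p_diff).sum()
    # information measures of correlation
    hxy = entropy
    pij_prod = px[:, None] * py[None, :]
    nzp = (p > 0) & (pij_prod > 0)
    hxy1 = -(p[nzp] * np.log2(pij_prod[nzp])).sum()
    nz2 = pij_prod > 0
    hxy2 = -(pij_prod[nz2] * np.log2(pij_prod[nz2])).sum()
    hx = -xlog2(px).sum()
    hy = -xlog2(py).sum()
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy))
    imc2 = np.sqrt(max(arg, 0.0))
    idn = (p / (1.0 + np.abs(i - j) / n)).sum()
    idmn = (p / (1.0 + ((i - j) / n) ** 2)).sum()
    return np.array([
        autocorrelation, contrast, correlation, cluster_prominence,
        cluster_shade, dissimilarity, energy, entropy, homogeneity,
        max_probability, sum_of_squares, sum_average, sum_variance,
        sum_entropy, difference_variance, difference_entropy, imc1, imc2,
        idn, idmn,
    ])


def _texture_block(channel_maps: dict, region_masks: dict, family: str,
                   param_values, levels: int):
    """Shared scaffolding for texoff/texscale: channel_maps maps
    (channel, param) -> image; params vary either offset d or scale sigma."""
    vals, meta = [], []
    for chan in CHANNELS:
        for pv in param_values:
            img, d = channel_maps[(chan, pv)]
            for rname in _region_iter(region_masks):
                mask = region_masks[rname]
                try:
                    feats = glcm_features(glcm(img, mask, d, levels=levels))
                except ValueError:
                    feats = np.zeros(20)
                vals.append(feats)
                tag = f"d{pv}" if family == "texoff" else f"s{pv:g}"
                meta.extend(
                    ColumnMeta(family, rname, chan, f"{name},{tag}")
                    for name in GLCM_FEATURE_NAMES
                )
    return np.concatenate(vals), meta


def texoff_features(crop: RetinalImage, region_masks: dict,
                    offsets=tuple(range(1, 11)), levels: int = 16):
    """GLCM statistics at varying pixel offset: 20 x 10 x 2 channels x regions."""
    channel_maps = {
        (chan, d): (crop.channel(chan), d) for chan in CHANNELS for d in offsets
    }
    return _texture_block(channel_maps, region_masks, "texoff", offsets, levels)


def texscale_features(crop: RetinalImage, region_masks: dict,
                      sigmas=DEFAULT_SIGMAS, levels: int = 16):
    """GLCM statistics (offset 1) after Gaussian smoothing at each scale:
    20 x 4 x 2 channels x regions."""
    channel_maps = {
        (chan, s): (gaussian_filter(crop.channel(chan), s), 1)
        for chan in CHANNELS
        for s in sigmas
    }
    return _texture_block(channel_maps, region_masks, "texscale", sigmas, levels)


# ---------------------------------------------------------------------------
# dyadic Gaussian (centre-surround) features
# ---------------------------------------------------------------------------

@dataclass
class DyadicConfig:
    centers: tuple = (2, 3, 4)
    deltas: tuple = (2, 3, 4)

    @property
    def pairs(self):
        return [(c, c + d) for c in self.centers for d in self.deltas]


_DYADIC_CHANNELS = ("Imn", "RG", "Yrg")


def _pyramid(img: np.ndarray, max_level: int):
    """Gaussian pyramid: blur + 2x downsample per level; level 0 = input."""
    levels = [np.asarray(img, float)]
    for _ in range(max_level):
        cur = gaussian_filter(levels[-1], 1.0, mode="reflect")
        levels.append(cur[::2, ::2])
    return levels


def dyadic_features(crop: RetinalImage, region_masks: dict,
                    cfg: DyadicConfig | None = None):
    """Centre-surround responses |centre - Interp(surround)| of the
    intensity (I_mn = (R+G)/2), opponent (R-G) and yellow
    (Y_rg = R+G-2|R-G|) channels, averaged per region at the centre-level
    resolution: 9 pairs x 3 channels x regions."""
    cfg = cfg or DyadicConfig()
    r = crop.red
    g = crop.green
    feats = {"Imn": (r + g) / 2.0, "RG": r - g, "Yrg": r + g - 2.0 * np.abs(r - g)}
    max_level = max(s for _, s in cfg.pairs)
    min_side = 2 ** max_level
    pad = max(0, min_side - min(r.shape))
    if pad:
        feats = {k: np.pad(v, ((0, pad), (0, pad)), mode="reflect")
                 for k, v in feats.items()}
    pyramids = {k: _pyramid(v, max_level) for k, v in feats.items()}
    vals, meta = [], []
    for chan in _DYADIC_CHANNELS:
        pyr = pyramids[chan]
        for c, s in cfg.pairs:
            up = resize(pyr[s], pyr[c].shape, order=1, mode="reflect",
                        anti_aliasing=False)
            cs = np.abs(pyr[c] - up)
            for rname in _region_iter(region_masks):
                mask = region_masks[rname]
                # region mask at centre-level resolution
                small = resize(mask.astype(float),
                               (mask.shape[0] // 2 ** c or 1,
                                mask.shape[1] // 2 ** c or 1),
                               order=0, anti_aliasing=False) > 0.5
                sub = cs[: small.shape[0], : small.shape[1]][small]
                vals.append(float(sub.mean()) if sub.size else 0.0)
                meta.append(ColumnMeta("dg", rname, chan, f"c{c},s{s}"))
    return np.array(vals), meta


# ---------------------------------------------------------------------------
# Gabor features
# ---------------------------------------------------------------------------

@dataclass
class GaborConfig:
    sigmas: tuple = (2.0, 4.0, 8.0, 16.0)
    gammas: tuple = (1 / 3, 1 / 2, 1.0, 2.0, 3.0)
    freqs: tuple = (1 / 4, 1 / 3, 1 / 2, 1.0, 2.0, 3.0, 4.0)
    thetas: tuple = (0.0, 45.0, 90.0, 135.0)


def gabor_kernel(sigma: float, gamma: float, freq: float,
                 theta_deg: float) -> np.ndarray:
    """Complex Gabor kernel truncated at 3 sigma.

    Envelope ``exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))`` with carrier
    ``exp(i 2 pi f x')`` along the rotated axis x'.
    """
    half = max(int(np.ceil(3.0 * sigma)), 1)
    rng = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(rng, rng)
    th = np.deg2rad(theta_deg)
    xr = xx * np.cos(th) + yy * np.sin(th)
    yr = yy * np.cos(th) - xx * np.sin(th)
    env = np.exp(-0.5 * (xr ** 2 + (gamma * yr) ** 2) / sigma ** 2)
    return env * np.exp(1j * 2.0 * np.pi * freq * xr)


def _fft_conv_same(img_f, img_shape, kern, fshape):
    kf = fft2(kern, fshape)
    full = ifft2(img_f * kf)
    # 'same' crop of the full convolution
    ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
    return full[ph : ph + img_shape[0], pw : pw + img_shape[1]]


def gabor_features(crop: RetinalImage, region_masks: dict,
                   cfg: GaborConfig | None = None):
    """Mean magnitude of the complex Gabor response per filter, channel and
    region: 4 x 5 x 7 x 4 x 2 channels x regions."""
    cfg = cfg or GaborConfig()
    h, w = crop.shape
    region_list = _region_iter(region_masks)
    vals, meta = [], []
    for chan in CHANNELS:
        image = crop.channel(chan)
        for s in cfg.sigmas:
            half = max(int(np.ceil(3.0 * s)), 1)
            ksz = 2 * half + 1
            fshape = (next_fast_len(h + ksz - 1), next_fast_len(w + ksz - 1))
            img_f = fft2(image, fshape)
            for gamma in cfg.gammas:
                for f in cfg.freqs:
                    for th in cfg.thetas:
                        kern = gabor_kernel(s, gamma, f, th)
                        mag = np.abs(_fft_conv_same(img_f, (h, w), kern, fshape))
                        for rname in region_list:
                            mask = region_masks[rname]
                            vals.append(float(mag[mask].mean()) if mask.any() else 0.0)
                            meta.append(ColumnMeta(
                                "gab", rname, chan,
                                f"t{th:g},s{s:g},g{gamma:.2g},f{f:.2g}",
                            ))
    return np.array(vals), meta


# ---------------------------------------------------------------------------
# wavelet features
# ---------------------------------------------------------------------------

@dataclass
class WaveletConfig:
    families: tuple = ("haar", "db3", "rbio3.3", "rbio3.5", "rbio3.7")
    bands: tuple = ("A", "H", "V", "D")


def wavelet_features(crop: RetinalImage, region_masks: dict,
                     cfg: WaveletConfig | None = None):
    """One-level DWT subband statistics per region.

    The channel is restricted to the region bounding box with outside-region
    pixels zeroed; per band, the average absolute coefficient (scaled by
    1/(p q)) and the coefficient energy (scaled by 1/(p^2 q^2)) are
    reported, with p x q the bounding-box size:
    5 families x 4 bands x 2 channels x 2 statistics x regions.
    """
    cfg = cfg or WaveletConfig()
    vals, meta = [], []
    for chan in CHANNELS:
        image = crop.channel(chan)
        for fam in cfg.families:
            wav = pywt.Wavelet(fam)
            for rname in _region_iter(region_masks):
                mask = region_masks[rname]
                if not mask.any():
                    for band in cfg.bands:
                        vals.extend([0.0, 0.0])
                        meta.extend([
                            ColumnMeta("wav", rname, chan, f"{fam},{band},Avg"),
                            ColumnMeta("wav", rname, chan, f"{fam},{band},Energy"),
                        ])
                    continue
                rows, cols = np.nonzero(mask)
                r0, r1 = rows.min(), rows.max() + 1
                c0, c1 = cols.min(), cols.max() + 1
                sub = np.where(mask[r0:r1, c0:c1], image[r0:r1, c0:c1], 0.0)
                p, q = c1 - c0, r1 - r0  # width, height
                if min(p, q) < wav.dec_len:
                    bands = {b: np.zeros((1, 1)) for b in cfg.bands}
                else:
                    ca, (ch_, cv, cd) = pywt.dwt2(sub, fam)
                    bands = {"A": ca, "H": ch_, "V": cv, "D": cd}
                for band in cfg.bands:
                    coef = bands[band]
                    avg = np.abs(coef).sum() / (p * q)
                    energy = (coef ** 2).sum() / (p ** 2 * q ** 2)
                    vals.extend([avg, energy])
                    meta.extend([
                        ColumnMeta("wav", rname, chan, f"{fam},{band},Avg"),
                        ColumnMeta("wav", rname, chan, f"{fam},{band},Energy"),
                    ])
    return np.array(vals), meta


# ---------------------------------------------------------------------------
# assembly and normalisation
# ---------------------------------------------------------------------------

def extract_sample(crop: RetinalImage, region_masks: dict,
                   bank: FilterBank | None = None,
                   dyadic_cfg: DyadicConfig | None = None,
                   gabor_cfg: GaborConfig | None = None,
                   wavelet_cfg: WaveletConfig | None = None):
    """All six feature blocks for one crop, in the canonical block order
    [dg, texoff, texscale, g, gab, wav]."""
    blocks = [
        dyadic_features(crop, region_masks, dyadic_cfg),
        texoff_features(crop, region_masks),
        texscale_features(crop, region_masks),
        gaussian_features(crop, region_masks, bank),
        gabor_features(crop, region_masks, gabor_cfg),
        wavelet_features(crop, region_masks, wavelet_cfg),
    ]
    vals = np.concatenate([b[0] for b in blocks])
    meta = [m for b in blocks for m in b[1]]
    return vals, meta


def assemble_feature_matrix(samples, global_mode: bool = False,
                            **kwargs) -> FeatureMatrix:
    """Build the feature matrix from ``samples`` =
    iterable of (crop RetinalImage, RegionMask-or-mask-dict).

    ``global_mode`` replaces the five regions with a single whole-crop
    region.
    """
    rows = []
    meta = None
    for crop, region in samples:
        if global_mode:
            masks = {"whole": np.ones(crop.shape, bool)}
        elif hasattr(region, "region_masks"):
            masks = region.region_masks()
        else:
            masks = region
        vals, m = extract_sample(crop, masks, **kwargs)
        rows.append(vals)
        if meta is None:
            meta = m
    return FeatureMatrix(np.vstack(rows), meta)


@dataclass
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns


def fit_zscore(fm: FeatureMatrix, train_rows=None) -> ZScoreStats:
    """Column means/SDs (population convention) from the training rows;
    zero-variance columns are dropped with a warning."""
    rows = slice(None) if train_rows is None else np.asarray(train_rows, int)
    x = fm.values[rows]
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0)
    kept = np.nonzero(sd > 0)[0]
    if kept.size < fm.n_features:
        warnings.warn(
            f"dropping {fm.n_features - kept.size} zero-variance feature columns"
        )
    return ZScoreStats(mean=mean[kept], sd=sd[kept], kept=kept)


def apply_zscore(fm: FeatureMatrix, stats: ZScoreStats) -> FeatureMatrix:
    sub = fm.subset(stats.kept)
    return FeatureMatrix((sub.values - stats.mean) / stats.sd, sub.columns)


def zscore_normalize(fm: FeatureMatrix, train_rows=None):
    """Z-score the matrix using statistics from the training rows only.

    Returns ``(normalised FeatureMatrix, ZScoreStats)``.
    """
    stats = fit_zscore(fm, train_rows)
    return apply_zscore(fm, stats), stats
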