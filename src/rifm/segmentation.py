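"""Optic-disc segmentation by profile matching along contour normals.

The segmenter is an active-shape-style model driven by a Gaussian
filter-bank representation of the image:

1. red and green channels are vessel-inpainted (directional grey closings)
   so the dark arcades do not drag the boundary;
2. both channels are convolved with a Gaussian filter bank — the Gaussian
   ``N(sigma)`` with peak ``1/(2 pi sigma^2)``, its first derivatives
   ``N_x, N_y`` and second derivatives ``N_xx, N_xy, N_yy`` at scales
   sigma = 2, 4, 8, 16 — giving M = 48 feature maps;
3. feature profiles are sampled along the outward normal of each contour
   point; a trained per-point profile model (mean + regularised covariance)
   scores candidate positions by Mahalanobis distance, and the best position
   per point is taken;
4. a statistical shape model (Procrustes-aligned PCA) regularises the
   contour after each update, and the disc centre is re-estimated as the
   mean of the final contour vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, grey_closing, map_coordinates
from scipy.ndimage import label as ndi_label
from skimage.filters import threshold_otsu

from .io import RetinalImage
from .localization import matched_filter_vessels, to_luma

DEFAULT_SIGMAS = (2.0, 4.0, 8.0, 16.0)
#: (y-order, x-order) pairs: N, N_x, N_y, N_xx, N_xy, N_yy
_BANK_ORDERS = ((0, 0), (0, 1), (1, 0), (0, 2), (1, 1), (2, 0))

N_POINTS = 64  # contour points
PROFILE_L = 20  # half-length of each normal profile (samples at -L..L)
N_CANDIDATES = 21  # candidate positions per normal (odd)


@dataclass
class FilterBank:
    sigmas: tuple = DEFAULT_SIGMAS
    channels: tuple = ("red", "green")

    @property
    def n_maps(self) -> int:
        return len(_BANK_ORDERS) * len(self.sigmas) * len(self.channels)


def gaussian_bank_maps(img: RetinalImage, bank: FilterBank | None = None,
                       inpaint: bool = True,
                       vessel_sigma: float | None = None) -> np.ndarray:
    """Stack of M filter-bank responses, shape (M, H, W).

    Channels are vessel-inpainted first unless ``inpaint`` is False.
    Boundary handling is reflective.
    """
    bank = bank or FilterBank()
    chans = {name: img.channel(name) for name in bank.channels}
    if inpaint:
        vessels = segment_vessels(img, sigma=vessel_sigma)
        chans = {k: inpaint_vessels(v, vessels) for k, v in chans.items()}
    maps = []
    for name in bank.channels:
        for s in bank.sigmas:
            for oy, ox in _BANK_ORDERS:
                maps.append(
                    gaussian_filter(chans[name], s, order=(oy, ox), mode="reflect")
                )
    return np.stack(maps)


_VESSEL_SIGMA = {"fundus": 4.0, "slo": 1.5}


def segment_vessels(img: RetinalImage, sigma: float | None = None,
                    min_size: int = 50) -> np.ndarray:
    """Vasculature mask: matched-filter response, Otsu threshold, and
    removal of components below ``min_size`` pixels."""
    if sigma is None:
        sigma = _VESSEL_SIGMA[img.modality]
    raw = matched_filter_vessels(to_luma(img), sigma, normalize=False)
    if np.ptp(raw) < 1e-9:  # featureless image
        return np.zeros(raw.shape, bool)
    resp = (raw - raw.min()) / np.ptp(raw)
    # vessels are a small bright fraction of the response map; re-apply Otsu
    # on the supra-threshold tail until the mask fraction is vessel-like
    t = threshold_otsu(resp)
    for _ in range(3):
        frac = (resp > t).mean()
        tail = resp[resp > t]
        if frac <= 0.15 or tail.size < 2 or np.ptp(tail) < 1e-8:
            break
        t = threshold_otsu(tail)
    mask = resp > t
    lab, n = ndi_label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


def _line_footprint(length: int, theta_deg: float) -> np.ndarray:
    fp = np.zeros((length, length), bool)
    c = (length - 1) / 2.0
    th = np.deg2rad(theta_deg)
    t = np.linspace(-c, c, 4 * length)
    rr = np.clip(np.round(c + t * np.sin(th)).astype(int), 0, length - 1)
    cc = np.clip(np.round(c + t * np.cos(th)).astype(int), 0, length - 1)
    fp[rr, cc] = True
    return fp


def inpaint_vessels(channel: np.ndarray, vessels: np.ndarray,
                    length: int = 11) -> np.ndarray:
    """Replace vessel pixels by the max over 8 directional grey closings.

    A linear structuring element is swept over 0..157.5 degrees in 22.5
    degree steps; closing bridges the dark vessel from the brighter tissue
    on either side, and the maximum response is kept per vessel pixel.
    Non-vessel pixels pass through unchanged.
    """
    channel = np.asarray(channel, float)
    vessels = np.asarray(vessels, bool)
    if vessels.shape != channel.shape:
        raise ValueError("vessel mask shape mismatch")
    if not vessels.any():
        return channel.copy()
    best = np.full_like(channel, -np.inf)
    for k in range(8):
        closed = grey_closing(
            channel, footprint=_line_footprint(length, 22.5 * k), mode="reflect"
        )
        best = np.maximum(best, closed)
    out = channel.copy()
    out[vessels] = best[vessels]
    return out


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

@dataclass
class DiscContour:
    """Ordered closed contour; ``points`` is (N, 2) as (x, y)."""

    points: np.ndarray
    converged: bool = True

    @property
    def centroid(self) -> tuple:
        """Disc centre re-estimated as the vertex mean."""
        c = np.asarray(self.points, float).mean(axis=0)
        return (float(c[0]), float(c[1]))

    def mask(self, shape) -> np.ndarray:
        from .io import contour_to_mask

        return contour_to_mask(self.points, shape)


def resample_contour(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` equally spaced (arc-length) points,
    keeping the starting vertex and orientation."""
    pts = np.asarray(points, float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def contour_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals (outward = away from the vertex centroid)."""
    pts = np.asarray(points, float)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    nrm = nrm / lens
    outward = pts - pts.mean(axis=0)
    flip = np.sum(nrm * outward, axis=1) < 0
    nrm[flip] *= -1.0
    return nrm


def _sample_along_normals(maps: np.ndarray, points: np.ndarray,
                          normals: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Bilinear samples, shape (N_points, M, len(offsets)); positions
    outside the image clamp to the border."""
    pos = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rows = pos[..., 1].ravel()
    cols = pos[..., 0].ravel()
    out = np.empty((maps.shape[0], rows.size))
    for m in range(maps.shape[0]):
        out[m] = map_coordinates(maps[m], [rows, cols], order=1, mode="nearest")
    n_pts, n_off = points.shape[0], offsets.size
    return out.reshape(maps.shape[0], n_pts, n_off).transpose(1, 0, 2)


def sample_normal_profiles(maps: np.ndarray, contour: np.ndarray, L: int,
                           offset: float = 0.0) -> np.ndarray:
    """Profile vectors: per contour point, 2L+1 bilinear samples along the
    outward normal of every map, concatenated map-major -> (N, (2L+1) M)."""
    pts = np.asarray(contour, float)
    normals = contour_normals(pts)
    offsets = np.arange(-L, L + 1, dtype=float) + offset
    samp = _sample_along_normals(np.asarray(maps, float), pts, normals, offsets)
    return samp.reshape(pts.shape[0], -1)


# ---------------------------------------------------------------------------
# profile model (per-point mean + regularised covariance, Mahalanobis)
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    mean: np.ndarray        # (N, d)
    dev: np.ndarray         # (N, k, d): training deviations / sqrt(k)
    lam: np.ndarray         # (N,) ridge per point
    minv: np.ndarray        # (N, k, k): inv(lam I + dev dev^T)
    L: int
    n_maps: int

    @property
    def n_points(self) -> int:
        return self.mean.shape[0]

    def mahalanobis2(self, point: int, profiles: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of candidate ``profiles`` (P, d) to
        the training distribution at contour point ``point``.

        The covariance ``C = dev^T dev + lam I`` is inverted through the
        Woodbury identity so the d x d matrix is never formed.
        """
        v = np.atleast_2d(profiles) - self.mean[point]
        b = self.dev[point]          # (k, d)
        lam = self.lam[point]
        bv = v @ b.T                 # (P, k)
        corr = np.einsum("pk,kl,pl->p", bv, self.minv[point], bv)
        return (np.einsum("pd,pd->p", v, v) - corr) / lam


def build_profile_model(profiles: np.ndarray, L: int, n_maps: int,
                        ridge_scale: float = 1e-3) -> ProfileModel:
    """Fit a per-point profile model from ``profiles`` (k, N, d)."""
    k = profiles.shape[0]
    mean = profiles.mean(axis=0)
    dev = (profiles - mean) / np.sqrt(k)
    # lam = ridge_scale * trace(cov)/d per point, floored for degeneracy
    tr = np.einsum("knd,knd->n", dev, dev)
    lam = np.maximum(ridge_scale * tr / profiles.shape[2], 1e-10)
    eye = np.eye(k)
    minv = np.stack([
        np.linalg.inv(lam[n] * eye + dev[:, n, :] @ dev[:, n, :].T)
        for n in range(profiles.shape[1])
    ])
    return ProfileModel(mean=mean, dev=dev.transpose(1, 0, 2), lam=lam,
                        minv=minv, L=L, n_maps=n_maps)


def train_profile_model(images, contours, bank: FilterBank | None = None,
                        L: int = PROFILE_L, n_points: int = N_POINTS,
                        vessel_sigma: float | None = None,
                        min_images: int = 5) -> ProfileModel:
    """Train the profile model from annotated images.

    ``contours`` are the annotated disc boundaries; each is arc-length
    resampled to ``n_points`` so points correspond across images.
    """
    if len(images) < min_images:
        raise ValueError(f"need at least {min_images} annotated images")
    if len(images) != len(contours):
        raise ValueError("images and contours must pair up")
    bank = bank or FilterBank()
    stack = []
    for img, cont in zip(images, contours):
        maps = gaussian_bank_maps(img, bank, vessel_sigma=vessel_sigma)
        pts = resample_contour(np.asarray(cont, float), n_points)
        stack.append(sample_normal_profiles(maps, pts, L))
    return build_profile_model(np.stack(stack), L, bank.n_maps)


# ---------------------------------------------------------------------------
# statistical shape model
# ---------------------------------------------------------------------------

@dataclass
class ShapeModel:
    mean_shape: np.ndarray   # (N, 2), centred, unit Frobenius norm
    components: np.ndarray   # (m, 2N) PCA modes
    eigvals: np.ndarray      # (m,) descending variances
    mean_scale: float        # mean centroid size of the training shapes

    @property
    def n_points(self) -> int:
        return self.mean_shape.shape[0]


def _kabsch_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation R minimising ||src @ R - dst|| (no reflection)."""
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _normalise_shape(pts: np.ndarray):
    c = pts.mean(axis=0)
    centred = pts - c
    s = np.linalg.norm(centred)
    if s <= 0:
        raise ValueError("zero-scale contour")
    return centred / s, c, s


def build_shape_model(contours, n_points: int = N_POINTS,
                      keep_variance: float = 0.95) -> ShapeModel:
    """Procrustes-align training contours and fit a PCA shape model."""
    shapes, scales = [], []
    for cont in contours:
        pts = resample_contour(np.asarray(cont, float), n_points)
        norm, _, s = _normalise_shape(pts)
        shapes.append(norm)
        scales.append(s)
    shapes = np.stack(shapes)
    ref = shapes[0]
    for _ in range(3):  # generalised Procrustes, few passes suffice
        aligned = np.stack([sh @ _kabsch_rotation(sh, ref) for sh in shapes])
        ref = aligned.mean(axis=0)
        ref /= np.linalg.norm(ref)
        shapes = aligned
    flat = shapes.reshape(len(shapes), -1)
    mean_flat = flat.mean(axis=0)
    dev = flat - mean_flat
    # population PCA via SVD
    u, sv, vt = np.linalg.svd(dev, full_matrices=False)
    var = sv ** 2 / len(shapes)
    if var.sum() <= 0:
        m = 0
    else:
        cum = np.cumsum(var) / var.sum()
        m = int(np.searchsorted(cum, keep_variance) + 1)
        m = min(m, len(var))
    return ShapeModel(
        mean_shape=mean_flat.reshape(-1, 2),
        components=vt[:m],
        eigvals=var[:m],
        mean_scale=float(np.mean(scales)),
    )


def shape_regularize(points: np.ndarray, model: ShapeModel,
                     n_sd: float = 3.0) -> np.ndarray:
    """Project a contour onto the shape model with clamped mode weights.

    The contour is similarity-aligned to the mean shape, its deviation is
    projected onto the kept PCA modes, coefficients are clamped to
    ``+/- n_sd * sqrt(eigenvalue)``, and the result is mapped back.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] != model.n_points:
        raise ValueError("contour point count does not match the shape model")
    norm, c, s = _normalise_shape(pts)
    rot = _kabsch_rotation(norm, model.mean_shape)
    aligned = norm @ rot
    z = aligned.reshape(-1) - model.mean_shape.reshape(-1)
    if model.components.shape[0]:
        b = model.components @ z
        lim = n_sd * np.sqrt(np.maximum(model.eigvals, 0.0))
        b = np.clip(b, -lim, lim)
        recon = model.mean_shape.reshape(-1) + model.components.T @ b
    else:
        recon = model.mean_shape.reshape(-1)
    back = recon.reshape(-1, 2) @ rot.T
    return back * s + c


# ---------------------------------------------------------------------------
# contour fitting
# ---------------------------------------------------------------------------

def fit_contour(img_or_maps, init_center, profile_model: ProfileModel,
                shape_model: ShapeModel, bank: FilterBank | None = None,
                P: int = N_CANDIDATES, max_iter: int = 20,
                tol: float = 0.5, vessel_sigma: float | None = None) -> DiscContour:
    """Fit the disc contour by iterated profile matching.

    Starting from the mean shape centred at ``init_center``, each iteration
    moves every point to the candidate offset (of ``P``, spaced 1 px along
    the normal) whose profile has minimum Mahalanobis distance to the
    trained distribution, then regularises with the shape model.  Stops when
    the mean displacement drops below ``tol`` px.
    """
    if isinstance(img_or_maps, RetinalImage):
        maps = gaussian_bank_maps(img_or_maps, bank, vessel_sigma=vessel_sigma)
    else:
        maps = np.asarray(img_or_maps, float)
    h, w = maps.shape[1:]
    L = profile_model.L
    half_p = (P - 1) // 2
    cx, cy = init_center
    pts = shape_model.mean_shape * shape_model.mean_scale + np.array([cx, cy])
    offsets = np.arange(-(L + half_p), L + half_p + 1, dtype=float)
    converged = False
    for _ in range(max_iter):
        normals = contour_normals(pts)
        ext = _sample_along_normals(maps, pts, normals, offsets)  # (N, M, W)
        best = np.zeros(pts.shape[0])
        for i in range(pts.shape[0]):
            wins = np.stack([
                ext[i, :, j : j + 2 * L + 1].reshape(-1) for j in range(P)
            ])
            d2 = profile_model.mahalanobis2(i, wins)
            best[i] = np.argmin(d2) - half_p
        moved = pts + best[:, None] * normals
        new_pts = shape_regularize(moved, shape_model)
        disp = np.linalg.norm(new_pts - pts, axis=1).mean()
        if (new_pts[:, 0].min() < -L or new_pts[:, 0].max() >= w + L
                or new_pts[:, 1].min() < -L or new_pts[:, 1].max() >= h + L):
            return DiscContour(points=pts, converged=False)
        pts = new_pts
        if disp < tol:
            converged = True
            break
    return DiscContour(points=pts, converged=converged)


# ---------------------------------------------------------------------------
# overlap metric
# ---------------------------------------------------------------------------

def dice(mask_a: np.ndarray, mask_b: np.ndarray,
         union_denominator: bool = False) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` in [0, 1].

    ``union_denominator=True`` uses ``2|A n B| / |A u B|`` instead (which
    can exceed 1); both-empty masks score 1 by convention.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = np.logical_and(a, b).sum()
    if union_denominator:
        denom = np.logical_or(a, b).sum()
    else:
        denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom
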