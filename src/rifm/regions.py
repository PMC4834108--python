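"""Disc-centred cropping and anatomical region division.

The optic-disc crop is split into five disjoint regions: the optic disc
itself (OD) and four quadrants bounded by the lines joining the disc centre
to the crop corners — superior (S, image top), inferior (I, bottom), and
nasal (N) / temporal (T), whose left/right assignment depends on the eye
side.  Eye side is decided from the intradisc vessel asymmetry: the nasal
half of the disc carries more vasculature, so a right-heavy vessel count
means a right eye (nasal on the right of the image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import RetinalImage, contour_to_mask

log = logging.getLogger(__name__)

OD, INFERIOR, SUPERIOR, NASAL, TEMPORAL = 1, 2, 3, 4, 5
REGION_NAMES = {OD: "OD", INFERIOR: "I", SUPERIOR: "S", NASAL: "N", TEMPORAL: "T"}
REGION_IDS = {v: k for k, v in REGION_NAMES.items()}


@dataclass
class RegionMask:
    """Per-pixel region labels over a disc-centred crop."""

    labels: np.ndarray  # H' x W' ints in {1..5}
    eye_side: str
    crop_offset: tuple  # (x0, y0) of the crop in source coordinates
    disc_center: tuple  # (x, y) in crop coordinates

    def mask(self, region) -> np.ndarray:
        rid = REGION_IDS[region] if isinstance(region, str) else region
        return self.labels == rid

    def region_masks(self) -> dict:
        return {name: self.labels == rid for rid, name in REGION_NAMES.items()}


def crop_disc(img: RetinalImage, center, crop_size: int):
    """Square crop of side ``crop_size`` centred on the disc centre.

    Out-of-frame area is mirror-padded.  Returns
    ``(cropped RetinalImage, (x0, y0) offset, padded flag)``; the offset maps
    crop coordinates back to source coordinates (which may be negative when
    padding occurred).
    """
    h, w = img.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"disc centre {center} lies outside the image")
    half = crop_size // 2
    x0, y0 = cx - half, cy - half
    x1, y1 = x0 + crop_size, y0 + crop_size
    pad_l = max(0, -x0)
    pad_t = max(0, -y0)
    pad_r = max(0, x1 - w)
    pad_b = max(0, y1 - h)
    padded = bool(pad_l or pad_t or pad_r or pad_b)
    px = img.pixels
    if padded:
        px = np.pad(px, ((pad_t, pad_b), (pad_l, pad_r), (0, 0)), mode="reflect")
    crop = px[y0 + pad_t : y1 + pad_t, x0 + pad_l : x1 + pad_l]
    return RetinalImage(crop, modality=img.modality), (x0, y0), padded


def determine_eye_side(vessel_mask: np.ndarray, disc_mask: np.ndarray,
                       center_col: int | None = None) -> str:
    """Eye side from intradisc vessel asymmetry (ties resolve to right)."""
    vessel_mask = np.asarray(vessel_mask, bool)
    disc_mask = np.asarray(disc_mask, bool)
    if vessel_mask.shape != disc_mask.shape:
        raise ValueError("mask shapes differ")
    if not disc_mask.any():
        raise ValueError("disc mask is empty")
    if center_col is None:
        center_col = int(round(np.nonzero(disc_mask)[1].mean()))
    intra = vessel_mask & disc_mask
    if not intra.any():
        log.warning("no vessel pixels inside the disc; defaulting to right eye")
        return "right"
    cols = np.nonzero(intra)[1]
    left = int((cols < center_col).sum())
    right = int((cols > center_col).sum())
    if right == left:
        log.warning("intradisc vessel tie; defaulting to right eye")
        return "right"
    return "right" if right > left else "left"


def build_region_mask(crop_shape, disc_contour: np.ndarray, eye_side: str,
                      center=None, crop_offset=(0, 0)) -> RegionMask:
    """Label every crop pixel as OD or one of the I/S/N/T quadrants.

    Quadrants are bounded by the lines from the (re-centred) disc centre to
    the four crop corners; pixels inside the disc contour override their
    quadrant label with OD.
    """
    h, w = crop_shape
    contour = np.asarray(disc_contour, float)
    if (contour[:, 0].min() < 0 or contour[:, 0].max() >= w
            or contour[:, 1].min() < 0 or contour[:, 1].max() >= h):
        raise ValueError("disc contour must lie inside the crop")
    if eye_side not in ("left", "right"):
        raise ValueError("eye_side must be 'left' or 'right'")
    if center is None:
        center = contour.mean(axis=0)
    cx, cy = float(center[0]), float(center[1])

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ang = np.arctan2(yy - cy, xx - cx)  # y-down: +angle toward image bottom
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )
    cang = np.arctan2(corners[:, 1] - cy, corners[:, 0] - cx)
    a_tl, a_tr, a_br, a_bl = cang  # top-left, top-right, bottom-right, bottom-left

    def between(a, lo, hi):
        # is angle a in the half-open interval [lo, hi), wrapping at pi;
        # half-open keeps the four boundary lines evenly distributed
        return np.mod(a - lo, 2 * np.pi) < np.mod(hi - lo, 2 * np.pi)

    labels = np.empty((h, w), dtype=np.int8)
    top = between(ang, a_tl, a_tr)        # superior: image top
    right_q = between(ang, a_tr, a_br)    # right side quadrant
    bottom = between(ang, a_br, a_bl)     # inferior
    left_q = ~(top | right_q | bottom)
    labels[top] = SUPERIOR
    labels[bottom] = INFERIOR
    if eye_side == "right":
        labels[right_q] = NASAL
        labels[left_q] = TEMPORAL
    else:
        labels[right_q] = TEMPORAL
        labels[left_q] = NASAL
    labels[contour_to_mask(contour, (h, w))] = OD
    return RegionMask(labels=labels, eye_side=eye_side,
                      crop_offset=tuple(crop_offset), disc_center=(cx, cy))
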