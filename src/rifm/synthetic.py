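"""Synthetic optic-disc-centred retinal images with full ground truth.

The generator emulates, at desk scale, the anatomy the pipeline keys on:

* a bright elliptical optic disc containing a brighter cup whose vertical
  cup-to-disc ratio (CDR) is controllable — the geometric glaucoma signal;
* dark vessel arcades entering the disc from above and below and bending
  toward the nasal side, which drives the eye-side decision;
* an optional peripapillary-atrophy (PPA) crescent: a bright, speckled
  (high-frequency) texture adjacent to the inferior/temporal disc border;
* a smooth illumination gradient and additive pixel noise.

All randomness flows from one seed; every rendered quantity is emitted as
ground truth so each downstream stage can be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .io import (
    RetinalImage,
    contour_to_mask,
    save_image,
    write_contour_csv,
    write_mask,
)

#: vertical CDR at or above which the single-eye generator labels glaucoma
CDR_CLASS_THRESHOLD = 0.55

_MAX_VESSEL_WIDTH = {"fundus": 50, "slo": 12}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic eye (pixel units unless noted)."""

    image_size: int = 192
    disc_center: tuple = (96.0, 96.0)  # (x, y)
    disc_rx: float = 24.0
    disc_ry: float = 26.0
    cdr: float = 0.35  # vertical cup-to-disc ratio, dimensionless
    n_vessels: int = 2  # arcs per (superior, inferior) arcade
    vessel_width: float = 4.0
    vessel_contrast: float = 0.35
    ppa: bool = False
    ppa_extent_deg: float = 110.0  # angular extent of the crescent
    illumination_amplitude: float = 0.10
    noise_sd: float = 0.02
    eye_side: str = "right"
    modality: str = "fundus"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.cdr < 1.0:
            raise ValueError(f"CDR must be in (0,1), got {self.cdr}")
        r = max(self.disc_rx, self.disc_ry)
        diam = 2.0 * r
        cx, cy = self.disc_center
        n = self.image_size
        # the 2x-diameter crop centred on the disc must fit in the frame
        if not (diam <= cx <= n - diam and diam <= cy <= n - diam):
            raise ValueError(
                "disc does not fit with a one-diameter margin "
                f"(centre {self.disc_center}, radius {r}, size {n})"
            )
        if self.vessel_width > _MAX_VESSEL_WIDTH[self.modality]:
            raise ValueError(
                f"vessel width {self.vessel_width} exceeds the "
                f"{self.modality} maximum {_MAX_VESSEL_WIDTH[self.modality]}"
            )
        if self.eye_side not in ("left", "right"):
            raise ValueError(f"eye side must be left/right, got {self.eye_side}")


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered eye."""

    disc_contour: np.ndarray  # (N, 2) (x, y)
    cup_contour: np.ndarray
    disc_center: tuple
    vessel_mask: np.ndarray
    eye_side: str
    label: str  # "normal" | "glaucoma"
    cdr: float

    def disc_mask(self, shape) -> np.ndarray:
        return contour_to_mask(self.disc_contour, shape)

    def cup_mask(self, shape) -> np.ndarray:
        return contour_to_mask(self.cup_contour, shape)


def _ellipse_contour(cx, cy, rx, ry, n_points=64) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _soft_ellipse(xx, yy, cx, cy, rx, ry, edge=0.06):
    """1 inside the ellipse, 0 outside, smooth sigmoid edge."""
    e = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    return 1.0 / (1.0 + np.exp((e - 1.0) / edge))


def _bezier(p0, p1, p2, n=400):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _stamp_curves(canvas, curves, width):
    h, w = canvas.shape
    for pts in curves:
        xi = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        yi = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        canvas[yi, xi] = True
    r = max(int(round(width / 2)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return binary_dilation(canvas, structure=xx ** 2 + yy ** 2 <= r ** 2)


def _vessel_curves(spec: SyntheticSpec, rng) -> list:
    """Central trunk plus arcades, entering the disc from top and bottom
    and bending toward the nasal side."""
    cx, cy = spec.disc_center
    rx, ry = spec.disc_rx, spec.disc_ry
    nasal = 1.0 if spec.eye_side == "right" else -1.0
    curves = []
    for vertical in (-1.0, 1.0):  # superior (-y) and inferior (+y) arcades
        jx = rng.uniform(-0.08, 0.08) * rx
        # near-vertical trunk crossing the disc slightly nasal of centre
        # (the central retinal vessels emerge at the disc centre)
        exit_pt = np.array([cx + nasal * 0.3 * rx + jx, cy + vertical * 1.5 * ry])
        p0 = np.array([cx + nasal * 0.15 * rx + jx, cy + vertical * 0.1 * ry])
        p1 = np.array([cx + nasal * 0.25 * rx + jx, cy + vertical * 0.8 * ry])
        curves.append(_bezier(p0, p1, exit_pt))
        for k in range(spec.n_vessels):
            # arcades fan out nasally after leaving the disc
            p1 = np.array(
                [cx + nasal * (0.5 + 0.4 * k) * rx, cy + vertical * (2.6 + 0.5 * k) * ry]
            )
            p2 = np.array(
                [cx + nasal * (3.0 + 1.0 * k) * rx, cy + vertical * (0.9 + 0.8 * k) * ry]
            )
            curves.append(_bezier(exit_pt, p1, p2))
        # short temporal twig keeps some signal on the temporal side
        p0 = np.array([cx + nasal * 0.1 * rx, cy + vertical * 0.35 * ry])
        p2 = np.array([cx - nasal * 1.8 * rx, cy + vertical * 1.6 * ry])
        p1 = 0.5 * (p0 + p2) + np.array([0.0, vertical * 0.6 * ry])
        curves.append(_bezier(p0, p1, p2))
    return curves


def _ppa_crescent(xx, yy, spec: SyntheticSpec):
    """Bright textured crescent hugging the inferior/temporal disc border."""
    cx, cy = spec.disc_center
    e = np.sqrt(((xx - cx) / spec.disc_rx) ** 2 + ((yy - cy) / spec.disc_ry) ** 2)
    band = np.exp(-(((e - 1.28) / 0.18) ** 2))
    temporal = -1.0 if spec.eye_side == "right" else 1.0
    # sector centred between inferior (+y) and temporal directions
    centre_ang = np.arctan2(1.0, temporal)  # y-down convention
    ang = np.arctan2(yy - cy, xx - cx)
    dang = np.angle(np.exp(1j * (ang - centre_ang)))
    half = np.deg2rad(spec.ppa_extent_deg) / 2.0
    sector = np.cos(np.clip(dang / half, -1.0, 1.0) * np.pi / 2) ** 2
    sector[np.abs(dang) > half] = 0.0
    return band * sector


def generate_eye(spec: SyntheticSpec) -> tuple[RetinalImage, GroundTruth]:
    """Render one synthetic eye. Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx, cy = spec.disc_center

    # background with a smooth horizontal illumination ramp
    structure = 0.28 + spec.illumination_amplitude * (xx / n - 0.5) * 2.0

    disc = _soft_ellipse(xx, yy, cx, cy, spec.disc_rx, spec.disc_ry)
    cup_rx = spec.cdr * spec.disc_rx * 0.92
    cup_ry = spec.cdr * spec.disc_ry
    cup = _soft_ellipse(xx, yy, cx, cy, cup_rx, cup_ry, edge=0.10)
    structure = structure + 0.40 * disc + 0.18 * cup

    if spec.ppa:
        crescent = _ppa_crescent(xx, yy, spec)
        speckle = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), 0.8)
        structure = structure + crescent * (0.16 + 0.10 * speckle)

    # vessels: dark curvilinear structures with a Gaussian cross-profile
    vessel_mask = _stamp_curves(
        np.zeros((n, n), bool), _vessel_curves(spec, rng), spec.vessel_width
    )
    vessel_soft = gaussian_filter(vessel_mask.astype(float), spec.vessel_width / 3.0)
    vessel_soft /= max(vessel_soft.max(), 1e-12)

    red = 0.05 + 0.95 * structure - 0.8 * spec.vessel_contrast * vessel_soft
    green = 0.85 * structure - spec.vessel_contrast * vessel_soft
    blue = 0.30 * structure if spec.modality == "fundus" else np.zeros((n, n))

    px = np.stack([red, green, blue], axis=-1)
    if spec.noise_sd > 0:
        px = px + rng.normal(0.0, spec.noise_sd, px.shape)
    px = np.clip(px, 0.0, 1.0)
    if spec.modality == "slo":
        px[:, :, 2] = 0.0

    label = "glaucoma" if (spec.cdr >= CDR_CLASS_THRESHOLD or spec.ppa) else "normal"
    gt = GroundTruth(
        disc_contour=_ellipse_contour(cx, cy, spec.disc_rx, spec.disc_ry),
        cup_contour=_ellipse_contour(cx, cy, cup_rx, cup_ry),
        disc_center=(cx, cy),
        vessel_mask=vessel_mask,
        eye_side=spec.eye_side,
        label=label,
        cdr=spec.cdr,
    )
    return RetinalImage(px, modality=spec.modality), gt


# ---------------------------------------------------------------------------
# dataset-level sampling
# ---------------------------------------------------------------------------

#: class-conditional parameter distributions (study conditions)
NORMAL_CDR_RANGE = (0.2, 0.5)
GLAUCOMA_CDR_RANGE = (0.6, 0.9)
PPA_PROB = {"normal": 0.1, "glaucoma": 0.7}


def sample_specs(
    n_normal: int,
    n_glaucoma: int,
    modality: str = "fundus",
    seed: int = 0,
    **overrides,
) -> list[tuple[SyntheticSpec, str]]:
    """Draw per-eye specs from the class-conditional distributions."""
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(
        n_normal + n_glaucoma
    ) % (2 ** 31)
    out = []
    labels = ["normal"] * n_normal + ["glaucoma"] * n_glaucoma
    for i, label in enumerate(labels):
        lo, hi = NORMAL_CDR_RANGE if label == "normal" else GLAUCOMA_CDR_RANGE
        rx = rng.uniform(22.0, 27.0)
        size = overrides.get("image_size", 192)
        lo_c = 2.2 * rx
        spec = SyntheticSpec(
            disc_center=(
                rng.uniform(lo_c, size - lo_c),
                rng.uniform(lo_c, size - lo_c),
            ),
            disc_rx=rx,
            disc_ry=rx * rng.uniform(1.02, 1.12),
            cdr=rng.uniform(lo, hi),
            ppa=bool(rng.random() < PPA_PROB[label]),
            eye_side="right" if rng.random() < 0.5 else "left",
            modality=modality,
            seed=int(child_seeds[i]),
        )
        spec = replace(spec, **{k: v for k, v in overrides.items() if k != "image_size"})
        if "image_size" in overrides:
            spec = replace(spec, image_size=overrides["image_size"])
        out.append((spec, label))
    return out


def generate_dataset(
    n_normal: int,
    n_glaucoma: int,
    modality: str = "fundus",
    seed: int = 0,
    out_dir=None,
    **overrides,
):
    """Generate a labelled synthetic dataset.

    Returns ``(manifest, eyes)`` where ``eyes`` is a list of
    ``(RetinalImage, GroundTruth)``.  When ``out_dir`` is given, images,
    contours, vessel masks and ``manifest.csv`` are also written to disk.
    """
    specs = sample_specs(n_normal, n_glaucoma, modality, seed, **overrides)
    eyes = []
    rows = []
    for i, (spec, label) in enumerate(specs):
        img, gt = generate_eye(spec)
        gt.label = label  # class is assigned by construction at dataset level
        eyes.append((img, gt))
        rows.append(
            {
                "path": f"img_{i:03d}.png",
                "modality": modality,
                "label": label,
                "annotation_path": f"disc_{i:03d}.csv",
                "cup_path": f"cup_{i:03d}.csv",
                "vessel_path": f"vessels_{i:03d}.png",
                "cdr": gt.cdr,
                "eye_side": gt.eye_side,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, (img, gt) in enumerate(eyes):
            save_image(img, out_dir / f"img_{i:03d}.png")
            write_contour_csv(gt.disc_contour, out_dir / f"disc_{i:03d}.csv")
            write_contour_csv(gt.cup_contour, out_dir / f"cup_{i:03d}.csv")
            write_mask(gt.vessel_mask, out_dir / f"vessels_{i:03d}.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, eyes
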