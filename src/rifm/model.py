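"""End-to-end screening model: localise, segment, divide, extract, select,
classify — with a statsmodels-style Model / Results interface.

``GlaucomaScreeningModel`` is built from labelled eyes (images plus disc
annotations for the training set); ``fit()`` runs the full pipeline and
returns a ``ScreeningResults`` carrying the fitted artefacts (profile and
shape models, normalisation statistics, selected features, classifier),
per-stage diagnostics (localisation error, segmentation Dice) and the
held-out classification metrics, with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classify, features, regions, segmentation, selection
from .evaluate import ConfusionCounts, acc_sn_sp
from .io import RetinalImage
from .localization import LocalizationConfig, build_feature_maps, localize_disc
from .segmentation import (
    FilterBank,
    build_shape_model,
    dice,
    fit_contour,
    resample_contour,
    sample_normal_profiles,
    build_profile_model,
    segment_vessels,
    gaussian_bank_maps,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    localization: LocalizationConfig
    crop_size: int
    bank: FilterBank = field(default_factory=FilterBank)
    vessel_sigma: float | None = None
    profile_L: int = segmentation.PROFILE_L
    n_candidates: int = segmentation.N_CANDIDATES
    n_contour_points: int = segmentation.N_POINTS
    alpha: float = 0.05
    criterion: str = "auc"
    selection_k: int = 5
    max_features: int = 30
    classifier: str = "twinsvm"
    classifier_params: dict = field(default_factory=dict)
    erus_B: int = 11
    cv_k: int = 5
    global_features: bool = False
    seed: int = 0

    @classmethod
    def fundus(cls, **kw) -> "PipelineConfig":
        loc = LocalizationConfig.fundus()
        return cls(localization=loc, crop_size=2 * loc.d_max, **kw)

    @classmethod
    def slo(cls, **kw) -> "PipelineConfig":
        loc = LocalizationConfig.slo()
        return cls(localization=loc, crop_size=2 * loc.d_max,
                   vessel_sigma=1.5, **kw)

    @classmethod
    def synthetic(cls, disc_diameter: float = 50.0, **kw) -> "PipelineConfig":
        """Desk-scale configuration matched to the synthetic generator's
        geometry (smaller profile model, vessel-scale matched filter)."""
        loc = LocalizationConfig.for_disc_diameter(disc_diameter, sigma=2.0,
                                                   w_max=10)
        kw.setdefault("vessel_sigma", 2.0)
        kw.setdefault("profile_L", 8)
        kw.setdefault("n_candidates", 13)
        return cls(localization=loc, crop_size=2 * loc.d_max, **kw)


@dataclass
class EyeState:
    """Per-eye artefacts accumulated along the pipeline."""

    image: RetinalImage
    label: str
    annotation: np.ndarray | None = None  # disc contour ground truth
    true_center: tuple | None = None
    maps: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None
    location: tuple | None = None
    contour: segmentation.DiscContour | None = None
    eye_side: str | None = None
    dice: float | None = None
    loc_error: float | None = None


class GlaucomaScreeningModel:
    """Normal-vs-glaucoma screening from optic-disc-centred images.

    Parameters
    ----------
    train_eyes, test_eyes : sequences of (RetinalImage, label) or
        (RetinalImage, label, disc_contour).  Training eyes must carry disc
        annotations (they train the profile and shape models); test
        annotations, when given, are used for Dice diagnostics only.
    config : PipelineConfig
    """

    def __init__(self, train_eyes, test_eyes=(), config: PipelineConfig | None = None):
        self.config = config or PipelineConfig.fundus()
        self.train = [self._coerce(e) for e in train_eyes]
        self.test = [self._coerce(e) for e in test_eyes]
        labels = {e.label for e in self.train}
        if len(labels) != 2:
            raise ValueError(
                f"training set must contain both classes, got {sorted(labels)}"
            )

    @staticmethod
    def _coerce(entry) -> EyeState:
        if isinstance(entry, EyeState):
            return entry
        img, label, *rest = entry
        ann = rest[0] if rest else None
        center = None
        if ann is not None:
            ann = np.asarray(ann, float)
            center = tuple(ann.mean(axis=0))
        return EyeState(image=img, label=label, annotation=ann,
                        true_center=center)

    @classmethod
    def from_synthetic(cls, eyes_train, eyes_test=(), config=None):
        """Build from ``(RetinalImage, GroundTruth)`` pairs."""

        def conv(eyes):
            return [(img, gt.label, gt.disc_contour) for img, gt in eyes]

        return cls(conv(eyes_train), conv(eyes_test),
                   config or PipelineConfig.synthetic())

    # -- pipeline stages ----------------------------------------------------

    def _prepare_eye(self, eye: EyeState) -> None:
        cfg = self.config
        fm = build_feature_maps(eye.image, cfg.localization)
        loc = localize_disc(fm, cfg.localization)
        eye.location = (loc.x, loc.y)
        eye.vessel_mask = segment_vessels(eye.image, sigma=cfg.vessel_sigma)
        eye.maps = gaussian_bank_maps(eye.image, cfg.bank,
                                      vessel_sigma=cfg.vessel_sigma)
        if eye.true_center is not None:
            eye.loc_error = float(np.hypot(loc.x - eye.true_center[0],
                                           loc.y - eye.true_center[1]))

    def _segment_eye(self, eye: EyeState) -> None:
        cfg = self.config
        eye.contour = fit_contour(
            eye.maps, eye.location, self.profile_model_, self.shape_model_,
            P=cfg.n_candidates,
        )
        if eye.annotation is not None:
            shape = eye.image.shape
            eye.dice = dice(eye.contour.mask(shape),
                            segmentation.DiscContour(eye.annotation).mask(shape))

    def _regionize(self, eye: EyeState):
        cfg = self.config
        shape = eye.image.shape
        disc_mask = eye.contour.mask(shape)
        cx, cy = eye.contour.centroid
        eye.eye_side = regions.determine_eye_side(
            eye.vessel_mask, disc_mask, center_col=int(round(cx))
        )
        crop, offset, _ = regions.crop_disc(eye.image, (cx, cy), cfg.crop_size)
        local = eye.contour.points - np.array(offset, float)
        local[:, 0] = np.clip(local[:, 0], 0, cfg.crop_size - 1)
        local[:, 1] = np.clip(local[:, 1], 0, cfg.crop_size - 1)
        rmask = regions.build_region_mask(
            crop.shape, local, eye.eye_side,
            center=(cx - offset[0], cy - offset[1]),
        )
        return crop, rmask

    def fit(self) -> "ScreeningResults":
        cfg = self.config
        for eye in self.train + self.test:
            self._prepare_eye(eye)

        # segmentation models come from the annotated training eyes
        annotated = [e for e in self.train if e.annotation is not None]
        if len(annotated) < 5:
            raise ValueError("need >= 5 annotated training eyes")
        profiles = []
        for e in annotated:
            pts = resample_contour(e.annotation, cfg.n_contour_points)
            profiles.append(sample_normal_profiles(e.maps, pts, cfg.profile_L))
        self.profile_model_ = build_profile_model(
            np.stack(profiles), cfg.profile_L, cfg.bank.n_maps
        )
        self.shape_model_ = build_shape_model(
            [e.annotation for e in annotated], cfg.n_contour_points
        )

        samples = []
        for eye in self.train + self.test:
            self._segment_eye(eye)
            samples.append(self._regionize(eye))

        fm = features.assemble_feature_matrix(
            samples, global_mode=cfg.global_features, bank=cfg.bank
        )
        labels = np.array([e.label for e in self.train + self.test])
        n_train = len(self.train)
        train_rows = np.arange(n_train)
        fm_z, self.zstats_ = features.zscore_normalize(fm, train_rows)

        sig = selection.significance_filter(
            fm_z.values[train_rows], labels[train_rows], alpha=cfg.alpha
        )
        sel = selection.wrapper_select(
            fm_z.values[train_rows][:, sig], labels[train_rows],
            criterion=cfg.criterion, k=cfg.selection_k, seed=cfg.seed,
            max_features=cfg.max_features,
        )
        chosen = sig[np.asarray(sel.selected, int)]
        self.selected_columns_ = chosen
        x_sel = fm_z.values[:, chosen]

        def factory():
            base = lambda: classify.make_classifier(cfg.classifier,
                                                    cfg.classifier_params)
            return classify.ERUSEnsemble(base, B=cfg.erus_B, seed=cfg.seed)

        cv = classify.cross_validate(
            x_sel[train_rows], labels[train_rows], factory,
            k=min(cfg.cv_k, n_train // 2), seed=cfg.seed,
            standardize=False, positive="glaucoma",
        )

        self.classifier_ = factory().fit(x_sel[train_rows], labels[train_rows])
        test_conf = None
        test_pred = None
        if self.test:
            test_pred = self.classifier_.predict(x_sel[n_train:])
            test_conf = classify.pooled_confusion(
                labels[n_train:], test_pred, positive="glaucoma"
            )
        return ScreeningResults(
            model=self,
            feature_matrix=fm,
            selection=sel,
            selected_meta=[fm_z.columns[i] for i in chosen],
            cv=cv,
            test_confusion=test_conf,
            test_predictions=test_pred,
            train_eyes=self.train,
            test_eyes=self.test,
        )

    def predict(self, img: RetinalImage) -> str:
        """Single-image deployment using the fitted artefacts."""
        if not hasattr(self, "classifier_"):
            raise RuntimeError("model is not fitted")
        eye = EyeState(image=img, label="?")
        self._prepare_eye(eye)
        self._segment_eye(eye)
        crop, rmask = self._regionize(eye)
        vals, meta = features.extract_sample(
            crop,
            {"whole": np.ones(crop.shape, bool)}
            if self.config.global_features else rmask.region_masks(),
            bank=self.config.bank,
        )
        fm = features.FeatureMatrix(vals[None, :], meta)
        z = features.apply_zscore(fm, self.zstats_)
        return str(self.classifier_.predict(z.values[:, self.selected_columns_])[0])


@dataclass
class ScreeningResults:
    """Fitted pipeline artefacts, diagnostics and held-out metrics."""

    model: GlaucomaScreeningModel
    feature_matrix: features.FeatureMatrix
    selection: selection.SelectionResult
    selected_meta: list
    cv: classify.CVResult
    test_confusion: dict | None
    test_predictions: np.ndarray | None
    train_eyes: list
    test_eyes: list

    @property
    def cv_accuracy(self) -> float:
        return float(np.mean(self.cv.fold_accuracies))

    @property
    def test_metrics(self) -> tuple | None:
        if self.test_confusion is None:
            return None
        c = self.test_confusion
        return acc_sn_sp(ConfusionCounts(c["TP"], c["FN"], c["TN"], c["FP"]))

    @property
    def test_accuracy(self) -> float | None:
        m = self.test_metrics
        return None if m is None else m[0] / 100.0

    def dice_scores(self, which: str = "test") -> list:
        eyes = self.test_eyes if which == "test" else self.train_eyes
        return [e.dice for e in eyes if e.dice is not None]

    def localization_errors(self, which: str = "both") -> list:
        eyes = {"train": self.train_eyes, "test": self.test_eyes}.get(
            which, self.train_eyes + self.test_eyes
        )
        return [e.loc_error for e in eyes if e.loc_error is not None]

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Regional image features screening model")
        add("=" * 46)
        add(f"training eyes: {len(self.train_eyes)}   "
            f"test eyes: {len(self.test_eyes)}")
        add(f"features extracted: {self.feature_matrix.n_features}")
        add(f"features selected ({self.selection.criterion}): "
            f"{len(self.selection.selected)}")
        if self.selection.trace:
            add(f"final wrapper criterion: {self.selection.trace[-1]:.3f}")
        locs = self.localization_errors()
        if locs:
            add(f"localisation error (px): mean {np.mean(locs):.1f}, "
                f"max {np.max(locs):.1f}")
        dtr = self.dice_scores("train")
        dte = self.dice_scores("test")
        if dtr:
            add(f"segmentation Dice (train): {np.mean(dtr):.3f}")
        if dte:
            add(f"segmentation Dice (test):  {np.mean(dte):.3f}")
        add(f"cross-validation accuracy: {100 * self.cv_accuracy:.1f}%")
        if self.test_confusion is not None:
            acc, sn, sp = self.test_metrics
            c = self.test_confusion
            add(f"test confusion: TP={c['TP']} FN={c['FN']} "
                f"TN={c['TN']} FP={c['FP']}")
            add(f"test accuracy {acc:.1f}%  sensitivity {sn:.1f}%  "
                f"specificity {sp:.1f}%")
        add("selected features:")
        for m in self.selected_meta:
            add(f"  {m.key}")
        return "\n".join(lines)
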