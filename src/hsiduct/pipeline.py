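"""Leave-one-patient-out training, classification and evaluation.

Pools ROI pixel spectra from the stained slides of every training patient,
fits a two-cluster K-means, maps clusters to tissue labels by majority
ground truth, classifies the held-out patient pixel by pixel, and scores
the result with a confusion matrix (cancer = positive class).  Also fits
one model per training patient to report per-patient training accuracy,
and renders red/blue detection overlays.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import imageio.v3 as iio

from . import kmeans
from .hypercube import Hypercube, Mask, band_image, flatten_pixels, nearest_band_index
from .phantom import LabeledCube, PhantomConfig, load_cohort
from .spectra import (
    ROISet,
    band_separation,
    pick_rois,
    region_spectrum,
    select_band,
)

__all__ = [
    "RunConfig",
    "LabeledModel",
    "Metrics",
    "ExperimentReport",
    "map_clusters_to_labels",
    "train_lopo",
    "classify_cube",
    "evaluate",
    "metrics_from_counts",
    "render_overlay",
    "run_experiment",
]

log = logging.getLogger("hsiduct")

FEATURE_MODES = ("full_spectrum", "single_band")


@dataclass
class RunConfig:
    """Everything one experiment needs: cohort parameters plus pipeline options."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    feature_mode: str = "full_spectrum"
    init_method: str = "farthest"
    held_out_patient: str | None = None
    reference_wavelength_nm: float = 550.0
    roi_side: int = 20
    n_regions: int = 4
    n_measurements: int = 10
    subsample_size: int = 25
    whole_slide: bool = False
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
        if self.init_method not in ("farthest", "random"):
            raise ValueError("init_method must be 'farthest' or 'random'")
        if self.roi_side < 1 or self.n_regions < 1 or self.n_measurements < 1:
            raise ValueError("roi_side, n_regions and n_measurements must be >= 1")

    def to_text(self) -> str:
        lines = [f"phantom.{k}={v}" for k, v in asdict(self.phantom).items()]
        for key, value in asdict(self).items():
            if key == "phantom":
                continue
            lines.append(f"{key}={value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        phantom_kwargs: dict = {}
        kwargs: dict = {}
        casts = {
            "feature_mode": str, "init_method": str, "held_out_patient": str,
            "reference_wavelength_nm": float, "roi_side": int, "n_regions": int,
            "n_measurements": int, "subsample_size": int,
            "whole_slide": lambda v: v.strip().lower() in ("1", "true", "yes"),
            "max_iter": int, "seed": int,
        }
        phantom_fields = PhantomConfig.__dataclass_fields__
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("phantom."):
                pkey = key.removeprefix("phantom.")
                if pkey in phantom_fields:
                    typ = phantom_fields[pkey].type
                    phantom_kwargs[pkey] = int(value) if typ == "int" else float(value)
            elif key in casts:
                if key == "held_out_patient" and value in ("", "None"):
                    continue
                kwargs[key] = casts[key](value)
        return cls(phantom=PhantomConfig(**phantom_kwargs), **kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def rng(self, stage: int) -> np.random.Generator:
        # independent, reproducible stream per pipeline stage
        return np.random.default_rng([self.seed, 104729, stage])


@dataclass
class LabeledModel:
    """A fitted cluster model plus the cluster -> tissue-label map."""

    model: kmeans.ClusterModel
    label_of_cluster: dict[int, int]
    feature_mode: str
    band_nm: float
    band_index: int
    training_patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.label_of_cluster) != set(range(self.model.c)):
            raise ValueError("label map must cover every cluster index")
        if self.model.c == 2 and set(self.label_of_cluster.values()) != {0, 1}:
            raise ValueError("with c = 2 the cluster labels must be {0, 1}")

    def label_points(self, points: np.ndarray) -> np.ndarray:
        assignment = kmeans.predict(self.model, points)
        lut = np.array([self.label_of_cluster[i] for i in range(self.model.c)])
        return lut[assignment.cluster_index]

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.model.centroids, dtype=np.float64).tobytes())
        h.update(json.dumps(self.label_of_cluster, sort_keys=True).encode())
        return h.hexdigest()


@dataclass
class Metrics:
    """Pixel confusion matrix with the standard derived rates (percent)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def tnr(self) -> float:
        return self.specificity

    @property
    def fpr(self) -> float:
        return 100.0 - self.tnr

    @property
    def fnr(self) -> float:
        return 100.0 - self.sensitivity

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "TNR": self.tnr, "FPR": self.fpr, "accuracy": self.accuracy,
        }


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion matrix")
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate(predicted: Mask, truth: Mask) -> Metrics:
    """Pixel-level confusion matrix; cancer (label 1) is the positive class."""
    if predicted.shape != truth.shape:
        raise ValueError(
            f"prediction shape {predicted.shape} != truth shape {truth.shape}"
        )
    p = predicted.labels.astype(bool)
    t = truth.labels.astype(bool)
    if t.size == 0:
        raise ValueError("empty masks")
    return Metrics(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _slide_features(
    cube: Hypercube, feature_mode: str, band_index: int
) -> np.ndarray:
    pm = flatten_pixels(cube)
    if feature_mode == "single_band":
        return pm.spectra[:, band_index : band_index + 1]
    return pm.spectra


def _roi_pixels(
    slide: LabeledCube,
    rois: ROISet,
    feature_mode: str,
    band_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all pixels of the ROI squares; labels come from the slide mask."""
    spectra, labels = [], []
    for region in rois.regions:
        rr, cc = region.pixel_indices()
        px = slide.cube.data[rr, cc, :]
        if feature_mode == "single_band":
            px = px[:, band_index : band_index + 1]
        spectra.append(px)
        labels.append(slide.mask.labels[rr, cc])
    return np.vstack(spectra), np.concatenate(labels).astype(np.int64)


def _stained_slides(cohort: list[LabeledCube], patient: str) -> dict[str, LabeledCube]:
    out = {
        lc.slide_class: lc
        for lc in cohort
        if lc.patient_id == patient and lc.staining == "stained"
    }
    if set(out) != {"normal", "dcis"}:
        raise ValueError(f"patient {patient} lacks stained normal/dcis slides")
    return out


def _patient_training_data(
    cohort: list[LabeledCube],
    patient: str,
    config: RunConfig,
    band_index: int,
    rng: np.random.Generator,
    rois_out: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Training pixels and labels from one patient's stained slides."""
    slides = _stained_slides(cohort, patient)
    if config.whole_slide:
        feats, labels = [], []
        for slide in slides.values():
            feats.append(_slide_features(slide.cube, config.feature_mode, band_index))
            labels.append(slide.mask.labels.ravel().astype(np.int64))
        return np.vstack(feats), np.concatenate(labels)
    feats, labels = [], []
    for slide_class, slide in sorted(slides.items()):
        target = slide.mask if slide_class == "dcis" else slide.cube
        rois = pick_rois(
            target, slide_class, n_regions=config.n_regions,
            side=config.roi_side, rng=rng,
        )
        if rois_out is not None:
            rois_out[(patient, slide_class)] = rois
        f, l = _roi_pixels(slide, rois, config.feature_mode, band_index)
        feats.append(f)
        labels.append(l)
    return np.vstack(feats), np.concatenate(labels)


# ---------------------------------------------------------------------------
# Cluster -> label mapping and LOPO training
# ---------------------------------------------------------------------------

def map_clusters_to_labels(
    model: kmeans.ClusterModel,
    points: np.ndarray,
    labels: np.ndarray,
    band_index: int,
    feature_mode: str = "full_spectrum",
    band_nm: float = 550.0,
    training_patients: list[str] | None = None,
) -> LabeledModel:
    """Give each cluster the majority ground-truth label of its members.

    An exact 50/50 tie labels as cancer the cluster whose centroid is
    darkest at the selected band (stained carcinoma is modeled darker).
    With c = 2, a degenerate majority vote that would give both clusters
    the same label falls back to the same darkness rule (warned).
    """
    labels = np.asarray(labels)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValueError("training labels must contain both classes")
    assignment = kmeans.predict(model, points)
    feat_band = 0 if feature_mode == "single_band" else band_index
    darkness_rank = np.argsort(model.centroids[:, feat_band], kind="stable")
    darkest = int(darkness_rank[0])

    label_of_cluster: dict[int, int] = {}
    for i in range(model.c):
        members = labels[assignment.cluster_index == i]
        if len(members) == 0:
            raise ValueError(f"cluster {i} has zero training members")
        n_cancer = int(np.count_nonzero(members == 1))
        if 2 * n_cancer == len(members):
            label_of_cluster[i] = 1 if i == darkest else 0
            log.info("cluster %d tied 50/50; darkness tie rule applied", i)
        else:
            label_of_cluster[i] = int(2 * n_cancer > len(members))
    if model.c == 2 and set(label_of_cluster.values()) != {0, 1}:
        warnings.warn(
            "majority vote gave both clusters the same label; "
            "falling back to darkness rule", stacklevel=2,
        )
        label_of_cluster = {i: int(i == darkest) for i in range(2)}
    return LabeledModel(
        model=model,
        label_of_cluster=label_of_cluster,
        feature_mode=feature_mode,
        band_nm=band_nm,
        band_index=band_index,
        training_patients=list(training_patients or []),
    )


def train_lopo(
    cohort: list[LabeledCube],
    held_out_patient: str,
    config: RunConfig,
    band_nm: float | None = None,
) -> tuple[LabeledModel, pd.DataFrame]:
    """Train on every patient except ``held_out_patient``.

    Returns the pooled two-cluster model (used for held-out prediction)
    plus a per-training-patient table of separate fits and their training
    accuracies.  The held-out patient's pixels never enter training.
    """
    patients = sorted({lc.patient_id for lc in cohort})
    if held_out_patient not in patients:
        raise ValueError(f"held-out patient '{held_out_patient}' not in cohort")
    training = [p for p in patients if p != held_out_patient]
    if not training:
        raise ValueError("cohort must contain at least 2 patients")
    train_cohort = [lc for lc in cohort if lc.patient_id != held_out_patient]

    wavelengths = train_cohort[0].cube.wavelengths
    band_nm = config.reference_wavelength_nm if band_nm is None else band_nm
    band_index = nearest_band_index(wavelengths, band_nm)

    rng_roi = config.rng(2)
    rng_fit = config.rng(3)
    feats_all, labels_all = [], []
    rows = []
    for patient in training:
        feats, labels = _patient_training_data(
            train_cohort, patient, config, band_index, rng_roi
        )
        feats_all.append(feats)
        labels_all.append(labels)
        # separate per-patient fit, scored on its own training pixels
        pmodel, ptrace = kmeans.fit(
            feats, 2, init_method=config.init_method, rng=rng_fit,
            max_iter=config.max_iter, wavelengths=wavelengths,
        )
        plabeled = map_clusters_to_labels(
            pmodel, feats, labels, band_index, config.feature_mode, band_nm, [patient]
        )
        acc = 100.0 * float(np.mean(plabeled.label_points(feats) == labels))
        rows.append(
            {
                "patient_id": patient,
                "n_pixels": len(feats),
                "training_accuracy": acc,
                "iterations": ptrace.iterations,
                "final_J": ptrace.objective[-1],
                "converged": ptrace.converged,
            }
        )
    points = np.vstack(feats_all)
    labels = np.concatenate(labels_all)
    model, trace = kmeans.fit(
        points, 2, init_method=config.init_method, rng=rng_fit,
        max_iter=config.max_iter, wavelengths=wavelengths,
    )
    log.info(
        "pooled K-means: %d pixels, %d iterations, J=%.4g, converged=%s",
        len(points), trace.iterations, trace.objective[-1], trace.converged,
    )
    labeled = map_clusters_to_labels(
        model, points, labels, band_index, config.feature_mode, band_nm, training
    )
    return labeled, pd.DataFrame(rows)


def classify_cube(labeled_model: LabeledModel, cube: Hypercube) -> Mask:
    """Per-pixel nearest-centroid prediction mapped to a binary cancer mask."""
    feats = _slide_features(cube, labeled_model.feature_mode, labeled_model.band_index)
    if feats.shape[1] != labeled_model.model.centroids.shape[1]:
        raise ValueError(
            f"cube features ({feats.shape[1]}) do not match model "
            f"({labeled_model.model.centroids.shape[1]})"
        )
    pred = labeled_model.label_points(feats)
    return Mask(labels=pred.reshape(cube.rows, cube.cols).astype(np.uint8))


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

def render_overlay(
    cube: Hypercube,
    predicted: Mask,
    rois: ROISet | None = None,
    band_nm: float = 550.0,
    path: str | None = None,
) -> np.ndarray:
    """Grayscale band image with cancer tinted red and normal tinted blue.

    Optional ROI squares are outlined in bright blue.  Returns the RGB
    uint8 image; writes a PNG when ``path`` is given.
    """
    band, _ = band_image(cube, band_nm)
    gray = np.clip(band, 0.0, 1.0)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    cancer = predicted.labels.astype(bool)
    red = np.array([1.0, 0.1, 0.1])
    blue = np.array([0.2, 0.2, 1.0])
    alpha = 0.35
    rgb[cancer] = (1 - alpha) * rgb[cancer] + alpha * red
    rgb[~cancer] = (1 - alpha) * rgb[~cancer] + alpha * blue
    if rois is not None:
        for region in rois.regions:
            r0, c0, s = region.row0, region.col0, region.side
            r1, c1 = r0 + s - 1, c0 + s - 1
            rgb[r0, c0 : c1 + 1] = rgb[r1, c0 : c1 + 1] = [0.0, 0.3, 1.0]
            rgb[r0 : r1 + 1, c0] = rgb[r0 : r1 + 1, c1] = [0.0, 0.3, 1.0]
    img = (rgb * 255).round().astype(np.uint8)
    if path is not None:
        iio.imwrite(path, img)
    return img


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    held_out_patient: str
    selected_band_nm: float
    selected_band_index: int
    pixel_metrics: Metrics
    region_metrics: Metrics | None
    per_patient: pd.DataFrame
    separation_score: np.ndarray
    wavelengths: np.ndarray
    config_text: str
    config_digest: str
    model_digest: str
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "held_out_patient": self.held_out_patient,
            "selected_band_nm": self.selected_band_nm,
            "selected_band_index": self.selected_band_index,
            "pixel_metrics": self.pixel_metrics.as_dict(),
            "region_metrics": (
                self.region_metrics.as_dict() if self.region_metrics else None
            ),
            "per_patient": self.per_patient.to_dict(orient="records"),
            "separation_score": [float(s) for s in self.separation_score],
            "wavelengths": [float(w) for w in self.wavelengths],
            "config_digest": self.config_digest,
            "model_digest": self.model_digest,
            "seed": self.seed,
        }


def select_band_for_cohort(
    cohort: list[LabeledCube],
    config: RunConfig,
    patients: list[str] | None = None,
):
    """Fig-6-style protocol: ROIs + repeated measurements on every stained
    slide, pooled into one per-band separation curve.  Returns the
    BandSeparation object."""
    if patients is None:
        patients = sorted({lc.patient_id for lc in cohort})
    rng = config.rng(1)
    cancer_summaries, normal_summaries = [], []
    for patient in patients:
        slides = _stained_slides(cohort, patient)
        for slide_class, slide in sorted(slides.items()):
            target = slide.mask if slide_class == "dcis" else slide.cube
            rois = pick_rois(
                target, slide_class, n_regions=config.n_regions,
                side=config.roi_side, rng=rng,
            )
            bucket = cancer_summaries if slide_class == "dcis" else normal_summaries
            for region in rois.regions:
                bucket.append(
                    region_spectrum(
                        slide.cube, region,
                        n_measurements=config.n_measurements,
                        subsample_size=config.subsample_size, rng=rng,
                    )
                )
    return band_separation(cancer_summaries, normal_summaries)


def run_experiment(
    cohort: list[LabeledCube] | str,
    config: RunConfig,
    out_dir: str | None = None,
) -> ExperimentReport:
    """Band selection -> LOPO training -> held-out classification -> metrics.

    ``cohort`` is either a loaded list of LabeledCubes or a cohort
    directory with a manifest.  Writes report.json, metrics.tsv,
    per_patient_accuracy.tsv, centroids.tsv, separation.tsv and overlay
    PNGs when ``out_dir`` is given.
    """
    try:
        if isinstance(cohort, str):
            cohort = load_cohort(cohort)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: load-cohort] {exc}") from exc

    patients = sorted({lc.patient_id for lc in cohort})
    held_out = config.held_out_patient or patients[-1]
    training = [p for p in patients if p != held_out]

    try:
        separation = select_band_for_cohort(cohort, config, patients=training)
        band_nm = select_band(separation)
        log.info("selected band: %.1f nm", band_nm)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: select-band] {exc}") from exc

    try:
        labeled, per_patient = train_lopo(cohort, held_out, config, band_nm=band_nm)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: train] {exc}") from exc

    try:
        held_slides = _stained_slides(cohort, held_out)
        tp = fp = tn = fn = 0
        predictions: dict[str, Mask] = {}
        for slide_class, slide in sorted(held_slides.items()):
            pred = classify_cube(labeled, slide.cube)
            predictions[slide_class] = pred
            m = evaluate(pred, slide.mask)
            tp, fp, tn, fn = tp + m.tp, fp + m.fp, tn + m.tn, fn + m.fn
        pixel_metrics = metrics_from_counts(tp, fp, tn, fn)

        # region-level comparison: majority vote inside fresh ROI squares
        rng_eval = config.rng(4)
        r_tp = r_fp = r_tn = r_fn = 0
        for slide_class, slide in sorted(held_slides.items()):
            target = slide.mask if slide_class == "dcis" else slide.cube
            rois = pick_rois(
                target, slide_class, n_regions=config.n_regions,
                side=config.roi_side, rng=rng_eval,
            )
            for region in rois.regions:
                rr, cc = region.pixel_indices()
                vote = int(predictions[slide_class].labels[rr, cc].mean() >= 0.5)
                true = int(slide.mask.labels[rr, cc].mean() >= 0.5)
                r_tp += vote and true
                r_fp += vote and not true
                r_tn += (not vote) and (not true)
                r_fn += (not vote) and true
        region_metrics = (
            Metrics(tp=r_tp, fp=r_fp, tn=r_tn, fn=r_fn)
            if (r_tp + r_fp + r_tn + r_fn) else None
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: classify-evaluate] {exc}") from exc

    report = ExperimentReport(
        held_out_patient=held_out,
        selected_band_nm=band_nm,
        selected_band_index=int(separation.best_band_index),
        pixel_metrics=pixel_metrics,
        region_metrics=region_metrics,
        per_patient=per_patient,
        separation_score=separation.score,
        wavelengths=separation.wavelengths,
        config_text=config.to_text(),
        config_digest=config.digest(),
        model_digest=labeled.digest(),
        seed=config.seed,
    )

    if out_dir is not None:
        try:
            os.makedirs(out_dir, exist_ok=True)
            with open(os.path.join(out_dir, "report.json"), "w") as fh:
                json.dump(report.to_json_dict(), fh, indent=2)
            pd.DataFrame([pixel_metrics.as_dict()]).to_csv(
                os.path.join(out_dir, "metrics.tsv"), sep="\t", index=False
            )
            per_patient.to_csv(
                os.path.join(out_dir, "per_patient_accuracy.tsv"), sep="\t", index=False
            )
            cent = pd.DataFrame(
                labeled.model.centroids,
                columns=(
                    [f"{w:.6g}" for w in labeled.model.wavelengths]
                    if labeled.model.wavelengths is not None
                    and labeled.model.centroids.shape[1]
                    == len(labeled.model.wavelengths)
                    else [f"f{i}" for i in range(labeled.model.centroids.shape[1])]
                ),
            )
            cent.insert(0, "label", [labeled.label_of_cluster[i] for i in range(labeled.model.c)])
            cent.to_csv(os.path.join(out_dir, "centroids.tsv"), sep="\t", index=False)
            pd.DataFrame(
                {"wavelength_nm": separation.wavelengths, "score": separation.score}
            ).to_csv(os.path.join(out_dir, "separation.tsv"), sep="\t", index=False)
            for slide_class, pred in predictions.items():
                render_overlay(
                    held_slides[slide_class].cube, pred, band_nm=band_nm,
                    path=os.path.join(out_dir, f"overlay_{held_out}_{slide_class}.png"),
                )
            with open(os.path.join(out_dir, "config.txt"), "w") as fh:
                fh.write(config.to_text())
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[stage: write-report] {exc}") from exc
    return report
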