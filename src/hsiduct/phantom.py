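"""Synthetic hyperspectral phantom cohorts of normal-duct and DCIS tissue.

Generates labeled patient cohorts — {normal, dcis} x {stained, unstained}
reflectance cubes with ground-truth masks — whose statistical structure
matches what the downstream analysis assumes: smooth class endmember
spectra whose stained-pair separation peaks at the band nearest 550 nm,
one multiplicative gain and one linear spectral tilt per patient, i.i.d.
Gaussian pixel noise per band (clipped to [0, 1]), duct-like ring texture
on non-cancer tissue and irregular elliptical carcinoma blobs.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .hypercube import Hypercube, Mask, write_envi, write_mask_pgm, read_envi, read_mask

__all__ = [
    "SpectralClassModel",
    "PhantomConfig",
    "LabeledCube",
    "default_spectral_model",
    "generate_mask",
    "generate_patient",
    "iter_cohort",
    "generate_cohort",
    "load_cohort",
]

TISSUE_CLASSES = ("normal", "cancer")
STAININGS = ("stained", "unstained")
SLIDE_CLASSES = ("normal", "dcis")


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


@dataclass
class SpectralClassModel:
    """Class endmember spectra plus the noise / patient-variation model.

    ``endmembers`` maps ``(tissue_class, staining)`` to a mean reflectance
    spectrum on the sensor wavelength grid.  At construction the model
    asserts its own calibration: for the stained pair the standardized
    |normal - cancer| difference must peak at the band nearest 550 nm, and
    the stained separation there must exceed the unstained one.
    """

    wavelengths: np.ndarray
    endmembers: dict[tuple[str, str], np.ndarray]
    pixel_noise_sd: float = 0.02
    patient_gain_sd: float = 0.03
    patient_tilt_sd: float = 3e-4  # per nm
    reference_wavelength_nm: float = 550.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for key in ((t, s) for t in TISSUE_CLASSES for s in STAININGS):
            if key not in self.endmembers:
                raise ValueError(f"endmember for {key} missing")
            em = np.asarray(self.endmembers[key], dtype=float)
            if em.shape != self.wavelengths.shape:
                raise ValueError(f"endmember {key} not on the sensor grid")
            if not (np.all(em > 0.0) and np.all(em < 1.0)):
                raise ValueError(f"endmember {key} must lie strictly in (0, 1)")
            self.endmembers[key] = em
        if self.pixel_noise_sd < 0 or self.patient_gain_sd < 0 or self.patient_tilt_sd < 0:
            raise ValueError("noise/variation SDs must be non-negative")

        ref_band = int(np.argmin(np.abs(self.wavelengths - self.reference_wavelength_nm)))
        sep = {s: self._standardized_separation(s) for s in STAININGS}
        if int(np.argmax(sep["stained"])) != ref_band:
            raise ValueError(
                "stained-pair separation must peak at the band nearest "
                f"{self.reference_wavelength_nm} nm (band {ref_band}), "
                f"peaks at band {int(np.argmax(sep['stained']))}"
            )
        if not sep["stained"][ref_band] > sep["unstained"][ref_band]:
            raise ValueError("stained separation must exceed unstained at the reference band")

    def _standardized_separation(self, staining: str) -> np.ndarray:
        diff = np.abs(
            self.endmembers[("normal", staining)] - self.endmembers[("cancer", staining)]
        )
        return diff / max(self.pixel_noise_sd, 1e-9)

    def endmember(self, tissue_class: str, staining: str) -> np.ndarray:
        return self.endmembers[(tissue_class, staining)]


def default_spectral_model(
    wavelengths: np.ndarray | None = None,
    pixel_noise_sd: float = 0.02,
    patient_gain_sd: float = 0.03,
    patient_tilt_sd: float = 3e-4,
) -> SpectralClassModel:
    """Default endmember model on the 31-band 461–641 nm sensor grid.

    The spectra are smooth sums of Gaussian bumps; the stained cancer
    endmember is darker than stained normal, with the difference a bump
    centered on the grid point nearest 550 nm (551 nm on the default
    grid).  Pure function: identical inputs give identical models.
    """
    if wavelengths is None:
        wavelengths = np.linspace(461.0, 641.0, 31)
    wl = np.asarray(wavelengths, dtype=float)
    peak = wl[int(np.argmin(np.abs(wl - 550.0)))]

    # narrow difference bump: the argmax must stay put under cohort-level
    # sampling noise in the standardized-separation curve
    normal_stained = 0.45 + 0.18 * _gauss(wl, 560.0, 70.0) + 0.05 * _gauss(wl, 475.0, 40.0)
    cancer_stained = normal_stained - 0.24 * _gauss(wl, peak, 12.0)
    normal_unstained = 0.55 + 0.08 * _gauss(wl, 540.0, 80.0)
    cancer_unstained = normal_unstained - 0.06 * _gauss(wl, peak, 30.0)

    return SpectralClassModel(
        wavelengths=wl,
        endmembers={
            ("normal", "stained"): normal_stained,
            ("cancer", "stained"): cancer_stained,
            ("normal", "unstained"): normal_unstained,
            ("cancer", "unstained"): cancer_unstained,
        },
        pixel_noise_sd=pixel_noise_sd,
        patient_gain_sd=patient_gain_sd,
        patient_tilt_sd=patient_tilt_sd,
    )


@dataclass
class PhantomConfig:
    """Cohort geometry, sampling parameters and seed."""

    n_patients: int = 10
    rows: int = 443
    cols: int = 313
    bands: int = 31
    wavelength_min: float = 461.0
    wavelength_max: float = 641.0
    cancer_area_fraction: float = 0.30
    pixel_noise_sd: float = 0.02
    patient_gain_sd: float = 0.03
    patient_tilt_sd: float = 3e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.rows, self.cols, self.bands) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError("wavelength_min must be < wavelength_max")
        if not 0.05 < self.cancer_area_fraction < 0.9:
            raise ValueError("cancer_area_fraction must lie in (0.05, 0.9)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.bands)

    def to_text(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in asdict(self).items()) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PhantomConfig":
        kwargs: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cls.__dataclass_fields__:
                continue
            typ = cls.__dataclass_fields__[key].type
            kwargs[key] = int(value) if typ == "int" else float(value)
        return cls(**kwargs)


@dataclass
class LabeledCube:
    """A hypercube plus its ground-truth mask and slide identity."""

    cube: Hypercube
    mask: Mask
    patient_id: str
    staining: str
    slide_class: str

    def __post_init__(self) -> None:
        if self.mask.shape != (self.cube.rows, self.cube.cols):
            raise ValueError("mask shape does not match cube spatial shape")
        if self.staining not in STAININGS:
            raise ValueError(f"staining must be one of {STAININGS}")
        if self.slide_class not in SLIDE_CLASSES:
            raise ValueError(f"slide_class must be one of {SLIDE_CLASSES}")
        if self.slide_class == "normal" and self.mask.labels.any():
            raise ValueError("normal slides must carry an all-zero mask")


# ---------------------------------------------------------------------------
# Mask and texture synthesis
# ---------------------------------------------------------------------------

def _blob(rows: int, cols: int, center: tuple[float, float], radius: float,
          aspect: float, angle: float, wobble: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one irregular elliptical blob as a boolean image."""
    theta = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    # low-order radial wobble makes the ellipse irregular
    r = radius * (1.0 + wobble[0] * np.sin(2 * theta + wobble[1]) + wobble[2] * np.sin(3 * theta + wobble[3]))
    x = r * np.cos(theta)
    y = r * aspect * np.sin(theta)
    ca, sa = np.cos(angle), np.sin(angle)
    pr = center[0] + x * ca - y * sa
    pc = center[1] + x * sa + y * ca
    img = np.zeros((rows, cols), dtype=bool)
    rr, cc = _draw_polygon(np.clip(pr, 0, rows - 1), np.clip(pc, 0, cols - 1))
    img[rr, cc] = True
    return img


def generate_mask(
    slide_class: str,
    rows: int,
    cols: int,
    cancer_area_fraction: float,
    rng: np.random.Generator,
) -> Mask:
    """Ground-truth mask: all zeros for normal slides, 2–6 irregular
    elliptical carcinoma blobs for DCIS slides.

    The realized cancer fraction lands within +/-50 % (relative) of the
    target; placement is rescaled and retried internally until it does.
    """
    if slide_class not in SLIDE_CLASSES:
        raise ValueError(f"unknown slide_class '{slide_class}'")
    if slide_class == "normal":
        return Mask(labels=np.zeros((rows, cols), dtype=np.uint8))
    if cancer_area_fraction > 0.9:
        raise ValueError("cancer_area_fraction > 0.9 is infeasible")

    n_blobs = int(rng.integers(2, 7))
    target_pixels = cancer_area_fraction * rows * cols
    # per-blob base radius assuming modest overlap and aspect ~0.7
    base_r = np.sqrt(target_pixels / (n_blobs * np.pi * 0.7))
    centers = np.stack(
        [rng.uniform(0.15 * rows, 0.85 * rows, n_blobs),
         rng.uniform(0.15 * cols, 0.85 * cols, n_blobs)], axis=1)
    aspects = rng.uniform(0.5, 0.95, n_blobs)
    angles = rng.uniform(0, np.pi, n_blobs)
    wobbles = np.stack(
        [rng.uniform(0.05, 0.18, n_blobs), rng.uniform(0, 2 * np.pi, n_blobs),
         rng.uniform(0.03, 0.12, n_blobs), rng.uniform(0, 2 * np.pi, n_blobs)], axis=1)
    sizes = rng.uniform(0.7, 1.3, n_blobs)

    scale = 1.0
    for _ in range(12):
        img = np.zeros((rows, cols), dtype=bool)
        for b in range(n_blobs):
            img |= _blob(rows, cols, tuple(centers[b]), base_r * sizes[b] * scale,
                         aspects[b], angles[b], wobbles[b], rng)
        frac = img.mean()
        if abs(frac - cancer_area_fraction) <= 0.4 * cancer_area_fraction:
            return Mask(labels=img.astype(np.uint8))
        # rescale radii toward the target area and redraw
        scale *= np.sqrt(cancer_area_fraction / max(frac, 1e-6)) if frac > 0 else 1.5
        scale = float(np.clip(scale, 0.2, 6.0))
    raise RuntimeError(
        f"could not realize cancer fraction {cancer_area_fraction} on a "
        f"{rows} x {cols} grid"
    )


def _duct_texture(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative ring texture mimicking duct cross-sections (around 1.0)."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    tex = np.ones((rows, cols))
    n_ducts = int(rng.integers(3, 7))
    for _ in range(n_ducts):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        rho = rng.uniform(0.05, 0.2) * min(rows, cols)
        width = rng.uniform(0.15, 0.35) * rho
        amp = rng.uniform(0.015, 0.035) * rng.choice([-1.0, 1.0])
        d = np.hypot(yy - cy, xx - cx)
        tex += amp * np.exp(-0.5 * ((d - rho) / max(width, 1.0)) ** 2)
    return tex


# ---------------------------------------------------------------------------
# Patient / cohort generation
# ---------------------------------------------------------------------------

def generate_patient(
    config: PhantomConfig,
    model: SpectralClassModel,
    patient_id: str,
    rng: np.random.Generator,
) -> list[LabeledCube]:
    """Generate the four slides of one patient.

    Every pixel spectrum is
    ``gain * (1 + tilt * (wl - wl_mid)) * endmember + N(0, pixel_noise_sd)``
    clipped to [0, 1], with one gain and one tilt drawn per patient and
    shared across the patient's four cubes.  Non-cancer tissue is
    additionally modulated by a mild duct-ring texture.
    """
    wl = model.wavelengths
    wl_mid = 0.5 * (wl[0] + wl[-1])
    gain = 1.0 + rng.normal(0.0, model.patient_gain_sd)
    tilt = rng.normal(0.0, model.patient_tilt_sd)
    tilt_curve = 1.0 + tilt * (wl - wl_mid)

    slides: list[LabeledCube] = []
    for slide_class in SLIDE_CLASSES:
        mask = generate_mask(
            slide_class, config.rows, config.cols, config.cancer_area_fraction, rng
        )
        texture = _duct_texture(config.rows, config.cols, rng)
        for staining in STAININGS:
            normal_spec = gain * tilt_curve * model.endmember("normal", staining)
            cancer_spec = gain * tilt_curve * model.endmember("cancer", staining)
            cancer = mask.labels.astype(bool)
            base = np.where(
                cancer[:, :, None],
                cancer_spec[None, None, :],
                texture[:, :, None] * normal_spec[None, None, :],
            )
            if model.pixel_noise_sd > 0:
                base = base + rng.normal(
                    0.0, model.pixel_noise_sd, size=base.shape
                )
            data = np.clip(base, 0.0, 1.0).astype(np.float32)
            cube = Hypercube(
                data=data,
                wavelengths=wl,
                metadata={
                    "patient id": patient_id,
                    "staining": staining,
                    "slide class": slide_class,
                    "patient gain": f"{gain:.9g}",
                    "patient tilt": f"{tilt:.9g}",
                    "section thickness um": "5",
                    "field of view um": "100 x 80",
                },
            )
            slides.append(
                LabeledCube(
                    cube=cube,
                    mask=mask if slide_class == "dcis"
                    else Mask(labels=np.zeros((config.rows, config.cols), dtype=np.uint8)),
                    patient_id=patient_id,
                    staining=staining,
                    slide_class=slide_class,
                )
            )
    return slides


def _patient_rng(config: PhantomConfig, index: int) -> np.random.Generator:
    # keyed per patient so cohorts are order-independent and reproducible
    return np.random.default_rng([config.seed, 7919, index])


def iter_cohort(config: PhantomConfig, model: SpectralClassModel | None = None):
    """Yield every LabeledCube of the cohort, patient by patient."""
    if model is None:
        model = default_spectral_model(
            config.wavelengths,
            pixel_noise_sd=config.pixel_noise_sd,
            patient_gain_sd=config.patient_gain_sd,
            patient_tilt_sd=config.patient_tilt_sd,
        )
    for k in range(config.n_patients):
        patient_id = f"patient_{k + 1:02d}"
        yield from generate_patient(config, model, patient_id, _patient_rng(config, k))


def generate_cohort(
    config: PhantomConfig,
    out_dir: str,
    model: SpectralClassModel | None = None,
) -> str:
    """Write the full cohort to ``out_dir`` and return the manifest path.

    Layout: ``patient_<k>/<slide_class>_<staining>.{hdr,img,pgm}`` plus
    ``manifest.tsv`` and the serialized config (``config.txt``).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = ["patient_id\tslide_class\tstaining\thdr_path\tmask_path\tseed"]
    for lc in iter_cohort(config, model):
        pdir = os.path.join(out_dir, lc.patient_id)
        os.makedirs(pdir, exist_ok=True)
        stem = os.path.join(pdir, f"{lc.slide_class}_{lc.staining}")
        hdr_path, _ = write_envi(lc.cube, stem + ".hdr")
        mask_path = write_mask_pgm(lc.mask, stem + ".pgm")
        rows.append(
            "\t".join(
                [
                    lc.patient_id,
                    lc.slide_class,
                    lc.staining,
                    os.path.relpath(hdr_path, out_dir),
                    os.path.relpath(mask_path, out_dir),
                    str(config.seed),
                ]
            )
        )
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    with open(os.path.join(out_dir, "config.txt"), "w") as fh:
        fh.write(config.to_text())
    return manifest_path


def load_cohort(cohort_dir: str) -> list[LabeledCube]:
    """Load every cube referenced by ``<cohort_dir>/manifest.tsv``."""
    manifest_path = os.path.join(cohort_dir, "manifest.tsv")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.tsv in {cohort_dir}")
    slides: list[LabeledCube] = []
    with open(manifest_path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            cube = read_envi(os.path.join(cohort_dir, parts[idx["hdr_path"]]))
            mask = read_mask(os.path.join(cohort_dir, parts[idx["mask_path"]]))
            slides.append(
                LabeledCube(
                    cube=cube,
                    mask=mask,
                    patient_id=parts[idx["patient_id"]],
                    staining=parts[idx["staining"]],
                    slide_class=parts[idx["slide_class"]],
                )
            )
    return slides


def manifest_digest(cohort_dir: str) -> str:
    """SHA-256 of the manifest plus every cube/mask file (determinism checks)."""
    h = hashlib.sha256()
    manifest_path = os.path.join(cohort_dir, "manifest.tsv")
    with open(manifest_path, "rb") as fh:
        h.update(fh.read())
    for root, _, files in sorted(os.walk(cohort_dir)):
        for name in sorted(files):
            if name.endswith((".img", ".pgm", ".hdr")):
                with open(os.path.join(root, name), "rb") as fh:
                    h.update(name.encode())
                    h.update(fh.read())
    return h.hexdigest()
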