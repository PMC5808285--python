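"""Manual-ROI spectral-reflectance protocol and discriminative band selection.

Square regions of interest are picked at random inside the eligible tissue
area (the cancer mask for DCIS slides, the whole field for normal slides).
Each region is summarized as a mean +/- SD reflectance spectrum over
repeated "measurements" — random fixed-size pixel subsamples of the region
— and the per-band class separation is scored as the absolute standardized
mean difference, whose argmax is the selected detection wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, Mask

__all__ = [
    "Region",
    "ROISet",
    "RegionSpectrumSummary",
    "BandSeparation",
    "pick_rois",
    "region_spectrum",
    "band_separation",
    "select_band",
]

_SD_EPS = 1e-9
_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class Region:
    """Axis-aligned square, 0-based, half-open: rows [row0, row0+side)."""

    row0: int
    col0: int
    side: int

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.mgrid[self.row0 : self.row0 + self.side,
                          self.col0 : self.col0 + self.side]
        return rr.ravel(), cc.ravel()

    def overlaps(self, other: "Region") -> bool:
        return not (
            self.row0 + self.side <= other.row0
            or other.row0 + other.side <= self.row0
            or self.col0 + self.side <= other.col0
            or other.col0 + other.side <= self.col0
        )


@dataclass
class ROISet:
    regions: list[Region]
    slide: str = ""
    side: int = 20

    def __post_init__(self) -> None:
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError("ROI squares must be pairwise non-overlapping")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class RegionSpectrumSummary:
    """Per-region mean +/- SD spectrum over repeated measurements."""

    wavelengths: np.ndarray
    mean_spectrum: np.ndarray
    sd_spectrum: np.ndarray
    n_measurements: int
    region: Region | None = None
    class_label: int | None = None
    sd_defined: bool = True

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.sd_spectrum = np.asarray(self.sd_spectrum, dtype=float)
        if self.mean_spectrum.shape != self.sd_spectrum.shape:
            raise ValueError("mean and SD spectra must have equal length")
        if np.any(self.sd_spectrum < 0):
            raise ValueError("SD spectrum must be elementwise >= 0")


@dataclass
class BandSeparation:
    """Per-band standardized class separation and its argmax."""

    wavelengths: np.ndarray
    score: np.ndarray
    best_band_index: int = field(init=False)
    best_wavelength_nm: float = field(init=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if self.wavelengths.shape != self.score.shape:
            raise ValueError("score and wavelength grids differ in length")
        if len(self.score) == 0:
            raise ValueError("empty separation")
        # argmax returns the first maximum; wavelengths increase, so ties
        # resolve toward the lower wavelength
        self.best_band_index = int(np.argmax(self.score))
        self.best_wavelength_nm = float(self.wavelengths[self.best_band_index])


def pick_rois(
    mask_or_cube: Mask | Hypercube,
    slide_class: str,
    n_regions: int = 4,
    side: int = 20,
    rng: np.random.Generator | None = None,
) -> ROISet:
    """Randomly place ``n_regions`` disjoint squares inside the eligible area.

    For DCIS slides every square must lie entirely within the cancer mask;
    for normal slides the whole field is eligible.  Placement is rejection
    sampling with a bounded number of attempts.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(mask_or_cube, Hypercube):
        rows, cols = mask_or_cube.rows, mask_or_cube.cols
        eligible = np.ones((rows, cols), dtype=bool)
    else:
        rows, cols = mask_or_cube.shape
        eligible = (
            mask_or_cube.labels.astype(bool)
            if slide_class == "dcis"
            else np.ones((rows, cols), dtype=bool)
        )
    if rows < side or cols < side:
        raise ValueError(f"image {rows} x {cols} cannot host a side-{side} square")
    if eligible.sum() < n_regions * side * side:
        raise ValueError(
            f"eligible area ({int(eligible.sum())} px) smaller than "
            f"{n_regions} disjoint side-{side} squares"
        )
    # integral image -> O(1) "square fully eligible" test
    integral = np.pad(np.cumsum(np.cumsum(eligible, 0), 1), ((1, 0), (1, 0)))

    def fully_eligible(r0: int, c0: int) -> bool:
        s = (
            integral[r0 + side, c0 + side]
            - integral[r0, c0 + side]
            - integral[r0 + side, c0]
            + integral[r0, c0]
        )
        return s == side * side

    chosen: list[Region] = []
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        if len(chosen) == n_regions:
            break
        r0 = int(rng.integers(0, rows - side + 1))
        c0 = int(rng.integers(0, cols - side + 1))
        cand = Region(r0, c0, side)
        if not fully_eligible(r0, c0):
            continue
        if any(cand.overlaps(other) for other in chosen):
            continue
        chosen.append(cand)
    if len(chosen) < n_regions:
        raise RuntimeError(
            f"could not place {n_regions} disjoint side-{side} squares inside "
            f"the eligible area after {_MAX_PLACEMENT_ATTEMPTS} attempts"
        )
    return ROISet(regions=chosen, side=side)


def region_spectrum(
    cube: Hypercube,
    region: Region,
    n_measurements: int = 10,
    subsample_size: int = 25,
    rng: np.random.Generator | None = None,
) -> RegionSpectrumSummary:
    """Summarize one region as mean +/- SD spectrum across measurements.

    One "measurement" is the mean spectrum of ``subsample_size`` region
    pixels drawn without replacement.  With a single measurement the SD is
    undefined and reported as zero with ``sd_defined=False``.
    """
    if n_measurements < 1:
        raise ValueError("n_measurements must be >= 1")
    if (
        region.row0 < 0
        or region.col0 < 0
        or region.row0 + region.side > cube.rows
        or region.col0 + region.side > cube.cols
    ):
        raise ValueError(f"region {region} not inside cube")
    n_pixels = region.side * region.side
    if n_pixels < subsample_size:
        raise ValueError(
            f"region has {n_pixels} pixels, fewer than subsample size {subsample_size}"
        )
    rng = np.random.default_rng() if rng is None else rng
    rr, cc = region.pixel_indices()
    pixels = cube.data[rr, cc, :]  # n_pixels x bands
    measurements = np.empty((n_measurements, cube.bands))
    for m in range(n_measurements):
        take = rng.choice(n_pixels, size=subsample_size, replace=False)
        measurements[m] = pixels[take].mean(axis=0)
    mean = measurements.mean(axis=0)
    if n_measurements == 1:
        sd = np.zeros(cube.bands)
        sd_defined = False
    else:
        sd = measurements.std(axis=0, ddof=1)
        sd_defined = True
    # spectrally constant bands must report the constant and SD exactly 0,
    # not a rounding residue
    constant = np.ptp(pixels, axis=0) == 0
    mean[constant] = pixels[0, constant]
    sd[constant] = 0.0
    return RegionSpectrumSummary(
        wavelengths=cube.wavelengths.copy(),
        mean_spectrum=mean,
        sd_spectrum=sd,
        n_measurements=n_measurements,
        region=region,
        sd_defined=sd_defined,
    )


def _pool_class(summaries: list[RegionSpectrumSummary]) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool region summaries into one class mean / variance over all measurements."""
    ns = np.array([s.n_measurements for s in summaries], dtype=float)
    means = np.stack([s.mean_spectrum for s in summaries])
    sds = np.stack([s.sd_spectrum for s in summaries])
    n_total = ns.sum()
    pooled_mean = (ns[:, None] * means).sum(axis=0) / n_total
    # total sum of squares = within-region + between-region parts
    ss = ((ns - 1)[:, None] * sds**2).sum(axis=0) + (
        ns[:, None] * (means - pooled_mean) ** 2
    ).sum(axis=0)
    var = ss / max(n_total - 1, 1.0)
    return pooled_mean, var, int(n_total)


def band_separation(
    summaries_cancer: list[RegionSpectrumSummary],
    summaries_normal: list[RegionSpectrumSummary],
) -> BandSeparation:
    """Score per-band class separation: |mu_c - mu_n| / pooled SD.

    Class means and variances pool all measurements of all regions; the
    two class variances are combined into one pooled SD per band, floored
    at a small epsilon.
    """
    if not summaries_cancer or not summaries_normal:
        raise ValueError("need at least one summary per class")
    wl = summaries_cancer[0].wavelengths
    for s in summaries_cancer + summaries_normal:
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise ValueError("summaries are not on a common wavelength grid")
    mean_c, var_c, n_c = _pool_class(summaries_cancer)
    mean_n, var_n, n_n = _pool_class(summaries_normal)
    dof = max(n_c + n_n - 2, 1)
    pooled_sd = np.sqrt(
        ((n_c - 1) * var_c + (n_n - 1) * var_n) / dof
    )
    score = np.abs(mean_c - mean_n) / np.maximum(pooled_sd, _SD_EPS)
    return BandSeparation(wavelengths=wl.copy(), score=score)


def select_band(separation: BandSeparation) -> float:
    """Best differentiating wavelength (nm): argmax of the separation score,
    ties toward the lower wavelength.  Pure and deterministic."""
    return separation.best_wavelength_nm
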