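"""expHTT inclusion quantification and hemisphere-level form categorisation.

The quantification pipeline mirrors a standard epifluorescence workflow
for counting bright protein aggregates: convert the projection to 8-bit,
remove slowly varying background with a rolling ball (radius 10 px),
apply an unsharp mask (sigma 1 px, weight 0.7), sharpen, take the Sobel
gradient magnitude ("find edges"), threshold with the intermodes rule
(histogram smoothed until bimodal, threshold midway between the two
modes) and count 8-connected particles with calibrated area of at least
1 µm². Spots — single large compact oval expHTT structures — are counted
among the particles; the pipeline deliberately does not distinguish them
from puncta-like inclusions.

Cell-level expHTT form labels (Diff, Inc, Diff+Inc, Spot, Diff+Spot,
NoHTT) are inputs assigned by expert inspection; this module only
computes the hemisphere-dominance category from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import filters, measure, restoration

logger = logging.getLogger(__name__)


class ChannelError(ValueError):
    """Input image is not single-channel."""


class ImageSizeError(ValueError):
    """Image too small for the operator chain."""


class UnimodalHistogramError(ValueError):
    """Histogram never became bimodal within the iteration cap."""


class EmptyHemisphereError(ValueError):
    """Hemisphere with no labelled cells."""


@dataclass
class Micrograph:
    """Single-channel intensity image with spatial calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class Particle:
    centroid: tuple[float, float]
    area_um2: float
    n_pixels: int


@dataclass
class ParticleSet:
    """Segmented particles for one hemisphere ROI."""

    particles: list[Particle] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.particles)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.particles])

    @property
    def mean_area_um2(self) -> float:
        return float(self.areas_um2.mean()) if self.particles else float("nan")


# ---------------------------------------------------------------------------
# Operator chain

_SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 12.0, -1.0], [-1.0, -1.0, -1.0]]
) / 4.0


def _to_8bit(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return np.round((img - lo) / (hi - lo) * 255.0)


def unsharp_mask(img: np.ndarray, sigma: float = 1.0, weight: float = 0.7) -> np.ndarray:
    """Subtractive unsharp mask ``(I - w*G_sigma(I)) / (1 - w)``.

    ``weight = 0`` is the identity; weights approaching 1 boost detail
    at the blur scale increasingly strongly. Output is clipped to the
    8-bit range.
    """
    if not 0 <= weight < 1:
        raise ValueError("weight must lie in [0, 1)")
    if weight == 0:
        return np.asarray(img, dtype=float).copy()
    blurred = ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma=sigma)
    return np.clip((img - weight * blurred) / (1.0 - weight), 0.0, 255.0)


def preprocess_inclusion_image(img: Micrograph) -> Micrograph:
    """Edge-enhance a micrograph for inclusion segmentation.

    Applies, in order: min-max rescale to the 0-255 integer range;
    rolling-ball background subtraction (radius 10 px, clipped at 0);
    unsharp mask ``(I - w*G_sigma(I)) / (1 - w)`` with sigma = 1 px and
    w = 0.7; a 3x3 sharpening convolution; and the Sobel gradient
    magnitude, rescaled back to 0-255. A flat image passes through as
    all zeros.
    """
    pix = img.pixels
    if pix.ndim != 2:
        raise ChannelError(f"expected a single-channel 2-D image, got shape {pix.shape}")
    if min(pix.shape) < 3:
        raise ImageSizeError("image must be at least 3x3 pixels")
    out = _to_8bit(pix)
    background = restoration.rolling_ball(out, radius=10)
    out = np.clip(out - background, 0.0, None)
    out = unsharp_mask(out, sigma=1.0, weight=0.7)
    out = np.clip(ndimage.convolve(out, _SHARPEN_KERNEL, mode="nearest"), 0.0, 255.0)
    out = filters.sobel(out)
    out = _to_8bit(out)
    return Micrograph(pixels=out, pixel_size_um=img.pixel_size_um, bit_depth=8)


def intermodes_threshold(img: Micrograph | np.ndarray, max_iter: int = 10_000) -> int:
    """Intermodes automatic threshold of an 8-bit-range image.

    The 256-bin histogram is smoothed with a 3-point running mean until
    exactly two local maxima remain; the threshold is the floor of the
    midpoint of the two mode locations, and foreground is every pixel
    strictly above it. Raises :class:`UnimodalHistogramError` when the
    histogram cannot be made bimodal within ``max_iter`` smoothing
    passes (e.g. a constant image).
    """
    pix = img.pixels if isinstance(img, Micrograph) else np.asarray(img, dtype=float)
    values = np.clip(np.round(pix), 0, 255).astype(int)
    hist = np.bincount(values.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise UnimodalHistogramError("histogram has fewer than two populated levels")
    kernel = np.array([1.0, 1.0, 1.0]) / 3.0
    for _ in range(max_iter):
        maxima = _local_maxima(hist)
        if maxima.size == 2:
            return int((maxima[0] + maxima[1]) // 2)
        if maxima.size < 2:
            raise UnimodalHistogramError("histogram became unimodal before bimodality")
        hist = np.convolve(hist, kernel, mode="same")
    raise UnimodalHistogramError(f"histogram not bimodal after {max_iter} smoothing passes")


def _local_maxima(hist: np.ndarray) -> np.ndarray:
    padded = np.concatenate(([-np.inf], hist, [-np.inf]))
    return np.nonzero((padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:]))[0]


def analyze_particles(
    mask: np.ndarray,
    pixel_size_um: float,
    min_size_um2: float = 1.0,
    fill_holes: bool = True,
) -> ParticleSet:
    """Count 8-connected foreground components with calibrated areas.

    ``fill_holes`` (default on) fills interior holes before labelling,
    reproducing outer-contour particle tracing: an edge ring and its
    enclosed interior count as one particle. Components smaller than
    ``min_size_um2`` (default 1 µm², the lower size limit that screens
    out background specks) are dropped. An empty mask yields an empty
    :class:`ParticleSet`, not an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    particles = []
    for region in measure.regionprops(labels):
        area = region.area * pixel_size_um**2
        if area < min_size_um2:
            continue
        particles.append(
            Particle(centroid=tuple(region.centroid), area_um2=float(area), n_pixels=int(region.area))
        )
    return ParticleSet(particles=particles)


def roi_to_mask(roi, shape: tuple[int, int]) -> np.ndarray:
    """Normalise an ROI spec to a boolean mask.

    Accepts ``None`` (whole frame), a boolean mask, a rectangle
    ``(r0, c0, r1, c1)`` with exclusive stop indices, or a polygon as an
    iterable of (row, col) vertices.
    """
    if roi is None:
        return np.ones(shape, dtype=bool)
    arr = np.asarray(roi)
    if arr.dtype == bool:
        if arr.shape != shape:
            raise ValueError("ROI mask shape does not match image")
        return arr
    if arr.ndim == 1 and arr.size == 4:
        r0, c0, r1, c1 = (int(v) for v in arr)
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError("rectangle ROI lies outside the image")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask
    if arr.ndim == 2 and arr.shape[1] == 2:
        return skdraw.polygon2mask(shape, arr)
    raise ValueError("unrecognised ROI specification")


def quantify_inclusions(
    img: Micrograph, roi=None, min_size_um2: float = 1.0
) -> ParticleSet:
    """Full inclusion quantification for one hemisphere ROI.

    Preprocess, intermodes-threshold, then analyse particles restricted
    to the ROI. When the preprocessed image has no bimodal histogram
    (e.g. a flat field with nothing to segment) the threshold step is
    skipped with a logged warning and zero particles are returned.
    Spots are counted among the particles — the pipeline does not
    separate them from puncta-like inclusions.
    """
    processed = preprocess_inclusion_image(img)
    try:
        level = intermodes_threshold(processed)
    except UnimodalHistogramError as exc:
        logger.warning("quantify_inclusions: %s; returning zero particles", exc)
        return ParticleSet()
    mask = processed.pixels > level
    mask &= roi_to_mask(roi, mask.shape)
    return analyze_particles(mask, img.pixel_size_um, min_size_um2=min_size_um2)


# ---------------------------------------------------------------------------
# expHTT form categorisation

#: Valid cell-level expHTT form labels.
CELL_FORM_LABELS = ("Diff", "Inc", "Diff+Inc", "Spot", "Diff+Spot", "NoHTT")

#: Base forms each cell label contributes to the hemisphere tally.
_LABEL_BASE_FORMS = {
    "Diff": ("Diff",),
    "Inc": ("Inc",),
    "Diff+Inc": ("Diff", "Inc"),
    "Spot": ("Spot",),
    "Diff+Spot": ("Diff", "Spot"),
    "NoHTT": (),
}

_PAIR_CATEGORY = {
    frozenset({"Diff", "Inc"}): "Diff+Inc",
    frozenset({"Diff", "Spot"}): "Diff+Spot",
    frozenset({"Spot", "Inc"}): "Spot+Inc",
}

#: Possible hemisphere-level dominant categories (NoHTT is a flag, not a
#: category: hemispheres whose cells all lack expHTT never dominate).
HEMISPHERE_CATEGORIES = (
    "Diff",
    "Diff+Inc",
    "Diff+Spot",
    "Spot",
    "Diff+Spot+Inc",
    "Spot+Inc",
    "Inc",
)


def dominant_form(cell_labels: Sequence[str]) -> str:
    """Hemisphere category from the most predominant expHTT base form.

    Each cell label is decomposed into its base forms (Diff, Spot, Inc);
    cells without expHTT staining are excluded from the tally. A strict
    plurality names the category outright; a two-way tie maps to the
    combined category (Diff+Inc, Diff+Spot or Spot+Inc) and a three-way
    tie to Diff+Spot+Inc. If every cell is NoHTT the "NoHTT" flag is
    returned.
    """
    labels = list(cell_labels)
    if not labels:
        raise EmptyHemisphereError("no labelled cells in hemisphere")
    tally = {"Diff": 0, "Spot": 0, "Inc": 0}
    for label in labels:
        if label not in _LABEL_BASE_FORMS:
            raise ValueError(f"unknown cell form label {label!r}")
        for base in _LABEL_BASE_FORMS[label]:
            tally[base] += 1
    top = max(tally.values())
    if top == 0:
        return "NoHTT"
    winners = frozenset(form for form, n in tally.items() if n == top)
    if len(winners) == 1:
        return next(iter(winners))
    if len(winners) == 2:
        return _PAIR_CATEGORY[winners]
    return "Diff+Spot+Inc"


@dataclass
class HemisphereRecord:
    """Per-hemisphere cell labels, LNv counts and derived dominant forms."""

    hemisphere_id: str
    slnv_labels: list[str]
    llnv_labels: list[str]
    pdf_slnv_count: Optional[int] = None
    per_slnv_count: Optional[int] = None
    llnv_count: Optional[int] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        for name, value in (
            ("pdf_slnv_count", self.pdf_slnv_count),
            ("per_slnv_count", self.per_slnv_count),
            ("llnv_count", self.llnv_count),
        ):
            if value is not None and not 0 <= value <= 5:
                raise ValueError(f"{name} must lie in 0..5")
        for labels in (self.slnv_labels, self.llnv_labels):
            for lab in labels:
                if lab not in CELL_FORM_LABELS:
                    raise ValueError(f"unknown cell form label {lab!r}")
            if len(labels) > 5:
                raise ValueError("at most 5 cells per LNv class per hemisphere")

    def dominant(self, cell_class: str) -> str:
        labels = self.slnv_labels if cell_class == "sLNv" else self.llnv_labels
        return dominant_form(labels)

    def has_spot(self, cell_class: str) -> bool:
        labels = self.slnv_labels if cell_class == "sLNv" else self.llnv_labels
        return any(lab in ("Spot", "Diff+Spot") for lab in labels)


def hemisphere_proportions(
    records: Sequence[HemisphereRecord],
    cell_class: str = "sLNv",
    grouping: Optional[dict[str, str]] = None,
) -> dict:
    """Hemisphere-dominance contingency table and spot prevalence per group.

    Returns a dict with ``table`` (category x group counts, ready for
    :func:`circafly.cohort_stats.fisher_mxn`), ``proportions`` (column-
    normalised) and ``spot_prevalence`` (fraction of hemispheres with at
    least one Spot-bearing cell of the class, per group). ``grouping``
    maps hemisphere_id to group; records carrying a ``group`` attribute
    need no mapping.
    """
    if not records:
        raise ValueError("no hemisphere records supplied")
    rows = []
    for rec in records:
        group = grouping[rec.hemisphere_id] if grouping else (rec.group or "all")
        labels = rec.slnv_labels if cell_class == "sLNv" else rec.llnv_labels
        if not labels:  # no surviving cells of this class to categorise
            continue
        rows.append(
            {
                "group": group,
                "category": rec.dominant(cell_class),
                "has_spot": rec.has_spot(cell_class),
            }
        )
    if not rows:
        raise ValueError(f"no hemisphere has labelled {cell_class} cells")
    frame = pd.DataFrame(rows)
    categorised = frame[frame["category"] != "NoHTT"]
    table = pd.crosstab(categorised["category"], categorised["group"])
    table = table.reindex(
        [c for c in HEMISPHERE_CATEGORIES if c in table.index], fill_value=0
    )
    proportions = table / table.sum(axis=0)
    spot_prev = frame.groupby("group")["has_spot"].mean()
    return {"table": table, "proportions": proportions, "spot_prevalence": spot_prev}
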