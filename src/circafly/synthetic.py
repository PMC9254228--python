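"""Synthetic DAM cohorts and micrographs with known ground truth.

The behavioural generator emulates the study design this package
analyses: one DAM2 monitor of 32 flies per genotype recorded in constant
darkness for 21 days at 20-minute bins, starting with 3-day-old flies.
Each fly's expected count per bin follows a von Mises profile of its
circadian phase — the concentration ``kappa`` is the single consolidation
knob (kappa = 0 is a uniform, arrhythmic profile; large kappa piles the
activity into a narrow peak) — scaled so the mean rate equals
``mean_counts_per_bin``; observed counts are Poisson draws. After an
optional arrhythmia-onset age the rate becomes uniform at the same mean,
so loss of rhythm is isolated from loss of activity; after an optional
death age all bins are zero. Each fly consumes an independent RNG
substream derived from (seed, fly index), so cohorts are reproducible
under parallel generation.

The image generator plants bright puncta ("inclusions", disks of known
calibrated area under a small Gaussian PSF) and larger compact ovals
("spots") on a background with a linear gradient, with optional Poisson
or Gaussian noise, and records centroids/areas/classes as ground truth
for closed-loop tests of the quantification pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import i0e

from .dam_io import ActivitySeries, ChannelMap, ChannelMapRow, write_dam_monitor
from .imaging import Micrograph, HemisphereRecord, CELL_FORM_LABELS

MINUTES_PER_DAY = 1440.0


class ConfigurationError(ValueError):
    """A simulation config field is invalid; the message names the field."""


class GenerationError(RuntimeError):
    """Requested objects cannot be placed in the frame."""


# ---------------------------------------------------------------------------
# Behaviour


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Study-design parameters for a simulated DAM cohort.

    Defaults follow the emulated protocol: 32 flies, 3-day-old at load,
    21 days of DD at 20-minute bins, a free-running period near 24 h and
    a moderate activity level of 5 expected counts per bin.
    """

    n_flies: int = 32
    start_age_days: float = 3.0
    n_days: float = 21.0
    bin_minutes: float = 20.0
    period_hours: float = 24.0
    kappa: float = 4.0
    mean_counts_per_bin: float = 5.0
    arrhythmia_onset_day: Optional[float] = None
    death_days: Optional[Sequence[Optional[float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ConfigurationError("n_flies must be at least 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be at least 1")
        if self.bin_minutes <= 0:
            raise ConfigurationError("bin_minutes must be positive")
        if not 14.0 < self.period_hours < 34.0:
            raise ConfigurationError("period_hours must lie in (14, 34)")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")
        if self.mean_counts_per_bin <= 0:
            raise ConfigurationError("mean_counts_per_bin must be positive")
        if self.death_days is not None and len(self.death_days) != self.n_flies:
            raise ConfigurationError("death_days must have one entry per fly")

    @property
    def n_bins(self) -> int:
        return int(round(self.n_days * MINUTES_PER_DAY / self.bin_minutes))


@dataclass
class FlyTruth:
    fly_id: str
    period_hours: float
    kappa: float
    arrhythmia_onset_day: Optional[float]
    death_day: Optional[float]

    @property
    def rhythmic(self) -> bool:
        return self.kappa > 0 and self.arrhythmia_onset_day is None


def rate_profile(config: BehaviorSimConfig, bin_ages_days: np.ndarray) -> np.ndarray:
    """Noise-free expected counts per bin for a rhythmic fly.

    The von Mises density on circadian phase, scaled so its circular
    mean equals ``mean_counts_per_bin``; its mean resultant length is
    ``I1(kappa)/I0(kappa)``, 0 in the uniform limit and 1 as kappa grows.
    """
    phase = 2.0 * np.pi * np.mod(bin_ages_days * 24.0, config.period_hours) / config.period_hours
    # exp(kappa*cos(phase - pi)) / I0(kappa), written with i0e for stability
    shape = np.exp(config.kappa * (np.cos(phase - np.pi) - 1.0)) / i0e(config.kappa)
    return config.mean_counts_per_bin * shape


def simulate_fly(
    config: BehaviorSimConfig, fly_index: int, genotype: str = "sim", run_id: str = "run1"
) -> tuple[ActivitySeries, FlyTruth]:
    """Simulate one fly's activity series plus its ground truth.

    The RNG substream is seeded by (config.seed, fly_index), so each fly
    is reproducible independently of the rest of the cohort.
    """
    if not 0 <= fly_index < config.n_flies:
        raise ConfigurationError("fly_index must be smaller than n_flies")
    rng = np.random.default_rng([config.seed, fly_index])
    mid_ages = (
        config.start_age_days
        + ((np.arange(config.n_bins) + 0.5) * config.bin_minutes) / MINUTES_PER_DAY
    )
    start_ages = (
        config.start_age_days + (np.arange(config.n_bins) * config.bin_minutes) / MINUTES_PER_DAY
    )
    rate = rate_profile(config, mid_ages)
    if config.arrhythmia_onset_day is not None:
        rate = np.where(start_ages >= config.arrhythmia_onset_day, config.mean_counts_per_bin, rate)
    death_day = config.death_days[fly_index] if config.death_days is not None else None
    counts = rng.poisson(rate)
    if death_day is not None:
        counts = np.where(start_ages > death_day, 0, counts)
    fly_id = f"{genotype}_{fly_index + 1:02d}"
    series = ActivitySeries(
        fly_id=fly_id,
        genotype=genotype,
        run_id=run_id,
        counts=counts,
        start_age_days=config.start_age_days,
        bin_minutes=config.bin_minutes,
        death_day=death_day,
    )
    truth = FlyTruth(
        fly_id=fly_id,
        period_hours=config.period_hours,
        kappa=config.kappa,
        arrhythmia_onset_day=config.arrhythmia_onset_day,
        death_day=death_day,
    )
    return series, truth


def simulate_cohort(
    config: BehaviorSimConfig, genotype: str = "sim", run_id: str = "run1"
) -> tuple[list[ActivitySeries], list[FlyTruth]]:
    """Simulate a full cohort; deterministic under a fixed config seed."""
    series, truths = [], []
    for i in range(config.n_flies):
        s, t = simulate_fly(config, i, genotype=genotype, run_id=run_id)
        series.append(s)
        truths.append(t)
    return series, truths


def write_cohort(
    cohort: Sequence[ActivitySeries], out_dir: str | Path, monitor_name: str = "Monitor1.txt"
) -> tuple[Path, Path]:
    """Write a cohort as DAM2 monitor text plus its channel-map CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    monitor_path = out_dir / monitor_name
    write_dam_monitor(cohort, monitor_path)
    rows = [
        ChannelMapRow(
            monitor_file=monitor_name,
            channel=i + 1,
            fly_id=s.fly_id,
            genotype=s.genotype,
            run_id=s.run_id,
            start_age_days=s.start_age_days,
        )
        for i, s in enumerate(cohort)
    ]
    map_path = out_dir / (monitor_name.rsplit(".", 1)[0] + "_channels.csv")
    ChannelMap(rows).to_csv(map_path)
    return monitor_path, map_path


# ---------------------------------------------------------------------------
# Micrographs


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters for a synthetic inclusion micrograph.

    Defaults give a 320x320 frame at 0.1 µm/pixel (a 32 µm field, the
    scale of an LNv cluster region), dim background with a shallow
    gradient, bright planted objects well above background, and
    inclusion/spot areas spanning the range of puncta-like aggregates
    down to sub-cut-off background specks.
    """

    shape: tuple[int, int] = (320, 320)
    pixel_size_um: float = 0.1
    background_level: float = 20.0
    gradient_amplitude: float = 10.0
    n_inclusions: int = 5
    inclusion_area_range_um2: tuple[float, float] = (1.5, 6.0)
    n_spots: int = 0
    spot_area_range_um2: tuple[float, float] = (12.0, 25.0)
    noise_model: str | tuple[str, float] = "none"
    object_peak: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.n_inclusions < 0 or self.n_spots < 0:
            raise ConfigurationError("n_inclusions and n_spots must be non-negative")
        for name, rng_ in (
            ("inclusion_area_range_um2", self.inclusion_area_range_um2),
            ("spot_area_range_um2", self.spot_area_range_um2),
        ):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ConfigurationError(f"{name} must be a positive (min, max) pair")
        if self.background_level < 0 or self.gradient_amplitude < 0:
            raise ConfigurationError("background_level and gradient_amplitude must be >= 0")
        kind = self.noise_model[0] if isinstance(self.noise_model, tuple) else self.noise_model
        if kind not in ("none", "poisson", "gaussian"):
            raise ConfigurationError("noise_model must be none, poisson or gaussian")


@dataclass
class PlantedObject:
    kind: str  # "inclusion" or "spot"
    centroid_px: tuple[float, float]
    area_um2: float


#: Point-spread blur (pixels) applied to every planted object; gives the
#: sharp-but-band-limited edges of PSF-limited epifluorescence puncta.
PSF_SIGMA_PX = 0.8


def simulate_micrograph(config: ImageSimConfig) -> tuple[Micrograph, list[PlantedObject]]:
    """Render background + gradient + planted objects (+ noise).

    Inclusions are bright disks of the stated area convolved with a
    small Gaussian point-spread function — sharp-edged "shiny specks";
    spots are larger compact ovals of the stated area under the same
    PSF. Ground-truth areas are the analytic disk/ellipse areas.
    Placement keeps objects apart and away from the border; when they
    cannot fit, :class:`GenerationError` is raised.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    image = np.full((rows, cols), config.background_level, dtype=float)
    image += config.gradient_amplitude * np.linspace(0.0, 1.0, cols)[None, :]

    truth: list[PlantedObject] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, exclusion radius px)

    def place(radius_px: float) -> tuple[float, float]:
        margin = radius_px + 8.0
        if 2 * margin >= min(rows, cols):
            raise GenerationError("object does not fit in the frame")
        for _ in range(3000):
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if all(
                math.hypot(r - pr, c - pc) >= radius_px + prad + 16.0
                for pr, pc, prad in placed
            ):
                placed.append((r, c, radius_px))
                return r, c
        raise GenerationError("could not place all objects without overlap")

    yy, xx = np.mgrid[0:rows, 0:cols]
    layer = np.zeros((rows, cols))
    for _ in range(config.n_inclusions):
        area = rng.uniform(*config.inclusion_area_range_um2)
        radius = math.sqrt(area / math.pi) / config.pixel_size_um
        r, c = place(radius)
        layer += ((yy - r) ** 2 + (xx - c) ** 2 <= radius**2).astype(float)
        truth.append(PlantedObject("inclusion", (r, c), area))
    for _ in range(config.n_spots):
        area = rng.uniform(*config.spot_area_range_um2)
        area_px = area / config.pixel_size_um**2
        aspect = rng.uniform(1.2, 1.8)
        b = math.sqrt(area_px / (math.pi * aspect))  # minor semi-axis, px
        a = aspect * b
        angle = rng.uniform(0.0, math.pi)
        r, c = place(a)
        dy, dx = yy - r, xx - c
        u = dx * math.cos(angle) + dy * math.sin(angle)
        v = -dx * math.sin(angle) + dy * math.cos(angle)
        layer += ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
        truth.append(PlantedObject("spot", (r, c), area))
    image += config.object_peak * ndimage.gaussian_filter(layer, sigma=PSF_SIGMA_PX)

    kind = config.noise_model[0] if isinstance(config.noise_model, tuple) else config.noise_model
    if kind == "poisson":
        image = rng.poisson(np.clip(image, 0.0, None)).astype(float)
    elif kind == "gaussian":
        sigma_n = config.noise_model[1]
        image = np.clip(image + rng.normal(0.0, sigma_n, image.shape), 0.0, None)
    return Micrograph(pixels=image, pixel_size_um=config.pixel_size_um), truth


def write_micrograph(
    img: Micrograph, truth: Sequence[PlantedObject], out_dir: str | Path, stem: str = "micrograph"
) -> tuple[Path, Path]:
    """Write a simulated image as 16-bit TIFF plus ground-truth JSON."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{stem}.tif"
    pixels = np.clip(img.pixels, 0, 65535).astype(np.uint16)
    tifffile.imwrite(tif_path, pixels)
    meta = {
        "pixel_size_um": img.pixel_size_um,
        "objects": [
            {"kind": o.kind, "centroid_px": list(o.centroid_px), "area_um2": o.area_um2}
            for o in truth
        ],
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=2))
    return tif_path, json_path


# ---------------------------------------------------------------------------
# Hemisphere label tables


def simulate_hemisphere_labels(
    n_hemispheres: int,
    form_probabilities: dict[str, float],
    lnv_count_distribution: Sequence[float],
    seed: int = 0,
    group: Optional[str] = None,
) -> list[HemisphereRecord]:
    """Draw per-hemisphere cell-level expHTT form labels and LNv counts.

    ``form_probabilities`` maps cell labels to probabilities (must sum to
    1); ``lnv_count_distribution`` is a length-6 probability vector over
    0-5 cells per hemisphere, used for both sLNv and lLNv cell numbers.
    """
    labels = list(form_probabilities)
    probs = np.array([form_probabilities[k] for k in labels], dtype=float)
    for lab in labels:
        if lab not in CELL_FORM_LABELS:
            raise ConfigurationError(f"form_probabilities has unknown label {lab!r}")
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ConfigurationError("form_probabilities must be non-negative and sum to 1")
    dist = np.asarray(lnv_count_distribution, dtype=float)
    if dist.size != 6 or abs(dist.sum() - 1.0) > 1e-9 or (dist < 0).any():
        raise ConfigurationError(
            "lnv_count_distribution must be a length-6 probability vector over 0-5"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_hemispheres):
        n_slnv = int(rng.choice(6, p=dist))
        n_llnv = int(rng.choice(6, p=dist))
        slnv = [str(lab) for lab in rng.choice(labels, size=n_slnv, p=probs)]
        llnv = [str(lab) for lab in rng.choice(labels, size=n_llnv, p=probs)]
        records.append(
            HemisphereRecord(
                hemisphere_id=f"hem_{i + 1:03d}",
                slnv_labels=slnv,
                llnv_labels=llnv,
                pdf_slnv_count=n_slnv,
                llnv_count=n_llnv,
                group=group,
            )
        )
    return records
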