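"""Foreground segmentation and per-drop growth-area extraction.

Background subtraction fits a two-component Gaussian mixture to the pixel
intensities of each registered frame (illumination drifts between incubation
days, so every frame gets its own fit); pixels assigned by maximum posterior
responsibility to the colony component form the foreground mask.  The growth
area of a drop is the count of foreground pixels within its circular ROI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from spotlag.experiment_model import ExperimentDesign, PlateLayout
from spotlag.registration import PlateImageSeries

logger = logging.getLogger(__name__)

#: mixture component means closer than this are treated as one population
SEPARABILITY_FLOOR = 0.05
#: a frame whose foreground fraction exceeds this is considered saturated
FOREGROUND_CAP = 0.9


class QuantificationError(RuntimeError):
    pass


@dataclass
class ForegroundMask:
    """Binary colony mask for one frame plus the mixture fit that produced it."""

    plate_id: str
    day: float
    mask: np.ndarray
    method_stats: dict = field(default_factory=dict)

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class GrowthCurve:
    """Per-drop (day, area-in-pixels) kinetics with the drop's assay metadata."""

    drop_id: str
    days: list[float]
    areas: list[int]
    metadata: dict = field(default_factory=dict)
    missing_days: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.days) != len(self.areas):
            raise ValueError("days and areas must align")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be >= 0")

    @property
    def points(self) -> list[tuple[float, int]]:
        return list(zip(self.days, self.areas))


def subtract_background(
    image: np.ndarray,
    *,
    plate_id: str = "plate",
    day: float = 0.0,
    colonies_brighter: bool = True,
    seed: int = 0,
    max_fit_pixels: int = 300_000,
) -> ForegroundMask:
    """Segment colony foreground from agar background on one registered frame.

    A 2-component Gaussian mixture (EM, k-means++ init, 100 iterations,
    tol 1e-6, fixed seed) is fitted to the intensity histogram; pixels whose
    posterior favours the colony component (brighter by default, polarity
    configurable) form the mask.  If the component means are closer than
    ``SEPARABILITY_FLOOR`` the frame is declared growth-free, and if the
    foreground would cover more than ``FOREGROUND_CAP`` of the frame the
    mask is emptied with a saturation warning.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise QuantificationError("non-finite pixel intensities")
    flat = img.reshape(-1, 1)
    rng = np.random.default_rng(seed)
    fit_data = flat
    if flat.shape[0] > max_fit_pixels:
        idx = rng.choice(flat.shape[0], size=max_fit_pixels, replace=False)
        fit_data = flat[idx]
    if float(fit_data.max() - fit_data.min()) < 1e-12:
        # perfectly uniform frame: nothing to separate
        return ForegroundMask(
            plate_id, day, np.zeros(img.shape, dtype=bool), {"uniform": True}
        )
    gmm = GaussianMixture(
        n_components=2,
        init_params="k-means++",
        max_iter=100,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-degenerate two-valued histograms
        gmm.fit(fit_data)
    means = gmm.means_.ravel()
    order = np.argsort(means)
    stats = {
        "means": [float(means[order[0]]), float(means[order[1]])],
        "weights": [float(gmm.weights_[order[0]]), float(gmm.weights_[order[1]])],
    }
    if abs(means[1] - means[0]) < SEPARABILITY_FLOOR:
        stats["separability"] = "below_floor"
        return ForegroundMask(plate_id, day, np.zeros(img.shape, dtype=bool), stats)
    colony_comp = order[1] if colonies_brighter else order[0]
    labels = gmm.predict(flat)
    mask = (labels == colony_comp).reshape(img.shape)
    if mask.mean() > FOREGROUND_CAP:
        logger.warning(
            "plate %s day %s: foreground fraction %.2f exceeds cap; "
            "frame treated as saturated",
            plate_id,
            day,
            mask.mean(),
        )
        stats["saturated"] = True
        mask = np.zeros(img.shape, dtype=bool)
    return ForegroundMask(plate_id, day, mask, stats)


def roi_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean disk: pixels whose centre lies within ``radius`` of ``center``."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def measure_area(mask: ForegroundMask, layout: PlateLayout, drop_id: str) -> int:
    """Foreground pixel count inside the drop's circular ROI."""
    drop = layout.drop(drop_id)  # raises KeyError on unknown id
    disk = roi_mask(mask.mask.shape, drop.center, drop.roi_radius)
    return int(np.count_nonzero(mask.mask & disk))


def assemble_kinetics(
    series: PlateImageSeries,
    layout: PlateLayout,
    design: ExperimentDesign | None = None,
    *,
    colonies_brighter: bool = True,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Segment every frame and build one :class:`GrowthCurve` per drop.

    When a ``design`` is given, frame days must be a subset of its imaging
    days (duplicates or unknown days raise); imaging days without a frame are
    recorded on each curve's ``missing_days`` rather than silently dropped.
    """
    frame_days = series.days
    if len(set(frame_days)) != len(frame_days):
        raise QuantificationError("duplicate frame day in series")
    missing: list[float] = []
    if design is not None:
        extra = set(frame_days) - set(design.imaging_days)
        if extra:
            raise QuantificationError(
                f"frame days {sorted(extra)} not in design imaging_days"
            )
        missing = sorted(set(design.imaging_days) - set(frame_days))
        if missing:
            logger.warning(
                "plate %s: no frame for imaging days %s", series.plate_id, missing
            )
    per_day_areas: dict[float, dict[str, int]] = {}
    for day, img in series.frames:
        fg = subtract_background(
            img,
            plate_id=series.plate_id,
            day=day,
            colonies_brighter=colonies_brighter,
            seed=seed,
        )
        per_day_areas[day] = {
            d.drop_id: measure_area(fg, layout, d.drop_id) for d in layout.drops
        }
    curves = []
    for d in layout.drops:
        curves.append(
            GrowthCurve(
                drop_id=d.drop_id,
                days=list(frame_days),
                areas=[per_day_areas[day][d.drop_id] for day in frame_days],
                metadata={
                    "plate_id": series.plate_id,
                    "strain": d.strain,
                    "genetic_group": d.genetic_group,
                    "dose": d.dose,
                    "density_class": d.density_class,
                    "replicate": d.replicate,
                    "modality": d.modality,
                    "residence_time_days": d.residence_time_days,
                },
                missing_days=missing,
            )
        )
    return curves


def kinetics_to_frame(curves: list[GrowthCurve]):
    """Long-format DataFrame (one row per drop x day) for CSV export."""
    import pandas as pd

    rows = []
    for c in curves:
        for day, area in c.points:
            rows.append({"drop_id": c.drop_id, **c.metadata, "day": day, "area_px": area})
    return pd.DataFrame(rows)
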