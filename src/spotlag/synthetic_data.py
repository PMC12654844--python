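"""Synthetic plate-image time series with full ground truth.

The generator emulates the plate screen's design so every pipeline stage is
testable without the original photographs: strains follow logistic
growth-area kinetics whose lag extends with cycloheximide dose (through a
log-dose law) and shrinks with inoculum density; plateau area (Amax) is
suppressed dose-dependently; some strains are completely inhibited above a
strain-specific dose.  Frames carry corner fiducials, per-frame geometric
jitter, a linear illumination gradient and additive Gaussian noise.

Colonies are rendered as exact-pixel-count disks: the per-drop foreground
pixel total equals the rounded logistic target area, so on noise-free,
jitter-free frames the quantification stage can recover truth areas exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from spotlag.experiment_model import (
    DENSITY_CLASSES,
    GENETIC_GROUPS,
    STANDARD_DOSES,
    T_HIGH_DEFAULT,
    T_LOW_DEFAULT,
    WINE_MODALITIES,
    DropSpec,
    ExperimentDesign,
    PlateLayout,
)
from spotlag.registration import PlateImageSeries

logger = logging.getLogger(__name__)

#: default imaging schedule (days): every 2-3 days over 20 days of incubation
IMAGING_DAYS_DEFAULT = (3.0, 6.0, 8.0, 10.0, 14.0, 17.0, 20.0)

#: decades of inoculum density above the lowest class
DENSITY_DECADES = {"low": 0.0, "medium": 1.0, "high": 2.0, "undiluted": 3.0}

#: dose scale of the log-dose lag-extension law (g/L)
DOSE_SCALE = 0.005

#: archetype mixture proportions: low tolerance / intermediate / resistant
PROFILE_PROPORTIONS = (0.15, 0.60, 0.25)

#: rendering constants
BACKGROUND_LEVEL = 0.2
FOREGROUND_LEVEL = 0.8
FIDUCIAL_LEVEL = 1.0
FIDUCIAL_RADIUS = 6.0
#: colony counts at or above this are drawn as one merged lawn disk
LAWN_COUNT = 200


def _log_dose(dose: float) -> float:
    return math.log10(1.0 + dose / DOSE_SCALE)


@dataclass(frozen=True)
class StrainModel:
    """Growth-kinetics parameters of one simulated strain.

    ``dose_sensitivity`` is the lag extension (days) per unit log10-dose;
    ``amax_dose_slope`` the fractional Amax reduction at the top dose
    (0.5 g/L); ``density_effect`` the lag reduction (days) per 10x inoculum;
    ``max_inhibitory_dose`` of None means the strain grows at every dose.
    """

    strain_id: str
    genetic_group: str
    base_lag: float
    dose_sensitivity: float
    max_inhibitory_dose: float | None
    amax_base: float
    amax_dose_slope: float
    density_effect: float
    growth_rate: float = 1.4
    archetype: str = "intermediate"

    def __post_init__(self) -> None:
        if self.base_lag <= 0:
            raise ValueError("base_lag must be > 0")
        if not 0 <= self.amax_dose_slope <= 1:
            raise ValueError("amax_dose_slope must be in [0, 1]")
        if self.amax_base <= T_HIGH_DEFAULT:
            raise ValueError("amax_base must exceed the high detection threshold")

    def amax_at(self, dose: float) -> float:
        """Plateau area (px) at a dose; 0 when the dose is fully inhibitory."""
        if self.max_inhibitory_dose is not None and dose >= self.max_inhibitory_dose:
            return 0.0
        return self.amax_base * (1.0 - self.amax_dose_slope * min(dose, 0.5) / 0.5)

    def lag_at(self, dose: float, density_class: str) -> float:
        """Continuous-time detection-threshold crossing (days); inf if never."""
        if self.amax_at(dose) <= 0:
            return math.inf
        decades = DENSITY_DECADES[density_class]
        lag = (
            self.base_lag
            + self.dose_sensitivity * _log_dose(dose)
            - self.density_effect * decades
        )
        return max(lag, 0.05)


def sample_strain_models(
    n: int,
    seed: int,
    proportions: tuple[float, float, float] = PROFILE_PROPORTIONS,
) -> list[StrainModel]:
    """Draw ``n`` strains from the three tolerance-profile archetypes.

    Defaults emulate the screened collection: base lags span 3-8 days, top
    doses suppress Amax by 0-60% depending on archetype, and the archetype
    mix is 15% low-tolerance / 60% intermediate / 25% resistant.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    archetypes = rng.choice(
        ["low_tolerance", "intermediate", "resistant"], size=n, p=props
    )
    models = []
    for i, arch in enumerate(archetypes):
        if arch == "low_tolerance":
            max_inhib = float(rng.choice([0.1, 0.25, 0.5]))
            sens = rng.uniform(2.0, 5.0)
            slope = rng.uniform(0.3, 0.6)
        elif arch == "intermediate":
            max_inhib = None
            sens = rng.uniform(2.0, 5.0)
            slope = rng.uniform(0.3, 0.6)
        else:  # resistant
            max_inhib = None
            sens = rng.uniform(0.0, 0.9)
            slope = rng.uniform(0.0, 0.2)
        models.append(
            StrainModel(
                strain_id=f"S{i:04d}",
                genetic_group=GENETIC_GROUPS[int(rng.integers(len(GENETIC_GROUPS)))],
                base_lag=float(rng.uniform(3.0, 8.0)),
                dose_sensitivity=float(sens),
                max_inhibitory_dose=max_inhib,
                amax_base=float(rng.uniform(1500.0, 3500.0)),
                amax_dose_slope=float(slope),
                density_effect=float(rng.uniform(0.5, 1.5)),
                growth_rate=float(rng.uniform(1.0, 1.8)),
                archetype=str(arch),
            )
        )
    return models


def drop_area_curve(
    model: StrainModel,
    dose: float,
    density_class: str,
    t: "float | np.ndarray",
    thresholds: tuple[float, float] = (T_HIGH_DEFAULT, T_LOW_DEFAULT),
) -> "float | np.ndarray":
    """Expected growth area (px) of a drop at time ``t`` days.

    Logistic in area, anchored so the continuous crossing of the drop's
    detection threshold occurs exactly at ``model.lag_at(dose, density)``:
    A(t) = Amax_d / (1 + exp(-k (t - t_mid))) with
    t_mid = lag + (1/k) ln(Amax_d / T - 1).  Identically zero at fully
    inhibitory doses; when Amax_d never exceeds the threshold the curve
    still rises to Amax_d but the drop stays undetectable.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    amax_d = model.amax_at(dose)
    if amax_d <= 0:
        return np.zeros_like(t) if t.ndim else 0.0
    t_high, t_low = thresholds
    threshold = t_low if density_class == "low" else t_high
    k = model.growth_rate
    lag = model.lag_at(dose, density_class)
    if amax_d > threshold * 1.001:
        t_mid = lag + math.log(amax_d / threshold - 1.0) / k
    else:
        # plateau below the detection threshold: undetectable growth
        t_mid = lag + 3.0 / k
    out = amax_d / (1.0 + np.exp(-k * (t - t_mid)))
    return out if out.ndim else float(out)


def true_lag_on_grid(continuous_lag: float, imaging_days) -> float:
    """First imaging day strictly after the continuous crossing; inf if none."""
    for d in imaging_days:
        if d > continuous_lag:
            return float(d)
    return math.inf


# ---------------------------------------------------------------------------
# wine-stress scenarios

#: added lag (days) at the top dose (0.5 g/L), per modality: (lo, hi) ranges
WINE_LAG_OFFSETS = {
    "original": (0.0, 0.0),
    "pH3.0": (0.0, 1.0),
    "pH3.0+SO2": (2.0, 3.0),
    "SO2": (2.0, 3.0),
    "ethanol14.5": (3.0, 5.0),
}


def make_wine_stress_scenario(
    base_models: list[StrainModel], modality: str, seed: int = 0
) -> list[StrainModel]:
    """Adjust strain models for growth out of a stressed wine sample.

    Each strain receives a modality-specific lag offset at the top dose
    (ethanol 14.5%: +3-5 d; sulfite modalities: +2-3 d; pH 3.0 alone:
    +0-1 d; unmodified wine: +0), scaling down proportionally at lower doses
    through the same log-dose law, so the stress ordering
    ethanol > SO2 > pH3.0 > original holds at every dose.
    """
    if modality not in WINE_MODALITIES:
        raise ValueError(
            f"unknown modality {modality!r}; expected one of {WINE_MODALITIES}"
        )
    lo, hi = WINE_LAG_OFFSETS[modality]
    if hi == 0.0:
        return list(base_models)
    rng = np.random.default_rng(seed)
    scale = _log_dose(0.5)
    out = []
    for m in base_models:
        offset = float(rng.uniform(lo, hi))
        out.append(replace(m, dose_sensitivity=m.dose_sensitivity + offset / scale))
    return out


# ---------------------------------------------------------------------------
# design construction


def make_screen_design(
    models: list[StrainModel],
    doses=STANDARD_DOSES,
    density_classes=("low", "high"),
    replicates: int = 1,
    imaging_days=IMAGING_DAYS_DEFAULT,
    *,
    roi_radius: float = 40.0,
    pitch: float = 90.0,
    grid_cols: int = 8,
    grid_rows: int = 8,
    modality: str = "YPD",
    residence_time_days: int | None = None,
) -> ExperimentDesign:
    """Lay the full strain x dose x density x replicate screen out on plates.

    Drops fill a ``grid_cols x grid_rows`` grid per plate at ``pitch`` px
    spacing (10 px/mm scale); corner fiducial centres define the plate
    corners.  As many plates as needed are created.
    """
    margin = 40.0
    inset = margin + 2 * FIDUCIAL_RADIUS + roi_radius + 10.0
    width = int(2 * inset + (grid_cols - 1) * pitch)
    height = int(2 * inset + (grid_rows - 1) * pitch)
    corners = [
        (margin, margin),
        (width - margin, margin),
        (width - margin, height - margin),
        (margin, height - margin),
    ]
    cells = [
        (m, dose, dc, rep)
        for m in models
        for dose in doses
        for dc in density_classes
        for rep in range(1, replicates + 1)
    ]
    per_plate = grid_cols * grid_rows
    plates = []
    for p_start in range(0, len(cells), per_plate):
        chunk = cells[p_start : p_start + per_plate]
        plate_id = f"P{p_start // per_plate:03d}"
        drops = []
        for i, (m, dose, dc, rep) in enumerate(chunk):
            r, c = divmod(i, grid_cols)
            drops.append(
                DropSpec(
                    drop_id=f"{plate_id}_d{i:03d}",
                    center=(inset + c * pitch, inset + r * pitch),
                    roi_radius=roi_radius,
                    strain=m.strain_id,
                    genetic_group=m.genetic_group,
                    dose=float(dose),
                    density_class=dc,
                    replicate=rep,
                    modality=modality,
                    residence_time_days=residence_time_days,
                )
            )
        plates.append(
            PlateLayout(
                plate_id=plate_id,
                width_px=width,
                height_px=height,
                corners=corners,
                drops=drops,
            )
        )
    return ExperimentDesign(plates=plates, imaging_days=list(imaging_days))


# ---------------------------------------------------------------------------
# rendering


@dataclass
class TruthTable:
    """Ground truth of a rendered experiment.

    ``drops``: one row per drop (true continuous lag, grid lag, true Amax,
    colony count); ``colony_centers``: (plate_id, drop_id) -> (m, 2) array;
    ``jitter``: (plate_id, day) -> 3x3 matrix applied to that frame.
    """

    drops: pd.DataFrame
    colony_centers: dict
    jitter: dict


def _paint_disk_exact(
    frame: np.ndarray, center: tuple[float, float], n_pixels: int, level: float
) -> int:
    """Set exactly ``n_pixels`` pixels nearest to ``center`` to ``level``.

    Ties in distance are broken deterministically (row- then column-order).
    Returns the number of pixels painted (clipped at the frame border).
    """
    if n_pixels <= 0:
        return 0
    h, w = frame.shape
    cx, cy = center
    r = int(math.ceil(math.sqrt(n_pixels / math.pi))) + 3
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    flat_d2 = d2.ravel()
    order = np.lexsort((xx.ravel(), yy.ravel(), flat_d2))
    take = order[: min(n_pixels, order.size)]
    frame[yy.ravel()[take], xx.ravel()[take]] = level
    return take.size


def _place_colonies(
    rng: np.random.Generator,
    drop_center: tuple[float, float],
    roi_radius: float,
    count: int,
    final_total_area: float,
) -> np.ndarray:
    """Colony centres inside the ROI, separated so final disks never overlap.

    Falls back to fewer colonies when the rejection sampler cannot pack the
    requested count (the drop then carries larger colonies, same total area).
    """
    count = max(1, count)
    while count >= 1:
        r_final = math.sqrt(max(final_total_area, 1.0) / (count * math.pi))
        placeable = roi_radius - r_final - 2.0
        if placeable <= 0:
            count = count // 2 if count > 1 else 0
            if count == 0:
                return np.array([[drop_center[0], drop_center[1]]])
            continue
        min_sep = 2.0 * r_final + 2.0
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < count and attempts < 400 * count:
            attempts += 1
            rad = placeable * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            cand = (
                drop_center[0] + rad * math.cos(ang),
                drop_center[1] + rad * math.sin(ang),
            )
            if all(
                math.hypot(cand[0] - x, cand[1] - y) >= min_sep for x, y in centers
            ):
                centers.append(cand)
        if len(centers) == count:
            return np.asarray(centers)
        count = count // 2  # packing failed: merge colonies
    return np.array([[drop_center[0], drop_center[1]]])


def _jitter_matrix(
    rng: np.random.Generator, width: int, height: int
) -> np.ndarray:
    """Random frame jitter: +-5 px translation, +-2 deg rotation about the
    frame centre, and <=1% projective distortion."""
    theta = math.radians(rng.uniform(-2.0, 2.0))
    tx, ty = rng.uniform(-5.0, 5.0, size=2)
    cx, cy = width / 2.0, height / 2.0
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array(
        [
            [c, -s, cx - c * cx + s * cy + tx],
            [s, c, cy - s * cx - c * cy + ty],
            [0, 0, 1.0],
        ]
    )
    proj = np.eye(3)
    proj[2, 0] = rng.uniform(-0.01, 0.01) / max(width, height)
    proj[2, 1] = rng.uniform(-0.01, 0.01) / max(width, height)
    m = rot @ proj
    return m / m[2, 2]


def render_series(
    design: ExperimentDesign,
    models: list[StrainModel],
    seed: int,
    *,
    sigma: float = 0.05,
    jitter: bool = True,
    gradient_amplitude: float = 0.03,
) -> tuple[dict[str, PlateImageSeries], TruthTable]:
    """Render the whole experiment: one frame per plate per imaging day.

    Per frame: colonies drawn as exact-pixel disks so the per-drop total
    matches the logistic target within integer rounding; corner fiducials;
    a per-frame random jitter transform (identity on the reference, i.e.
    last, frame) applied and recorded; a linear illumination gradient and
    additive Gaussian noise (``sigma``).  Bitwise deterministic per seed.
    """
    from skimage import transform as sktf

    rng = np.random.default_rng(seed)
    model_by_strain = {m.strain_id: m for m in models}
    thresholds = (design.t_high, design.t_low)
    truth_rows = []
    colony_centers: dict = {}
    jitter_mats: dict = {}
    series_by_plate: dict[str, PlateImageSeries] = {}

    for plate in design.plates:
        # --- per-drop static truth -------------------------------------
        drop_truth = {}
        for d in plate.drops:
            m = model_by_strain[d.strain]
            count = int(rng.poisson(DENSITY_CLASSES[d.density_class]))
            amax_d = m.amax_at(d.dose)
            capacity = 0.8 * math.pi * d.roi_radius**2
            if amax_d > capacity:
                logger.warning(
                    "drop %s: target Amax %.0f px exceeds ROI capacity; clipped",
                    d.drop_id,
                    amax_d,
                )
                amax_d = capacity
            cont_lag = m.lag_at(d.dose, d.density_class)
            if count >= LAWN_COUNT:
                centers = _lawn_centers(rng, d, count)
            elif count > 0 and amax_d > 0:
                centers = _place_colonies(rng, d.center, d.roi_radius, count, amax_d)
            else:
                centers = np.empty((0, 2))
            drop_truth[d.drop_id] = (m, count, amax_d, cont_lag, centers)
            colony_centers[(plate.plate_id, d.drop_id)] = centers
            truth_rows.append(
                {
                    "plate_id": plate.plate_id,
                    "drop_id": d.drop_id,
                    "strain": d.strain,
                    "genetic_group": d.genetic_group,
                    "dose": d.dose,
                    "density_class": d.density_class,
                    "replicate": d.replicate,
                    "modality": d.modality,
                    "residence_time_days": d.residence_time_days,
                    "true_lag_continuous": cont_lag,
                    "true_lag_grid": true_lag_on_grid(cont_lag, design.imaging_days),
                    # Amax is read at the end of incubation, so its truth is
                    # the expected area on the last imaging day, not the
                    # asymptotic plateau
                    "true_amax_px": (
                        min(
                            float(
                                drop_area_curve(
                                    m,
                                    d.dose,
                                    d.density_class,
                                    design.imaging_days[-1],
                                    thresholds,
                                )
                            ),
                            amax_d,
                        )
                        if count > 0 and amax_d > 0
                        else 0.0
                    ),
                    "plateau_px": amax_d if count > 0 else 0.0,
                    "colony_count": count,
                }
            )

        # --- frames ------------------------------------------------------
        frames = []
        n_days = len(design.imaging_days)
        for i, day in enumerate(design.imaging_days):
            frame = np.full(
                (plate.height_px, plate.width_px), BACKGROUND_LEVEL, dtype=float
            )
            if gradient_amplitude:
                gx = np.linspace(-gradient_amplitude, gradient_amplitude,
                                 plate.width_px)
                frame += gx[None, :]
            for d in plate.drops:
                m, count, amax_d, cont_lag, centers = drop_truth[d.drop_id]
                if count == 0 or amax_d <= 0 or len(centers) == 0:
                    continue
                target = drop_area_curve(m, d.dose, d.density_class, day, thresholds)
                target = min(float(target), amax_d)
                total = int(round(target))
                if total <= 0:
                    continue
                n_col = len(centers)
                base, rem = divmod(total, n_col)
                for j, (cx, cy) in enumerate(centers):
                    n_px = base + (1 if j < rem else 0)
                    _paint_disk_exact(frame, (cx, cy), n_px, FOREGROUND_LEVEL)
            for corner in plate.corners:
                _paint_disk_exact(
                    frame,
                    corner,
                    int(round(math.pi * FIDUCIAL_RADIUS**2)),
                    FIDUCIAL_LEVEL,
                )
            if jitter and i < n_days - 1:
                mat = _jitter_matrix(rng, plate.width_px, plate.height_px)
                frame = sktf.warp(
                    frame,
                    inverse_map=sktf.ProjectiveTransform(
                        matrix=np.linalg.inv(mat)
                    ),
                    order=1,
                    cval=BACKGROUND_LEVEL,
                    mode="constant",
                    preserve_range=True,
                )
            else:
                mat = np.eye(3)
            jitter_mats[(plate.plate_id, day)] = mat
            if sigma > 0:
                frame = frame + rng.normal(0.0, sigma, size=frame.shape)
            frames.append((day, np.clip(frame, 0.0, 1.0)))
        series_by_plate[plate.plate_id] = PlateImageSeries(plate.plate_id, frames)

    truth = TruthTable(
        drops=pd.DataFrame(truth_rows),
        colony_centers=colony_centers,
        jitter=jitter_mats,
    )
    return series_by_plate, truth


def _lawn_centers(rng: np.random.Generator, drop: DropSpec, count: int) -> np.ndarray:
    """Dense drops merge into one lawn disk rendered at the drop centre."""
    return np.array([[drop.center[0], drop.center[1]]])


def save_frames(series_by_plate: dict, out_dir, truth: TruthTable | None = None):
    """Write frames as 8-bit PNGs plus a manifest CSV (and truth.csv if given)."""
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for plate_id, series in series_by_plate.items():
        for day, img in series.frames:
            name = f"{plate_id}_d{day:g}.png"
            iio.imwrite(out / name, (np.clip(img, 0, 1) * 255).astype(np.uint8))
            rows.append({"plate_id": plate_id, "day": day, "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    if truth is not None:
        truth.drops.to_csv(out / "truth.csv", index=False)
    return manifest
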