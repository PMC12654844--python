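"""Experiment design: domain types, layout/config I/O and wine-condition chemistry.

Coordinates are pixel units, origin at the top-left corner, x rightward,
y downward, 0-based.  Plate corners are listed clockwise from top-left and
must form a convex quadrilateral; every drop region of interest (a disk of
``roi_radius`` pixels around the drop centre) must lie strictly inside it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

#: Cycloheximide doses used by the plate screen (g/L).
STANDARD_DOSES = (0.0, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5)

#: Inoculum-density classes -> nominal colonies per 2 uL drop.
DENSITY_CLASSES = {"low": 7, "medium": 75, "high": 750, "undiluted": 5000}

#: Microsatellite/genome-defined subpopulations of B. bruxellensis.
GENETIC_GROUPS = ("A1", "A2", "A3", "Admixed", "Admixed D1/D2", "D1", "D2")

#: Wine modalities emulating oenological stresses.
WINE_MODALITIES = ("original", "pH3.0", "pH3.0+SO2", "SO2", "ethanol14.5")

#: Detection thresholds (pixels): growth area must strictly exceed the
#: threshold for a drop to count as detected.  T_LOW applies to the lowest
#: inoculum-density class, T_HIGH to all others.
T_HIGH_DEFAULT = 500
T_LOW_DEFAULT = 250

#: First dissociation constant of aqueous SO2 at 20 C.
PKA_SO2_WATER_20C = 1.81
#: Ethanol correction (pKa units per %vol), calibrated once against the two
#: printed (free SO2, pH) -> molecular SO2 anchor conditions of the wine
#: assays; see calibrate_pka.
PKA_ETHANOL_SLOPE = 0.0160368


class DesignError(ValueError):
    """Invalid experiment design or plate layout."""


@dataclass(frozen=True)
class DropSpec:
    """One spotted 2-uL drop on a plate, with its assay metadata."""

    drop_id: str
    center: tuple[float, float]
    roi_radius: float
    strain: str
    genetic_group: str = "A1"
    dose: float = 0.0
    density_class: str = "low"
    replicate: int = 1
    modality: str = "YPD"
    residence_time_days: int | None = None

    def __post_init__(self) -> None:
        if self.roi_radius <= 0:
            raise DesignError(f"drop {self.drop_id}: roi_radius must be > 0")
        if self.dose < 0:
            raise DesignError(f"drop {self.drop_id}: dose must be >= 0")
        if self.density_class not in DENSITY_CLASSES:
            raise DesignError(
                f"drop {self.drop_id}: unknown density_class {self.density_class!r}"
            )
        if not 1 <= int(self.replicate) <= 3:
            raise DesignError(f"drop {self.drop_id}: replicate must be 1..3")


def _signed_area(corners: list[tuple[float, float]]) -> float:
    x = [c[0] for c in corners]
    y = [c[1] for c in corners]
    n = len(corners)
    return 0.5 * sum(x[i] * y[(i + 1) % n] - x[(i + 1) % n] * y[i] for i in range(n))


def _is_convex(corners: list[tuple[float, float]]) -> bool:
    # all cross products of consecutive edges must share a sign
    n = len(corners)
    signs = set()
    for i in range(n):
        ax, ay = corners[i]
        bx, by = corners[(i + 1) % n]
        cx, cy = corners[(i + 2) % n]
        cross = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if cross != 0:
            signs.add(cross > 0)
    return len(signs) == 1


def point_in_convex_quad(
    point: tuple[float, float], corners: list[tuple[float, float]], margin: float = 0.0
) -> bool:
    """True if ``point`` lies at least ``margin`` inside the convex polygon."""
    n = len(corners)
    orient = 1.0 if _signed_area(corners) > 0 else -1.0
    px, py = point
    for i in range(n):
        ax, ay = corners[i]
        bx, by = corners[(i + 1) % n]
        ex, ey = bx - ax, by - ay
        norm = math.hypot(ex, ey)
        if norm == 0:
            return False
        # signed distance of point to edge, positive towards the interior
        d = orient * ((ex) * (py - ay) - (ey) * (px - ax)) / norm
        if d < margin:
            return False
    return True


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of one plate: corner anchors and the drop-position template."""

    plate_id: str
    width_px: int
    height_px: int
    corners: list[tuple[float, float]]
    drops: list[DropSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.corners) != 4:
            raise DesignError(f"plate {self.plate_id}: exactly 4 corners required")
        if abs(_signed_area(self.corners)) <= 0 or not _is_convex(self.corners):
            raise DesignError(
                f"plate {self.plate_id}: corners must form a convex quadrilateral"
            )
        seen: set[str] = set()
        for d in self.drops:
            if d.drop_id in seen:
                raise DesignError(
                    f"plate {self.plate_id}: duplicate drop_id {d.drop_id!r}"
                )
            seen.add(d.drop_id)
            if not point_in_convex_quad(d.center, self.corners, margin=d.roi_radius):
                raise DesignError(
                    f"plate {self.plate_id}: drop {d.drop_id} ROI not inside corners"
                )
        for i, a in enumerate(self.drops):
            for b in self.drops[i + 1 :]:
                dist = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if dist < a.roi_radius + b.roi_radius:
                    raise DesignError(
                        f"plate {self.plate_id}: ROIs of {a.drop_id} and "
                        f"{b.drop_id} overlap"
                    )

    def drop(self, drop_id: str) -> DropSpec:
        for d in self.drops:
            if d.drop_id == drop_id:
                return d
        raise KeyError(f"unknown drop_id {drop_id!r} on plate {self.plate_id}")


@dataclass(frozen=True)
class WineCondition:
    """One oenological stress condition, characterised by its molecular SO2.

    molecular_so2 is derived from (free_so2, pH, temperature, ethanol) via
    the first dissociation equilibrium of SO2 and is filled in automatically.
    """

    label: str
    pH: float
    free_so2: float
    ethanol: float
    temperature: float = 20.0
    molecular_so2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.pH < 14:
            raise DesignError(f"condition {self.label}: pH out of (0, 14)")
        if self.free_so2 < 0:
            raise DesignError(f"condition {self.label}: free_so2 must be >= 0")
        mso2 = compute_molecular_so2(
            self.free_so2, self.pH, self.temperature, self.ethanol
        )
        object.__setattr__(self, "molecular_so2", mso2)
        if self.label not in WINE_MODALITIES:
            logger.warning("unknown wine modality label %r", self.label)


@dataclass(frozen=True)
class ExperimentDesign:
    """Plates, imaging schedule, detection thresholds and wine conditions."""

    plates: list[PlateLayout]
    imaging_days: list[float]
    t_high: float = T_HIGH_DEFAULT
    t_low: float = T_LOW_DEFAULT
    conditions: list[WineCondition] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = list(self.imaging_days)
        if not days:
            raise DesignError("imaging_days must be non-empty")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DesignError("imaging_days must be strictly increasing")
        if max(days) > 30:
            raise DesignError("imaging_days must not exceed 30 days")
        if not self.t_high > self.t_low > 0:
            raise DesignError("thresholds must satisfy t_high > t_low > 0")
        seen: set[str] = set()
        for p in self.plates:
            if p.plate_id in seen:
                raise DesignError(f"duplicate plate_id {p.plate_id!r}")
            seen.add(p.plate_id)

    def plate(self, plate_id: str) -> PlateLayout:
        for p in self.plates:
            if p.plate_id == plate_id:
                return p
        raise KeyError(f"unknown plate_id {plate_id!r}")

    def threshold_for(self, density_class: str) -> float:
        """Detection threshold: t_low for the lowest density class, else t_high."""
        return self.t_low if density_class == "low" else self.t_high

    def all_drops(self):
        for p in self.plates:
            for d in p.drops:
                yield p.plate_id, d


# ---------------------------------------------------------------------------
# molecular SO2


def pka_eff(temperature: float = 20.0, ethanol: float = 0.0) -> float:
    """Effective first pKa of SO2, corrected for ethanol content.

    pKa_eff = pKa_water(T) + beta * ethanol.  Within the 20 C assay range the
    temperature dependence of pKa1 is negligible against the ethanol term and
    pKa_water is held at its 20 C value; beta is calibrated against the two
    printed wine-condition anchors (see :func:`calibrate_pka`).
    """
    return PKA_SO2_WATER_20C + PKA_ETHANOL_SLOPE * ethanol


def compute_molecular_so2(
    free_so2: float, pH: float, temperature: float = 20.0, ethanol: float = 0.0
) -> float:
    """Molecular (undissociated, biologically active) SO2 from free SO2.

    Henderson-Hasselbalch on the first dissociation:
    mSO2 = free_so2 / (1 + 10**(pH - pKa_eff)).

    Parameters
    ----------
    free_so2 : mg/L free SO2 (>= 0)
    pH : must lie in (0, 14)
    temperature : C
    ethanol : % vol

    Returns
    -------
    mg/L molecular SO2, in [0, free_so2].
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} out of (0, 14)")
    if free_so2 < 0:
        raise ValueError("free_so2 must be >= 0")
    return free_so2 / (1.0 + 10.0 ** (pH - pka_eff(temperature, ethanol)))


def calibrate_pka(
    anchors: list[tuple[float, float, float]],
) -> tuple[float, list[float]]:
    """Calibrate a single shared pKa_eff from (free_so2, pH, molecular_so2) anchors.

    Returns ``(pka_shared, pka_per_anchor)``: the shared value minimises the
    summed squared relative error over all anchors; the per-anchor values are
    exact 1-D roots and serve as a consistency check (they should agree
    closely if one equilibrium constant explains every anchor).
    """
    from scipy.optimize import brentq, minimize_scalar

    def model(free, ph, pka):
        return free / (1.0 + 10.0 ** (ph - pka))

    per_anchor = [
        float(brentq(lambda p: model(f, ph, p) - target, -2.0, 10.0))
        for f, ph, target in anchors
    ]

    def objective(p: float) -> float:
        return sum(
            ((model(f, ph, p) - target) / target) ** 2 for f, ph, target in anchors
        )

    res = minimize_scalar(
        objective,
        bounds=(min(per_anchor) - 1.0, max(per_anchor) + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), per_anchor


# ---------------------------------------------------------------------------
# design I/O (YAML)


def _layout_to_dict(p: PlateLayout) -> dict:
    return {
        "plate_id": p.plate_id,
        "width_px": p.width_px,
        "height_px": p.height_px,
        "corners": [list(map(float, c)) for c in p.corners],
        "drops": [
            {
                "drop_id": d.drop_id,
                "center": list(map(float, d.center)),
                "roi_radius": float(d.roi_radius),
                "strain": d.strain,
                "genetic_group": d.genetic_group,
                "dose": float(d.dose),
                "density_class": d.density_class,
                "replicate": int(d.replicate),
                "modality": d.modality,
                "residence_time_days": d.residence_time_days,
            }
            for d in p.drops
        ],
    }


def _layout_from_dict(obj: dict) -> PlateLayout:
    try:
        drops = [
            DropSpec(
                drop_id=str(d["drop_id"]),
                center=tuple(float(v) for v in d["center"]),
                roi_radius=float(d["roi_radius"]),
                strain=str(d["strain"]),
                genetic_group=str(d.get("genetic_group", "A1")),
                dose=float(d.get("dose", 0.0)),
                density_class=str(d.get("density_class", "low")),
                replicate=int(d.get("replicate", 1)),
                modality=str(d.get("modality", "YPD")),
                residence_time_days=d.get("residence_time_days"),
            )
            for d in obj.get("drops", [])
        ]
        return PlateLayout(
            plate_id=str(obj["plate_id"]),
            width_px=int(obj["width_px"]),
            height_px=int(obj["height_px"]),
            corners=[tuple(float(v) for v in c) for c in obj["corners"]],
            drops=drops,
        )
    except KeyError as exc:
        raise DesignError(f"plate config missing key {exc}") from exc


def load_design(path) -> ExperimentDesign:
    """Load and validate an :class:`ExperimentDesign` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            obj = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise DesignError(f"cannot parse design file {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise DesignError(f"design file {path} must hold a mapping")
    try:
        plates = [_layout_from_dict(p) for p in obj.get("plates", [])]
        conditions = [
            WineCondition(
                label=str(c["label"]),
                pH=float(c["pH"]),
                free_so2=float(c.get("free_so2", 0.0)),
                ethanol=float(c.get("ethanol", 0.0)),
                temperature=float(c.get("temperature", 20.0)),
            )
            for c in obj.get("conditions", [])
        ]
        return ExperimentDesign(
            plates=plates,
            imaging_days=[float(d) for d in obj["imaging_days"]],
            t_high=float(obj.get("t_high", T_HIGH_DEFAULT)),
            t_low=float(obj.get("t_low", T_LOW_DEFAULT)),
            conditions=conditions,
        )
    except KeyError as exc:
        raise DesignError(f"design file {path} missing key {exc}") from exc


def save_design(design: ExperimentDesign, path) -> None:
    """Write a design back to YAML (inverse of :func:`load_design`)."""
    obj = {
        "imaging_days": [float(d) for d in design.imaging_days],
        "t_high": float(design.t_high),
        "t_low": float(design.t_low),
        "plates": [_layout_to_dict(p) for p in design.plates],
        "conditions": [
            {
                "label": c.label,
                "pH": float(c.pH),
                "free_so2": float(c.free_so2),
                "ethanol": float(c.ethanol),
                "temperature": float(c.temperature),
            }
            for c in design.conditions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
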