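"""Phenotype extraction from growth curves.

Phenotypes mirror the plate assay's readouts:

* **lag phase** — the first imaging day on which a drop's growth area
  strictly exceeds its detection threshold (250 px for the lowest inoculum
  density, 500 px otherwise); drops that never cross are right-censored at
  the last imaging day and carried as explicit ``>D`` values.
* **Amax** — the maximum growth area reached over the incubation.
* **normalized lag** — lag minus the lag of the matched no-drug control of
  the same strain (and, for wine-grown samples, the same residence time in
  the unmodified wine).
* **tolerance profile** — low-tolerance / intermediate / resistant, from the
  full dose response of a strain.

Lag values live on the discrete imaging grid: the assay reads plates every
2-3 days, so no interpolation between days is attempted.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import numpy as np

from spotlag.quantification import GrowthCurve

logger = logging.getLogger(__name__)

PROFILE_CLASSES = ("low_tolerance", "intermediate", "resistant")


class PairingError(ValueError):
    """Record/control pair does not share the required keys."""


@dataclass(frozen=True, order=False)
class Lag:
    """A lag phase in days, possibly right-censored (``>day``)."""

    day: float
    censored: bool = False

    def __str__(self) -> str:
        v = f"{self.day:g}"
        return f">{v}" if self.censored else v

    @classmethod
    def parse(cls, text: str) -> "Lag":
        text = str(text).strip()
        if text.startswith(">"):
            return cls(float(text[1:]), censored=True)
        return cls(float(text))

    def __sub__(self, other: "Lag"):
        if other.censored:
            return None  # difference against a censored control is undefined
        return Lag(self.day - other.day, censored=self.censored)


@dataclass
class PhenotypeRecord:
    """Phenotypes of one drop (strain x dose x density x modality x replicate)."""

    drop_id: str
    strain: str
    dose: float
    density_class: str
    replicate: int = 1
    genetic_group: str = "A1"
    modality: str = "YPD"
    residence_time_days: int | None = None
    lag: Lag | None = None
    amax_px: int = 0
    normalized_lag: Lag | None = None
    profile: str | None = None


@dataclass
class LagDistribution:
    """Lag-class counts per (genetic_group, dose), censored records in their own bin."""

    bin_edges: list[float]
    table: "object"  # pandas DataFrame: group keys, lag_class, count, fraction


def extract_lag(
    curve: GrowthCurve, thresholds: tuple[float, float] = (500.0, 250.0)
) -> Lag:
    """First imaging day whose area strictly exceeds the detection threshold.

    ``thresholds = (T_high, T_low)``; T_low applies to the lowest inoculum
    density class, T_high to every other class.  A curve that never crosses
    is censored at its last imaging day.
    """
    if not curve.days:
        raise ValueError("empty growth curve")
    t_high, t_low = thresholds
    density = curve.metadata.get("density_class", "low")
    threshold = t_low if density == "low" else t_high
    for day, area in curve.points:
        if area > threshold:
            return Lag(day)
    return Lag(curve.days[-1], censored=True)


def extract_amax(curve: GrowthCurve) -> int:
    """Maximum growth area over the whole series (last frame for monotone curves)."""
    if not curve.areas:
        raise ValueError("empty growth curve")
    return int(max(curve.areas))


def normalize_lag(record: PhenotypeRecord, control: PhenotypeRecord) -> Lag | None:
    """Lag of ``record`` minus the lag of its matched no-drug control.

    For YPD-grown samples the control is the same strain at dose 0; for
    wine-grown samples it is the same strain after the same residence time in
    the unmodified wine, plated without cycloheximide.  A censored record
    yields a censored difference; a censored control makes the normalized
    lag undefined (``None``) with a warning.
    """
    if record.strain != control.strain:
        raise PairingError("record and control must share strain")
    if control.dose != 0:
        raise PairingError("control must be the dose-0 condition")
    wine_mode = record.modality != "YPD"
    if wine_mode:
        if record.residence_time_days != control.residence_time_days:
            raise PairingError("wine-mode control must share residence_time_days")
        if control.modality not in ("original", "YPD"):
            raise PairingError("wine-mode control must come from the unmodified wine")
    if record.lag is None or control.lag is None:
        raise PairingError("both records need an extracted lag")
    diff = record.lag - control.lag
    if diff is None:
        logger.warning(
            "strain %s: control lag censored (%s); normalized lag undefined",
            record.strain,
            control.lag,
        )
    return diff


def classify_profile(
    curves_by_dose: dict[float, GrowthCurve],
    thresholds: tuple[float, float] = (500.0, 250.0),
    *,
    r_max_days: float = 2.0,
    amax_ratio_min: float = 0.8,
) -> str:
    """Assign a strain's tolerance profile from its full dose response.

    * ``low_tolerance`` — growth completely inhibited (censored lag) at one
      or more tested doses;
    * ``resistant`` — lag extension at the highest dose at most
      ``r_max_days`` and Amax at the highest dose at least
      ``amax_ratio_min`` of the no-drug Amax;
    * ``intermediate`` — everything else (growth at all doses but clearly
      delayed or reduced).
    """
    doses = sorted(curves_by_dose)
    if len(doses) < 3 or 0.0 not in curves_by_dose:
        raise PairingError("need curves for >=3 doses including dose 0")
    lags = {d: extract_lag(curves_by_dose[d], thresholds) for d in doses}
    if any(lag.censored for lag in lags.values()):
        return "low_tolerance"
    top = doses[-1]
    delay = lags[top].day - lags[0.0].day
    amax0 = extract_amax(curves_by_dose[0.0])
    ratio = extract_amax(curves_by_dose[top]) / amax0 if amax0 > 0 else 0.0
    if delay <= r_max_days and ratio >= amax_ratio_min:
        return "resistant"
    return "intermediate"


def summarize_lag_distribution(
    records: list[PhenotypeRecord], bin_edges: list[float]
) -> LagDistribution:
    """Histogram of lag classes per (genetic_group, dose) with a censored bin.

    ``bin_edges`` delimit half-open day classes ``[e_i, e_{i+1})``; observed
    lags outside the edges fall into the flanking open classes.  Fractions
    sum to 1 within every group x dose cell.
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to summarize")
    edges = sorted(bin_edges)
    labels = (
        [f"<{edges[0]:g}"]
        + [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
        + [f">={edges[-1]:g}", "censored"]
    )
    rows = []
    for r in records:
        if r.lag is None:
            continue
        if r.lag.censored:
            cls = "censored"
        else:
            cls = labels[int(np.searchsorted(edges, r.lag.day, side="right"))]
        rows.append(
            {"genetic_group": r.genetic_group, "dose": r.dose, "lag_class": cls}
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["genetic_group", "dose", "lag_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["fraction"] = counts["count"] / counts.groupby(
        ["genetic_group", "dose"], observed=True
    )["count"].transform("sum")
    return LagDistribution(bin_edges=edges, table=counts)


def curves_to_records(
    curves: list[GrowthCurve], thresholds: tuple[float, float] = (500.0, 250.0)
) -> list[PhenotypeRecord]:
    """Extract lag and Amax for every curve, carrying the drop metadata along."""
    records = []
    for c in curves:
        m = c.metadata
        records.append(
            PhenotypeRecord(
                drop_id=c.drop_id,
                strain=m.get("strain", "unknown"),
                dose=float(m.get("dose", 0.0)),
                density_class=m.get("density_class", "low"),
                replicate=int(m.get("replicate", 1)),
                genetic_group=m.get("genetic_group", "A1"),
                modality=m.get("modality", "YPD"),
                residence_time_days=m.get("residence_time_days"),
                lag=extract_lag(c, thresholds),
                amax_px=extract_amax(c),
            )
        )
    return records


def _control_key(r: PhenotypeRecord, wine_mode: bool):
    if wine_mode:
        return (r.strain, r.residence_time_days, r.density_class)
    return (r.strain, r.density_class, r.replicate)


def attach_normalized_lags(records: list[PhenotypeRecord]) -> list[PhenotypeRecord]:
    """Fill ``normalized_lag`` on every record by pairing with its dose-0 control.

    YPD mode pairs on (strain, density_class, replicate); wine mode pairs on
    (strain, residence_time, density_class) against the unmodified-wine
    control, summarizing control replicates by their median observed lag.
    Records without a matching control keep ``normalized_lag = None``.
    """
    out = []
    controls: dict = {}
    for r in records:
        if r.dose == 0 and r.modality in ("YPD", "original"):
            controls.setdefault(_control_key(r, r.modality != "YPD"), []).append(r)
    for r in records:
        wine_mode = r.modality != "YPD"
        group = controls.get(_control_key(r, wine_mode))
        if not group:
            logger.warning("no dose-0 control for %s; lag not normalized", r.drop_id)
            out.append(r)
            continue
        ctrl = _median_control(group)
        out.append(replace_normalized(r, ctrl))
    return out


def _median_control(group: list[PhenotypeRecord]) -> PhenotypeRecord:
    observed = [r for r in group if r.lag is not None and not r.lag.censored]
    if not observed:
        return group[0]  # all controls censored -> normalization undefined
    med = statistics.median(r.lag.day for r in observed)
    proto = observed[0]
    out = PhenotypeRecord(**{**proto.__dict__})
    out.lag = Lag(med)
    return out


def replace_normalized(r: PhenotypeRecord, ctrl: PhenotypeRecord) -> PhenotypeRecord:
    out = PhenotypeRecord(**{**r.__dict__})
    out.normalized_lag = normalize_lag(r, ctrl)
    return out


def summarize_replicates(records: list[PhenotypeRecord]) -> list[PhenotypeRecord]:
    """Collapse replicates to one record per condition (median lag and Amax).

    Replicates disagreeing by more than one imaging interval on the lag are
    flagged in the log but still summarized.  Censored replicates are
    excluded from the median unless all replicates are censored.
    """
    groups: dict = {}
    for r in records:
        key = (r.strain, r.dose, r.density_class, r.modality, r.residence_time_days)
        groups.setdefault(key, []).append(r)
    out = []
    for key, group in groups.items():
        observed = [r for r in group if r.lag is not None and not r.lag.censored]
        proto = PhenotypeRecord(**{**group[0].__dict__})
        proto.replicate = 0  # summary row
        proto.amax_px = int(statistics.median(r.amax_px for r in group))
        if observed:
            days = [r.lag.day for r in observed]
            if max(days) - min(days) > _max_imaging_interval(days):
                logger.warning("replicates disagree on lag for %s: %s", key, days)
            proto.lag = Lag(statistics.median(days))
        else:
            proto.lag = group[0].lag
        norm = [
            r.normalized_lag.day
            for r in group
            if r.normalized_lag is not None and not r.normalized_lag.censored
        ]
        proto.normalized_lag = Lag(statistics.median(norm)) if norm else None
        out.append(proto)
    return out


def _max_imaging_interval(days: list[float]) -> float:
    # the assay images every 2-3 days; one interval is at most 4 days
    return 4.0


def records_to_frame(records: list[PhenotypeRecord]):
    """Flat DataFrame for CSV export (lags as text, censored flag explicit)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "drop_id": r.drop_id,
                "strain": r.strain,
                "genetic_group": r.genetic_group,
                "dose": r.dose,
                "density_class": r.density_class,
                "replicate": r.replicate,
                "modality": r.modality,
                "residence_time_days": r.residence_time_days,
                "lag_days": str(r.lag) if r.lag is not None else "",
                "lag_censored": bool(r.lag.censored) if r.lag is not None else "",
                "amax_px": r.amax_px,
                "normalized_lag_days": (
                    str(r.normalized_lag) if r.normalized_lag is not None else ""
                ),
                "profile": r.profile or "",
            }
        )
    return pd.DataFrame(rows)
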