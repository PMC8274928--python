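"""Per-sample processing: replicate diameters -> areas -> fitted curves.

Each vessel sample is measured on a rising pressure grid (the standard
protocol uses 15, 30, 45, 60, 80, 100, 125, 200, 250 and 300 mmHg); at each
pressure three replicate inner-diameter readings are taken. Replicates are
averaged at the diameter level, the mean diameter is converted to a lumen
area under a circular-lumen assumption, and the resulting pressure-area
series is fitted with the arctangent model. A sample that ruptured before
the top grid pressure keeps its surviving points and carries the rupture
pressure as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .model import FitResult, SummaryMetrics

__all__ = [
    "PAPER_PRESSURE_GRID",
    "TESTABLE_LOCATIONS",
    "ALL_LOCATIONS",
    "PressureDiameterRecord",
    "PressureAreaSeries",
    "mean_diameter",
    "diameter_to_area",
    "build_series",
    "series_from_table",
    "fit_series",
    "process_dataset",
    "empirical_compliance",
    "empirical_distensibility",
]

#: The protocol's 10-point static pressure grid, mmHg.
PAPER_PRESSURE_GRID = (15.0, 30.0, 45.0, 60.0, 80.0, 100.0, 125.0, 200.0, 250.0, 300.0)

#: Canonical vessel locations; the first four were mechanically tested.
TESTABLE_LOCATIONS = (
    "proximal_aorta",
    "distal_aorta",
    "common_carotid",
    "external_iliac",
)
ALL_LOCATIONS = TESTABLE_LOCATIONS + ("cranial_carotid", "femoral", "median")


@dataclass(frozen=True)
class PressureDiameterRecord:
    """One pressure step of one sample: triplicate inner-diameter readings."""

    sample_id: str
    horse_id: str
    age_group: str  # "young" | "old"
    location: str
    pressure: float  # mmHg
    diameters: tuple[float, ...]  # replicate inner diameters, mm

    def __post_init__(self) -> None:
        if self.age_group not in ("young", "old"):
            raise ValidationError(f"unknown age group {self.age_group!r}")
        if len(self.diameters) == 0:
            raise ValidationError("at least one replicate diameter required")
        if any((not np.isfinite(d)) or d <= 0 for d in self.diameters):
            raise ValidationError(
                f"non-positive diameter in sample {self.sample_id} "
                f"at {self.pressure} mmHg: {self.diameters}"
            )
        if not (np.isfinite(self.pressure) and self.pressure > 0):
            raise ValidationError(f"invalid pressure {self.pressure}")


@dataclass(frozen=True)
class PressureAreaSeries:
    """Ordered pressure grid with one mean lumen area per pressure."""

    sample_id: str
    pressures: tuple[float, ...]  # mmHg, strictly increasing
    areas: tuple[float, ...]  # mm^2
    truncated_at: float | None = None  # rupture pressure, mmHg
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.pressures) != len(self.areas) or len(self.pressures) < 1:
            raise ValidationError("pressures/areas must be equal-length, non-empty")
        p = np.asarray(self.pressures)
        if np.any(np.diff(p) <= 0):
            raise ValidationError("pressures must be strictly increasing")
        if any(a <= 0 for a in self.areas):
            raise ValidationError("areas must be positive")


def mean_diameter(record: PressureDiameterRecord) -> float:
    """Arithmetic mean of the replicate inner diameters, mm."""
    return float(np.mean(record.diameters))


def diameter_to_area(diameter: float) -> float:
    """Lumen cross-sectional area from inner diameter, circular assumption.

    area = pi * (d/2)^2, mm^2.
    """
    if not (np.isfinite(diameter) and diameter > 0):
        raise ValidationError(f"diameter must be positive, got {diameter}")
    return math.pi * (diameter / 2.0) ** 2


def build_series(
    records: list[PressureDiameterRecord],
    *,
    ruptured: bool = False,
    full_grid_top: float = PAPER_PRESSURE_GRID[-1],
) -> PressureAreaSeries:
    """Assemble one sample's pressure-area series from its pressure records.

    Replicates are averaged at the diameter level before the circular
    conversion to area. When ``ruptured`` is set and the grid stops short
    of ``full_grid_top``, the last completed pressure is recorded as
    ``truncated_at``; the rupture event itself contributes no data point.
    """
    if not records:
        raise ValidationError("no records")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValidationError(f"records span multiple samples: {sorted(sample_ids)}")
    recs = sorted(records, key=lambda r: r.pressure)
    pressures = [r.pressure for r in recs]
    if len(set(pressures)) != len(pressures):
        raise ValidationError(
            f"duplicate pressures for sample {recs[0].sample_id}: {pressures}"
        )
    areas = [diameter_to_area(mean_diameter(r)) for r in recs]
    truncated_at = None
    if ruptured and pressures[-1] < full_grid_top:
        truncated_at = pressures[-1]
    first = recs[0]
    return PressureAreaSeries(
        sample_id=first.sample_id,
        pressures=tuple(pressures),
        areas=tuple(areas),
        truncated_at=truncated_at,
        meta={
            "horse_id": first.horse_id,
            "age_group": first.age_group,
            "location": first.location,
        },
    )


def series_from_table(table: pd.DataFrame) -> list[PressureAreaSeries]:
    """Group a long-format record table into per-sample series.

    Expects columns sample_id, horse_id, age_group, location, pressure_mmHg,
    replicate_index, diameter_mm and an optional boolean ``ruptured`` column.
    """
    required = {
        "sample_id",
        "horse_id",
        "age_group",
        "location",
        "pressure_mmHg",
        "diameter_mm",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    out = []
    for sample_id, g in table.groupby("sample_id", sort=True):
        records = []
        for pressure, gp in g.groupby("pressure_mmHg"):
            records.append(
                PressureDiameterRecord(
                    sample_id=str(sample_id),
                    horse_id=str(gp["horse_id"].iloc[0]),
                    age_group=str(gp["age_group"].iloc[0]),
                    location=str(gp["location"].iloc[0]),
                    pressure=float(pressure),
                    diameters=tuple(float(d) for d in gp["diameter_mm"]),
                )
            )
        ruptured = bool(g["ruptured"].any()) if "ruptured" in g.columns else False
        out.append(build_series(records, ruptured=ruptured))
    return out


def fit_series(series: PressureAreaSeries, *, min_points: int = model.MIN_FIT_POINTS) -> FitResult:
    """Fit the arctangent model to one sample's series."""
    return model.fit_arctangent(series.pressures, series.areas, min_points=min_points)


def process_dataset(
    table: pd.DataFrame,
    *,
    pressure_range: tuple[float, float] = (15.0, 300.0),
    min_points: int = model.MIN_FIT_POINTS,
) -> pd.DataFrame:
    """Fit every sample in a long-format measurement table.

    Returns one row per sample with the fitted parameters, fit quality and
    summary metrics. Samples that cannot be fitted (too few surviving
    pressure points, degenerate areas) are kept in the output with a
    ``fit_status`` explaining why, never dropped silently.
    """
    if table is None or len(table) == 0:
        raise ValidationError("empty measurement table")
    rows = []
    for series in series_from_table(table):
        row = {
            "sample_id": series.sample_id,
            "horse_id": series.meta.get("horse_id"),
            "age_group": series.meta.get("age_group"),
            "location": series.meta.get("location"),
            "n_pressures": len(series.pressures),
            "max_measured_area_mm2": max(series.areas),
            "truncated_at": series.truncated_at,
        }
        try:
            fit = fit_series(series, min_points=min_points)
        except InsufficientDataError as e:
            row.update(fit_status=f"insufficient_data: {e}")
        except DegenerateDataError as e:
            row.update(fit_status=f"degenerate: {e}")
        else:
            sm = model.summary_metrics(fit.params, pressure_range)
            row.update(
                Am_mm2=fit.params.Am,
                P0_mmHg=fit.params.P0,
                P1_mmHg=fit.params.P1,
                rss=fit.rss,
                r_squared=fit.r_squared,
                max_compliance=sm.max_compliance,
                p_at_max_compliance=sm.pressure_at_max_compliance,
                max_distensibility=sm.max_distensibility,
                p_at_max_distensibility=sm.pressure_at_max_distensibility,
                fit_status="ok" if fit.converged else "not_converged",
            )
        rows.append(row)
    cols = [
        "sample_id", "horse_id", "age_group", "location", "n_pressures",
        "Am_mm2", "P0_mmHg", "P1_mmHg", "rss", "r_squared",
        "max_measured_area_mm2", "max_compliance", "p_at_max_compliance",
        "max_distensibility", "p_at_max_distensibility",
        "truncated_at", "fit_status",
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def empirical_compliance(series: PressureAreaSeries) -> pd.DataFrame:
    """Finite-difference compliance of one series at interval midpoints.

    For consecutive grid points the slope (A_{i+1}-A_i)/(P_{i+1}-P_i) is
    assigned to the midpoint pressure; the empirical distensibility divides
    that slope by the midpoint-interpolated area.
    """
    if len(series.pressures) < 2:
        raise ValidationError("need at least 2 points for finite differences")
    P = np.asarray(series.pressures)
    A = np.asarray(series.areas)
    dP = np.diff(P)
    dA = np.diff(A)
    mid_p = (P[:-1] + P[1:]) / 2.0
    mid_a = (A[:-1] + A[1:]) / 2.0
    comp = dA / dP
    return pd.DataFrame(
        {
            "sample_id": series.sample_id,
            "pressure_mmHg": mid_p,
            "compliance": comp,
            "distensibility": comp / mid_a,
            "mid_area_mm2": mid_a,
        }
    )


def empirical_distensibility(series: PressureAreaSeries) -> pd.DataFrame:
    """Alias view of :func:`empirical_compliance` keyed on distensibility."""
    return empirical_compliance(series)
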