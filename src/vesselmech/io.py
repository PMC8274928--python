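"""CSV parsing/serialization, run configuration and report assembly.

Canonical interchange is long-format UTF-8 CSV with a header row:

* inflation measurements — one row per sample x pressure x replicate,
  columns ``sample_id, horse_id, age_group, location, pressure_mmHg,
  replicate_index, diameter_mm`` (optional boolean ``ruptured``);
* histology — one row per slide layer x stain x frame, columns
  ``horse_id, age_group, location, layer, stain, frame_index, area_pct,
  thickness_um``.

Validation failures raise :class:`~vesselmech.errors.ParseError` naming the
offending row and column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

log = logging.getLogger("vesselmech")

INFLATION_COLUMNS = [
    "sample_id", "horse_id", "age_group", "location",
    "pressure_mmHg", "replicate_index", "diameter_mm",
]
HISTOLOGY_COLUMNS = [
    "horse_id", "age_group", "location", "layer", "stain",
    "frame_index", "area_pct", "thickness_um",
]


@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML-loadable)."""

    inflation_csv: str | None = None
    histology_csv: str | None = None
    output_dir: str = "results"
    alpha: float = 0.05
    pressure_range: tuple[float, float] = (15.0, 300.0)
    min_fit_points: int = 5
    seed: int = 0
    curve_kinds: tuple[str, ...] = ("area", "compliance", "distensibility")
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        lo, hi = self.pressure_range
        if not lo < hi:
            raise ValidationError(f"pressure range must be ordered, got {lo}..{hi}")
        if self.min_fit_points < 4:
            raise ValidationError("min_fit_points must be >= 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pressure_range" in raw:
            raw["pressure_range"] = tuple(raw["pressure_range"])
        if "curve_kinds" in raw:
            raw["curve_kinds"] = tuple(raw["curve_kinds"])
        return cls(**raw)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, column: str, path, *, positive=False,
                   lo=None, hi=None, allow_nan=False) -> pd.Series:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() & df[column].notna() if allow_nan else vals.isna()
    if not allow_nan:
        bad |= ~np.isfinite(vals.fillna(np.nan))
    if positive:
        bad |= vals <= 0
    if lo is not None:
        bad |= vals < lo
    if hi is not None:
        bad |= vals > hi
    if allow_nan:
        bad &= df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ParseError(
            f"{path}: invalid value in column '{column}' at row {row}: "
            f"{df.loc[bad.idxmax(), column]!r}"
        )
    return vals


def read_inflation_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format inflation measurement table."""
    df = _read_csv(path)
    _require_columns(df, INFLATION_COLUMNS, path)
    df["pressure_mmHg"] = _check_numeric(df, "pressure_mmHg", path, positive=True)
    df["diameter_mm"] = _check_numeric(df, "diameter_mm", path, positive=True)
    bad_age = ~df["age_group"].isin(["young", "old"])
    if bad_age.any():
        row = int(bad_age.idxmax()) + 2
        raise ParseError(
            f"{path}: unknown age_group at row {row}: "
            f"{df.loc[bad_age.idxmax(), 'age_group']!r}"
        )
    if "ruptured" not in df.columns:
        df["ruptured"] = False
    return df


def write_inflation_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_histology_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format histology frame table.

    Out-of-range area% (outside [0,100]) is rejected at parse time, not
    clipped.
    """
    df = _read_csv(path)
    _require_columns(df, HISTOLOGY_COLUMNS, path)
    is_pct = df["stain"] != "thickness"
    pct = df.loc[is_pct]
    if len(pct):
        _check_numeric(pct, "area_pct", path, lo=0.0, hi=100.0, allow_nan=False)
    th = df.loc[~is_pct]
    if len(th):
        _check_numeric(th, "thickness_um", path, positive=True)
    return df


def write_histology_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report assembly


def _metric_table(summary: pd.DataFrame, value: str) -> pd.DataFrame | None:
    if value not in summary.columns:
        return None
    g = summary.groupby(["location", "age_group"])[value].agg(["mean", "std", "count"])
    return g.unstack("age_group")


def report(
    fit_summary: pd.DataFrame | None = None,
    curve_comparisons: list | None = None,
    metric_anovas: dict | None = None,
    histo_overall: pd.DataFrame | None = None,
    histo_anovas: dict | None = None,
    *,
    output_dir: str | Path = "results",
) -> str:
    """Assemble one human-readable summary plus machine-readable CSVs.

    Sections absent from the inputs (e.g. no histology in an
    inflation-only run) are marked absent, not dropped. Returns the report
    text; also writes ``report.md`` and the per-section CSVs under
    ``output_dir``.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# Arterial mechanics and histomorphometry summary", ""]

    if fit_summary is not None and len(fit_summary):
        fit_summary.to_csv(outdir / "fit_summary.csv", index=False)
        lines += ["## Inflation-extension fits", ""]
        lines += [f"Samples fitted: {len(fit_summary)}; "
                  f"converged: {(fit_summary['fit_status'] == 'ok').sum()}", ""]
        for metric, label in [
            ("Am_mm2", "Maximal area (mm^2)"),
            ("max_compliance", "Maximal compliance (mm^2/mmHg)"),
            ("max_distensibility", "Maximal distensibility (1/mmHg)"),
        ]:
            tab = _metric_table(fit_summary, metric)
            if tab is not None:
                lines += [f"### {label}", "", tab.round(4).to_markdown(), ""]
    else:
        lines += ["## Inflation-extension fits", "", "_absent from this run_", ""]

    if curve_comparisons:
        rows = [
            {
                "location": c.location, "curve_kind": c.curve_kind,
                "f_statistic": c.f_statistic, "df_num": c.df_num,
                "df_den": c.df_den, "p_value": c.p_value,
                "degenerate": c.degenerate,
            }
            for c in curve_comparisons
        ]
        cc = pd.DataFrame(rows)
        cc.to_csv(outdir / "curve_comparisons.csv", index=False)
        lines += ["## Age effect on pressure curves (nested F-tests)", "",
                  cc.round(5).to_markdown(index=False), ""]

    def _anova_section(title, anovas, fname):
        nonlocal lines
        if not anovas:
            lines += [f"## {title}", "", "_absent from this run_", ""]
            return
        rows = []
        for outcome, res in anovas.items():
            if res.degenerate:
                rows.append({"outcome": outcome, "factor": "-", "F": np.nan,
                             "p_value": np.nan, "note": res.note})
                continue
            for factor, r in res.effects.iterrows():
                rows.append({"outcome": outcome, "factor": factor,
                             "F": r["F"], "df_num": r["df_num"],
                             "df_den": r["df_den"], "p_value": r["p_value"],
                             "note": res.note})
        tab = pd.DataFrame(rows)
        tab.to_csv(outdir / fname, index=False)
        lines += [f"## {title}", "", tab.round(5).to_markdown(index=False), ""]
        for outcome, res in anovas.items():
            if res.letters:
                lines += [f"Location letters ({outcome}): "
                          + ", ".join(f"{k}: {v}" for k, v in res.letters.items()),
                          ""]

    _anova_section("Summary-metric ANOVA (age x location)",
                   metric_anovas, "metric_anova.csv")

    if histo_overall is not None and len(histo_overall):
        histo_overall.to_csv(outdir / "histology_overall.csv", index=False)
        lines += ["## Histomorphometry (per horse x location overall metrics)", ""]
        for metric in ["thickness_um", "elastin", "sma", "col1", "col3"]:
            tab = _metric_table(histo_overall, metric)
            if tab is not None:
                lines += [f"### {metric}", "", tab.round(2).to_markdown(), ""]
    else:
        lines += ["## Histomorphometry", "", "_absent from this run_", ""]

    _anova_section("Histology ANOVA (horse random, age x location fixed)",
                   histo_anovas, "histo_anova.csv")

    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    log.info("report written to %s", outdir / "report.md")
    return text
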