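"""Layer-weighted histomorphometry of the arterial wall.

In most equine arteries the tunica media splits into an inner smooth-muscle
rich layer (layer 1) and an outer elastin-fibre rich layer (layer 2). Each
slide yields, per layer and stain, the mean positively-stained area percent
over five image frames, and five thickness measurements per layer. Layer
values are combined into one wall-level figure by thickness weighting:

    overall% = pct1 * t1/(t1+t2) + pct2 * t2/(t1+t2)

Single-layer walls (the proximal aorta throughout; the distal aorta in the
horses without a visible split) bypass the weighting. Age and location
effects on the per-horse overall metrics are tested with a univariate ANOVA
treating horse as a random factor nested in age group, using the classical
expected-mean-squares construction: the age effect is tested against the
between-horse (within age) mean square, location and the age x location
interaction against the horse x location residual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

from .errors import ValidationError
from .stats import AnovaResult, bonferroni, compact_letters

__all__ = [
    "HistoRecord",
    "mean_of_frames",
    "overall_area_percent",
    "aggregate_histology",
    "histo_anova",
]

HISTO_OUTCOMES = ("thickness_um", "elastin", "sma", "col1", "col3")


@dataclass(frozen=True)
class HistoRecord:
    """One slide layer's stain measurements (five image frames)."""

    horse_id: str
    age_group: str
    location: str
    layer: str  # "1" | "2" | "single"
    stain: str
    frame_area_pcts: tuple[float, ...]
    layer_thickness_measurements: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for v in self.frame_area_pcts:
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"area% out of [0,100]: {v}")
        for t in self.layer_thickness_measurements:
            if t <= 0:
                raise ValidationError(f"thickness must be > 0, got {t}")


def mean_of_frames(values) -> float:
    """Arithmetic mean of the per-frame values (area% in [0,100] or
    thickness > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValidationError("need at least one frame value")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite frame value")
    return float(arr.mean())


def overall_area_percent(
    pct1: float, t1: float, pct2: float | None = None, t2: float = 0.0
) -> float:
    """Thickness-weighted overall area% across the two media layers.

    With a single layer (``t2 == 0`` / ``pct2 is None``) the layer value
    passes through unchanged.
    """
    if t1 < 0 or t2 < 0:
        raise ValidationError("thicknesses must be >= 0")
    if t1 + t2 <= 0:
        raise ValidationError("total thickness must be positive")
    if not (0.0 <= pct1 <= 100.0):
        raise ValidationError(f"area% out of [0,100]: {pct1}")
    if pct2 is None:
        return float(pct1)
    if not (0.0 <= pct2 <= 100.0):
        raise ValidationError(f"area% out of [0,100]: {pct2}")
    w1 = t1 / (t1 + t2)
    return float(pct1 * w1 + pct2 * (1.0 - w1))


def aggregate_histology(table: pd.DataFrame) -> pd.DataFrame:
    """Frame table -> per horse x location overall metrics.

    Input columns: horse_id, age_group, location, layer, stain,
    frame_index, area_pct, thickness_um. Stain rows carry ``area_pct``;
    thickness rows carry ``stain == 'thickness'`` and ``thickness_um``.
    Frames are averaged first (per slide layer), then layer means are
    thickness-weighted; this order matters and follows the measurement
    protocol.

    Returns one row per horse x location with columns ``thickness_um``
    (total intima-media thickness; NaN where not assessed) and the overall
    area% per stain.
    """
    required = {"horse_id", "age_group", "location", "layer", "stain"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    pct = table.loc[table["stain"] != "thickness"]
    bad = pct["area_pct"].dropna()
    if ((bad < 0) | (bad > 100)).any():
        raise ValidationError("area_pct outside [0,100] in input table")

    rows = []
    for (horse, loc), g in table.groupby(["horse_id", "location"], sort=True):
        age = g["age_group"].iloc[0]
        th = g[g["stain"] == "thickness"]
        layer_thickness = {
            layer: mean_of_frames(sub["thickness_um"].dropna())
            for layer, sub in th.groupby("layer")
        } if len(th) else {}
        total_th = sum(layer_thickness.values()) if layer_thickness else np.nan
        row = {
            "horse_id": horse,
            "age_group": age,
            "location": loc,
            "thickness_um": total_th,
        }
        for stain, gs in g[g["stain"] != "thickness"].groupby("stain"):
            layer_means = {
                layer: mean_of_frames(sub["area_pct"].dropna())
                for layer, sub in gs.groupby("layer")
            }
            layers = sorted(layer_means)
            if len(layers) == 1:
                row[stain] = layer_means[layers[0]]
            elif len(layers) == 2:
                l1, l2 = layers
                t1 = layer_thickness.get(l1, np.nan)
                t2 = layer_thickness.get(l2, np.nan)
                if np.isnan(t1) or np.isnan(t2):
                    # no thickness available (e.g. equal weighting impossible):
                    # fall back to the unweighted mean and flag via NaN thickness
                    row[stain] = float(np.mean(list(layer_means.values())))
                else:
                    row[stain] = overall_area_percent(
                        layer_means[l1], t1, layer_means[l2], t2
                    )
            else:
                raise ValidationError(
                    f"{horse}/{loc}/{stain}: expected 1 or 2 layers, got {layers}"
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _classical_mixed_anova(df: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Expected-mean-squares ANOVA with horse nested in age, crossed with
    location.

    Sequential decomposition: age | horse(age) | location | age x location,
    residual = horse x location. F_age = MS_age / MS_horse(age); location
    and interaction are tested against the residual. Exact for the
    balanced horse x location layouts the generator produces.

    Returns (effects table, residual MS, residual df).
    """
    model = smf.ols(
        "value ~ C(age_group) + C(horse_id) + C(location) "
        "+ C(age_group):C(location)",
        data=df,
    ).fit()
    tab = anova_lm(model, typ=1)

    def _row(name):
        return float(tab.loc[name, "sum_sq"]), float(tab.loc[name, "df"])

    ss_age, df_age = _row("C(age_group)")
    ss_horse, df_horse = _row("C(horse_id)")
    ss_loc, df_loc = _row("C(location)")
    ss_int, df_int = _row("C(age_group):C(location)")
    ss_res, df_res = _row("Residual")

    if df_horse <= 0 or df_res <= 0:
        raise ValidationError("design leaves no df for the horse or residual stratum")

    ms_horse = ss_horse / df_horse
    ms_res = ss_res / df_res

    def _f(ss, dfn, ms_den, dfd):
        if ms_den <= 0:
            return np.nan, np.nan
        f = (ss / dfn) / ms_den
        return f, float(sps.f.sf(f, dfn, dfd))

    f_age, p_age = _f(ss_age, df_age, ms_horse, df_horse)
    f_loc, p_loc = _f(ss_loc, df_loc, ms_res, df_res)
    f_int, p_int = _f(ss_int, df_int, ms_res, df_res)
    eff = pd.DataFrame(
        {
            "F": [f_age, f_loc, f_int],
            "df_num": [df_age, df_loc, df_int],
            "df_den": [df_horse, df_res, df_res],
            "p_value": [p_age, p_loc, p_int],
        },
        index=["age", "location", "age x location"],
    )
    return eff, ms_res, df_res


def histo_anova(
    overall: pd.DataFrame,
    outcomes: tuple[str, ...] = HISTO_OUTCOMES,
    *,
    alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Age/location ANOVA per histology outcome, horse as random factor.

    ``overall`` is the per horse x location table from
    :func:`aggregate_histology`. Outcomes with rows missing at some
    locations (thickness at the proximal aorta) are analysed on the
    locations that carry data. When the horse stratum is confounded with
    the residual (each horse contributes a single row) the analysis falls
    back to a two-way fixed-effects ANOVA and says so in the result note.
    Pairwise location contrasts use the residual stratum's mean square,
    Bonferroni-adjusted over C(k, 2).
    """
    results: dict[str, AnovaResult] = {}
    for outcome in outcomes:
        if outcome not in overall.columns:
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="outcome missing from table",
            )
            continue
        df = overall.dropna(subset=[outcome]).copy()
        df = df.rename(columns={outcome: "value"})
        n_horse = df["horse_id"].nunique()
        n_loc = df["location"].nunique()
        n_age = df["age_group"].nunique()
        if n_age < 2 or n_loc < 2:
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="need >= 2 age groups and >= 2 locations",
            )
            continue
        per_age = df.groupby("age_group")["horse_id"].nunique()
        if (per_age < 2).any():
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="single-horse age group: horse random factor not estimable",
            )
            continue
        if float(np.var(df["value"])) == 0.0:
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="zero total variance: F undefined",
            )
            continue

        note = ""
        if len(df) <= n_horse:  # one row per horse: horse == residual
            model = smf.ols(
                "value ~ C(age_group) * C(location)", data=df
            ).fit()
            tab = anova_lm(model, typ=2)
            eff = pd.DataFrame(
                {
                    "F": tab["F"].iloc[:-1].to_numpy(),
                    "df_num": tab["df"].iloc[:-1].to_numpy(),
                    "df_den": float(model.df_resid),
                    "p_value": tab["PR(>F)"].iloc[:-1].to_numpy(),
                },
                index=["age", "location", "age x location"][: len(tab) - 1],
            )
            ms_res = float(model.mse_resid)
            df_res = float(model.df_resid)
            note = "horse confounded with residual: fixed-effects fallback"
        else:
            eff, ms_res, df_res = _classical_mixed_anova(df)

        locs = sorted(df["location"].unique())
        pairs = list(itertools.combinations(locs, 2))
        rows, pair_p, raw_ps = [], {}, []
        for a, b in pairs:
            ya = df.loc[df["location"] == a, "value"]
            yb = df.loc[df["location"] == b, "value"]
            se = np.sqrt(ms_res * (1.0 / len(ya) + 1.0 / len(yb)))
            t = (ya.mean() - yb.mean()) / se
            praw = float(2 * sps.t.sf(abs(t), df_res))
            raw_ps.append(praw)
            rows.append({"a": a, "b": b, "diff": float(ya.mean() - yb.mean()),
                         "t": float(t), "p_raw": praw})
        if rows:
            adj = bonferroni(raw_ps, family_size=len(pairs))
            for r, pa in zip(rows, adj):
                r["p_adj"] = float(pa)
                pair_p[frozenset((r["a"], r["b"]))] = float(pa)
        order = df.groupby("location")["value"].mean().sort_values(ascending=False)
        letters = compact_letters(list(order.index), pair_p, alpha=alpha)
        results[outcome] = AnovaResult(
            outcome=outcome, effects=eff, posthoc=pd.DataFrame(rows),
            letters=letters, note=note,
        )
    return results
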