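"""Group comparisons: nested nonlinear F-tests and summary-metric ANOVA.

The age effect on a whole pressure curve is tested with the
extra-sum-of-squares F-test for nested nonlinear regressions: one curve
fitted to all points pooled versus one curve per age group. With k groups
and p parameters per curve,

    F = [(RSS_pooled - RSS_separate) / (p*(k-1))] / [RSS_separate / (N - p*k)]

referred to an F(p*(k-1), N - p*k) distribution. Three curve kinds are
supported: the pressure-area relation itself (3 parameters), the analytic
compliance (Lorentzian) form fitted to finite-difference compliance points
(3 parameters), and the distensibility form fitted to finite-difference
distensibility points. The distensibility curve D(P) = C(P)/A(P) does not
depend on Am (it cancels), so that family has 2 free parameters (P0, P1)
and the degrees of freedom follow the actual parameter count.

Summary metrics (maximal area, maximal compliance, maximal distensibility)
are compared with per-outcome two-way fixed-effects ANOVA (age, location,
interaction) with Bonferroni-adjusted pairwise location contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.optimize import least_squares

from .errors import ValidationError
from .pipeline import PressureAreaSeries, empirical_compliance

__all__ = [
    "CurveComparisonResult",
    "AnovaResult",
    "nested_f_test",
    "permutation_nested_f",
    "anova_summary_metrics",
    "bonferroni",
    "compact_letters",
    "group_curve_params",
]


@dataclass(frozen=True)
class CurveComparisonResult:
    location: str
    curve_kind: str
    rss_pooled: float
    rss_separate: float
    df_num: int
    df_den: int
    f_statistic: float
    p_value: float
    n_points: int
    n_params_per_group: int
    degenerate: bool = False
    group_params: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class AnovaResult:
    outcome: str
    effects: pd.DataFrame  # index factor; columns F, df_num, df_den, p_value
    posthoc: pd.DataFrame | None = None  # pairwise location contrasts
    letters: dict | None = None  # compact letter display per location
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Curve families for the nested fits


class _ArctanFamily:
    """A(P) = Am*(1/2 + arctan((P-P0)/P1)/pi)."""

    n_params = 3

    @staticmethod
    def predict(theta, P):
        Am, P0, P1 = theta
        return Am * (0.5 + np.arctan((P - P0) / P1) / np.pi)

    @staticmethod
    def inits(P, y):
        am0 = 1.05 * max(float(np.max(y)), 1e-9)
        p0_0 = float(P[np.argmin(np.abs(y - am0 / 2.0))])
        q25, q75 = np.percentile(P, [25, 75])
        return [np.array([am0, p0_0, max((q75 - q25) / 2.0, 1.0)])]

    @staticmethod
    def bounds(P, y):
        top = 10.0 * max(float(np.max(y)), 1e-9)
        return np.array([1e-12, -1e3, 1e-12]), np.array([top, 1e3, 1e4])


class _LorentzFamily:
    """C(P) = s / (1 + ((P-P0)/P1)^2) with s = Am/(pi*P1)."""

    n_params = 3

    @staticmethod
    def predict(theta, P):
        s, P0, P1 = theta
        x = (P - P0) / P1
        return s / (1.0 + x * x)

    @staticmethod
    def inits(P, y):
        s0 = max(float(np.max(y)), 1e-9)
        p0_0 = float(P[np.argmax(y)])
        q25, q75 = np.percentile(P, [25, 75])
        return [np.array([s0, p0_0, max((q75 - q25) / 2.0, 1.0)])]

    @staticmethod
    def bounds(P, y):
        top = 10.0 * max(float(np.max(np.abs(y))), 1e-9)
        return np.array([1e-12, -1e3, 1e-12]), np.array([top, 1e3, 1e4])


class _DistFamily:
    """D(P) = 1 / (pi*P1 * (1+x^2) * (1/2 + arctan(x)/pi)); Am cancels."""

    n_params = 2

    @staticmethod
    def predict(theta, P):
        P0, P1 = theta
        x = (P - P0) / P1
        return 1.0 / (np.pi * P1 * (1.0 + x * x) * (0.5 + np.arctan(x) / np.pi))

    @staticmethod
    def inits(P, y):
        ymax = max(float(np.max(y)), 1e-9)
        p1_0 = max(2.0 / (np.pi * ymax), 1.0)
        # D peaks near P0 - 0.43*P1
        p0_0 = float(P[np.argmax(y)]) + 0.43 * p1_0
        q25, q75 = np.percentile(P, [25, 75])
        return [
            np.array([p0_0, p1_0]),
            np.array([float(np.median(P)), max((q75 - q25) / 2.0, 1.0)]),
        ]

    @staticmethod
    def bounds(P, y):
        return np.array([-1e3, 1e-12]), np.array([1e3, 1e4])


_FAMILIES = {
    "area": _ArctanFamily,
    "compliance": _LorentzFamily,
    "distensibility": _DistFamily,
}


def _fit_family(family, P, y, w=None, extra_inits=()):
    """Best bounded least-squares fit over several starts.

    ``w`` are per-point noise-scale weights: residuals are (f - y)/w, so the
    returned RSS is a weighted sum of squares. Returns (theta, rss).
    """
    lb, ub = family.bounds(P, y)
    if w is None:
        w = np.ones_like(y)
    best = None
    starts = list(family.inits(P, y)) + [np.asarray(t, float) for t in extra_inits]
    for theta0 in starts:
        t0 = np.clip(theta0, lb + 1e-12, ub)
        try:
            res = least_squares(
                lambda t: (family.predict(t, P) - y) / w,
                t0,
                bounds=(lb, ub),
                method="trf",
                ftol=1e-10,
                xtol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise ValidationError("curve fit failed for all starting points")
    return best


def _curve_points(series: PressureAreaSeries, curve_kind: str):
    """Points (P, y) and noise-scale weights for one series.

    Diameter measurement error is multiplicative, so area noise has a
    constant coefficient of variation: the area weight is the observed
    area itself. Finite-difference compliance/distensibility points
    inherit propagated weights, sqrt(A_i^2 + A_{i+1}^2)/dP for compliance
    (further divided by the midpoint area for distensibility), capturing
    both the area noise scale and the uneven grid spacing.
    """
    if curve_kind == "area":
        y = np.asarray(series.areas)
        return np.asarray(series.pressures), y, y.copy()
    emp = empirical_compliance(series)
    col = "compliance" if curve_kind == "compliance" else "distensibility"
    A = np.asarray(series.areas)
    dP = np.diff(np.asarray(series.pressures))
    w = np.sqrt(A[:-1] ** 2 + A[1:] ** 2) / dP
    if curve_kind == "distensibility":
        w = w / emp["mid_area_mm2"].to_numpy()
    return emp["pressure_mmHg"].to_numpy(), emp[col].to_numpy(), w


def nested_f_test(
    series_list: list[PressureAreaSeries],
    curve_kind: str = "area",
    *,
    group_key: str = "age_group",
    location: str | None = None,
    weighting: str = "relative",
) -> CurveComparisonResult:
    """Extra-sum-of-squares F-test for a group effect on one curve family.

    All samples should come from a single vessel location; the grouping
    label (age group by default) is read from each series' metadata.

    ``weighting='relative'`` (default) scales each point's residual by its
    measurement-noise scale (areas have constant relative error because
    diameter readings do; finite-difference points inherit propagated
    scales). This keeps the weighted residuals homoscedastic, which the
    nested F distribution assumes; ``weighting='none'`` uses raw
    residuals.

    Raises
    ------
    ValidationError
        Unknown curve kind, fewer than two groups, a group with fewer than
        two samples, or too few pooled points to fit the nested models.
    """
    if curve_kind not in _FAMILIES:
        raise ValidationError(f"unknown curve kind {curve_kind!r}")
    family = _FAMILIES[curve_kind]

    groups: dict[str, list[PressureAreaSeries]] = {}
    for s in series_list:
        groups.setdefault(str(s.meta.get(group_key)), []).append(s)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for g, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")

    if location is None:
        locs = {s.meta.get("location") for s in series_list}
        location = locs.pop() if len(locs) == 1 else "mixed"

    if weighting not in ("relative", "none"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    pts = {
        g: [np.concatenate(v) for v in zip(
            *(_curve_points(s, curve_kind) for s in members)
        )]
        for g, members in groups.items()
    }
    if weighting == "none":
        for v in pts.values():
            v[2] = np.ones_like(v[2])
    P_all = np.concatenate([pts[g][0] for g in pts])
    y_all = np.concatenate([pts[g][1] for g in pts])
    w_all = np.concatenate([pts[g][2] for g in pts])
    N = int(P_all.size)
    k = len(groups)
    p = family.n_params
    if N < 2 * p + 2:
        raise ValidationError(f"too few pooled points ({N}) to compare nested fits")

    theta_pool, rss_pool = _fit_family(family, P_all, y_all, w_all)
    rss_sep = 0.0
    group_params = {"pooled": theta_pool}
    for g, (Pg, yg, wg) in pts.items():
        # start each group from the pooled optimum too: guarantees
        # rss_separate <= rss_pooled up to optimizer tolerance
        theta_g, rss_g = _fit_family(family, Pg, yg, wg, extra_inits=[theta_pool])
        rss_sep += rss_g
        group_params[g] = theta_g
    rss_sep = min(rss_sep, rss_pool)

    df_num = p * (k - 1)
    df_den = N - p * k
    if df_den <= 0:
        raise ValidationError("no residual degrees of freedom for separate fits")

    tss = float(np.sum(((y_all - y_all.mean()) / w_all) ** 2))
    if rss_sep <= 1e-12 * max(tss, 1e-300):
        return CurveComparisonResult(
            location=location, curve_kind=curve_kind,
            rss_pooled=rss_pool, rss_separate=rss_sep,
            df_num=df_num, df_den=df_den,
            f_statistic=0.0, p_value=1.0,
            n_points=N, n_params_per_group=p,
            degenerate=True, group_params=group_params,
        )

    f_stat = ((rss_pool - rss_sep) / df_num) / (rss_sep / df_den)
    f_stat = max(f_stat, 0.0)
    p_value = float(sps.f.sf(f_stat, df_num, df_den))
    return CurveComparisonResult(
        location=location, curve_kind=curve_kind,
        rss_pooled=rss_pool, rss_separate=rss_sep,
        df_num=df_num, df_den=df_den,
        f_statistic=float(f_stat), p_value=p_value,
        n_points=N, n_params_per_group=p,
        group_params=group_params,
    )


def permutation_nested_f(
    series_list: list[PressureAreaSeries],
    curve_kind: str = "area",
    *,
    n_perm: int = 199,
    seed: int | np.random.SeedSequence = 0,
    group_key: str = "age_group",
) -> float:
    """Label-permutation p-value for the same nested comparison.

    Sample-level group labels are shuffled; the F statistic is recomputed
    for each permutation. Used as an assumption-light cross-check of the
    parametric F-test on small datasets.
    """
    obs = nested_f_test(series_list, curve_kind, group_key=group_key)
    family = _FAMILIES[curve_kind]
    sample_pts = [_curve_points(s, curve_kind) for s in series_list]
    labels = np.array([str(s.meta.get(group_key)) for s in series_list])
    theta_pool = obs.group_params["pooled"]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        # pooled fit is label-invariant: only the group fits are redone
        rss_sep = 0.0
        for g in np.unique(perm):
            idx = np.flatnonzero(perm == g)
            Pg, yg, wg = (
                np.concatenate([sample_pts[i][j] for i in idx]) for j in range(3)
            )
            _, rss_g = _fit_family(family, Pg, yg, wg, extra_inits=[theta_pool])
            rss_sep += rss_g
        rss_sep = min(rss_sep, obs.rss_pooled)
        if rss_sep <= 0:
            f_perm = np.inf
        else:
            f_perm = ((obs.rss_pooled - rss_sep) / obs.df_num) / (
                rss_sep / obs.df_den
            )
        if f_perm >= obs.f_statistic:
            count += 1
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Summary-metric ANOVA


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * family_size)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValidationError("family_size smaller than number of p-values")
    return np.minimum(1.0, p * m)


def compact_letters(levels, pair_p: dict, alpha: float = 0.05) -> dict:
    """Compact-letter display over an adjusted pairwise-p matrix
    (insert-and-absorb).

    Levels sharing a letter are not significantly different at ``alpha``.
    ``pair_p`` maps frozenset({a, b}) -> adjusted p-value; missing pairs are
    treated as not significant.
    """
    levels = list(levels)
    groups: list[set] = [set(levels)]
    for pair, p in pair_p.items():
        if p > alpha:
            continue
        a, b = tuple(pair)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            for t in (g - {a}, g - {b}):
                if t and not any(t <= u for u in groups):
                    groups.append(t)
    groups = [g for g in groups if not any(g < u for u in groups if u is not g)]
    # deterministic letter order: by the best-ranked member in `levels`
    groups.sort(key=lambda g: min(levels.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for i, g in enumerate(groups):
        for lev in g:
            out[lev] += alphabet[i % len(alphabet)]
    return {lev: "".join(sorted(out[lev])) for lev in levels}


def anova_summary_metrics(
    metrics: pd.DataFrame,
    outcomes: tuple[str, ...] = ("Am_mm2", "max_compliance", "max_distensibility"),
    *,
    alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Two-way fixed-effects ANOVA (age x location) per summary metric.

    One univariate ANOVA per outcome with age, location and their
    interaction as fixed factors (type-II sums of squares), followed by
    pairwise location contrasts using the pooled residual variance,
    Bonferroni-adjusted over C(k, 2) comparisons.
    """
    required = {"age_group", "location"}
    if not required <= set(metrics.columns):
        raise ValidationError(f"metrics table must have columns {sorted(required)}")
    results: dict[str, AnovaResult] = {}
    for outcome in outcomes:
        df = metrics.dropna(subset=[outcome, "age_group", "location"]).copy()
        if df.empty:
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="no data",
            )
            continue
        y = df[outcome].to_numpy(dtype=float)
        if np.var(y) == 0:
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note="zero total variance: F undefined",
            )
            continue
        df = df.rename(columns={outcome: "value"})
        model = smf.ols("value ~ C(age_group) * C(location)", data=df).fit()
        try:
            tab = sm.stats.anova_lm(model, typ=2)
        except Exception as e:  # e.g. empty cells
            results[outcome] = AnovaResult(
                outcome=outcome, effects=pd.DataFrame(), degenerate=True,
                note=f"not estimable: {e}",
            )
            continue
        df_resid = float(model.df_resid)
        eff = pd.DataFrame(
            {
                "F": tab["F"].iloc[:-1].to_numpy(),
                "df_num": tab["df"].iloc[:-1].to_numpy(),
                "df_den": df_resid,
                "p_value": tab["PR(>F)"].iloc[:-1].to_numpy(),
            },
            index=[str(i) for i in tab.index[:-1]],
        )
        eff.index = eff.index.str.replace("C(age_group)", "age", regex=False)
        eff.index = eff.index.str.replace("C(location)", "location", regex=False)
        eff.index = eff.index.str.replace(":", " x ", regex=False)

        # pairwise location contrasts on raw location means, pooled MSE
        mse = float(model.mse_resid)
        locs = sorted(df["location"].unique())
        pairs = list(itertools.combinations(locs, 2))
        rows, pair_p = [], {}
        if len(pairs) >= 1 and df_resid > 0:
            raw_ps = []
            for a, b in pairs:
                ya = df.loc[df["location"] == a, "value"]
                yb = df.loc[df["location"] == b, "value"]
                se = np.sqrt(mse * (1.0 / len(ya) + 1.0 / len(yb)))
                t = (ya.mean() - yb.mean()) / se
                praw = 2 * sps.t.sf(abs(t), df_resid)
                raw_ps.append(praw)
                rows.append({"a": a, "b": b, "diff": ya.mean() - yb.mean(),
                             "t": float(t), "p_raw": float(praw)})
            adj = bonferroni(raw_ps, family_size=len(pairs))
            for r, pa in zip(rows, adj):
                r["p_adj"] = float(pa)
                pair_p[frozenset((r["a"], r["b"]))] = float(pa)
        posthoc = pd.DataFrame(rows)
        order = df.groupby("location")["value"].mean().sort_values(ascending=False)
        letters = compact_letters(list(order.index), pair_p, alpha=alpha)
        results[outcome] = AnovaResult(
            outcome=outcome, effects=eff, posthoc=posthoc, letters=letters,
        )
    return results


def group_curve_params(
    series_list: list[PressureAreaSeries],
    curve_kind: str = "area",
    *,
    method: str = "pooled",
    group_key: str = "age_group",
) -> dict[str, np.ndarray]:
    """Representative curve parameters per group for plotting.

    ``method='pooled'`` (default) fits one curve to each group's pooled
    points; ``method='mean'`` fits each sample separately and averages the
    parameters within a group.
    """
    if curve_kind not in _FAMILIES:
        raise ValidationError(f"unknown curve kind {curve_kind!r}")
    family = _FAMILIES[curve_kind]
    groups: dict[str, list[PressureAreaSeries]] = {}
    for s in series_list:
        groups.setdefault(str(s.meta.get(group_key)), []).append(s)
    out = {}
    for g, members in groups.items():
        if method == "pooled":
            P, y, w = (np.concatenate(v) for v in zip(
                *(_curve_points(s, curve_kind) for s in members)
            ))
            out[g], _ = _fit_family(family, P, y, w)
        elif method == "mean":
            thetas = []
            for s in members:
                P, y, w = _curve_points(s, curve_kind)
                theta, _ = _fit_family(family, P, y, w)
                thetas.append(theta)
            out[g] = np.mean(thetas, axis=0)
        else:
            raise ValidationError(f"unknown method {method!r}")
    return out
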