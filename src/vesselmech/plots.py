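"""Curve-family figures: per-location pressure-area/-compliance/-distensibility.

One panel per vessel location; individual samples as points, fitted group
curves as lines (young vs old distinguished by colour and line style).
Deterministic output for fixed inputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .pipeline import PressureAreaSeries
from .stats import _FAMILIES, group_curve_params, _curve_points

_GROUP_STYLE = {
    "young": {"color": "tab:blue", "ls": "-"},
    "old": {"color": "tab:red", "ls": "--"},
}
_YLABEL = {
    "area": "Lumen area (mm$^2$)",
    "compliance": "Compliance (mm$^2$/mmHg)",
    "distensibility": "Distensibility (1/mmHg)",
}


def plot_curve_families(
    series_list: list[PressureAreaSeries],
    curve_kind: str = "area",
    out_path: str | Path = "curves.png",
    *,
    method: str = "pooled",
    group_key: str = "age_group",
) -> Path:
    """Write a multi-panel figure of per-location curve families.

    Returns the path written. Raises on an unknown curve kind or empty
    input.
    """
    if curve_kind not in _FAMILIES:
        raise ValidationError(f"unknown curve kind {curve_kind!r}")
    if not series_list:
        raise ValidationError("no series to plot")
    family = _FAMILIES[curve_kind]

    locations = sorted({str(s.meta.get("location")) for s in series_list})
    ncol = min(len(locations), 2)
    nrow = int(np.ceil(len(locations) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(5.5 * ncol, 4.0 * nrow), squeeze=False
    )

    for ax, loc in zip(axes.ravel(), locations):
        loc_series = [s for s in series_list if str(s.meta.get("location")) == loc]
        groups = sorted({str(s.meta.get(group_key)) for s in loc_series})
        p_grid = np.linspace(15, 300, 400)
        try:
            params = group_curve_params(
                loc_series, curve_kind, method=method, group_key=group_key
            )
        except ValidationError:
            params = {}
        for g in groups:
            style = _GROUP_STYLE.get(g, {"color": "tab:gray", "ls": "-"})
            for s in loc_series:
                if str(s.meta.get(group_key)) != g:
                    continue
                P, y, _w = _curve_points(s, curve_kind)
                ax.plot(P, y, "o" if g == "young" else "^",
                        color=style["color"], ms=3, alpha=0.45)
            if g in params:
                ax.plot(p_grid, family.predict(params[g], p_grid),
                        color=style["color"], ls=style["ls"], lw=2, label=g)
        ax.set_title(loc.replace("_", " "))
        ax.set_xlabel("Pressure (mmHg)")
        ax.set_ylabel(_YLABEL[curve_kind])
        ax.legend(fontsize=8)
    for ax in axes.ravel()[len(locations):]:
        ax.set_visible(False)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
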