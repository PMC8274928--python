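"""Synthetic cohort generator with known ground truth.

Emulates the structure of the reference experiment's raw measurements so
every pipeline stage is testable offline: an inflation-extension dataset
(per horse x
vessel location: triplicate inner diameters on the 10-point pressure grid)
and a histology dataset (per horse x location x media layer x stain: five
image-frame area-percent values, plus five layer-thickness measurements).

Vessel defaults are anchored to published equine group means: maximal
area Am per location and age group, P0 = 112.5 mmHg (midpoint of the
100-125 mmHg range where equine maximal compliance occurs), and the
half-width pressure backed out of the reported maximal compliance via
P1 = Am / (pi * C_max). Histology defaults mirror the reported per-location
mean +/- SD of intima-media thickness and of elastin, smooth-muscle actin
and collagen I/III area percentages. Between-horse spreads and the 2%
multiplicative diameter measurement noise are synthetic assumptions and are
documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import ArctanParams, area_at
from .pipeline import PAPER_PRESSURE_GRID

__all__ = [
    "VesselProfile",
    "HistoProfile",
    "default_profiles",
    "default_histo_profiles",
    "gen_inflation_dataset",
    "gen_histology_dataset",
    "null_profiles",
    "STAINS",
]


@dataclass(frozen=True)
class VesselProfile:
    """Ground-truth distribution of one location x age group's mechanics."""

    location: str
    age_group: str
    true_params: ArctanParams
    sd_Am: float = 0.0  # between-horse SD of Am, mm^2
    sd_P0: float = 0.0  # mmHg
    sd_P1: float = 0.0  # mmHg
    diameter_noise: float = 0.02  # multiplicative SD per replicate reading

    def __post_init__(self) -> None:
        if min(self.sd_Am, self.sd_P0, self.sd_P1) < 0:
            raise ValidationError("between-horse SDs must be >= 0")
        if not (0.0 <= self.diameter_noise <= 0.2):
            raise ValidationError("diameter noise fraction must be in [0, 0.2]")


@dataclass(frozen=True)
class HistoProfile:
    """Ground-truth histology distribution of one location x age group.

    ``stain_means``/``stain_sds`` map stain -> overall area% mean and
    between-horse SD. ``thickness_um`` is the intima-media thickness mean;
    ``None`` for the proximal aorta, whose wall exceeded the measurable
    range. ``layer_split`` is the thickness fraction of the inner
    (smooth-muscle-rich) media layer; the proximal aorta is single-layered.
    """

    location: str
    age_group: str
    stain_means: dict = field(default_factory=dict)
    stain_sds: dict = field(default_factory=dict)
    thickness_um: float | None = None
    thickness_sd: float = 0.0
    layer_split: float = 0.6
    single_layer: bool = False
    frame_sd: float = 3.0  # within-slide frame-to-frame area% SD
    thickness_meas_cv: float = 0.05  # per-measurement thickness noise CV

    def __post_init__(self) -> None:
        for s, m in self.stain_means.items():
            if not (0.0 <= m <= 100.0):
                raise ValidationError(f"stain mean out of [0,100] for {s}: {m}")
        if any(v < 0 for v in self.stain_sds.values()):
            raise ValidationError("stain SDs must be >= 0")
        if not (0.0 < self.layer_split < 1.0):
            raise ValidationError("layer_split must be in (0,1)")


# ---------------------------------------------------------------------------
# Defaults: reported group means for the four mechanically tested vessels.
# (Am mean +/- SD in mm^2; maximal compliance C_max in mm^2/mmHg.)
_MECHANICS_TABLE = {
    # location: {age: (Am_mean, Am_sd, C_max)}
    "proximal_aorta": {"young": (3313.0, 471.0, 18.0), "old": (3154.0, 852.0, 17.0)},
    "distal_aorta": {"young": (1039.0, 198.0, 10.0), "old": (1132.0, 279.0, 10.0)},
    "common_carotid": {"young": (100.0, 14.0, 0.7), "old": (114.0, 27.0, 0.8)},
    "external_iliac": {"young": (172.0, 64.0, 0.7), "old": (215.0, 53.0, 0.8)},
}

_DEFAULT_P0 = 112.5  # mmHg, midpoint of the 100-125 range of maximal compliance
_DEFAULT_P0_SD = 10.0  # mmHg, synthetic between-horse spread


def default_profiles(
    *,
    p0: float = _DEFAULT_P0,
    diameter_noise: float = 0.02,
    between_horse: bool = True,
) -> list[VesselProfile]:
    """Vessel profiles for the 4 tested locations x 2 age groups.

    P1 is backed out of the reported compliance maximum: P1 = Am/(pi*C_max).
    Between-horse SDs default to the reported Am SD, 20% of P1, and 10 mmHg
    on P0; pass ``between_horse=False`` for a fixed-parameter population.
    """
    out = []
    for loc, by_age in _MECHANICS_TABLE.items():
        for age, (am, am_sd, cmax) in by_age.items():
            p1 = am / (np.pi * cmax)
            out.append(
                VesselProfile(
                    location=loc,
                    age_group=age,
                    true_params=ArctanParams(Am=am, P0=p0, P1=p1),
                    sd_Am=am_sd if between_horse else 0.0,
                    sd_P0=_DEFAULT_P0_SD if between_horse else 0.0,
                    sd_P1=0.2 * p1 if between_horse else 0.0,
                    diameter_noise=diameter_noise,
                )
            )
    return out


# Histology defaults: per location, (young, old) for thickness (um) and each
# stain's overall area% (mean, SD). Thickness is not assessed at the
# proximal aorta; its media is single-layered.
_HISTO_TABLE = {
    "common_carotid": {
        "thickness": ((1654, 145), (1800, 225)),
        "elastin": ((16, 7), (14, 5)),
        "sma": ((43, 6), (46, 6)),
        "col1": ((17, 5), (20, 5)),
        "col3": ((18, 2), (21, 6)),
    },
    "cranial_carotid": {
        "thickness": ((1622, 179), (1800, 231)),
        "elastin": ((15, 5), (14, 5)),
        "sma": ((43, 2), (50, 6)),
        "col1": ((20, 8), (23, 10)),
        "col3": ((19, 2), (18, 5)),
    },
    "proximal_aorta": {
        "thickness": None,
        "elastin": ((35, 11), (34, 8)),
        "sma": ((42, 7), (45, 10)),
        "col1": ((25, 11), (23, 11)),
        "col3": ((15, 5), (18, 8)),
    },
    "distal_aorta": {
        "thickness": ((2219, 361), (2300, 327)),
        "elastin": ((15, 4), (14, 9)),
        "sma": ((36, 6), (41, 7)),
        "col1": ((20, 9), (16, 6)),
        "col3": ((23, 8), (21, 7)),
    },
    "median": {
        "thickness": ((1739, 302), (1885, 265)),
        "elastin": ((7, 2), (9, 6)),
        "sma": ((48, 9), (51, 10)),
        "col1": ((29, 10), (20, 12)),
        "col3": ((19, 4), (16, 8)),
    },
    "external_iliac": {
        "thickness": ((1655, 360), (1840, 253)),
        "elastin": ((11, 5), (11, 6)),
        "sma": ((41, 10), (44, 8)),
        "col1": ((27, 9), (20, 9)),
        "col3": ((23, 1), (22, 5)),
    },
    "femoral": {
        "thickness": ((1469, 147), (1870, 325)),
        "elastin": ((12, 5), (15, 6)),
        "sma": ((39, 6), (41, 7)),
        "col1": ((21, 5), (15, 9)),
        "col3": ((25, 7), (24, 4)),
    },
}

STAINS = ("elastin", "sma", "col1", "col3")

# Mean-preserving layer contrast (percentage points): the inner media layer
# is smooth-muscle rich, the outer layer elastin rich.
_LAYER_CONTRAST = {"elastin": -12.0, "sma": 12.0, "col1": 0.0, "col3": 0.0}


def default_histo_profiles() -> list[HistoProfile]:
    """Histology profiles for all 7 sampled locations x 2 age groups."""
    out = []
    for loc, tab in _HISTO_TABLE.items():
        for iage, age in enumerate(("young", "old")):
            th = tab["thickness"]
            out.append(
                HistoProfile(
                    location=loc,
                    age_group=age,
                    stain_means={s: float(tab[s][iage][0]) for s in STAINS},
                    stain_sds={s: float(tab[s][iage][1]) for s in STAINS},
                    thickness_um=float(th[iage][0]) if th is not None else None,
                    thickness_sd=float(th[iage][1]) if th is not None else 0.0,
                    single_layer=(th is None),
                )
            )
    return out


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (fast enough at the mild
    truncations used here)."""
    if sd == 0:
        return np.clip(np.broadcast_to(float(mean), () if size is None else size), lo, hi)
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    # bounded retries, then clip: draws are far from the bounds in practice
    for _ in range(100):
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def _horse_ids(n_young: int, n_old: int) -> list[tuple[str, str]]:
    ids = [(f"Y{i + 1:02d}", "young") for i in range(n_young)]
    ids += [(f"O{i + 1:02d}", "old") for i in range(n_old)]
    return ids


def gen_inflation_dataset(
    profiles: list[VesselProfile] | None = None,
    n_young: int = 6,
    n_old: int = 14,
    seed: int | np.random.SeedSequence = 0,
    *,
    pressure_grid: tuple[float, ...] = PAPER_PRESSURE_GRID,
    n_replicates: int = 3,
    rupture_fraction: float = 0.0,
    rupture_pressure: float = 250.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an inflation-extension measurement table.

    For each horse x tested location: draw that horse's true arctangent
    parameters around the profile mean (truncated to the valid domain),
    evaluate lumen areas on the pressure grid, invert to diameters under
    the circular-lumen assumption, and emit ``n_replicates`` diameter
    readings per pressure with multiplicative measurement noise.

    ``rupture_fraction`` of old-group samples (rounded down, chosen by the
    RNG) lose the grid points above ``rupture_pressure`` and are flagged
    ruptured, mimicking vessel failure at high pressure.

    Returns
    -------
    (measurements, truth)
        ``measurements``: long-format table, one row per sample x pressure
        x replicate, columns sample_id, horse_id, age_group, location,
        pressure_mmHg, replicate_index, diameter_mm, ruptured.
        ``truth``: per-sample true parameters for recovery checks.
    """
    if n_young < 1 or n_old < 1:
        raise ValidationError("need at least one horse per age group")
    if profiles is None:
        profiles = default_profiles()
    by_key = {(p.location, p.age_group): p for p in profiles}
    locations = sorted({p.location for p in profiles}, key=str)

    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    horses = _horse_ids(n_young, n_old)

    old_samples = [
        (h, loc) for h, age in horses if age == "old" for loc in locations
    ]
    n_rupt = int(rupture_fraction * len(old_samples))
    rupt_idx = set(
        rng.choice(len(old_samples), size=n_rupt, replace=False).tolist()
    ) if n_rupt else set()
    ruptured_keys = {old_samples[i] for i in rupt_idx}

    for horse_id, age in horses:
        for loc in locations:
            prof = by_key.get((loc, age))
            if prof is None:
                raise ValidationError(f"no profile for ({loc}, {age})")
            tp = prof.true_params
            am = float(_truncnorm(rng, tp.Am, prof.sd_Am, 1e-6 + 0.2 * tp.Am, 5 * tp.Am))
            p0 = float(rng.normal(tp.P0, prof.sd_P0)) if prof.sd_P0 else tp.P0
            p1 = float(_truncnorm(rng, tp.P1, prof.sd_P1, 0.2 * tp.P1, 5 * tp.P1))
            params = ArctanParams(Am=am, P0=p0, P1=p1)
            sample_id = f"{horse_id}_{loc}"
            ruptured = (horse_id, loc) in ruptured_keys
            grid = [
                p for p in pressure_grid
                if (not ruptured) or p <= rupture_pressure
            ]
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "horse_id": horse_id,
                    "age_group": age,
                    "location": loc,
                    "Am_true": am,
                    "P0_true": p0,
                    "P1_true": p1,
                    "ruptured": ruptured,
                }
            )
            for pres in grid:
                a = area_at(params, pres)
                d_true = 2.0 * np.sqrt(a / np.pi)
                noise = rng.normal(0.0, prof.diameter_noise, size=n_replicates)
                for k in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "horse_id": horse_id,
                            "age_group": age,
                            "location": loc,
                            "pressure_mmHg": pres,
                            "replicate_index": k + 1,
                            "diameter_mm": d_true * (1.0 + noise[k]),
                            "ruptured": ruptured,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_histology_dataset(
    profiles: list[HistoProfile] | None = None,
    n_young: int = 6,
    n_old: int = 14,
    seed: int | np.random.SeedSequence = 0,
    *,
    n_frames: int = 5,
    age_effects: dict | None = None,
    two_layer_fraction_distal_aorta: float = 0.4,
) -> pd.DataFrame:
    """Simulate a histology table (one row per slide layer x stain x frame).

    Per horse x location a horse-level overall mean is drawn for each stain
    (truncated normal on [0,100]) and total intima-media thickness; the two
    media layers get mean-preserving contrasts (inner layer smooth-muscle
    rich, outer layer elastin rich) so that thickness-weighting the layer
    means recovers the horse-level overall value. Five frame values per
    layer x stain and five thickness measurements per layer are emitted.

    The distal aorta shows a two-layered media in only
    ``two_layer_fraction_distal_aorta`` of horses (single layer otherwise);
    the proximal aorta is always single-layered and carries no thickness.

    ``age_effects`` optionally adds {outcome: shift} to the old group's
    horse-level means ("thickness_um" or a stain name), for power studies.
    """
    if n_young < 1 or n_old < 1:
        raise ValidationError("need at least one horse per age group")
    if profiles is None:
        profiles = default_histo_profiles()
    by_key = {(p.location, p.age_group): p for p in profiles}
    locations = sorted({p.location for p in profiles}, key=str)
    age_effects = age_effects or {}

    rng = np.random.default_rng(seed)
    rows = []
    for horse_id, age in _horse_ids(n_young, n_old):
        for loc in locations:
            prof = by_key[(loc, age)]
            single = prof.single_layer
            if loc == "distal_aorta" and not single:
                single = rng.random() >= two_layer_fraction_distal_aorta

            if prof.thickness_um is not None:
                th_mean = prof.thickness_um + (
                    age_effects.get("thickness_um", 0.0) if age == "old" else 0.0
                )
                total_th = float(
                    _truncnorm(rng, th_mean, prof.thickness_sd, 50.0, 1e4)
                )
            else:
                total_th = None

            layers = ("single",) if single else ("1", "2")
            if single:
                weights = {"single": 1.0}
            else:
                weights = {"1": prof.layer_split, "2": 1.0 - prof.layer_split}

            for stain in STAINS:
                m = prof.stain_means[stain] + (
                    age_effects.get(stain, 0.0) if age == "old" else 0.0
                )
                overall = float(
                    _truncnorm(rng, m, prof.stain_sds[stain], 0.0, 100.0)
                )
                delta = 0.0 if single else _LAYER_CONTRAST[stain]
                layer_means = {}
                if single:
                    layer_means["single"] = overall
                else:
                    w1, w2 = weights["1"], weights["2"]
                    layer_means["1"] = np.clip(overall + delta * w2, 0, 100)
                    layer_means["2"] = np.clip(overall - delta * w1, 0, 100)
                for layer in layers:
                    vals = _truncnorm(
                        rng, layer_means[layer], prof.frame_sd, 0.0, 100.0,
                        size=n_frames,
                    )
                    for k in range(n_frames):
                        rows.append(
                            {
                                "horse_id": horse_id,
                                "age_group": age,
                                "location": loc,
                                "layer": layer,
                                "stain": stain,
                                "frame_index": k + 1,
                                "area_pct": float(vals[k]),
                                "thickness_um": np.nan,
                            }
                        )
            # thickness measurements: one block per layer, stain field empty
            if total_th is not None:
                for layer in layers:
                    lth = total_th * weights[layer]
                    meas = lth * (
                        1.0 + rng.normal(0.0, prof.thickness_meas_cv, size=n_frames)
                    )
                    for k in range(n_frames):
                        rows.append(
                            {
                                "horse_id": horse_id,
                                "age_group": age,
                                "location": loc,
                                "layer": layer,
                                "stain": "thickness",
                                "frame_index": k + 1,
                                "area_pct": np.nan,
                                "thickness_um": float(max(meas[k], 1.0)),
                            }
                        )
    return pd.DataFrame(rows)


def null_profiles(
    base: list[VesselProfile] | None = None,
    *,
    location: str = "proximal_aorta",
) -> list[VesselProfile]:
    """Profiles for a no-age-difference population at one location.

    Both age groups share the young group's true parameters with zero
    between-horse spread; only measurement noise separates samples. Used by
    the type-I-error calibration of the nested F-test.
    """
    if base is None:
        base = default_profiles()
    ref = next(
        p for p in base if p.location == location and p.age_group == "young"
    )
    return [
        replace(ref, age_group="young", sd_Am=0.0, sd_P0=0.0, sd_P1=0.0),
        replace(ref, age_group="old", sd_Am=0.0, sd_P0=0.0, sd_P1=0.0),
    ]
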