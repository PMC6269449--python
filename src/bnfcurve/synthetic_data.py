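"""Synthetic multi-site, multi-treatment soybean N-fixation trials.

No plot-level data accompany the study design this package analyses, so
the generator emulates its statistical structure end to end: 23 sites x
4 nitrogen treatments (unfertilized control, N at sowing, N at V4, N at R2)
x 3 blocks, stem ureide/nitrate assays at four stages (V4, R2, R6, R8) on a
thermal-time axis anchored at V2, and plot-level agronomic outcomes (seed
yield, biomass, harvest index, seed protein and oil).

Calibration of the defaults:

* The fixation-group base curves (high / medium / low) use the fitted
  control-parameter triples of the source trial network — (90, 397, 1117),
  (84, 362, 1066) and (71, 0, 931) for (RAU_max %, t_m °Cd, t_max °Cd) —
  with per-treatment additive shifts taken from the high-group fertilized
  fits (N at R2 depresses RAU_max by ~15 points).
* RAU noise is additive Gaussian with SD 13 RAU points, the middle of the
  11-16 band of residual SDs (Syx) reported for the group-level curve fits,
  clipped to [0, 100].
* Thermal time to R6 is drawn uniformly on [909, 1733] °Cd, the observed
  range across sites; V4, R2 and R8 sit at fixed fractions of it.
* Each site carries a persistent amplitude effect on RAU_max (Gaussian,
  SD 5 RAU points, matching the within-group spread of control RAU_R6
  across sites), and its curve's thermal axis (t_m, t_max) is scaled by
  the site's season length relative to the network mean — R6 samples sit
  near the RAU peak in short- and long-season sites alike, as observed.
* Yield rises bilinearly with thermal time to R6 and carries a linear
  fixation cost of -13 kg ha^-1 per % RAU_R6 (the headline rate); harvest
  index analogously at -0.0011 per %.  Oil carries a small negative RAU
  effect; protein and biomass carry none (they were unrelated to RAU_R6
  once phenology was removed).

Each assay is emitted as a (ureide, nitrate) concentration pair that
inverts the RAU formula exactly (ureide fixed at 1, nitrate =
4U(100 - RAU)/RAU), so recomputing RAU from the pair recovers the simulated
value bit-for-bit.  Weather is synthesized so that degree-day accumulation
from the V2 date reproduces each site's stage thermal times exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bnf_curve import beta_rau
from .errors import DomainError
from .ureide_thermal import STAGE_ORDER, Stage, Treatment, compute_rau

__all__ = ["TraitModel", "SimulationSpec", "simulate_rau", "simulate_trials"]

#: Fitted control curves of the three fixation groups: (rau_max, t_m, t_max).
DEFAULT_GROUP_PARAMS: dict[str, tuple[float, float, float]] = {
    "high": (90.0, 397.0, 1117.0),
    "medium": (84.0, 362.0, 1066.0),
    "low": (71.0, 0.0, 931.0),
}

#: Additive treatment shifts on (rau_max, t_m, t_max), from the high-group
#: fertilized fits relative to the control.
DEFAULT_TREATMENT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "control": (0.0, 0.0, 0.0),
    "N_sowing": (-7.0, 64.0, 36.0),
    "N_V4": (-9.0, -9.0, -14.0),
    "N_R2": (-15.0, -140.0, -45.0),
}

#: Stage thermal times as fractions of the site's thermal time to R6.
DEFAULT_STAGE_FRACTIONS: dict[Stage, float] = {
    Stage.V4: 0.20,
    Stage.R2: 0.55,
    Stage.R6: 1.00,
    Stage.R8: 1.25,
}


@dataclass(frozen=True)
class TraitModel:
    """Bilinear phenology trend plus a linear RAU_R6 cost for one trait.

    trait = b + a * min(tt_r6, tt_o) + d * max(tt_r6 - tt_o, 0)
            + bnf_cost_slope * (rau_r6 - mean rau_r6) + N(0, noise_sd)
    """

    a: float
    b: float
    d: float
    tt_o: float
    bnf_cost_slope: float
    noise_sd: float

    def trend(self, tt_r6):
        tt = np.asarray(tt_r6, dtype=float)
        return self.b + self.a * np.minimum(tt, self.tt_o) + self.d * np.maximum(tt - self.tt_o, 0.0)


# Defaults span the observed trait ranges: yield 3151-7175 kg/ha,
# HI 0.37-0.56, oil 16.7-23.9 and protein 31.9-41.8 g/100 g.
DEFAULT_YIELD_MODEL = TraitModel(a=3.0, b=1500.0, d=0.5, tt_o=1300.0,
                                 bnf_cost_slope=-13.0, noise_sd=300.0)
DEFAULT_HI_MODEL = TraitModel(a=2.0e-4, b=0.20, d=-1.0e-4, tt_o=1300.0,
                              bnf_cost_slope=-0.0011, noise_sd=0.02)
DEFAULT_OIL_MODEL = TraitModel(a=4.0e-3, b=16.0, d=0.0, tt_o=1300.0,
                               bnf_cost_slope=-0.02, noise_sd=0.5)
DEFAULT_PROTEIN_MODEL = TraitModel(a=-2.0e-3, b=40.0, d=0.0, tt_o=1300.0,
                                   bnf_cost_slope=0.0, noise_sd=1.2)


@dataclass
class SimulationSpec:
    """Full description of a simulated trial network.

    ``group_fractions`` splits the sites into the low/medium/high fixation
    groups (quartile split: 25% / 50% / 25% by construction).
    ``heteroscedastic_hi`` scales HI noise up where the phenology-expected
    HI is low, steepening the lower response boundary relative to the mean
    (the contrast the 0.01-quantile regression is designed to expose).
    """

    n_sites: int = 23
    treatments: tuple[str, ...] = tuple(t.value for t in Treatment)
    n_blocks: int = 3
    group_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    treatment_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS))
    rau_noise_sd: float = 13.0
    site_rau_sd: float = 5.0
    scale_axis_with_season: bool = True
    tt_r6_range: tuple[float, float] = (909.0, 1733.0)
    stage_fractions: Mapping[Stage, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    yield_model: TraitModel = DEFAULT_YIELD_MODEL
    hi_model: TraitModel = DEFAULT_HI_MODEL
    oil_model: TraitModel = DEFAULT_OIL_MODEL
    protein_model: TraitModel = DEFAULT_PROTEIN_MODEL
    heteroscedastic_hi: bool = False
    season_start: _dt.date = _dt.date(2016, 6, 1)
    seed: int = 0

    def __post_init__(self):
        if self.rau_noise_sd < 0:
            raise DomainError("rau_noise_sd must be >= 0")
        fracs = [self.stage_fractions[s] for s in STAGE_ORDER]
        if not all(b > a for a, b in zip(fracs, fracs[1:])):
            raise DomainError("stage thermal times must be strictly increasing")
        for g, (r, tm, te) in self.group_params.items():
            if not (0 < r <= 100 and 0 <= tm < te):
                raise DomainError(f"invalid curve triple for group {g!r}: {(r, tm, te)}")

    def site_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    def site_groups(self) -> dict[str, str]:
        """Deterministic quartile assignment of sites to fixation groups."""
        ids = self.site_ids()
        n = len(ids)
        n_low = max(1, round(0.25 * n))
        n_high = max(1, round(0.25 * n))
        groups = {}
        for i, sid in enumerate(ids):
            if i < n_low:
                groups[sid] = "low"
            elif i >= n - n_high:
                groups[sid] = "high"
            else:
                groups[sid] = "medium"
        return groups

    def curve_params(self, group: str, treatment: str,
                     rau_shift: float = 0.0,
                     axis_scale: float = 1.0) -> tuple[float, float, float]:
        """Curve triple for one cell, with optional per-site adjustments.

        ``rau_shift`` is the site's persistent amplitude effect;
        ``axis_scale`` stretches the thermal axis with the site's season
        length (t_m and t_max both scale, preserving the curve's shape).
        """
        base = np.asarray(self.group_params[group], dtype=float)
        shift = np.asarray(self.treatment_effects[treatment], dtype=float)
        r, tm, te = base + shift
        r = float(np.clip(r + rau_shift, 1.0, 100.0))
        te = float(max(te * axis_scale, 1.0))
        tm = float(np.clip(tm * axis_scale, 0.0, 0.98 * te))
        return r, tm, te


def _assay_pair(rau: float) -> tuple[float, float]:
    """Invert RAU exactly into a (ureide, nitrate) pair with ureide = 1."""
    if rau <= 0:
        return 0.0, 1.0
    if rau >= 100:
        return 1.0, 0.0
    return 1.0, 4.0 * (100.0 - rau) / rau


def simulate_rau(spec: SimulationSpec, group: str, treatment: str, stage_tt: float,
                 rng: np.random.Generator, rau_shift: float = 0.0,
                 axis_scale: float = 1.0) -> tuple[float, float, float]:
    """Draw one noisy RAU value and its exact-inverting assay pair.

    Returns ``(rau, ureide_conc, nitrate_conc)``; the pair satisfies
    ``compute_rau(ureide, nitrate) == rau`` up to floating point.
    """
    params = spec.curve_params(group, treatment, rau_shift, axis_scale)
    true_rau = max(beta_rau(stage_tt, params), 0.0)
    rau = float(np.clip(true_rau + rng.normal(0.0, spec.rau_noise_sd), 0.0, 100.0))
    u, nconc = _assay_pair(rau)
    return rau, u, nconc


def _site_weather(site_id: str, stage_tts: dict[Stage, float],
                  start: _dt.date) -> tuple[pd.DataFrame, dict[Stage, _dt.date]]:
    """Daily weather whose degree-day accumulation hits each stage exactly.

    Between consecutive stage targets the daily increment is constant
    (<= 14 °Cd, i.e. mean <= 22 °C over a base of 8 °C) and chosen so the
    cumulative sum at each stage date equals the target to float precision.
    Day 0 is the V2 origin; its increment does not count on the V2-anchored
    clock, which accrues a day's increment on the day itself.
    """
    targets = [(s, stage_tts[s]) for s in STAGE_ORDER]
    incs: list[float] = []
    dates: dict[Stage, _dt.date] = {}
    prev_tt = 0.0
    for stage, tt in targets:
        delta = tt - prev_tt
        if delta < 0:
            raise DomainError(f"{site_id}: stage thermal times must be non-decreasing")
        n_days = max(1, int(np.ceil(delta / 14.0)))
        incs.extend([delta / n_days] * n_days)
        dates[stage] = start + _dt.timedelta(days=len(incs))
        prev_tt = tt
    # day 0 (the origin) plus one trailing day of padding
    incs = [12.0] + incs + [12.0]
    mean_temp = 8.0 + np.asarray(incs)
    df = pd.DataFrame({
        "site_id": site_id,
        "date": [start + _dt.timedelta(days=i) for i in range(len(incs))],
        "tmax_c": mean_temp + 6.0,
        "tmin_c": mean_temp - 6.0,
    })
    return df, dates


def simulate_trials(spec: SimulationSpec, seed: int | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Generate a full trial network from the spec.

    Returns a dict of DataFrames:

    * ``trials`` — one row per site x treatment x block with tt_r6, rau_r6
      and the agronomic outcomes;
    * ``assays`` — one stem assay row per plot and stage (ureide and
      nitrate concentrations);
    * ``weather`` — daily tmax/tmin per site from the V2 origin;
    * ``stages`` — stage dates and thermal times per site;
    * ``sites`` — site ids with their true fixation group and V2 date.

    Deterministic for a fixed ``seed`` (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups = spec.site_groups()
    lo, hi = spec.tt_r6_range
    site_tt_r6 = {sid: float(rng.uniform(lo, hi)) for sid in spec.site_ids()}
    site_rau_shift = {
        sid: float(rng.normal(0.0, spec.site_rau_sd)) for sid in spec.site_ids()
    }
    tt_ref = 0.5 * (lo + hi)

    weather_parts, stage_rows, assay_rows, trial_rows = [], [], [], []
    for sid in spec.site_ids():
        tt_r6 = site_tt_r6[sid]
        axis_scale = tt_r6 / tt_ref if spec.scale_axis_with_season else 1.0
        stage_tts = {s: f * tt_r6 for s, f in spec.stage_fractions.items()}
        wdf, stage_dates = _site_weather(sid, stage_tts, spec.season_start)
        weather_parts.append(wdf)
        for s in STAGE_ORDER:
            stage_rows.append({
                "site_id": sid, "stage": s.value,
                "date": stage_dates[s], "tt": stage_tts[s],
            })
        for treatment in spec.treatments:
            for block in range(1, spec.n_blocks + 1):
                rau_r6_plot = None
                for s in STAGE_ORDER:
                    rau, u, nconc = simulate_rau(
                        spec, groups[sid], treatment, stage_tts[s], rng,
                        rau_shift=site_rau_shift[sid], axis_scale=axis_scale)
                    if s is Stage.R6:
                        rau_r6_plot = rau
                    assay_rows.append({
                        "site_id": sid, "treatment": treatment, "block": block,
                        "stage": s.value, "ureide_conc": u, "nitrate_conc": nconc,
                    })
                trial_rows.append({
                    "site_id": sid, "treatment": treatment, "block": block,
                    "tt_r6": tt_r6, "rau_r6": rau_r6_plot,
                })

    trials = pd.DataFrame(trial_rows)
    rau_centered = trials["rau_r6"] - trials["rau_r6"].mean()

    def draw_trait(model: TraitModel, hetero: bool = False) -> np.ndarray:
        trend = model.trend(trials["tt_r6"].to_numpy())
        sd = np.full(len(trials), model.noise_sd)
        if hetero:
            # inflate noise where the trend is low: widens the bottom
            # boundary relative to the mean response
            rel = (trend - trend.min()) / max(np.ptp(trend), 1e-12)
            sd = sd * (1.0 + 2.0 * (1.0 - rel))
        return trend + model.bnf_cost_slope * rau_centered.to_numpy() + rng.normal(0.0, sd)

    trials["seed_yield"] = draw_trait(spec.yield_model)
    trials["hi"] = np.clip(draw_trait(spec.hi_model, spec.heteroscedastic_hi), 0.05, 0.95)
    trials["oil"] = draw_trait(spec.oil_model)
    trials["protein"] = draw_trait(spec.protein_model)
    trials["biomass"] = trials["seed_yield"] / trials["hi"]

    sites = pd.DataFrame({
        "site_id": spec.site_ids(),
        "group_true": [groups[s] for s in spec.site_ids()],
        "v2_date": spec.season_start,
        "tt_r6": [site_tt_r6[s] for s in spec.site_ids()],
    })
    return {
        "trials": trials,
        "assays": pd.DataFrame(assay_rows),
        "weather": pd.concat(weather_parts, ignore_index=True),
        "stages": pd.DataFrame(stage_rows),
        "sites": sites,
    }
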