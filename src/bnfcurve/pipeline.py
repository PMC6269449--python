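"""Orchestration of the full seasonal-BNF analysis.

Stages, in order:

1. **Grouping** — sites are split into low / medium / high fixation groups
   by the quartiles of control-treatment RAU_R6 across sites.
2. **Curve fitting** — one beta growth curve per (group, treatment) cell on
   pooled observations, with derived traits (max rate, t_0.5, AUC raw and
   normalized to the dataset maximum).
3. **Treatment comparison** — AICc, control vs each fertilized treatment
   within a group (pairwise shared-vs-separate curves).
4. **De-trending** — bilinear phenology trends of yield, HI and oil on
   thermal time to R6 (site x treatment means by default), then mean and
   0.01/0.99-quantile regressions of the residuals on RAU_R6.  Protein and
   biomass are computed too but flagged as expected non-significant.
5. **Site summaries** — per-site across-treatment means with normal-theory
   95% confidence intervals (t distribution on n - 1 df).

``run_full_pipeline`` is deterministic for a fixed seed and returns a
report bundle serializable to JSON and Markdown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data
from .bnf_curve import AiccComparison, BetaCurveFit, compare_fits_aicc, fit_beta
from .errors import BnfCurveError, DomainError, InsufficientDataError
from .phenology_residuals import (
    fit_bilinear,
    residual_mean_regression,
    residual_quantile_regression,
)
from .ureide_thermal import STAGE_ORDER, Stage, Treatment, compute_rau

logger = logging.getLogger("bnfcurve.pipeline")

__all__ = [
    "GroupAssignment",
    "assign_bnf_groups",
    "pooled_group_curves",
    "summarize_sites",
    "detrend_and_regress",
    "run_full_pipeline",
]

GROUPS = ("low", "medium", "high")
#: Traits de-trended against thermal time to R6; the flagged ones are
#: reported but expected non-significant.
DETREND_TRAITS = ("seed_yield", "hi", "oil", "protein", "biomass")
EXPECTED_NONSIG = ("protein", "biomass")


@dataclass(frozen=True)
class GroupAssignment:
    """Quartile split of sites by control RAU_R6.

    Sites strictly below the 25th percentile are "low", at or above the
    75th are "high", the rest "medium"; ties at the lower quartile stay
    medium.  When the two quartiles coincide (no spread) every site is
    medium.
    """

    groups: Mapping[str, str]
    q25: float
    q75: float

    def sites_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def assign_bnf_groups(control_rau_r6: Mapping[str, float]) -> GroupAssignment:
    """Split sites into fixation groups by quartiles of control RAU_R6.

    Quartiles use linear interpolation between order statistics.
    """
    if not control_rau_r6:
        raise InsufficientDataError("no control RAU_R6 values supplied")
    if len(control_rau_r6) < 4:
        raise InsufficientDataError(
            f"need >= 4 sites to form quartile groups, got {len(control_rau_r6)}"
        )
    values = np.array(list(control_rau_r6.values()), dtype=float)
    q25, q75 = np.quantile(values, [0.25, 0.75])
    groups = {}
    for site, v in control_rau_r6.items():
        if v < q25:
            groups[site] = "low"
        elif v >= q75 and q75 > q25:
            groups[site] = "high"
        else:
            groups[site] = "medium"
    return GroupAssignment(groups=dict(groups), q25=float(q25), q75=float(q75))


def _assay_observations(assays: pd.DataFrame, stage_tts: pd.DataFrame) -> pd.DataFrame:
    """Join assays with per-site stage thermal times and compute RAU."""
    tt = stage_tts.rename(columns={"tt": "t"})[["site_id", "stage", "t"]]
    df = assays.merge(tt, on=["site_id", "stage"], how="left")
    if df["t"].isna().any():
        missing = df.loc[df["t"].isna(), ["site_id", "stage"]].drop_duplicates()
        raise DomainError(f"no stage thermal time for: {missing.to_dict('records')}")
    df["rau"] = compute_rau(df["ureide_conc"].to_numpy(), df["nitrate_conc"].to_numpy())
    return df


def pooled_group_curves(
    assays: pd.DataFrame,
    stage_tts: pd.DataFrame,
    assignment: GroupAssignment,
) -> dict[tuple[str, str], BetaCurveFit]:
    """Fit one beta curve per (group, treatment) cell on pooled observations.

    Cells with fewer than 4 observations are skipped with a warning rather
    than aborting the run.
    """
    df = _assay_observations(assays, stage_tts)
    df["group"] = df["site_id"].map(assignment.groups)
    fits: dict[tuple[str, str], BetaCurveFit] = {}
    for (group, treatment), cell in df.groupby(["group", "treatment"], sort=True):
        if len(cell) < 4:
            logger.warning("skipping (%s, %s): only %d observations", group, treatment, len(cell))
            continue
        fits[(group, treatment)] = fit_beta(
            (cell["t"].to_numpy(), cell["rau"].to_numpy())
        )
    return fits


def fits_table(fits: Mapping[tuple[str, str], BetaCurveFit],
               t_end_by_group: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Tabulate fitted parameters and derived traits, one row per cell.

    ``t_end_by_group`` gives the AUC integration end (last observed stage
    thermal time); when omitted, 1.25 x t_max is used per cell.  AUC is
    normalized to the largest raw AUC in the table.
    """
    rows = []
    for (group, treatment), f in sorted(fits.items()):
        t_end = (t_end_by_group or {}).get(group, 1.25 * f.t_max_)
        raw, _ = f.auc(t_end)
        rows.append({
            "group": group, "treatment": treatment,
            "rau_max": f.rau_max, "se_rau_max": f.se_rau_max,
            "t_m": f.t_m, "se_t_m": f.se_t_m,
            "t_max": f.t_max_, "se_t_max": f.se_t_max,
            "t_half": f.t_half, "max_rate": f.max_rate,
            "auc_raw": raw, "r2": f.r2, "syx": f.syx, "n_obs": f.n_obs,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["auc_rel"] = out["auc_raw"] / out["auc_raw"].max()
    return out


def compare_treatments(
    assays: pd.DataFrame,
    stage_tts: pd.DataFrame,
    assignment: GroupAssignment,
) -> pd.DataFrame:
    """AICc comparison of control vs each fertilized treatment within groups."""
    df = _assay_observations(assays, stage_tts)
    df["group"] = df["site_id"].map(assignment.groups)
    rows = []
    for group, gdf in df.groupby("group", sort=True):
        ctrl = gdf[gdf["treatment"] == Treatment.control.value]
        if len(ctrl) < 4:
            continue
        for treatment in sorted(gdf["treatment"].unique()):
            if treatment == Treatment.control.value:
                continue
            other = gdf[gdf["treatment"] == treatment]
            if len(other) < 4:
                continue
            cmp = compare_fits_aicc(
                (ctrl["t"].to_numpy(), ctrl["rau"].to_numpy()),
                (other["t"].to_numpy(), other["rau"].to_numpy()),
            )
            rows.append({
                "group": group, "treatment": treatment,
                "aicc_shared": cmp.aicc_shared, "aicc_separate": cmp.aicc_separate,
                "delta": cmp.delta, "preferred": cmp.preferred,
                "evidence_ratio": cmp.evidence_ratio,
            })
    return pd.DataFrame(rows)


def summarize_sites(trials: pd.DataFrame, traits: Sequence[str] = ("seed_yield", "protein", "oil", "rau_r6")) -> pd.DataFrame:
    """Per-site across-treatment means with t-based 95% confidence intervals.

    Missing trait values are dropped per trait, with the used count
    reported; a site with a single value gets a zero-width interval is not
    assumed — its half-width is NaN.
    """
    rows = []
    for site, sdf in trials.groupby("site_id", sort=True):
        row = {"site_id": site}
        for trait in traits:
            vals = sdf[trait].dropna().to_numpy(dtype=float)
            n = vals.size
            row[f"{trait}_n"] = n
            if n == 0:
                row[f"{trait}_mean"] = np.nan
                row[f"{trait}_ci95"] = np.nan
                continue
            m = float(np.mean(vals))
            if n > 1:
                sem = float(np.std(vals, ddof=1) / np.sqrt(n))
                half = float(stats.t.ppf(0.975, n - 1) * sem)
            else:
                half = np.nan
            row[f"{trait}_mean"] = m
            row[f"{trait}_ci95"] = half
        rows.append(row)
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def detrend_and_regress(
    trials: pd.DataFrame,
    taus: Sequence[float] = (0.01, 0.99),
    use_site_treatment_means: bool = True,
    traits: Sequence[str] = DETREND_TRAITS,
) -> dict:
    """Bilinear de-trending on thermal time to R6 + residual regressions.

    By default each trait is averaged to site x treatment means before
    de-trending (92 points in the reference design); set
    ``use_site_treatment_means=False`` for plot-level fits.  Each trait is
    de-trended independently; residuals are regressed on RAU_R6 at the mean
    (OLS with a slope test) and at the requested quantiles.
    """
    if use_site_treatment_means:
        df = (
            trials.groupby(["site_id", "treatment"], as_index=False)
            [["tt_r6", "rau_r6", *traits]].mean()
        )
    else:
        df = trials.copy()
    out: dict = {"points_used": int(len(df)), "traits": {}}
    for trait in traits:
        sub = df.dropna(subset=[trait, "tt_r6", "rau_r6"])
        x = sub["tt_r6"].to_numpy(dtype=float)
        y = sub[trait].to_numpy(dtype=float)
        u = sub["rau_r6"].to_numpy(dtype=float)
        blf = fit_bilinear(x, y)
        mean_reg = residual_mean_regression(blf.residuals, u)
        entry = {
            "bilinear": {"a": blf.a, "b": blf.b, "d": blf.d,
                         "tt_o": blf.tt_o, "r2": blf.r2},
            "mean": {"slope": mean_reg.slope, "intercept": mean_reg.intercept,
                     "p_value": mean_reg.p_value, "stars": _stars(mean_reg.p_value),
                     "n": mean_reg.n},
            "quantiles": {},
            "expected_nonsignificant": trait in EXPECTED_NONSIG,
        }
        for tau in taus:
            qr = residual_quantile_regression(blf.residuals, u, tau)
            entry["quantiles"][str(tau)] = {
                "slope": qr.slope, "intercept": qr.intercept, "n": qr.n,
            }
        out["traits"][trait] = entry
    return out


@dataclass
class PipelineConfig:
    """Configuration for ``run_full_pipeline``.

    Either supply input tables (``trials``, ``assays``, ``stages`` frames
    or CSV paths via the CLI) or a :class:`~bnfcurve.synthetic_data.SimulationSpec`.
    """

    simulation: synthetic_data.SimulationSpec | None = None
    trials: pd.DataFrame | None = None
    assays: pd.DataFrame | None = None
    stages: pd.DataFrame | None = None
    seed: int = 0
    taus: tuple[float, ...] = (0.01, 0.99)
    use_site_treatment_means: bool = True


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run grouping, curve fits, AICc comparisons, de-trending and summaries.

    Deterministic for a fixed configuration and seed; the returned bundle is
    JSON-serializable (see :func:`report_json` / :func:`report_markdown`).
    Any stage failure aborts with the stage name attached.
    """
    if config.simulation is not None:
        tables = synthetic_data.simulate_trials(config.simulation, seed=config.seed)
        trials, assays, stages = tables["trials"], tables["assays"], tables["stages"]
    else:
        trials, assays, stages = config.trials, config.assays, config.stages
    if trials is None or assays is None or stages is None:
        raise DomainError("pipeline needs trials, assays and stage thermal times")

    def _stage(name, fn):
        try:
            return fn()
        except BnfCurveError as exc:
            raise BnfCurveError(f"pipeline stage {name!r} failed: {exc}") from exc

    control = trials[trials["treatment"] == Treatment.control.value]
    control_rau = control.groupby("site_id")["rau_r6"].mean().to_dict()
    assignment = _stage("grouping", lambda: assign_bnf_groups(control_rau))

    fits = _stage("curves", lambda: pooled_group_curves(assays, stages, assignment))
    t_end_by_group = (
        stages.merge(
            pd.Series(assignment.groups, name="group"),
            left_on="site_id", right_index=True)
        .groupby("group")["tt"].max().to_dict()
    )
    table = fits_table(fits, t_end_by_group)
    comparisons = _stage("aicc", lambda: compare_treatments(assays, stages, assignment))
    regressions = _stage("detrend", lambda: detrend_and_regress(
        trials, taus=config.taus,
        use_site_treatment_means=config.use_site_treatment_means))
    summaries = _stage("summaries", lambda: summarize_sites(trials))

    logger.info(
        "pipeline: %d sites, quartile rule q25=%.2f q75=%.2f (ties at q25 -> medium), "
        "breakpoint grid = observed tt_r6 minus 2 extremes/end, seed=%d, taus=%s",
        len(assignment.groups), assignment.q25, assignment.q75, config.seed,
        list(config.taus),
    )
    return {
        "seed": config.seed,
        "groups": {
            "assignment": dict(sorted(assignment.groups.items())),
            "q25": assignment.q25,
            "q75": assignment.q75,
            "sizes": {g: len(assignment.sites_in(g)) for g in GROUPS},
        },
        "curve_fits": table.to_dict(orient="records"),
        "aicc_comparisons": comparisons.to_dict(orient="records"),
        "residual_regressions": regressions,
        "site_summaries": summaries.to_dict(orient="records"),
    }


def report_json(report: dict, indent: int = 2) -> str:
    """Serialize a report bundle deterministically (sorted keys)."""
    return json.dumps(report, indent=indent, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def report_markdown(report: dict) -> str:
    """Render the report bundle as a human-readable Markdown summary."""
    lines = ["# Seasonal BNF analysis report", ""]
    g = report["groups"]
    lines += [
        "## Fixation groups (quartiles of control RAU_R6)",
        f"- q25 = {g['q25']:.2f}%, q75 = {g['q75']:.2f}%",
        f"- sizes: low {g['sizes']['low']}, medium {g['sizes']['medium']}, high {g['sizes']['high']}",
        "",
        "## Beta curve fits per (group, treatment)",
        "| group | treatment | RAU_max | t_m | t_max | t_0.5 | max rate | AUC_rel | R2 | Syx |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for row in report["curve_fits"]:
        lines.append(
            "| {group} | {treatment} | {rau_max:.1f} | {t_m:.0f} | {t_max:.0f} | "
            "{t_half:.0f} | {max_rate:.4f} | {auc_rel:.2f} | {r2:.2f} | {syx:.1f} |".format(**row)
        )
    lines += ["", "## AICc: control vs fertilized (within group)",
              "| group | treatment | delta AICc | preferred | evidence ratio |",
              "|---|---|---|---|---|"]
    for row in report["aicc_comparisons"]:
        lines.append(
            "| {group} | {treatment} | {delta:.1f} | {preferred} | {evidence_ratio:.1f} |".format(**row)
        )
    lines += ["", "## Residual regressions vs RAU_R6 (phenology removed)"]
    for trait, entry in report["residual_regressions"]["traits"].items():
        m = entry["mean"]
        flag = " (expected non-significant)" if entry["expected_nonsignificant"] else ""
        lines.append(
            f"- **{trait}**{flag}: mean slope {m['slope']:.4g} per % RAU_R6 "
            f"(p = {m['p_value']:.3g} {m['stars']})"
        )
        for tau, q in entry["quantiles"].items():
            lines.append(f"  - tau={tau}: slope {q['slope']:.4g}")
    return "\n".join(lines) + "\n"
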