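"""One-call orchestration of the full per-treatment analysis.

Stages, in order: SD imputation → effect sizes → overall random-effects fit
→ one single-moderator model per listed moderator → trend meta-regressions
(with the treatment's trimming rule) → fertilizer GHG accounting (NPK only)
→ sensitivity rerun excluding imputed-SD records. Every stage is a pure
function of the input records and the config, so a rerun on the same input
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_io, effects, ghg, meta, trends
from .data_io import ObservationRecord

logger = logging.getLogger("silvicarbon")

#: Moderators tested per treatment (categorical ones; continuous covariates
#: are handled by the trend stage).
DEFAULT_MODERATORS: dict[str, list[str]] = {
    "interplant": [
        "prev_land_use",
        "tree_genus",
        "soil_moisture_regime",
        "intercrop_genus",
        "wood_type",
        "experimental_design",
    ],
    "npk": [
        "prev_land_use",
        "tree_genus",
        "soil_moisture_regime",
        "wood_type",
        "application_method",
    ],
    "thin": ["prev_land_use", "soil_moisture_regime", "wood_type", "tree_genus"],
}

#: Trend regressions per treatment: (label, covariate, trim_max).
DEFAULT_TRENDS: dict[str, list[tuple[str, str, float]]] = {
    "interplant": [
        ("stand_age", "stand_age", trends.AGE_TRIM_INTERPLANT),
        ("map_mm", "map_mm", math.inf),
    ],
    "npk": [
        ("time_since_treatment", "__npk_time__", trends.TIME_TRIM_NPK),
        ("map_mm", "map_mm", math.inf),
    ],
    "thin": [
        ("time_since_treatment", "time_since_treatment", math.inf),
        ("basal_area_removed", "basal_area_removed", math.inf),
        ("map_mm", "map_mm", math.inf),
    ],
}


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    treatment: str
    input_path: str | None = None
    moderators: list[str] | None = None
    out_dir: str | None = None
    seed: int = 0
    exclude_imputed: bool = False
    ghg_constants: ghg.GhgConstants = field(default_factory=ghg.GhgConstants)

    def __post_init__(self) -> None:
        if self.treatment not in data_io.TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        allowed = set(DEFAULT_MODERATORS[self.treatment])
        for mod in self.moderators or []:
            if mod not in allowed:
                raise ValueError(
                    f"moderator {mod!r} is not in the {self.treatment} schema "
                    f"(allowed: {sorted(allowed)})"
                )


@dataclass
class ReportBundle:
    """Everything one analysis run computed."""

    treatment: str
    effects: pd.DataFrame
    overall: meta.MetaFit
    moderator_fits: dict[str, meta.MetaFit]
    skipped_moderators: dict[str, str]
    trend_fits: dict[str, trends.TrendFit]
    trend_dropped: dict[str, int]
    funnel: pd.DataFrame
    egger: dict | None
    sensitivity: meta.SensitivityResult | None
    ghg_results: list[ghg.GhgResult]
    ghg_regression: ghg.NetBalanceRegression | None
    log_lines: list[str]

    def report_dict(self) -> dict:
        """JSON-serializable summary of the run."""
        qm, df, p = self.overall.omnibus
        out: dict = {
            "treatment": self.treatment,
            "k": self.overall.k,
            "m": self.overall.m,
            "overall": {
                "lnrr": float(self.overall.coefficients[0]),
                "tau2": self.overall.tau2,
                "percent_change": float(self.overall.percent["estimate_pct"][0]),
                "ci_low_pct": float(self.overall.percent["ci_low_pct"][0]),
                "ci_high_pct": float(self.overall.percent["ci_high_pct"][0]),
                "p": p,
            },
            "moderators": {},
            "skipped_moderators": self.skipped_moderators,
            "trends": {},
            "egger": self.egger,
            "log": self.log_lines,
        }
        for name, fit in self.moderator_fits.items():
            qm, df, p = fit.omnibus
            out["moderators"][name] = {
                "omnibus_QM": qm,
                "omnibus_df": df,
                "omnibus_p": p,
                "dropped_categories": fit.dropped_categories,
                "terms": fit.summary_frame().to_dict("records"),
            }
        for name, tfit in self.trend_fits.items():
            out["trends"][name] = {
                "intercept": tfit.intercept,
                "slope": tfit.slope,
                "percent_per_unit": tfit.percent_per_unit,
                "percent_per_unit_exact": tfit.percent_per_unit_exact,
                "p_slope": tfit.p_slope,
                "n_used": tfit.n_used,
                "n_trimmed": self.trend_dropped.get(name, 0),
                "zero_crossing": trends.zero_crossing(tfit),
            }
        if self.sensitivity is not None:
            out["sensitivity"] = {
                "n_removed": self.sensitivity.n_removed,
                "robust": self.sensitivity.robust,
                "difference": self.sensitivity.difference.to_dict("records"),
            }
        if self.ghg_regression is not None:
            g = self.ghg_regression
            out["ghg"] = {
                "n": g.n,
                "intercept": g.intercept,
                "slope": g.slope,
                "r_squared": g.r_squared,
                "p_slope": g.p_slope,
                "median_net_balance": g.median_net_balance,
                "break_even_n": g.break_even_n,
            }
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write the CSV/JSON artifact set and the run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.effects.to_csv(out / "effects.csv", index=False)
        self.overall.summary_frame().to_csv(out / "overall.csv", index=False)
        mod_dir = out / "moderators"
        mod_dir.mkdir(exist_ok=True)
        for name, fit in self.moderator_fits.items():
            fit.summary_frame().to_csv(mod_dir / f"{name}.csv", index=False)
        if self.trend_fits:
            rows = []
            for name, tfit in self.trend_fits.items():
                rows.append(
                    {
                        "trend": name,
                        "intercept": tfit.intercept,
                        "slope": tfit.slope,
                        "percent_per_unit": tfit.percent_per_unit,
                        "p_slope": tfit.p_slope,
                        "n_used": tfit.n_used,
                        "zero_crossing": trends.zero_crossing(tfit),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "trend.csv", index=False)
        self.funnel.to_csv(out / "funnel.csv", index=False)
        if self.ghg_results:
            ghg.ghg_results_frame(self.ghg_results).to_csv(out / "ghg.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, default=_json_default)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(log: list[str], name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def run_analysis(
    config: RunConfig,
    records: Sequence[ObservationRecord] | None = None,
) -> ReportBundle:
    """Execute the full analysis for one treatment.

    ``records`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from ``config.input_path``. Moderators with
    fewer than two populated categories are skipped with a warning rather
    than aborting the run.
    """
    log: list[str] = []
    if records is None:
        if config.input_path is None:
            raise ValueError("RunConfig needs an input_path when no records are given")
        records = _stage(log, "read", data_io.read_compilation, config.input_path)
    records = [r for r in records if r.treatment == config.treatment]
    if not records:
        raise RuntimeError(f"stage 'select': no {config.treatment!r} records in input")
    log.append(f"selected {len(records)} {config.treatment} comparisons")

    eff = _stage(log, "effects", effects.compute_effect_sizes, records)
    n_imputed = int((eff["sd_imputed_treat"] | eff["sd_imputed_ctrl"]).sum())
    log.append(f"imputed SDs for {n_imputed} of {len(eff)} comparisons")
    if config.exclude_imputed:
        keep = ~(eff["sd_imputed_treat"] | eff["sd_imputed_ctrl"])
        dropped = int((~keep).sum())
        records = [r for r, k in zip(records, keep) if k]
        eff = eff[keep].reset_index(drop=True)
        log.append(f"excluded {dropped} imputed-SD comparisons (--exclude-imputed)")

    overall = _stage(log, "overall_fit", meta.fit_random_effects, eff)
    log.append(
        f"overall: k={overall.k}, m={overall.m}, tau2={overall.tau2:.5f}, "
        f"lnRR={overall.coefficients[0]:+.4f}"
    )

    rec_frame = data_io.records_to_frame(records)
    moderator_fits: dict[str, meta.MetaFit] = {}
    skipped: dict[str, str] = {}
    for mod in config.moderators or DEFAULT_MODERATORS[config.treatment]:
        values = rec_frame[mod]
        try:
            fit = meta.fit_moderator_model(eff, values=values, moderator=mod)
        except ValueError as exc:
            skipped[mod] = str(exc)
            log.append(f"moderator {mod!r} skipped: {exc}")
            continue
        moderator_fits[mod] = fit
        if fit.dropped_categories:
            log.append(
                f"moderator {mod!r}: dropped single-observation categories "
                f"{fit.dropped_categories}"
            )

    trend_fits: dict[str, trends.TrendFit] = {}
    trend_dropped: dict[str, int] = {}
    for label, covariate, trim_max in DEFAULT_TRENDS[config.treatment]:
        if covariate == "__npk_time__":
            raw = trends.npk_time_values(records)
        else:
            raw = [getattr(r, covariate) for r in records]
        vals = pd.Series(raw, dtype=float)
        trimmed = vals.where(vals <= trim_max)
        n_trim = int((vals > trim_max).sum())
        trend_dropped[label] = n_trim
        if n_trim:
            log.append(f"trend {label!r}: trimmed {n_trim} records above {trim_max}")
        try:
            tfit = trends.fit_time_meta_regression(
                eff, covariate=label, values=trimmed
            )
        except (ValueError, KeyError) as exc:
            skipped[f"trend:{label}"] = str(exc)
            log.append(f"trend {label!r} skipped: {exc}")
            continue
        trend_fits[label] = tfit

    funnel, egger = _stage(log, "funnel", meta.funnel_data, eff)

    ghg_results: list[ghg.GhgResult] = []
    ghg_reg = None
    if config.treatment == "npk":
        ghg_results = _stage(
            log, "ghg", ghg.compute_ghg_results, records, config.ghg_constants
        )
        log.append(f"ghg accounting for {len(ghg_results)} comparisons")
        if len(ghg_results) >= 3:
            ghg_reg = _stage(
                log, "ghg_regression", ghg.fit_net_balance_regression, ghg_results
            )

    sensitivity = None
    if not config.exclude_imputed and n_imputed > 0:
        sensitivity = _stage(
            log, "sensitivity", meta.sensitivity_reanalysis, records
        )
        log.append(
            f"sensitivity: removed {sensitivity.n_removed} imputed records, "
            f"robust={sensitivity.robust}"
        )

    bundle = ReportBundle(
        treatment=config.treatment,
        effects=eff,
        overall=overall,
        moderator_fits=moderator_fits,
        skipped_moderators=skipped,
        trend_fits=trend_fits,
        trend_dropped=trend_dropped,
        funnel=funnel,
        egger=egger,
        sensitivity=sensitivity,
        ghg_results=ghg_results,
        ghg_regression=ghg_reg,
        log_lines=log,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
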