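"""Log response ratio effect sizes, sampling variances, SD imputation.

The effect size is the natural log of the response ratio,

    lnRR = ln(X̄_t / X̄_c) = ln X̄_t − ln X̄_c,

where X̄_t and X̄_c are mean aboveground carbon in the paired treatment and
control arms. lnRR = 0 means no treatment effect; effects are pooled with
inverse-variance weights. The delta-method sampling variance is

    v = sd_t² / (n_t · X̄_t²) + sd_c² / (n_c · X̄_c²).

Studies that omit arm SDs get them imputed from the median coefficient of
variation (SD/mean) of the complete records in the same treatment analysis
and arm, multiplied by the record's own reported mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ObservationRecord


@dataclass(frozen=True)
class EffectSize:
    """One comparison's lnRR, its sampling variance, and imputation flags."""

    lnrr: float
    variance: float
    sd_imputed_treat: bool = False
    sd_imputed_ctrl: bool = False

    @property
    def weight(self) -> float:
        """Inverse-variance weight; infinite variance would weigh zero."""
        if self.variance <= 0:
            raise ValueError("weight undefined for non-positive variance")
        return 1.0 / self.variance


def compute_lnrr(mean_treat: float, mean_ctrl: float) -> float:
    """lnRR = ln(mean_treat) − ln(mean_ctrl). Both means must be positive."""
    if mean_treat <= 0 or mean_ctrl <= 0:
        raise ValueError(
            f"lnRR requires positive means, got ({mean_treat}, {mean_ctrl})"
        )
    return math.log(mean_treat) - math.log(mean_ctrl)


def lnrr_variance(
    sd_treat: float,
    n_treat: int,
    mean_treat: float,
    sd_ctrl: float,
    n_ctrl: int,
    mean_ctrl: float,
) -> float:
    """Delta-method sampling variance of lnRR from arm summaries.

    Raises
    ------
    ValueError
        If either SD is missing (impute first) or preconditions fail.
    """
    if sd_treat is None or sd_ctrl is None:
        raise ValueError("missing SD: run impute_missing_sd before computing variances")
    if mean_treat <= 0 or mean_ctrl <= 0:
        raise ValueError("means must be positive")
    if n_treat < 1 or n_ctrl < 1:
        raise ValueError("replicate counts must be >= 1")
    if sd_treat < 0 or sd_ctrl < 0:
        raise ValueError("SDs must be non-negative")
    return sd_treat**2 / (n_treat * mean_treat**2) + sd_ctrl**2 / (
        n_ctrl * mean_ctrl**2
    )


def percent_change(lnrr: float) -> float:
    """Back-transform lnRR to percent change relative to control.

    (e^lnRR − 1) × 100; strictly increasing in lnRR, bounded below by −100.
    """
    if not math.isfinite(lnrr):
        raise ValueError(f"lnrr must be finite, got {lnrr}")
    return (math.exp(lnrr) - 1.0) * 100.0


def impute_missing_sd(
    records: Sequence[ObservationRecord],
) -> tuple[list[ObservationRecord], pd.DataFrame]:
    """Fill missing arm SDs by the median coefficient of variation.

    For each treatment analysis (interplant / npk / thin) and each arm
    (treatment vs control), the median CV = SD/mean is computed across the
    records of that analysis that report the arm's SD; a record missing the
    arm SD gets SD = median CV × its own reported mean. Complete records are
    returned untouched; the function is idempotent.

    Returns the new record list plus a flags table with columns
    ``sd_imputed_treat`` / ``sd_imputed_ctrl`` aligned to the records.

    Raises
    ------
    ValueError
        If an imputation is needed in a group with no complete record.
    """
    records = list(records)
    median_cv: dict[tuple[str, str], float] = {}
    for treatment in sorted({r.treatment for r in records}):
        for arm in ("treat", "ctrl"):
            cvs = [
                getattr(r, f"sd_{arm}") / getattr(r, f"mean_{arm}")
                for r in records
                if r.treatment == treatment and getattr(r, f"sd_{arm}") is not None
            ]
            if cvs:
                median_cv[(treatment, arm)] = float(np.median(cvs))

    out: list[ObservationRecord] = []
    flags = {"sd_imputed_treat": [], "sd_imputed_ctrl": []}
    for r in records:
        updates: dict[str, float] = {}
        for arm in ("treat", "ctrl"):
            missing = getattr(r, f"sd_{arm}") is None
            flags[f"sd_imputed_{arm}"].append(missing)
            if missing:
                key = (r.treatment, arm)
                if key not in median_cv:
                    raise ValueError(
                        f"cannot impute sd_{arm} for treatment {r.treatment!r}: "
                        "no record in this group reports both mean and SD"
                    )
                updates[f"sd_{arm}"] = median_cv[key] * getattr(r, f"mean_{arm}")
        out.append(replace(r, **updates) if updates else r)
    return out, pd.DataFrame(flags)


def compute_effect_sizes(
    records: Sequence[ObservationRecord],
    *,
    impute: bool = True,
    variance_floor: float = 1e-12,
) -> pd.DataFrame:
    """Full effect-size table for a record list.

    Imputes missing SDs (unless ``impute=False``, in which case records with
    missing SDs raise), then computes lnRR and its sampling variance per
    comparison. Zero sampling variances are floored at ``variance_floor`` so
    inverse-variance weights stay finite; floored rows are flagged.

    Returns a DataFrame with one row per comparison: ``study_id``,
    ``site_id``, ``treatment``, ``lnrr``, ``variance``, ``weight``,
    ``sd_imputed_treat``, ``sd_imputed_ctrl``, ``variance_floored``.
    """
    if impute:
        filled, flags = impute_missing_sd(records)
    else:
        filled = list(records)
        flags = pd.DataFrame(
            {
                "sd_imputed_treat": [False] * len(filled),
                "sd_imputed_ctrl": [False] * len(filled),
            }
        )
    rows = []
    for i, rec in enumerate(filled):
        lnrr = compute_lnrr(rec.mean_treat, rec.mean_ctrl)
        v = lnrr_variance(
            rec.sd_treat, rec.n_treat, rec.mean_treat,
            rec.sd_ctrl, rec.n_ctrl, rec.mean_ctrl,
        )
        floored = v < variance_floor
        v = max(v, variance_floor)
        rows.append(
            {
                "study_id": rec.study_id,
                "site_id": rec.site_id,
                "treatment": rec.treatment,
                "lnrr": lnrr,
                "variance": v,
                "weight": 1.0 / v,
                "sd_imputed_treat": bool(flags["sd_imputed_treat"].iloc[i]),
                "sd_imputed_ctrl": bool(flags["sd_imputed_ctrl"].iloc[i]),
                "variance_floored": floored,
            }
        )
    return pd.DataFrame(rows)
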