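"""Time and continuous-covariate meta-regressions with trimming rules.

The effect of a treatment on aboveground carbon is rarely static: the
benefit of interplanted N-fixers builds with stand age, fertilization gains
fade with time since application, and thinning losses are recouped as the
residual stand grows. These trends are estimated with the same
publication-level random-effects machinery as the moderator models, using an
intercept + slope design on the lnRR scale.

Trimming rules guard the regressions against sparse data at long horizons:
interplanting drops stand ages above 20 years, NPK fertilization drops times
since treatment above 5 years, and thinning keeps all time-since-thinning
data. For NPK, studies applying fertilizer continuously over the study
period use stand age as the time variable; pulse-application studies use
time since treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ObservationRecord
from .meta import MetaFit, fit_moderator_model

#: Trimming thresholds: covariate values above these are dropped before the
#: trend regression. Thinning uses all time-since-thinning data (no cap).
AGE_TRIM_INTERPLANT = 20.0
TIME_TRIM_NPK = 5.0


@dataclass
class TrendFit:
    """A fitted lnRR-vs-covariate meta-regression."""

    covariate: str
    intercept: float
    slope: float
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    p_slope: float
    tau2: float
    n_used: int
    n_dropped: int
    meta_fit: MetaFit

    @property
    def percent_per_unit(self) -> float:
        """Approximate percent change in the response ratio per covariate
        unit: 100·slope (small-effect approximation on the lnRR scale)."""
        return 100.0 * self.slope

    @property
    def percent_per_unit_exact(self) -> float:
        """Exact multiplicative alternative, 100·(e^slope − 1)."""
        return 100.0 * (math.exp(self.slope) - 1.0)

    def predict(
        self, grid: np.ndarray | None = None, n_points: int = 50,
        lo: float | None = None, hi: float | None = None,
    ) -> pd.DataFrame:
        """Fitted line with a pointwise Wald 95% band over a covariate grid."""
        if grid is None:
            if lo is None or hi is None:
                raise ValueError("pass a grid or (lo, hi) bounds")
            grid = np.linspace(lo, hi, n_points)
        grid = np.asarray(grid, dtype=float)
        X = np.column_stack([np.ones_like(grid), grid])
        yhat = X @ self.meta_fit.coefficients
        var = np.einsum("ij,jk,ik->i", X, self.meta_fit.coef_cov, X)
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        return pd.DataFrame(
            {
                self.covariate: grid,
                "lnrr_fit": yhat,
                "lnrr_low": yhat - half,
                "lnrr_high": yhat + half,
            }
        )


def trim_by_covariate(
    records: Sequence[ObservationRecord],
    covariate: str,
    max_value: float,
) -> tuple[list[ObservationRecord], int]:
    """Drop records whose covariate exceeds ``max_value``.

    Records missing the covariate are kept (the regression drops them
    later). Returns the retained records and the dropped count.
    ``max_value=inf`` keeps everything.
    """
    kept = [
        r
        for r in records
        if getattr(r, covariate) is None or getattr(r, covariate) <= max_value
    ]
    return kept, len(records) - len(kept)


def fit_time_meta_regression(
    effects,
    study_ids=None,
    covariate: str = "time_since_treatment",
    values: Sequence | None = None,
) -> TrendFit:
    """Mixed-effects meta-regression of lnRR on a continuous covariate.

    ``effects`` follows the conventions of
    :func:`silvicarbon.meta.fit_moderator_model`; the covariate is a column
    of the effects table or an explicit aligned ``values`` vector. Requires
    at least 3 comparisons carrying the covariate and a non-constant
    covariate.
    """
    if values is not None:
        n_total = len(values)
        n_with = int(pd.Series(list(values)).notna().sum())
    elif isinstance(effects, pd.DataFrame) and covariate in effects.columns:
        n_total = len(effects)
        n_with = int(effects[covariate].notna().sum())
    else:
        raise KeyError(f"covariate {covariate!r} not found in effects table")
    if n_with < 3:
        raise ValueError(
            f"need >= 3 comparisons with {covariate!r}, have {n_with}"
        )
    fit = fit_moderator_model(effects, study_ids, moderator=covariate, values=values)
    ci = fit.ci95
    return TrendFit(
        covariate=covariate,
        intercept=float(fit.coefficients[0]),
        slope=float(fit.coefficients[1]),
        ci95_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        p_slope=float(fit.pvalues[1]),
        tau2=fit.tau2,
        n_used=fit.k,
        n_dropped=n_total - fit.k,
        meta_fit=fit,
    )


def zero_crossing(fit: TrendFit) -> float | None:
    """Covariate value where the fitted lnRR line crosses zero.

    Returns −intercept/slope when the slope is nonzero and the crossing lies
    at a positive covariate value (e.g. the stand age at which an initially
    negative interplanting effect turns positive, or the time at which a
    thinning deficit disappears); ``None`` otherwise.
    """
    if fit.slope == 0:
        return None
    x = -fit.intercept / fit.slope
    return x if x > 0 else None


def npk_time_values(records: Sequence[ObservationRecord]) -> list[float | None]:
    """Per-record time variable for the NPK trend regression.

    Continuously fertilized studies use stand age; pulse-application studies
    use time since treatment. Records without an application method fall
    back to time since treatment.
    """
    out: list[float | None] = []
    for r in records:
        if r.application_method == "continuous":
            out.append(r.stand_age)
        else:
            out.append(r.time_since_treatment)
    return out
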