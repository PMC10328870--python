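"""Publication-level random-effects meta-analysis fitted by REML.

Model
-----
For comparison *i* nested in publication *j*,

    y_ij = x_ij' β + u_j + ε_ij,    u_j ~ N(0, τ²),  ε_ij ~ N(0, v_ij),

with y the lnRR effect size, v its known sampling variance, and a single
publication-level variance component τ² absorbing the non-independence of
multiple comparisons reported by one study. The marginal covariance is block
diagonal over publications, V_j = diag(v) + τ² 𝟙𝟙', which inverts in closed
form (Sherman–Morrison), so the restricted log-likelihood

    ℓ_R(τ²) = −½ [ log|V| + log|X'V⁻¹X| + (y − Xβ̂)' V⁻¹ (y − Xβ̂) ]

profiles over the scalar τ² only. τ̂² maximizes ℓ_R on [0, 10·var(y)] by
bounded 1-D optimization (deterministic, no random starts); β̂ is the GLS
estimate at τ̂², with Wald z 95% intervals.

Moderators are tested one at a time: categorical moderators use a cell-means
(no-intercept) design so each coefficient is a category mean on the lnRR
scale, after dropping categories with a single observation; continuous
moderators use intercept + slope. Moderator significance is the omnibus Wald
chi-square QM = b'Σ_b⁻¹b over the tested coefficient block (all coefficients
for cell-means models, the slope alone for intercept+slope models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import ObservationRecord
from .effects import EffectSize, compute_effect_sizes, percent_change

#: Floor for zero sampling variances so inverse-variance weights stay finite.
VARIANCE_FLOOR = 1e-12

#: Convergence tolerance of the 1-D REML profile optimization.
REML_XATOL = 1e-10


class ConvergenceError(RuntimeError):
    """REML profile optimization failed; carries the evaluation trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class MetaFit:
    """A fitted mixed-effects meta-analytic model on the lnRR scale."""

    coefficients: np.ndarray
    coef_cov: np.ndarray
    tau2: float
    k: int
    m: int
    term_names: list[str]
    tested: np.ndarray  # indices of the omnibus-tested coefficient block
    omnibus: tuple[float, int, float] = field(init=False)
    dropped_categories: list[str] = field(default_factory=list)
    k_per_term: list[int] | None = None
    moderator: str | None = None

    def __post_init__(self) -> None:
        self.omnibus = omnibus_test(self)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.coef_cov))

    @property
    def ci95(self) -> np.ndarray:
        """(p, 2) array of Wald z 95% intervals on the lnRR scale."""
        z = stats.norm.ppf(0.975)
        lo = self.coefficients - z * self.se
        hi = self.coefficients + z * self.se
        return np.column_stack([lo, hi])

    @property
    def percent(self) -> pd.DataFrame:
        """Back-transformed percent change per coefficient with CI bounds.

        The exponential back-transform preserves the ordering of the
        lnRR-scale bounds, so lower < estimate < upper always.
        """
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate_pct": [percent_change(b) for b in self.coefficients],
                "ci_low_pct": [percent_change(b) for b in ci[:, 0]],
                "ci_high_pct": [percent_change(b) for b in ci[:, 1]],
            }
        )

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald z p-value per coefficient."""
        z = self.coefficients / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        """One row per coefficient: estimate, CI, percent change, omnibus p."""
        ci = self.ci95
        pct = self.percent
        qm, df, p = self.omnibus
        return pd.DataFrame(
            {
                "term": self.term_names,
                "k": self.k_per_term if self.k_per_term else [self.k] * len(self.term_names),
                "estimate_lnrr": self.coefficients,
                "se": self.se,
                "ci_low_lnrr": ci[:, 0],
                "ci_high_lnrr": ci[:, 1],
                "estimate_pct": pct["estimate_pct"],
                "ci_low_pct": pct["ci_low_pct"],
                "ci_high_pct": pct["ci_high_pct"],
                "p_coef": self.pvalues,
                "omnibus_QM": qm,
                "omnibus_df": df,
                "omnibus_p": p,
            }
        )


def _as_arrays(
    effects, study_ids=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce effects input (DataFrame or EffectSize sequence) to arrays."""
    if isinstance(effects, pd.DataFrame):
        y = effects["lnrr"].to_numpy(dtype=float)
        v = effects["variance"].to_numpy(dtype=float)
        if study_ids is None:
            study_ids = effects["study_id"].to_numpy()
    elif len(effects) > 0 and isinstance(effects[0], EffectSize):
        y = np.array([e.lnrr for e in effects], dtype=float)
        v = np.array([e.variance for e in effects], dtype=float)
    else:
        y = np.asarray(effects, dtype=float)
        v = None  # caller must pass (y, v) tuple via DataFrame or EffectSize
    if v is None:
        raise TypeError("effects must be a DataFrame or a sequence of EffectSize")
    if study_ids is None:
        raise ValueError("study_ids required when effects carry no study_id column")
    sid = np.asarray(study_ids)
    if len(y) != len(sid):
        raise ValueError("effects and study_ids length mismatch")
    return y, v, sid


def _profile_pieces(
    tau2: float,
    y: np.ndarray,
    w: np.ndarray,
    X: np.ndarray,
    starts: np.ndarray,
    logv_sum: float,
):
    """GLS building blocks at a given τ² using per-block Sherman–Morrison.

    With V_j = D_j + τ²𝟙𝟙' and weights w = 1/v,
      V_j⁻¹ = D_j⁻¹ − c_j (D_j⁻¹𝟙)(𝟙'D_j⁻¹),   c_j = τ² / (1 + τ² s_j),
      log|V_j| = Σ log v_i + log(1 + τ² s_j),   s_j = Σ_{i∈j} w_i.

    Requires rows pre-sorted by publication; ``starts`` are block offsets.
    """
    Xw = X * w[:, None]
    A = X.T @ Xw  # X' W X
    b = Xw.T @ y  # X' W y
    q = float(np.dot(y * w, y))  # y' W y
    s = np.add.reduceat(w, starts)
    g = np.add.reduceat(Xw, starts, axis=0)  # per-block Σ w x  (m, p)
    h = np.add.reduceat(w * y, starts)  # per-block Σ w y
    if tau2 > 0:
        c = tau2 / (1.0 + tau2 * s)
        A = A - (g * c[:, None]).T @ g
        b = b - g.T @ (c * h)
        q = q - float(np.dot(c * h, h))
        logdetV = logv_sum + float(np.sum(np.log1p(tau2 * s)))
    else:
        logdetV = logv_sum
    return A, b, q, logdetV


def _neg_restricted_ll(tau2, y, w, X, starts, logv_sum) -> float:
    A, b, q, logdetV = _profile_pieces(tau2, y, w, X, starts, logv_sum)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss = q - float(b @ beta)
    return 0.5 * (logdetV + logdetA + max(rss, 0.0))


def _fit_gls(
    y: np.ndarray,
    v: np.ndarray,
    study: np.ndarray,
    X: np.ndarray,
    term_names: list[str],
    tested: np.ndarray,
    **meta_kwargs,
) -> MetaFit:
    """Profile τ² by REML, then GLS at τ̂²."""
    k, p = X.shape
    if k == 0:
        raise ValueError("no effect sizes to fit")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (unidentifiable model)")
    order = np.argsort(study, kind="stable")
    y_s, v_s, X_s, sid_s = y[order], v[order], X[order], study[order]
    v_s = np.maximum(v_s, VARIANCE_FLOOR)
    w = 1.0 / v_s
    boundaries = np.flatnonzero(np.r_[True, sid_s[1:] != sid_s[:-1]])
    m = len(boundaries)
    logv_sum = float(np.sum(np.log(v_s)))

    trace: list[tuple[float, float]] = []

    def objective(t2: float) -> float:
        val = _neg_restricted_ll(t2, y_s, w, X_s, boundaries, logv_sum)
        trace.append((t2, val))
        return val

    if k <= p:
        # no residual degrees of freedom: τ² unidentified, pin at 0
        tau2 = 0.0
    else:
        upper = max(10.0 * float(np.var(y_s)), 10.0 * VARIANCE_FLOOR)
        res = optimize.minimize_scalar(
            objective, bounds=(0.0, upper), method="bounded",
            options={"xatol": REML_XATOL},
        )
        if not res.success or not np.isfinite(res.fun):
            raise ConvergenceError(
                f"REML profile optimization failed: {res.message}", trace
            )
        tau2 = float(res.x)
        # bounded Brent never lands exactly on the boundary; snap when the
        # boundary value is at least as good
        if objective(0.0) <= res.fun + 1e-12:
            tau2 = 0.0

    A, b, _, _ = _profile_pieces(tau2, y_s, w, X_s, boundaries, logv_sum)
    cov = np.linalg.inv(A)
    beta = cov @ b
    return MetaFit(
        coefficients=beta,
        coef_cov=cov,
        tau2=tau2,
        k=k,
        m=m,
        term_names=term_names,
        tested=tested,
        **meta_kwargs,
    )


def fit_random_effects(effects, study_ids=None) -> MetaFit:
    """Overall (intercept-only) random-effects pooled estimate.

    Parameters
    ----------
    effects
        DataFrame with ``lnrr``, ``variance`` (and optionally ``study_id``)
        columns, or a sequence of :class:`EffectSize`.
    study_ids
        Publication identifiers, one per effect; optional if the DataFrame
        carries ``study_id``.
    """
    y, v, sid = _as_arrays(effects, study_ids)
    X = np.ones((len(y), 1))
    return _fit_gls(y, v, sid, X, ["overall"], tested=np.array([0]))


def fit_moderator_model(
    effects,
    study_ids=None,
    moderator: str | None = None,
    values: Sequence | None = None,
    min_category_n: int = 2,
) -> MetaFit:
    """Single-moderator mixed-effects meta-regression.

    The moderator is either a column name of the ``effects`` DataFrame or an
    explicit ``values`` vector aligned to the effects. Rows with a missing
    moderator value are dropped for this model only. Categorical moderators
    drop categories with fewer than ``min_category_n`` observations before
    fitting (single-observation categories carry no within-category
    replication).
    """
    y, v, sid = _as_arrays(effects, study_ids)
    if values is None:
        if moderator is None:
            raise ValueError("pass a moderator column name or an explicit values vector")
        if not isinstance(effects, pd.DataFrame) or moderator not in effects.columns:
            raise KeyError(f"moderator column {moderator!r} not found in effects table")
        values = effects[moderator]
    vals = pd.Series(list(values))
    if len(vals) != len(y):
        raise ValueError("moderator values and effects length mismatch")

    keep = vals.notna().to_numpy()
    vals = vals[keep].reset_index(drop=True)
    y, v, sid = y[keep], v[keep], sid[keep]
    if len(y) == 0:
        raise ValueError(f"no observations carry moderator {moderator!r}")

    numeric = pd.api.types.is_numeric_dtype(vals)
    name = moderator or "moderator"
    if numeric:
        x = vals.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"moderator {name!r} is constant: slope unidentifiable")
        X = np.column_stack([np.ones_like(x), x])
        return _fit_gls(
            y, v, sid, X, ["intercept", name], tested=np.array([1]), moderator=name
        )

    cats = vals.astype(str)
    counts = cats.value_counts()
    retained = sorted(counts[counts >= min_category_n].index)
    dropped = sorted(counts[counts < min_category_n].index)
    if not retained:
        raise ValueError(
            f"all categories of moderator {name!r} dropped (fewer than "
            f"{min_category_n} observations each)"
        )
    in_retained = cats.isin(retained).to_numpy()
    cats, y, v, sid = cats[in_retained].reset_index(drop=True), y[in_retained], v[in_retained], sid[in_retained]
    X = np.column_stack([(cats == c).to_numpy(dtype=float) for c in retained])
    k_per = [int(counts[c]) for c in retained]
    return _fit_gls(
        y, v, sid, X, list(retained), tested=np.arange(len(retained)),
        dropped_categories=dropped, k_per_term=k_per, moderator=name,
    )


def omnibus_test(fit: MetaFit) -> tuple[float, int, float]:
    """Wald chi-square QM over the tested coefficient block.

    QM = b' Σ_b⁻¹ b with df = block size; p from χ²(df). The tested block is
    every coefficient for cell-means models and the slope only for
    intercept+slope models.
    """
    idx = np.asarray(fit.tested, dtype=int)
    b = fit.coefficients[idx]
    S = fit.coef_cov[np.ix_(idx, idx)]
    try:
        qm = float(b @ np.linalg.solve(S, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient covariance in omnibus test") from exc
    df = len(idx)
    p = float(stats.chi2.sf(qm, df))
    return qm, df, p


def funnel_data(effects, study_ids=None) -> tuple[pd.DataFrame, dict | None]:
    """Funnel-plot table (lnRR vs standard error) plus an Egger diagnostic.

    The table is sorted by precision (smallest SE first). With k ≥ 3 an
    Egger-style regression of the standardized effect y/se on precision 1/se
    is fitted by OLS; its intercept estimates small-study asymmetry and is
    reported as a diagnostic only (CI covering 0 is consistent with no
    publication bias).
    """
    y, v, sid = _as_arrays(effects, study_ids)
    se = np.sqrt(np.maximum(v, VARIANCE_FLOOR))
    table = pd.DataFrame({"study_id": sid, "lnrr": y, "se": se}).sort_values(
        "se", kind="stable"
    ).reset_index(drop=True)
    egger = None
    if len(y) >= 3:
        import statsmodels.api as sm

        Xe = sm.add_constant(1.0 / se)
        fit = sm.OLS(y / se, Xe).fit()
        ci = fit.conf_int()
        egger = {
            "intercept": float(fit.params[0]),
            "intercept_se": float(fit.bse[0]),
            "intercept_ci_low": float(ci[0][0]),
            "intercept_ci_high": float(ci[0][1]),
            "p_value": float(fit.pvalues[0]),
            "k": int(len(y)),
        }
    return table, egger


@dataclass
class SensitivityResult:
    """Paired overall fits with and without imputed-SD records."""

    fit_all: MetaFit
    fit_complete: MetaFit
    n_all: int
    n_complete: int
    n_removed: int
    difference: pd.DataFrame

    @property
    def robust(self) -> bool:
        return bool(self.difference["robust"].all())


def sensitivity_reanalysis(records: Sequence[ObservationRecord]) -> SensitivityResult:
    """Re-fit the pooled model excluding records that needed SD imputation.

    Mirrors the sensitivity analysis for the median-CV imputation: the
    overall model is fitted on all records (after imputation) and again on
    the subset reporting both SDs; the difference table compares
    back-transformed percent changes and flags the result ``robust`` when the
    estimate keeps its sign and the 5%-level significance verdict.
    """
    eff_all = compute_effect_sizes(records, impute=True)
    complete = [r for r in records if r.sd_treat is not None and r.sd_ctrl is not None]
    if not complete:
        raise ValueError("sensitivity analysis needs at least one complete-SD record")
    eff_complete = compute_effect_sizes(complete, impute=True)

    fit_all = fit_random_effects(eff_all)
    fit_complete = fit_random_effects(eff_complete)

    rows = []
    for label, fit in (("all", fit_all), ("complete_sd_only", fit_complete)):
        est = fit.coefficients[0]
        lo, hi = fit.ci95[0]
        rows.append(
            {
                "subset": label,
                "k": fit.k,
                "m": fit.m,
                "estimate_pct": percent_change(est),
                "ci_low_pct": percent_change(lo),
                "ci_high_pct": percent_change(hi),
                "significant": bool(lo > 0 or hi < 0),
                "sign": int(np.sign(est)),
            }
        )
    diff = pd.DataFrame(rows)
    same_sign = diff["sign"].nunique() == 1
    same_sig = diff["significant"].nunique() == 1
    diff["robust"] = same_sign and same_sig
    return SensitivityResult(
        fit_all=fit_all,
        fit_complete=fit_complete,
        n_all=len(list(records)),
        n_complete=len(complete),
        n_removed=len(list(records)) - len(complete),
        difference=diff,
    )
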