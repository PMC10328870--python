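"""Fertilizer greenhouse-gas accounting and net carbon balance.

Nitrogen fertilization carries a climate cost: a fraction of applied N is
emitted in-field as nitrous oxide (N₂O, a potent greenhouse gas), and
manufacturing the fertilizer emits CO₂ upstream. With an N₂O-N emission
fraction of 2.54% and GWP₁₀₀ = 298, the in-field factor is

    EF_infield = 0.0254 × (44/28) × 298 ≈ 11.9 Mg CO₂e per Mg N applied,

(44/28 converts N₂O-N mass to N₂O mass), plus an upstream factor of
4.0 Mg CO₂e per Mg N produced. The net balance of a fertilized stand
compares the extra aboveground carbon gained (ΔC, treated − control,
converted to CO₂e by 44/12) with those emissions:

    net = ΔC × 44/12 − N_applied × (EF_infield + EF_upstream)   [Mg CO₂e ha⁻¹]

Regressing the net balance on N applied gives the break-even application
rate −intercept/slope: the N dose at which the climate benefit vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ObservationRecord

#: N₂O mass per unit N₂O-N mass (molar masses 44 g/mol N₂O vs 28 g/mol N₂).
N2O_N_TO_N2O = 44.0 / 28.0
#: CO₂ mass per unit carbon mass.
C_TO_CO2E = 44.0 / 12.0


def derive_infield_ef(n2o_fraction: float, gwp_n2o: float) -> float:
    """In-field emission factor, Mg CO₂e per Mg N applied.

    ``n2o_fraction`` is the fraction of applied N emitted as N₂O-N;
    ``gwp_n2o`` the 100-year global warming potential of N₂O. The product
    n2o_fraction × (44/28) × GWP is rounded to 1 decimal for reporting
    (0.0254 and 298 give 11.9).
    """
    if n2o_fraction < 0 or gwp_n2o < 0:
        raise ValueError("emission inputs must be non-negative")
    return round(n2o_fraction * N2O_N_TO_N2O * gwp_n2o, 1)


@dataclass(frozen=True)
class GhgConstants:
    """Emission factors for fertilizer carbon accounting."""

    n2o_fraction: float = 0.0254
    gwp_n2o: float = 298.0
    upstream_ef: float = 4.0  # Mg CO₂e per Mg N produced
    c_to_co2e: float = C_TO_CO2E

    @property
    def infield_ef(self) -> float:
        """Mg CO₂e per Mg N applied in-field (derived, reported to 1 dp)."""
        return derive_infield_ef(self.n2o_fraction, self.gwp_n2o)

    @property
    def total_ef(self) -> float:
        return self.infield_ef + self.upstream_ef


@dataclass(frozen=True)
class GhgResult:
    """Per-comparison fertilizer emissions and net CO₂e balance."""

    study_id: str
    site_id: str
    delta_c: float  # Mg C ha⁻¹, treated − control
    n_applied: float  # Mg N ha⁻¹
    emissions: float  # Mg CO₂e ha⁻¹
    net_balance: float  # Mg CO₂e ha⁻¹


def per_tree_to_per_ha(kg_per_tree: float, stems_per_ha: float) -> float:
    """Convert a per-tree N dose to kg N ha⁻¹ using stand density."""
    if stems_per_ha is None or not stems_per_ha > 0:
        raise ValueError(
            "per-tree N application needs a positive stand density to convert"
        )
    return kg_per_tree * stems_per_ha


def net_balance(
    delta_c: float, n_applied: float, constants: GhgConstants = GhgConstants()
) -> float:
    """Net CO₂e balance: carbon gain as CO₂e minus fertilizer emissions.

    ``delta_c`` in Mg C ha⁻¹, ``n_applied`` in Mg N ha⁻¹; returns
    Mg CO₂e ha⁻¹. Strictly decreasing in ``n_applied`` at fixed ``delta_c``.
    """
    if n_applied < 0:
        raise ValueError("n_applied must be non-negative")
    return delta_c * constants.c_to_co2e - n_applied * constants.total_ef


def compute_ghg_results(
    records: Sequence[ObservationRecord],
    constants: GhgConstants = GhgConstants(),
) -> list[GhgResult]:
    """Per-comparison GHG accounting for NPK records reporting N applied.

    Per-tree doses are converted to per-hectare with the record's stand
    density; kg N ha⁻¹ is converted to Mg N ha⁻¹. ΔC is the raw arm
    difference (treated − control aboveground carbon). Records without an
    N-applied value are skipped.
    """
    out: list[GhgResult] = []
    for r in records:
        if r.treatment != "npk" or r.n_applied is None:
            continue
        if r.n_applied_unit == "kg_per_tree":
            kg_ha = per_tree_to_per_ha(r.n_applied, r.stand_density)
        else:
            kg_ha = r.n_applied
        n_mg = kg_ha / 1000.0
        delta_c = r.mean_treat - r.mean_ctrl
        emissions = n_mg * constants.total_ef
        out.append(
            GhgResult(
                study_id=r.study_id,
                site_id=r.site_id,
                delta_c=delta_c,
                n_applied=n_mg,
                emissions=emissions,
                net_balance=net_balance(delta_c, n_mg, constants),
            )
        )
    return out


def ghg_results_frame(results: Sequence[GhgResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "site_id": r.site_id,
                "delta_c_mgc_ha": r.delta_c,
                "n_applied_mgn_ha": r.n_applied,
                "emissions_mgco2e_ha": r.emissions,
                "net_balance_mgco2e_ha": r.net_balance,
            }
            for r in results
        ]
    )


@dataclass
class NetBalanceRegression:
    """OLS of net balance on N applied, with the break-even dose."""

    intercept: float
    slope: float
    r_squared: float
    p_slope: float
    n: int
    median_net_balance: float
    break_even_n: float | None = field(default=None)


def fit_net_balance_regression(
    results: Sequence[GhgResult],
) -> NetBalanceRegression:
    """Regress net CO₂e balance on N applied; report the break-even dose.

    Ordinary least squares of net_balance (Mg CO₂e ha⁻¹) on n_applied
    (Mg N ha⁻¹). When the fitted slope is negative the break-even N dose
    −intercept/slope (Mg N ha⁻¹) is reported: applications above it make the
    stand a net emitter. The median net balance across comparisons is
    reported alongside.
    """
    if len(results) < 3:
        raise ValueError("need >= 3 comparisons for the net-balance regression")
    x = np.array([r.n_applied for r in results], dtype=float)
    y = np.array([r.net_balance for r in results], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("N applied is constant: slope unidentifiable")

    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    break_even = -intercept / slope if slope < 0 else None
    return NetBalanceRegression(
        intercept=intercept,
        slope=slope,
        r_squared=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=len(results),
        median_net_balance=float(np.median(y)),
        break_even_n=break_even,
    )
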