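# Methods

## Effect sizes

The unit of analysis is one treatment–control comparison of aboveground
carbon. Biomass rows are converted to carbon on read with a fixed carbon
fraction of 0.47, guarded by an explicit `units` column so the conversion
can never be applied twice. The effect size is lnRR = ln(X̄t/X̄c); 0 means no
effect, and back-transformation to percent change is (e^lnRR − 1)×100, which
is strictly increasing and maps CI bounds order-preservingly.

The sampling variance is the delta-method form
v = sd_t²/(n_t·X̄t²) + sd_c²/(n_c·X̄c²). The inputs are the arm SDs and
replicate counts as studies report them; no small-sample bias correction is
applied to lnRR.

**Missing SDs.** Studies that omit SDs get them imputed as the median
coefficient of variation (SD/mean) of the complete records — computed per
treatment analysis (interplant / NPK / thin) and per arm (treatment vs
control), across publications — multiplied by the record's own reported
mean. The cross-publication pooling of CVs is a deliberate choice: per-study
medians would often rest on one or two values. Medians of an even count use
the midpoint of the two central CVs. Imputation is idempotent and flagged,
and a sensitivity rerun refits the pooled model on complete-SD records only,
reporting whether the sign and 5%-level significance of the estimate
survive.

## The meta-analytic model

Comparisons are modeled as y_ij = x_ij'β + u_j + ε_ij with a single
publication-level random effect u_j ~ N(0, τ²) and known sampling variances
ε_ij ~ N(0, v_ij). This is the only random-effects structure used: multiple
comparisons within a publication (including those sharing a control plot)
are treated as conditionally independent given u_j. Shared controls are
recorded via `control_id` and reported diagnostically, but no residual
covariance is modeled for them; this understates within-study dependence
slightly and is a known limitation.

**Estimation.** τ² is estimated by REML. Because the marginal covariance is
block diagonal with blocks V_j = diag(v) + τ²𝟙𝟙', the Sherman–Morrison
identity gives V_j⁻¹ and log|V_j| in closed form, and the restricted
log-likelihood is profiled over the scalar τ² alone by bounded deterministic
1-D optimization on [0, 10·var(y)] (tolerance 10⁻¹⁰, no random starts; the
boundary τ²=0 is checked explicitly and preferred on ties). β̂ is the GLS
estimate at τ̂², with Wald z 95% intervals (not Knapp–Hartung). With k ≤ p
observations τ² is unidentified and pinned at 0. Zero sampling variances are
floored at 10⁻¹² so weights stay finite, and floored rows are flagged.

**Moderators.** Each moderator is tested in its own model on all rows that
carry it. Categorical moderators use a no-intercept cell-means design (each
coefficient is a category mean on the lnRR scale) after dropping categories
with fewer than two observations; continuous moderators use intercept +
slope. Significance is the omnibus Wald chi-square QM = b'Σ_b⁻¹b over the
tested block — all coefficients for cell-means models (so QM tests whether
the category means are jointly zero, not whether they differ), the slope
alone for intercept+slope models. No multiplicity correction is applied
across moderators.

**Funnel diagnostics.** The funnel table pairs each lnRR with its standard
error, sorted by precision. With k ≥ 3 an Egger-style OLS of the
standardized effect y/se on precision 1/se is reported; its intercept
estimates small-study asymmetry and is a diagnostic only.

## Trends and trimming

Time trends reuse the moderator machinery with a continuous covariate.
Trimming rules limit leverage from sparse long-horizon data: stand ages
above 20 years are dropped for interplanting, times since treatment above
5 years for NPK, and thinning keeps all time-since-thinning data. For NPK,
continuously fertilized studies use stand age as the time variable (the
stand has been treated since planting) while pulse-application studies use
time since treatment. Slopes are reported as 100·slope "% per unit" (the
small-effect reading of an lnRR slope); the exact alternative
100·(e^slope − 1) is exported alongside. The fitted line's zero crossing
−intercept/slope is reported when it falls at a positive covariate value,
locating when an effect appears (interplanting) or fades (thinning).

## Fertilizer GHG accounting

In-field emissions use an N₂O-N emission fraction of 2.54% of applied N:
EF_infield = 0.0254 × (44/28) × GWP₁₀₀, and GWP₁₀₀ = 298 is the default
because it is the 100-year N₂O potential consistent with the conventional
11.9 Mg CO₂e per Mg N factor (reported rounded to one decimal). Upstream
manufacturing adds 4.0 Mg CO₂e per Mg N produced; the upstream factor
applies to N mass only, not P or K. Per-tree N doses are converted to
per-hectare with the reported stand density. ΔC is the raw arm difference
(treated − control, Mg C ha⁻¹), converted to CO₂e by 44/12 — the only
mass-consistent choice. The net balance is ΔC·(44/12) − N·(EF_infield +
EF_upstream), strictly decreasing in N. The balance is regressed on N
applied by OLS; when the slope is negative, −intercept/slope is the
break-even dose. The median net balance across comparisons is reported
alongside.

## Synthetic compilations

The generator emulates the compiled literature's structure: for each
publication j it draws u_j ~ N(0, τ²) and 2–13 comparisons (range by
treatment); each comparison's true effect is
θ = μ + Σ(offset − E[offset]) + Σ slope·(x − centre) + u_j. Moderator
offsets and slope terms are centred (probability-weighted for categories,
range-midpoint for covariates) so μ stays the marginal mean lnRR whatever
the moderator mix — this keeps the configured μ directly comparable to the
pooled estimate. Control true means are log-normal (median 45 Mg C ha⁻¹,
σ_log 0.6 — typical mid-rotation plantation stocks); treated true means are
control × e^θ. Arm SDs are CV × true mean with CV ~ U(0.05, 0.30) and 3–6
replicates; *observed* arm means add N(0, sd²/n) noise (resampled into the
positive half-line), so observed lnRRs scatter around θ with approximately
the delta-method variance the analysis assumes. SDs are blanked MCAR for 20%
of comparisons (both arms at once, as studies omit SDs wholesale), and with
probability 0.3 a comparison reuses the previous comparison's control plot.
All draws come from one `numpy` Generator seeded by the config; replicate r
of an experiment uses seed + r.

Default configurations fix the study conditions per treatment: 43
publications (+20% mean effect, stand-age slope +3.6%/yr, soil-moisture and
design moderators) for interplanting; 17 publications (+44.5%,
time-since-treatment slope −6.66%/yr, application-method moderator, N doses
U(50, 600) kg ha⁻¹) for NPK; 8 publications (−34%, time slope +4.6%/yr,
basal-area slope −1.3%/%) for thinning. Continuously fertilized synthetic
stands report stand age (equal to their time under treatment) and no
separate time-since-treatment, matching how such studies report.

**What the generator does not emulate:** realistic geographic or genus
frequencies, non-random missingness, correlated moderators, non-linear time
responses, and publication bias. Passing tests therefore demonstrate that
the estimators are correct and calibrated under the stated generative model,
not that any particular field compilation satisfies that model.

## Experiment sizes and numerical choices

Parameter-recovery experiments use 200 publications × 2–4 comparisons, 500
replicates for bias/coverage and 1000 replicates for the omnibus type-I
error (under μ = 0 and a no-effect categorical moderator, so the cell-means
null holds); these sizes put the Monte-Carlo error of a coverage estimate
near 0.01. The REML grid oracle used in tests scans τ² ∈ [0, 1] in 10⁻⁵
steps with dense linear algebra, independent of the production code path.
Ties at τ² = 0 resolve to 0. Categorical ties in the median CV cannot arise
(the median is a numeric midpoint). Degenerate inputs — one observation,
identical effects, constant covariates, all-dropped categories — either
yield the closed-form answer (τ̂² = 0, fixed-effect mean) or raise a
descriptive error, as documented in each function.

## Known limitations

- Shared-control covariance is not modeled (publication random effects
  absorb it only partially), so CIs can be slightly narrow when many
  comparisons share controls.
- Wald z intervals are anti-conservative for very few publications; with
  fewer than ~10 publications interpret CIs cautiously.
- The GHG balance uses aboveground carbon only, ignores soil carbon and P/K
  manufacturing emissions, and applies no temporal discounting.
- lnRR assumes positive means and approximately log-normal ratio sampling;
  very small replicate counts with large CVs strain the delta-method
  variance.
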