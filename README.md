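# silvicarbon

Meta-analysis of how common silvicultural treatments — interplanting
nitrogen-fixing species, inorganic NPK fertilization, and thinning — change
aboveground carbon stocks in monoculture forest plantations, plus the
greenhouse-gas accounting needed to judge whether fertilizer-driven carbon
gains survive the fertilizer's own emissions.

The package is aimed at forest ecologists and carbon-accounting analysts who
have (or want to simulate) a compilation of paired treatment/control
measurements — one CSV row per comparison, with arm means of aboveground
carbon (Mg C ha⁻¹) or biomass (Mg ha⁻¹), arm SDs (possibly missing),
replicate counts, and moderator columns — and want pooled effect sizes,
moderator tests, time trends, and a fertilizer net-carbon balance.

## The model

Each comparison *i* in publication *j* contributes a log response ratio

```
lnRR_ij = ln(X̄t / X̄c),    v_ij = sd_t²/(n_t X̄t²) + sd_c²/(n_c X̄c²)
```

where X̄t and X̄c are mean aboveground carbon in the treated and control
arms. Missing arm SDs are imputed as (median CV of complete records in the
same treatment analysis and arm) × the record's own mean, with a sensitivity
rerun excluding imputed rows. Effects are pooled with a publication-level
random-effects model

```
lnRR_ij = x_ij'β + u_j + ε_ij,    u_j ~ N(0, τ²),  ε_ij ~ N(0, v_ij)
```

with τ² estimated by restricted maximum likelihood (REML) and β by GLS at
τ̂²; moderators are tested one at a time with a cell-means design and a Wald
chi-square omnibus test QM; results are back-transformed to percent change,
(e^lnRR − 1)×100. Time trends (stand age, time since treatment, basal area
removed) use intercept+slope designs with treatment-specific trimming rules,
and the fitted line's zero crossing locates where an effect appears or
disappears. For fertilized stands, the net balance per comparison is
ΔC·(44/12) − N·(11.9 + 4.0) Mg CO₂e ha⁻¹, combining the in-field N₂O
emission factor (2.54% of applied N as N₂O-N at GWP₁₀₀ = 298 → 11.9 Mg CO₂e
per Mg N) with a 4.0 Mg CO₂e/Mg N manufacturing factor; regressing the
balance on N applied gives the break-even dose −intercept/slope.

A synthetic-data generator (`silvicarbon.synthetic`) reproduces the
compilation's structure — comparisons nested in publications, shared
controls, moderator-dependent effects, covariate trends, missing SDs — with
every latent value in a truth ledger, so all of the above is testable
end-to-end without any external data.

## Worked example

```python
from silvicarbon import compute_effect_sizes, fit_random_effects, generate_compilation
from silvicarbon.synthetic import default_config

records, truth = generate_compilation(default_config("interplant", seed=1))
effects = compute_effect_sizes(records)
fit = fit_random_effects(effects)
print(fit.percent.round(1))
```

Running `python examples/02_pooled_meta_analysis.py` prints:

```
k=183 comparisons in m=43 publications; tau2=0.0939
interplanting N-fixers changes aboveground carbon by +17.1% [+6.7, +28.6]

soil moisture regime: QM=217.8 (df=4), omnibus p=5.5e-46
   term  k  estimate_pct  ci_low_pct  ci_high_pct
perudic 30          45.7        31.9         60.9
   udic 84          11.3         1.4         22.1
  ustic 42          28.5        16.6         41.5
  xeric 27          -4.1       -13.2          6.0
```

The first line is the pooled percent change in aboveground carbon from
interplanting (with its 95% CI) across a simulated 43-publication
compilation whose true mean effect is +20%; the table gives per-category
mean changes for the soil-moisture-regime moderator, wetter regimes
responding more strongly, with the omnibus QM testing all category means
jointly. The other scripts in `examples/` cover effect-size construction,
time trends and zero crossings, fertilizer GHG accounting, and parameter
recovery.

A thin CLI mirrors the pipeline stages:

```
silvicarbon simulate --treatment npk --seed 5 --out npk.csv
silvicarbon fit --input npk.csv --treatment npk
silvicarbon report --treatment thin --seed 3 --out results/thin
```

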