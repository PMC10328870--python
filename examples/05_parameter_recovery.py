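"""Check estimator calibration with a small parameter-recovery experiment.

Repeatedly generates compilations with a known mean effect (lnRR 0.2) and
between-publication variance (tau2 0.05), refits the model, and summarizes
bias and confidence-interval coverage.
"""

from dataclasses import replace

from silvicarbon.synthetic import default_config, recovery_experiment

config = replace(
    default_config("interplant", seed=9),
    n_publications=60,
    mu_true=0.2,
    tau2_true=0.05,
    moderator_spec={},
    slope_spec=(),
)
table = recovery_experiment(config, 50)
row = table.iloc[0]
print(table.round(4).to_string(index=False))
print(
    f"\nmu bias {row.mu_bias:+.4f} (+- {row.mu_bias_mcse:.4f} MC error); "
    f"95% CI coverage {row.coverage:.2f}"
)
# Bias near zero and coverage near 0.95 show the REML fit and its Wald
# intervals are calibrated under the data-generating conditions.
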