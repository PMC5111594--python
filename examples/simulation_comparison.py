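"""Desk-scale comparison of estimators on simulated meta-analyses.

Generates small (K = 5) meta-analyses at two heterogeneity levels —
tau^2 = 0 (I^2 = 0%) and tau^2 = 1.302 (I^2 = 95%) with within-study
variance 0.069 — and compares the conventional DerSimonian–Laird estimator
with data augmentation (generic IG(1.14, 0.08) prior) and the grid-Bayes
posterior.  Replicate counts are kept small here so the script runs in
seconds; increase n_reps for publication-grade Monte Carlo error.
"""

from hetaug import SimScenario, run_study

for tau2 in (0.0, 1.302):
    sc = SimScenario(
        K=5,
        tau2=tau2,
        n_reps=300,
        seed=2026,
        methods=("dl", "da_ml", "da_reml", "bayes_grid"),
    )
    metrics = run_study(sc)
    print(f"\ntrue tau2 = {tau2} (K = {sc.K}, {sc.n_reps} replicates):")
    print(
        metrics.to_frame()[
            ["method", "mean_tau2", "rmse_tau2", "coverage_mu", "mean_interval_length"]
        ].to_string(index=False, float_format=lambda x: f"{x:.3f}")
    )

print(
    "\nPatterns to note: DL averages above zero even for homogeneous data; "
    "at high heterogeneity the prior-informed methods shrink tau2 toward the "
    "prior, and augmented REML tracks the fully Bayesian mean more closely "
    "than augmented ML."
)
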