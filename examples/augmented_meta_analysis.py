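"""Approximate Bayesian meta-analysis by pseudo-data augmentation.

Four small trials of a drug against control on a subjective (self-reported)
outcome, on the log odds ratio scale.  With so few studies the between-study
variance tau^2 is nearly unidentified, so we encode the empirically derived
IG(1.45, 0.18) prior for this research setting as three precise artificial
studies and refit with REML.
"""

from hetaug import (
    InverseGammaPrior,
    augment,
    build_pseudo_data,
    dataset_from_arrays,
    fit_dl,
    fit_reml,
    wald_ci,
)

data = dataset_from_arrays(
    effects=[2.8, 0.3, 1.9, 0.9],
    variances=[0.65, 0.50, 0.60, 0.55],
)

conventional = fit_dl(data)
print("conventional DL:")
print(f"  tau2 = {conventional.tau2:.3f}  95% CI {conventional.tau2_ci}")
print(f"  log OR = {conventional.mu:.3f}  I2 = {conventional.I2:.0%}")

prior = InverseGammaPrior(1.45, 0.18)
pseudo = build_pseudo_data(prior)
print(
    f"\nprior IG({prior.shape}, {prior.scale}) encoded as "
    f"{pseudo.n_studies} artificial studies with effect {pseudo.effect:.3f}"
)
print(
    f"achieved prior after rounding: IG({pseudo.achieved_prior.shape}, "
    f"{pseudo.achieved_prior.scale})"
)

augmented = fit_reml(augment(data, pseudo))
lo, hi = wald_ci(augmented.mu, augmented.mu_se)
print("\naugmented REML (approximate posterior estimates):")
print(f"  tau2 = {augmented.tau2:.3f}  95% CI {augmented.tau2_ci}")
print(f"  log OR = {augmented.mu:.3f}  95% CI ({lo:.3f}, {hi:.3f})")
print(
    "\nThe informative prior shrinks the heterogeneity estimate and "
    "tightens the summary-effect interval relative to the conventional fit."
)
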