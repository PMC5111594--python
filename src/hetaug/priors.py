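"""Inverse-gamma priors for the between-study variance tau^2.

An inverse-gamma(alpha, beta) prior on tau^2 is equivalent to a gamma(alpha,
rate beta) prior on the between-study precision 1/tau^2, which is the
conjugate family for the normal random-effects model and the family that can
be encoded as pseudo data.  The registry holds empirically derived predictive
distributions for the heterogeneity expected in binary-outcome (log odds
ratio) meta-analyses, indexed by outcome type and intervention-comparison
type, plus a generic prior for settings not covered by the nine cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "InverseGammaPrior",
    "PriorRegistryKey",
    "PRIOR_REGISTRY",
    "GENERIC_PRIOR",
    "get_prior",
    "parse_prior_spec",
    "OUTCOME_TYPES",
    "COMPARISON_TYPES",
]


@dataclass(frozen=True)
class InverseGammaPrior:
    """Inverse-gamma distribution IG(shape, scale) for a variance parameter.

    Density: ``scale^shape / Gamma(shape) * x^(-shape-1) * exp(-scale/x)``.
    The mean ``scale/(shape-1)`` exists only for shape > 1 and the variance
    ``scale^2 / ((shape-1)^2 (shape-2))`` only for shape > 2.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"inverse-gamma parameters must be positive, got "
                f"shape={self.shape}, scale={self.scale}"
            )

    # scipy frozen distribution of tau^2 itself
    def _dist(self):
        return stats.invgamma(self.shape, scale=self.scale)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("inverse-gamma density requires x > 0")
        return self._dist().pdf(x)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("inverse-gamma density requires x > 0")
        return self._dist().logpdf(x)

    def cdf(self, x):
        return self._dist().cdf(x)

    def sf(self, x):
        """Upper tail P(X > x) = gamma_cdf(scale/x; shape), float-accurate
        where the cdf saturates at 1."""
        x = np.asarray(x, dtype=float)
        return stats.gamma.cdf(self.scale / x, self.shape)

    def isf(self, p):
        """Upper-tail quantile: x with P(X > x) = p."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("tail level must lie strictly in (0, 1)")
        return self.scale / stats.gamma.ppf(p, self.shape)

    def quantile(self, p):
        """Quantile via the gamma inverse-CDF of the reciprocal.

        If X ~ IG(a, b) then 1/X ~ Gamma(a, rate b), so
        ``Q_X(p) = b / Q_Gamma(1 - p; a, 1)`` — numerically robust for the
        small shapes typical of heterogeneity priors.
        """
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile level must lie strictly in (0, 1)")
        return self.scale / stats.gamma.isf(p, self.shape)

    @property
    def mean(self) -> float:
        if self.shape <= 1:
            raise ValueError(f"mean undefined for shape {self.shape} <= 1")
        return self.scale / (self.shape - 1.0)

    @property
    def variance(self) -> float:
        if self.shape <= 2:
            raise ValueError(f"variance undefined for shape {self.shape} <= 2")
        return self.scale**2 / ((self.shape - 1.0) ** 2 * (self.shape - 2.0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n variates as scale / gamma(shape) deviates."""
        return self.scale / rng.gamma(self.shape, size=n)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"IG({self.shape:g}, {self.scale:g})"


OUTCOME_TYPES = ("all_cause_mortality", "semi_objective", "subjective", "generic")
COMPARISON_TYPES = (
    "pharma_vs_placebo_control",
    "pharma_vs_pharma",
    "non_pharma",
    "generic",
)


@dataclass(frozen=True)
class PriorRegistryKey:
    """Research-setting key: outcome type x intervention-comparison type."""

    outcome_type: str
    comparison_type: str

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise ValueError(
                f"unknown outcome type {self.outcome_type!r}; valid: {OUTCOME_TYPES}"
            )
        if self.comparison_type not in COMPARISON_TYPES:
            raise ValueError(
                f"unknown comparison type {self.comparison_type!r}; "
                f"valid: {COMPARISON_TYPES}"
            )
        if ("generic" in (self.outcome_type, self.comparison_type)) and (
            self.outcome_type != self.comparison_type
        ):
            raise ValueError("'generic' outcome pairs only with 'generic' comparison")


# Predictive IG distributions for tau^2 in future binary-outcome
# meta-analyses, by research setting.  Constants as printed, no re-derivation.
PRIOR_REGISTRY: dict[tuple[str, str], InverseGammaPrior] = {
    ("all_cause_mortality", "pharma_vs_placebo_control"): InverseGammaPrior(1.06, 0.01),
    ("all_cause_mortality", "pharma_vs_pharma"): InverseGammaPrior(2.93, 0.00003),
    ("all_cause_mortality", "non_pharma"): InverseGammaPrior(0.80, 0.007),
    ("semi_objective", "pharma_vs_placebo_control"): InverseGammaPrior(1.32, 0.08),
    ("semi_objective", "pharma_vs_pharma"): InverseGammaPrior(1.04, 0.04),
    ("semi_objective", "non_pharma"): InverseGammaPrior(0.88, 0.05),
    ("subjective", "pharma_vs_placebo_control"): InverseGammaPrior(1.45, 0.18),
    ("subjective", "pharma_vs_pharma"): InverseGammaPrior(1.13, 0.09),
    ("subjective", "non_pharma"): InverseGammaPrior(1.39, 0.13),
}

GENERIC_PRIOR = InverseGammaPrior(1.14, 0.08)
PRIOR_REGISTRY[("generic", "generic")] = GENERIC_PRIOR


def get_prior(key: PriorRegistryKey) -> InverseGammaPrior:
    """Look up the tabulated prior for a research setting."""
    k = (key.outcome_type, key.comparison_type)
    try:
        return PRIOR_REGISTRY[k]
    except KeyError:
        valid = sorted(PRIOR_REGISTRY)
        raise KeyError(f"no prior registered for {k}; valid keys: {valid}") from None


# CLI-facing shorthand: outcome aliases and comparison aliases.
_OUTCOME_ALIASES = {
    "mortality": "all_cause_mortality",
    "all_cause_mortality": "all_cause_mortality",
    "semi_objective": "semi_objective",
    "semiobjective": "semi_objective",
    "subjective": "subjective",
    "generic": "generic",
}
_COMPARISON_ALIASES = {
    "pharma_placebo": "pharma_vs_placebo_control",
    "pharma_vs_placebo_control": "pharma_vs_placebo_control",
    "pharma_pharma": "pharma_vs_pharma",
    "pharma_vs_pharma": "pharma_vs_pharma",
    "non_pharma": "non_pharma",
    "nonpharma": "non_pharma",
    "generic": "generic",
}


def parse_prior_spec(spec: str) -> InverseGammaPrior:
    """Parse ``'outcome:comparison'``, ``'generic'`` or ``'shape,scale'``."""
    spec = spec.strip()
    if "," in spec:
        shape_s, scale_s = spec.split(",", 1)
        return InverseGammaPrior(float(shape_s), float(scale_s))
    if spec == "generic":
        return GENERIC_PRIOR
    if ":" in spec:
        out_s, cmp_s = spec.split(":", 1)
        try:
            out = _OUTCOME_ALIASES[out_s.strip().lower()]
            comp = _COMPARISON_ALIASES[cmp_s.strip().lower()]
        except KeyError:
            raise ValueError(
                f"unrecognised prior spec {spec!r}; use e.g. "
                f"'subjective:pharma_placebo' or 'shape,scale'"
            ) from None
        return get_prior(PriorRegistryKey(out, comp))
    raise ValueError(f"unrecognised prior spec {spec!r}")
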