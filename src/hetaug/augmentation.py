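"""Encode an inverse-gamma heterogeneity prior as pseudo study data.

The likelihood of K0 artificial studies with common effect y0, mean zero and
(near-)zero within-study variance, expressed in terms of the log between-study
precision phi = log(1/tau^2) = -2 log(tau), is proportional to
``exp(alpha*phi - beta*exp(phi))`` with ``alpha = K0/2`` and
``beta = K0*y0^2/2`` — exactly a gamma(alpha, rate beta) prior density on the
precision, i.e. an inverse-gamma(alpha, beta) prior on tau^2.  Appending the
pseudo studies to the observed data and fitting a standard intercept-free
random-effects meta-regression therefore yields approximate posterior
estimates with frequentist software.

Because K0 = 2*alpha must be rounded to an integer, the prior actually
encoded (the *achieved* prior) can differ from the declared one in its shape
parameter; the scale is preserved exactly.  Both are always reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_model import Dataset, StudyRecord
from .priors import InverseGammaPrior

__all__ = [
    "PSEUDO_VARIANCE",
    "PseudoData",
    "build_pseudo_data",
    "augment",
    "augmented_loglik_identity_check",
]

# Within-study variance assigned to artificial studies: effectively zero on
# the log odds ratio scale while keeping the likelihood well defined.
PSEUDO_VARIANCE = 1e-20


@dataclass(frozen=True)
class PseudoData:
    """The artificial-study block representing an IG(shape, scale) prior.

    ``n_studies`` (K0) precise studies, each with effect ``effect`` (y0) and
    within-study variance ``within_variance``.  ``achieved_prior`` is the
    prior the block actually encodes, IG(K0/2, K0*y0^2/2); its scale equals
    the requested prior's scale exactly, only the shape moves with rounding.
    """

    n_studies: int
    effect: float
    within_variance: float
    achieved_prior: InverseGammaPrior

    def records(self) -> tuple[StudyRecord, ...]:
        """Pseudo study records for a plain (single-indicator) design."""
        return tuple(
            StudyRecord(
                study_id=f"pseudo_{i + 1}",
                effect=self.effect,
                within_variance=self.within_variance,
                covariates=(0.0,),
                is_pseudo=True,
            )
            for i in range(self.n_studies)
        )


def build_pseudo_data(
    prior: InverseGammaPrior, within_variance: float = PSEUDO_VARIANCE
) -> PseudoData:
    """Construct the pseudo-data block equivalent to an IG prior on tau^2.

    K0 = round(2*shape) artificial studies (minimum 1), each with effect
    y0 = sqrt(2*scale / K0) computed from the *rounded* K0 so the achieved
    prior keeps the requested scale exactly.  Ties round half up.
    """
    k0 = int(math.floor(2.0 * prior.shape + 0.5))  # round half up
    k0 = max(k0, 1)
    y0 = math.sqrt(2.0 * prior.scale / k0)
    # K0*y0^2/2 == scale by construction; write it directly to avoid float
    # round-trip noise in the reported achieved prior
    achieved = InverseGammaPrior(k0 / 2.0, prior.scale)
    return PseudoData(
        n_studies=k0,
        effect=y0,
        within_variance=within_variance,
        achieved_prior=achieved,
    )


def augment(data: Dataset, pseudo: PseudoData) -> Dataset:
    """Append the pseudo block to an observed dataset.

    Observed records keep their covariates (a plain meta-analysis gets the
    single observed-data indicator, value 1); pseudo records get an all-zero
    covariate row so they are centred at zero and contribute nothing to the
    effect estimate.  The result is intercept free.
    """
    if data.is_augmented:
        raise ValueError("dataset already contains pseudo records; cannot re-augment")
    pseudo_records = tuple(
        StudyRecord(
            study_id=f"pseudo_{i + 1}",
            effect=pseudo.effect,
            within_variance=pseudo.within_variance,
            covariates=(0.0,) * data.p,
            is_pseudo=True,
        )
        for i in range(pseudo.n_studies)
    )
    return replace(
        data, records=data.records + pseudo_records, intercept_free=True
    )


def _loglik(y, v, mean, tau2) -> float:
    s = v + tau2
    return float(np.sum(-0.5 * (np.log(2.0 * np.pi * s) + (y - mean) ** 2 / s)))


def augmented_loglik_identity_check(
    data: Dataset, prior: InverseGammaPrior, mu: float, tau2: float
) -> float:
    """Difference between the augmented log-likelihood and observed
    log-likelihood plus log prior density of phi = -2 log(tau).

    For a prior with integer 2*shape (no rounding), this difference is a
    constant in (mu, tau2) up to the perturbation from the near-zero pseudo
    variance: the pseudo block's likelihood contribution *is* the prior
    density on the log-precision scale, Jacobian included.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    two_alpha = 2.0 * prior.shape
    if abs(two_alpha - round(two_alpha)) > 1e-12:
        raise ValueError(
            "identity holds only for priors with integer 2*shape (no rounding); "
            f"got shape {prior.shape}"
        )
    pseudo = build_pseudo_data(prior)
    aug = augment(data.observed(), pseudo)

    obs = data.observed()
    ll_obs = _loglik(obs.effects(), obs.variances(), mu, tau2)

    mask = np.array([r.is_pseudo for r in aug.records])
    y = aug.effects()
    v = aug.variances()
    ll_aug = _loglik(y[~mask], v[~mask], mu, tau2) + _loglik(
        y[mask], v[mask], 0.0, tau2
    )

    # gamma(alpha, rate beta) density of the precision, transformed to
    # phi = log(1/tau2):  p(phi) = beta^alpha/Gamma(alpha) exp(alpha*phi
    # - beta*exp(phi))
    alpha, beta = prior.shape, prior.scale
    phi = -math.log(tau2)
    log_prior_phi = (
        alpha * math.log(beta) - math.lgamma(alpha) + alpha * phi - beta * math.exp(phi)
    )
    return ll_aug - (ll_obs + log_prior_phi)
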