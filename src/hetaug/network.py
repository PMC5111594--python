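"""Network meta-analysis of two-arm contrasts as intercept-free
meta-regression.

With interventions 0..p and intervention 0 the global reference, the basic
parameters are the contrasts mu_0j of each intervention j against the
reference.  Each study contributes one row of an indicator design: if the
study includes the reference, the other arm's column is +1; otherwise the
study's non-reference arm gets +1 and its within-study reference arm -1.
Under consistency every other contrast is a difference of basic parameters
(mu_jk = mu_0k - mu_0j).  Pseudo rows representing a heterogeneity prior get
an all-zero covariate row, exactly as in pairwise augmentation, and a single
common tau^2 is assumed for all contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Dataset, StudyRecord, logodds_from_2x2
from .remeta import FitResult, wald_ci

__all__ = [
    "ContrastRecord",
    "NetworkSpec",
    "nma_design",
    "split_multiarm",
    "derived_contrast",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastRecord:
    """One study's treatment-vs-control contrast on the log odds ratio scale."""

    study_id: str
    treat: str
    control: str
    effect: float
    within_variance: float

    def __post_init__(self) -> None:
        if self.treat == self.control:
            raise ValueError(
                f"study {self.study_id!r}: treat and control arms are identical"
            )
        if self.within_variance <= 0:
            raise ValueError(f"study {self.study_id!r}: variance must be > 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Declared intervention set, global reference and contrast records."""

    interventions: tuple[str, ...]
    reference: str
    contrasts: tuple[ContrastRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "interventions", tuple(self.interventions))
        object.__setattr__(self, "contrasts", tuple(self.contrasts))
        if len(set(self.interventions)) != len(self.interventions):
            raise ValueError("duplicate intervention labels")
        if self.reference not in self.interventions:
            raise ValueError(f"reference {self.reference!r} not in intervention set")
        known = set(self.interventions)
        for c in self.contrasts:
            for arm in (c.treat, c.control):
                if arm not in known:
                    raise ValueError(
                        f"study {c.study_id!r}: intervention {arm!r} not declared"
                    )

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(t for t in self.interventions if t != self.reference)

    def connected_check(self) -> None:
        """Every intervention must be reachable from the reference through
        contrasts, else basic parameters are unidentifiable."""
        adj: dict[str, set[str]] = {t: set() for t in self.interventions}
        for c in self.contrasts:
            adj[c.treat].add(c.control)
            adj[c.control].add(c.treat)
        seen = {self.reference}
        stack = [self.reference]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        unreachable = sorted(set(self.interventions) - seen)
        if unreachable:
            raise ValueError(
                f"network is disconnected; unreachable interventions: {unreachable}"
            )


def nma_design(spec: NetworkSpec) -> Dataset:
    """Build the intercept-free meta-regression dataset for a network.

    One row per contrast with p = len(interventions) - 1 columns (one per
    non-reference intervention): +1 for the non-reference arm, and -1 for the
    study's reference arm when that arm is not the global reference.
    """
    spec.connected_check()
    cols = spec.non_reference
    col_index = {t: i for i, t in enumerate(cols)}
    p = len(cols)
    records = []
    for c in spec.contrasts:
        row = [0.0] * p
        if c.treat != spec.reference:
            row[col_index[c.treat]] = 1.0
        if c.control != spec.reference:
            row[col_index[c.control]] = -1.0
        records.append(
            StudyRecord(
                study_id=f"{c.study_id}:{c.treat}v{c.control}",
                effect=c.effect,
                within_variance=c.within_variance,
                covariates=tuple(row),
            )
        )
    return Dataset(tuple(records), p=p, intercept_free=True)


def split_multiarm(
    study_id: str,
    arms: Sequence[tuple[str, int, int]],
    reference_arm: str,
    correction: float = 0.5,
) -> list[ContrastRecord]:
    """Split an m-arm study into m - 1 two-arm contrasts vs its reference arm.

    ``arms`` are ``(label, events, total)`` triples.  The contrasts are
    treated as independent; the within-study correlation induced by the
    shared reference arm is deliberately ignored (logged as a warning for
    studies with more than two arms).
    """
    if len(arms) < 2:
        raise ValueError(f"study {study_id!r}: need at least two arms")
    by_label = {}
    for label, events, total in arms:
        if total <= 0:
            raise ValueError(f"study {study_id!r}, arm {label!r}: zero total")
        if not 0 <= events <= total:
            raise ValueError(f"study {study_id!r}, arm {label!r}: events out of range")
        by_label[label] = (events, total - events)
    if reference_arm not in by_label:
        raise ValueError(f"study {study_id!r}: reference arm {reference_arm!r} absent")
    if len(arms) > 2:
        logger.warning(
            "study %r: %d arms split into independent two-arm contrasts; "
            "within-study correlation is ignored",
            study_id,
            len(arms),
        )
    ref_e, ref_ne = by_label[reference_arm]
    out = []
    for label, events, total in arms:
        if label == reference_arm:
            continue
        eff, var = logodds_from_2x2(
            events, total - events, ref_e, ref_ne, correction=correction
        )
        out.append(
            ContrastRecord(
                study_id=study_id,
                treat=label,
                control=reference_arm,
                effect=eff,
                within_variance=var,
            )
        )
    return out


def derived_contrast(
    fit: FitResult,
    spec: NetworkSpec,
    j: str,
    k: str,
    level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Estimate, SE and Wald interval for the contrast of k vs j.

    Under consistency, mu_jk = mu_0k - mu_0j with variance
    var(mu_0k) + var(mu_0j) - 2 cov; the reference's own basic parameter is
    identically zero.
    """
    for arm in (j, k):
        if arm not in spec.interventions:
            raise ValueError(f"intervention {arm!r} not in the network")
    if j == k:
        return 0.0, 0.0, (0.0, 0.0)
    cols = spec.non_reference
    idx = {t: i for i, t in enumerate(cols)}
    vec = np.zeros(len(cols))
    if k != spec.reference:
        vec[idx[k]] += 1.0
    if j != spec.reference:
        vec[idx[j]] -= 1.0
    est = float(vec @ fit.coefficients)
    var = float(vec @ fit.coef_cov @ vec)
    se = math.sqrt(max(var, 0.0))
    return est, se, wald_ci(est, se, level)
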