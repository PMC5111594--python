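"""Study-level containers for random-effects meta-analysis.

Effects live on the log odds ratio scale throughout; exponentiation to odds
ratios happens only at reporting time.  Within-study variances are treated as
fixed and known, as is conventional in the normal-approximation random-effects
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "Dataset",
    "logodds_from_2x2",
    "read_studies",
    "write_studies",
    "dataset_from_arrays",
]


@dataclass(frozen=True)
class StudyRecord:
    """One study's effect estimate on the log odds ratio scale.

    Parameters
    ----------
    study_id
        Label identifying the study.
    effect
        Estimated log odds ratio ``y_i``.
    within_variance
        Within-study variance ``sigma_i^2``, treated as fixed and known.
        Must be strictly positive for observed studies; artificial (pseudo)
        studies carry the near-zero constant set by the augmentation step.
    covariates
        Covariate row ``x_i`` of the meta-regression design matrix.  For a
        plain meta-analysis this is the single intercept entry ``(1.0,)``.
    is_pseudo
        True for artificial records that encode a heterogeneity prior.
    """

    study_id: str
    effect: float
    within_variance: float
    covariates: tuple[float, ...] = (1.0,)
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect):
            raise ValueError(f"study {self.study_id!r}: non-finite effect")
        if not self.is_pseudo and self.within_variance <= 0:
            raise ValueError(
                f"study {self.study_id!r}: within-study variance must be > 0, "
                f"got {self.within_variance}"
            )
        object.__setattr__(self, "covariates", tuple(float(c) for c in self.covariates))


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of study records sharing one design.

    ``p`` is the number of covariate columns; ``intercept_free`` marks designs
    with no intercept column (augmented data and network meta-analysis use
    intercept-free indicator designs).
    """

    records: tuple[StudyRecord, ...]
    p: int = 1
    intercept_free: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for r in self.records:
            if len(r.covariates) != self.p:
                raise ValueError(
                    f"study {r.study_id!r}: covariate row has length "
                    f"{len(r.covariates)}, expected p={self.p}"
                )

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def k_observed(self) -> int:
        return sum(not r.is_pseudo for r in self.records)

    @property
    def k_pseudo(self) -> int:
        return sum(r.is_pseudo for r in self.records)

    @property
    def is_augmented(self) -> bool:
        return self.k_pseudo > 0

    def effects(self) -> np.ndarray:
        return np.array([r.effect for r in self.records], dtype=float)

    def variances(self) -> np.ndarray:
        return np.array([r.within_variance for r in self.records], dtype=float)

    def design(self) -> np.ndarray:
        """The n x p design matrix assembled row-wise from covariates."""
        if self.n == 0:
            return np.empty((0, self.p))
        return np.array([r.covariates for r in self.records], dtype=float)

    def observed(self) -> "Dataset":
        """The sub-dataset of observed (non-pseudo) records."""
        return replace(self, records=tuple(r for r in self.records if not r.is_pseudo))

    def validate_for_fit(self) -> None:
        """Check fitting preconditions: >= 2 observed studies, full-rank design."""
        if self.k_observed < 2:
            raise ValueError("at least two studies required for a meta-analysis")
        X = self.design()
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("design matrix is rank deficient")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [r.study_id for r in self.records],
                "effect": self.effects(),
                "variance": self.variances(),
                "is_pseudo": [r.is_pseudo for r in self.records],
            }
        )


def logodds_from_2x2(
    events_trt: int,
    nonevents_trt: int,
    events_ctl: int,
    nonevents_ctl: int,
    correction: float = 0.5,
) -> tuple[float, float]:
    """Log odds ratio and its variance from a 2x2 table.

    The continuity ``correction`` is added to all four cells if and only if at
    least one cell is zero (Haldane–Anscombe convention).  Returns
    ``(log((a*d)/(b*c)), 1/a + 1/b + 1/c + 1/d)`` on the possibly corrected
    cells ``a, b, c, d``.
    """
    cells = (events_trt, nonevents_trt, events_ctl, nonevents_ctl)
    if any(c < 0 for c in cells):
        raise ValueError(f"negative count in 2x2 table {cells}")
    if events_trt + nonevents_trt == 0 or events_ctl + nonevents_ctl == 0:
        raise ValueError(f"arm with zero total in 2x2 table {cells}")
    if correction < 0:
        raise ValueError("continuity correction must be >= 0")
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    if min(a, b, c, d) == 0.0:
        raise ValueError(
            f"2x2 table {cells}: zero cell remains after continuity correction"
        )
    effect = math.log((a * d) / (b * c))
    variance = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return effect, variance


_EV_COLS = ["study", "effect", "variance"]
_TAB_COLS = ["study", "events_trt", "nonevents_trt", "events_ctl", "nonevents_ctl"]


def read_studies(
    path, schema: str = "effect_variance", correction: float = 0.5
) -> Dataset:
    """Read study-level data from CSV.

    ``schema='effect_variance'`` expects columns ``study,effect,variance`` on
    the log odds ratio scale; ``schema='table_2x2'`` expects
    ``study,events_trt,nonevents_trt,events_ctl,nonevents_ctl`` and converts
    each row via :func:`logodds_from_2x2`.
    """
    if schema not in ("effect_variance", "table_2x2"):
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    needed = _EV_COLS if schema == "effect_variance" else _TAB_COLS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records = []
    for idx, row in df.iterrows():
        sid = str(row["study"])
        if schema == "effect_variance":
            try:
                effect = float(row["effect"])
                variance = float(row["variance"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} row {idx} (study {sid!r}): non-numeric cell") from exc
            if not (math.isfinite(effect) and math.isfinite(variance)):
                raise ValueError(f"{path} row {idx} (study {sid!r}): non-finite value")
            if variance <= 0:
                raise ValueError(
                    f"{path} row {idx} (study {sid!r}): variance must be > 0"
                )
        else:
            try:
                counts = [int(row[c]) for c in _TAB_COLS[1:]]
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} row {idx} (study {sid!r}): non-numeric count") from exc
            effect, variance = logodds_from_2x2(*counts, correction=correction)
        records.append(StudyRecord(sid, effect, variance))
    ds = Dataset(tuple(records))
    if ds.k_observed < 2:
        raise ValueError("at least two studies required")
    return ds


def write_studies(data: Dataset, path) -> None:
    """Write observed records to CSV in the effect_variance schema.

    Full ``repr`` precision is kept so a write/read round trip reproduces the
    dataset exactly.
    """
    obs = data.observed()
    df = pd.DataFrame(
        {
            "study": [r.study_id for r in obs.records],
            "effect": [repr(r.effect) for r in obs.records],
            "variance": [repr(r.within_variance) for r in obs.records],
        }
    )
    df.to_csv(path, index=False)


def dataset_from_arrays(
    effects: Sequence[float],
    variances: Sequence[float],
    study_ids: Iterable[str] | None = None,
) -> Dataset:
    """Convenience constructor for a plain (intercept-only) meta-analysis."""
    effects = list(effects)
    variances = list(variances)
    if len(effects) != len(variances):
        raise ValueError("effects and variances differ in length")
    ids = list(study_ids) if study_ids is not None else [
        f"study_{i + 1}" for i in range(len(effects))
    ]
    return Dataset(
        tuple(
            StudyRecord(sid, float(y), float(v))
            for sid, y, v in zip(ids, effects, variances)
        )
    )
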