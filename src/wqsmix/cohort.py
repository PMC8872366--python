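"""Cohort container: exposures, covariates, sex, outcome, optional truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExposurePanel

#: covariate columns of the adjusted IQ model, in reporting order
COVARIATE_COLS = ["MNI", "Energy", "MomAge", "MomWeight", "MomEduc", "MomIQ", "Smoker"]

#: stratum labels; sex is coded 0 = boy (reference), 1 = girl
STRATA = ("boy", "girl")


@dataclass
class TrueModel:
    """Generating model for synthetic outcomes.

    The outcome follows the stratified-interaction linear model

        y = beta0 + beta1*WQS + beta2*x + beta12*x*WQS + phi'z + eps,

    where x is the female indicator, WQS is the weighted sum of decile
    scores under the subject's sex stratum, z the covariates and
    eps ~ Normal(0, sigma^2).  ``true_weights`` holds the 2*c stratum-by-
    chemical weights on a single simplex (boys block first).
    """

    beta0: float
    beta1: float
    beta2: float
    beta12: float
    phi: dict[str, float]
    true_weights: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if np.any(self.true_weights < 0):
            raise ValueError("true weights must be nonnegative")
        if abs(self.true_weights.sum() - 1.0) > 1e-10:
            raise ValueError("true weights must sum to 1 within 1e-10")
        if self.sigma <= 0:
            raise ValueError("residual sigma must be positive")
        extra = set(self.phi) - set(COVARIATE_COLS)
        if extra:
            raise ValueError(f"unknown covariate coefficients: {sorted(extra)}")


@dataclass
class Cohort:
    """Aligned subject-level data for one analysis.

    All components share subject count and ordering; ``truth`` is present
    only for synthetic cohorts.
    """

    exposures: ExposurePanel
    covariates: pd.DataFrame
    sex: np.ndarray
    outcome: np.ndarray
    truth: TrueModel | None = field(default=None)

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype=int)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n = self.exposures.n_subjects
        if not (len(self.covariates) == len(self.sex) == len(self.outcome) == n):
            raise ValueError(
                "exposures, covariates, sex and outcome must have equal subject counts"
            )
        if not np.isin(self.sex, (0, 1)).all():
            raise ValueError("sex must be coded 0 (boy) or 1 (girl)")
        missing = [c for c in COVARIATE_COLS if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")

    @property
    def n(self) -> int:
        return self.exposures.n_subjects

    @property
    def subjects(self) -> pd.Index:
        return self.exposures.subjects

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row subset by positional indices, preserving alignment."""
        panel = self.exposures
        sub_panel = ExposurePanel(
            values=panel.values.iloc[idx],
            nondetect=panel.nondetect.iloc[idx],
            classes=dict(panel.classes),
            urinary=panel.urinary,
            creatinine=None if panel.creatinine is None else panel.creatinine.iloc[idx],
        )
        return Cohort(
            exposures=sub_panel,
            covariates=self.covariates.iloc[idx],
            sex=self.sex[idx],
            outcome=self.outcome[idx],
            truth=self.truth,
        )
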