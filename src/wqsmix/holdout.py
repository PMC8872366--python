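"""Repeated 40/60 holdout validation of the stratified WQS analysis.

Each repeat draws a fresh random split of the cohort: the training share
estimates the bootstrap-ensemble weights, the holdout share gets the
frozen-weight index and an ordinary least-squares interaction fit.  The
distribution of coefficients and weights across repeats is the reported
result — mean, SD-across-repeats as the standard error, 2.5/97.5
percentiles, and sign/threshold exceedance fractions.

Quantile breakpoints are computed once on the full sample before any split
and frozen, so all repeats share one quantile designation.  Per-repeat
seeds derive deterministically from the master seed, so any single repeat
can be re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .preprocess import QuantileMatrix
from .wqs import (
    INTERACTION,
    WQS,
    CoefficientTable,
    WeightSet,
    compute_index,
    ensemble_weights,
    equi_weight_threshold,
    fit_index_model,
    fit_single_bootstrap,
)

logger = logging.getLogger(__name__)


@dataclass
class HoldoutRepeat:
    """One split's record: seed, training weights, holdout coefficients."""

    split_seed: int
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    weights: WeightSet
    coefficients: CoefficientTable
    n_unconverged: int


@dataclass
class HoldoutEnsemble:
    """All per-repeat records plus the settings that produced them."""

    repeats: list[HoldoutRepeat]
    n_repeats: int
    split_fraction: float
    n_failed: int = 0

    def coefficient_frame(self) -> pd.DataFrame:
        """Repeats x parameters matrix of holdout estimates."""
        return pd.DataFrame([r.coefficients.params for r in self.repeats])

    def weight_frame(self) -> pd.DataFrame:
        """Long format: repeat, stratum, chemical, weight."""
        frames = []
        for i, r in enumerate(self.repeats):
            f = r.weights.to_frame()
            f.insert(0, "repeat", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


@dataclass
class EnsembleSummary:
    """Parameter and weight summaries across repeats (reporting layout)."""

    parameters: pd.DataFrame
    weights: pd.DataFrame
    threshold: float


def split(cohort: Cohort, fraction: float = 0.4, seed: int = 0, max_attempts: int = 10):
    """Simple random split into training and holdout index arrays.

    ``fraction`` is the training share; the training size is
    floor(fraction * n).  A split leaving either sex stratum empty in either
    part is resampled with a derived seed (logged), up to ``max_attempts``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"training fraction must be in (0, 1), got {fraction}")
    n = cohort.n
    n_train = int(np.floor(fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"fraction {fraction} leaves an empty training or holdout set")
    strata_present = len(np.unique(cohort.sex)) > 1
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        perm = rng.permutation(n)
        train, hold = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if not strata_present:
            return train, hold
        ok = all(
            len(np.unique(cohort.sex[part])) == 2 for part in (train, hold)
        )
        if ok:
            return train, hold
        logger.warning("split attempt %d left a stratum empty; resampling", attempt)
    raise ValueError(
        f"could not produce a split with both strata in both parts after {max_attempts} attempts"
    )


def run_repeated_holdout(
    cohort: Cohort,
    quantiles: QuantileMatrix,
    n_repeats: int = 100,
    n_boot: int = 100,
    fraction: float = 0.4,
    direction: str = "negative",
    seed: int = 0,
    ensemble_mode: str = "mean",
    n_restarts: int = 3,
    maxiter: int = 300,
) -> HoldoutEnsemble:
    """Run the full repeated-holdout procedure.

    For each repeat: split -> ``n_boot`` bootstrap weight fits on the
    training part -> ensemble average -> frozen-weight index on the holdout
    part -> interaction OLS.  A repeat that fails outright is recorded and
    excluded from summaries.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    scores = quantiles.scores
    repeats: list[HoldoutRepeat] = []
    n_failed = 0
    for rep in range(n_repeats):
        rep_seed = int(
            np.random.SeedSequence([seed, rep]).generate_state(1, np.uint32)[0] % (2**31)
        )
        try:
            train, hold = split(cohort, fraction, seed=rep_seed)
            fits = []
            for b in range(n_boot):
                boot_seed = int(
                    np.random.SeedSequence([seed, rep, b]).generate_state(1, np.uint32)[0]
                    % (2**31)
                )
                fits.append(
                    fit_single_bootstrap(
                        scores.iloc[train],
                        cohort.covariates.iloc[train],
                        cohort.sex[train],
                        cohort.outcome[train],
                        direction=direction,
                        seed=boot_seed,
                        n_restarts=n_restarts,
                        maxiter=maxiter,
                    )
                )
            n_unconv = sum(not f.converged for f in fits)
            if n_unconv:
                logger.info("repeat %d: %d/%d bootstrap fits unconverged", rep, n_unconv, n_boot)
            weights = ensemble_weights(fits, mode=ensemble_mode)
            index_hold = compute_index(scores.iloc[hold], weights, cohort.sex[hold])
            coefs = fit_index_model(
                index_hold,
                cohort.covariates.iloc[hold],
                cohort.sex[hold],
                cohort.outcome[hold],
            )
            repeats.append(
                HoldoutRepeat(rep_seed, train, hold, weights, coefs, n_unconv)
            )
        except Exception:  # noqa: BLE001 - a failed repeat is data, not a crash
            logger.exception("repeat %d failed; excluded from summaries", rep)
            n_failed += 1
    if not repeats:
        raise ValueError("every holdout repeat failed")
    return HoldoutEnsemble(
        repeats=repeats, n_repeats=n_repeats, split_fraction=fraction, n_failed=n_failed
    )


def summarize_ensemble(
    ensemble: HoldoutEnsemble, threshold: float | None = None
) -> EnsembleSummary:
    """Summarize coefficient and weight distributions across repeats.

    Parameters get mean, SD-across-repeats (reported as "Std. Error"),
    2.5/97.5 percentiles and the fraction of repeats with a negative
    estimate.  Weights get mean, 2.5/25/50/75/97.5 percentiles and the
    fraction of repeats above the equi-weight guideline threshold.
    """
    coefs = ensemble.coefficient_frame()
    params = pd.DataFrame(
        {
            "Estimate": coefs.mean(),
            "Std. Error": coefs.std(ddof=1) if len(coefs) > 1 else 0.0 * coefs.mean(),
            "2.5%": coefs.quantile(0.025),
            "97.5%": coefs.quantile(0.975),
            "Frac. negative": (coefs < 0).mean(),
        }
    )
    order = [c for c in coefs.columns if c not in (WQS, INTERACTION)]
    params = params.reindex(
        [coefs.columns[0]]
        + [WQS]
        + [c for c in order if c != coefs.columns[0]]
        + [INTERACTION]
    )

    wf = ensemble.weight_frame()
    ref = ensemble.repeats[0].weights
    if threshold is None:
        threshold = equi_weight_threshold(len(ref.chemicals), len(ref.strata))
    g = wf.groupby(["stratum", "chemical"], sort=False)["weight"]
    weights = g.agg(
        mean="mean",
        p2_5=lambda s: s.quantile(0.025),
        p25=lambda s: s.quantile(0.25),
        p50=lambda s: s.quantile(0.50),
        p75=lambda s: s.quantile(0.75),
        p97_5=lambda s: s.quantile(0.975),
    )
    weights["frac_above_threshold"] = g.apply(lambda s: float((s > threshold).mean()))
    return EnsembleSummary(parameters=params, weights=weights.reset_index(), threshold=threshold)
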