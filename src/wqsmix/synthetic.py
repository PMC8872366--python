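"""Synthetic pregnancy-cohort generator with known ground truth.

The restricted-access cohort this package targets cannot be redistributed,
so every downstream stage is exercised on simulated data that emulate its
published summary statistics: n = 678 mother-child pairs, 26 chemicals in
five classes with block-correlated lognormal concentrations, covariate
marginals matching the published cohort table, and a 7-year IQ outcome
generated from the sex-stratified interaction index model with sparse
sex-specific true weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemicals import ChemicalSpec, class_map, default_chemicals
from .cohort import COVARIATE_COLS, Cohort, TrueModel
from .preprocess import ExposurePanel, QuantileMatrix, creatinine_adjust, quantile_score

#: published covariate marginals (mean, sd) or (probability,) for binaries
DEFAULT_COVARIATE_PARAMS = {
    "MNI": (66.8, 14.0),
    "Energy": (1895.0, 545.0),
    "MomAge": (31.3, 4.6),
    "MomWeight": (68.8, 13.5),
    "MomIQ": (114.8, 14.9),
    "MomEduc": (0.69,),
    "Smoker": (0.11,),
}
DEFAULT_FEMALE_FRACTION = 0.51

#: creatinine marginal (mmol/L): mean 10.4, sd 4.7 on the natural scale
_CRE_SIGMA = float(np.sqrt(np.log(1.0 + (4.7 / 10.4) ** 2)))
_CRE_MU = float(np.log(10.4) - 0.5 * _CRE_SIGMA**2)

#: outcome-model coefficients of the published holdout-ensemble fit, used as
#: the default generating truth
DEFAULT_BETAS = {"beta0": 88.7, "beta1": -2.13, "beta2": -0.622, "beta12": 1.98}
DEFAULT_PHI = {
    "MNI": 0.073,
    "Energy": 0.000,
    "MomAge": -0.158,
    "MomWeight": -0.098,
    "MomEduc": 4.79,
    "MomIQ": 0.158,
    "Smoker": -2.10,
}

#: default sparse supports: chemicals carrying nonzero true weight per sex,
#: uniform within each active set (8 for boys, 6 for girls)
DEFAULT_ACTIVE_BOYS = ("BPF", "TCP", "MBzP", "PFOA", "Triclosan", "MOiNCH", "MEP", "MCiNP")
DEFAULT_ACTIVE_GIRLS = ("DPHP", "MEP", "BPF", "BPS", "PFHxS", "PFUnDA")

LOD_SUBSTITUTION = 1.0 / np.sqrt(2.0)


def default_truth(
    chems: list[ChemicalSpec] | None = None,
    sigma: float = 10.0,
    active_boys: tuple[str, ...] = DEFAULT_ACTIVE_BOYS,
    active_girls: tuple[str, ...] = DEFAULT_ACTIVE_GIRLS,
) -> TrueModel:
    """Default generating truth: published coefficients, sparse uniform weights.

    The 2c-weight vector lives on one simplex (boys block then girls block);
    each truly active stratum-chemical term gets weight 1/(n_active_total).
    """
    chems = chems if chems is not None else default_chemicals()
    names = [c.name for c in chems]
    for a in set(active_boys) | set(active_girls):
        if a not in names:
            raise ValueError(f"active chemical {a!r} not in the panel")
    c = len(names)
    w = np.zeros(2 * c)
    n_active = len(active_boys) + len(active_girls)
    for a in active_boys:
        w[names.index(a)] = 1.0 / n_active
    for a in active_girls:
        w[c + names.index(a)] = 1.0 / n_active
    return TrueModel(
        beta0=DEFAULT_BETAS["beta0"],
        beta1=DEFAULT_BETAS["beta1"],
        beta2=DEFAULT_BETAS["beta2"],
        beta12=DEFAULT_BETAS["beta12"],
        phi=dict(DEFAULT_PHI),
        true_weights=w,
        sigma=sigma,
    )


def _block_correlation(chems: list[ChemicalSpec], rho_within: float, rho_between: float):
    classes = [c.chem_class for c in chems]
    p = len(chems)
    r = np.full((p, p), rho_between)
    for i in range(p):
        for j in range(p):
            if classes[i] == classes[j]:
                r[i, j] = rho_within
    np.fill_diagonal(r, 1.0)
    return r


def simulate_exposures(
    n: int,
    chems: list[ChemicalSpec] | None = None,
    rho_within: float = 0.4,
    rho_between: float = 0.1,
    seed: int = 0,
    lod_substitution: float = LOD_SUBSTITUTION,
) -> ExposurePanel:
    """Draw a subject-by-chemical concentration panel.

    Dependence uses a Gaussian copula with two-level block-exchangeable
    correlation (``rho_within`` inside a chemical class, ``rho_between``
    across classes) and lognormal marginals.  Urinary analytes are stored
    unadjusted (the analysis-scale concentration multiplied by a lognormal
    creatinine), so the creatinine-adjustment step is exercised for real.
    Values below each chemical's detection limit — the (1 - detect_rate)
    quantile of its marginal — are flagged and substituted by
    ``lod_substitution`` times the limit.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    chems = chems if chems is not None else default_chemicals()
    if rho_between > rho_within:
        raise ValueError("rho_between must not exceed rho_within")
    r = _block_correlation(chems, rho_within, rho_between)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"correlation matrix not positive definite for rho_within={rho_within}, "
            f"rho_between={rho_between}"
        ) from None
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(chems))) @ chol.T
    creatinine = np.exp(_CRE_MU + _CRE_SIGMA * rng.standard_normal(n))

    from scipy.stats import norm

    subjects = pd.RangeIndex(n, name="subject")
    values = {}
    nondetect = {}
    for j, chem in enumerate(chems):
        conc = np.exp(chem.log_mean + chem.log_sd * z[:, j])
        if chem.urinary:
            conc = conc * creatinine
            mu, sd = chem.log_mean + _CRE_MU, float(np.hypot(chem.log_sd, _CRE_SIGMA))
        else:
            mu, sd = chem.log_mean, chem.log_sd
        if chem.detect_rate >= 1.0:
            flag = np.zeros(n, dtype=bool)
        else:
            lod = float(np.exp(mu + sd * norm.ppf(1.0 - chem.detect_rate)))
            flag = conc < lod
            conc = np.where(flag, lod * lod_substitution, conc)
        values[chem.name] = conc
        nondetect[chem.name] = flag
    return ExposurePanel(
        values=pd.DataFrame(values, index=subjects),
        nondetect=pd.DataFrame(nondetect, index=subjects),
        classes=class_map(chems),
        urinary=frozenset(c.name for c in chems if c.urinary),
        creatinine=pd.Series(creatinine, index=subjects, name="creatinine"),
    )


def simulate_covariates(
    n: int,
    seed: int = 0,
    params: dict | None = None,
    female_fraction: float = DEFAULT_FEMALE_FRACTION,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the covariate table and child sex.

    Continuous covariates are independent normals and binaries independent
    Bernoullis at the published cohort marginals; override any entry via
    ``params`` (tuples ``(mean, sd)`` or ``(prob,)``).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p = dict(DEFAULT_COVARIATE_PARAMS)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    cols = {}
    for name in COVARIATE_COLS:
        spec = p[name]
        if len(spec) == 1:
            cols[name] = (rng.random(n) < spec[0]).astype(float)
        else:
            mean, sd = spec
            cols[name] = mean + sd * rng.standard_normal(n)
    sex = (rng.random(n) < female_fraction).astype(int)
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject")), sex


def true_index(quantiles: QuantileMatrix, sex: np.ndarray, truth: TrueModel) -> np.ndarray:
    """Weighted index under the generating weights (subject's stratum block)."""
    q = quantiles.scores.to_numpy(dtype=float)
    c = q.shape[1]
    if truth.true_weights.size != 2 * c:
        raise ValueError(
            f"truth has {truth.true_weights.size} weights but panel needs {2 * c}"
        )
    w_boy = truth.true_weights[:c]
    w_girl = truth.true_weights[c:]
    sex = np.asarray(sex)
    return np.where(sex == 0, q @ w_boy, q @ w_girl)


def simulate_outcome(
    quantiles: QuantileMatrix,
    covariates: pd.DataFrame,
    sex: np.ndarray,
    truth: TrueModel,
    seed: int = 0,
) -> np.ndarray:
    """Generate the IQ outcome from the stratified-interaction linear model."""
    n = quantiles.n_subjects
    if not (len(covariates) == len(sex) == n):
        raise ValueError("quantiles, covariates and sex must have equal lengths")
    wqs = true_index(quantiles, sex, truth)
    z = covariates[COVARIATE_COLS].to_numpy(dtype=float)
    phi = np.array([truth.phi.get(c, 0.0) for c in COVARIATE_COLS])
    systematic = (
        truth.beta0
        + truth.beta1 * wqs
        + truth.beta2 * sex
        + truth.beta12 * sex * wqs
        + z @ phi
    )
    rng = np.random.default_rng(seed)
    return systematic + truth.sigma * rng.standard_normal(n)


def simulate_cohort(
    n: int = 678,
    seed: int = 0,
    chems: list[ChemicalSpec] | None = None,
    truth: TrueModel | None = None,
    rho_within: float = 0.4,
    rho_between: float = 0.1,
    k: int = 10,
    confounding: float = 0.0,
) -> tuple[Cohort, QuantileMatrix]:
    """End-to-end cohort draw: exposures, covariates, outcome, decile scores.

    Returns the cohort (raw, unadjusted exposure panel) together with the
    quantile matrix used to generate the outcome, scored on the
    creatinine-adjusted panel with frozen full-sample breakpoints.

    ``confounding`` > 0 tilts MNI and smoking along a latent factor shared
    with the exposures, for stress-testing covariate adjustment; the default
    keeps covariates independent of exposures.
    """
    chems = chems if chems is not None else default_chemicals()
    truth = truth if truth is not None else default_truth(chems)
    seeds = np.random.SeedSequence(seed).spawn(3)
    panel = simulate_exposures(n, chems, rho_within, rho_between, seed=seeds[0])
    covariates, sex = simulate_covariates(n, seed=seeds[1])
    if confounding:
        adj = creatinine_adjust(panel)
        logs = np.log(adj.values.to_numpy(dtype=float))
        u = (logs - logs.mean(axis=0)) / logs.std(axis=0)
        factor = u.mean(axis=1) / u.mean(axis=1).std()
        covariates = covariates.copy()
        covariates["MNI"] = covariates["MNI"] - confounding * 14.0 * factor
    quantiles = quantile_score(creatinine_adjust(panel), k=k)
    outcome = simulate_outcome(quantiles, covariates, sex, truth, seed=seeds[2])
    cohort = Cohort(
        exposures=panel, covariates=covariates, sex=sex, outcome=outcome, truth=truth
    )
    return cohort, quantiles
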