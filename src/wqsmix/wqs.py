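"""Sex-stratified-interaction weighted quantile sum (WQS) regression.

The index is WQS_i = sum_j w[s(i), j] * q_ij, where q_ij are quantile
scores, s(i) is subject i's sex stratum, and the 2c stratum-by-chemical
weights live on a single simplex (so the equi-weight guideline is 1/(2c)).
The outcome model is the stratified interaction parameterization

    y = beta0 + beta1*WQS + beta2*x + beta12*x*WQS + phi'z + eps,

with x the female indicator: beta1 is the boys' slope and beta1 + beta12
the girls' slope.  Estimation is the classic two-step scheme: (i) weights
estimated by minimizing the residual sum of squares jointly over weights
(softmax-parameterized on the simplex) and coefficients (profiled out by
least squares), with the index slope beta1 sign-constrained to a chosen
direction, averaged over bootstrap resamples; (ii) the ensemble-averaged
weights frozen and the index tested by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import COVARIATE_COLS, STRATA
from .preprocess import QuantileMatrix

INTERCEPT = "Intercept"
WQS = "WQS"
FEMALE = "Female"
INTERACTION = "WQS:Female"


@dataclass
class WeightSet:
    """Nonnegative stratum-by-chemical weights on a single simplex."""

    weights: np.ndarray  # shape (n_strata, c)
    chemicals: list[str]
    strata: tuple[str, ...] = STRATA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a (n_strata, c) matrix")
        if self.weights.shape != (len(self.strata), len(self.chemicals)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{len(self.strata)} strata x {len(self.chemicals)} chemicals"
            )
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be nonnegative")
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1 within 1e-8, got {total}")

    @property
    def flat(self) -> np.ndarray:
        """Weights flattened stratum-major (all of stratum 0, then stratum 1)."""
        return self.weights.ravel()

    @property
    def threshold(self) -> float:
        """Equi-weight guideline value 1/(n_strata * c)."""
        return equi_weight_threshold(len(self.chemicals), len(self.strata))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (stratum, chemical, weight) table."""
        rows = [
            {"stratum": s, "chemical": ch, "weight": self.weights[i, j]}
            for i, s in enumerate(self.strata)
            for j, ch in enumerate(self.chemicals)
        ]
        return pd.DataFrame(rows)


@dataclass
class CoefficientTable:
    """Regression coefficients in the stratified-interaction layout.

    ``params``/``se`` are indexed by term name (Intercept, WQS, Female,
    covariates, WQS:Female); percentile columns are attached by ensemble
    summaries.  The girls' slope is always derived as beta1 + beta12, never
    stored as a free parameter.
    """

    params: pd.Series
    se: pd.Series | None = None
    extra: pd.DataFrame | None = field(default=None)

    @property
    def beta0(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def beta1(self) -> float:
        return float(self.params.get(WQS, 0.0))

    @property
    def beta2(self) -> float:
        return float(self.params.get(FEMALE, 0.0))

    @property
    def beta12(self) -> float:
        return float(self.params.get(INTERACTION, 0.0))

    def tvalue(self, name: str = WQS) -> float:
        if self.se is None or name not in self.params.index:
            return float("nan")
        s = float(self.se[name])
        return float(self.params[name]) / s if s > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"Estimate": self.params})
        if self.se is not None:
            out["Std. Error"] = self.se
        if self.extra is not None:
            out = out.join(self.extra)
        return out


@dataclass
class BootstrapFit:
    """One bootstrap-resample weight fit (step i of the two-step scheme)."""

    weights: WeightSet
    coefficients: CoefficientTable
    objective: float
    converged: bool
    seed: int


def equi_weight_threshold(c: int, n_strata: int = 2) -> float:
    """Guideline cutoff for a non-negligible mean weight: 1/(n_strata*c)."""
    if c < 1 or n_strata < 1:
        raise ValueError("c and n_strata must be at least 1")
    return 1.0 / (n_strata * c)


def stratum_slope(coefs: CoefficientTable, stratum: str) -> float:
    """Index slope per stratum: boys -> beta1, girls -> beta1 + beta12."""
    if stratum == "boy":
        return coefs.beta1
    if stratum == "girl":
        return coefs.beta1 + coefs.beta12
    raise ValueError(f"stratum must be 'boy' or 'girl', got {stratum!r}")


def _as_scores(q) -> tuple[np.ndarray, list[str]]:
    if isinstance(q, QuantileMatrix):
        return q.scores.to_numpy(dtype=float), list(q.scores.columns)
    if isinstance(q, pd.DataFrame):
        return q.to_numpy(dtype=float), list(q.columns)
    arr = np.asarray(q, dtype=float)
    return arr, [f"chem{j}" for j in range(arr.shape[1])]


def _check_sex(sex: np.ndarray) -> np.ndarray:
    sex = np.asarray(sex)
    if not np.isin(sex, (0, 1)).all():
        bad = sorted(set(sex[~np.isin(sex, (0, 1))].tolist()))
        raise ValueError(f"sex values outside {{0, 1}}: {bad}")
    return sex.astype(int)


def compute_index(q, weights: WeightSet, sex: np.ndarray) -> np.ndarray:
    """Weighted index per subject using only the subject's stratum block."""
    scores, chems = _as_scores(q)
    if chems != list(weights.chemicals):
        raise ValueError("quantile matrix chemicals do not match weight set")
    sex = _check_sex(sex)
    if len(weights.strata) == 1:
        return scores @ weights.weights[0]
    return np.where(sex == 0, scores @ weights.weights[0], scores @ weights.weights[1])


def _stratum_masked_scores(scores: np.ndarray, sex: np.ndarray, two_strata: bool):
    """n x (S*c) matrix with q_ij in the subject's own stratum block, else 0."""
    n, c = scores.shape
    if not two_strata:
        return scores
    qmask = np.zeros((n, 2 * c))
    boys = sex == 0
    qmask[boys, :c] = scores[boys]
    qmask[~boys, c:] = scores[~boys]
    return qmask


def _covariate_matrix(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0, 0)), []
    cols = [c for c in COVARIATE_COLS if c in covariates.columns]
    cols += [c for c in covariates.columns if c not in cols]
    return covariates[cols].to_numpy(dtype=float), cols


def design_matrix(
    index: np.ndarray,
    sex: np.ndarray,
    covariates: pd.DataFrame | None = None,
    interaction: bool = True,
) -> pd.DataFrame:
    """Design for the stratified interaction model, Table-style column order.

    Sex main effect and interaction columns are dropped automatically when
    the sample contains a single stratum.
    """
    sex = _check_sex(sex)
    n = len(index)
    z, zcols = _covariate_matrix(covariates)
    two = len(np.unique(sex)) > 1
    cols = {INTERCEPT: np.ones(n), WQS: np.asarray(index, dtype=float)}
    if two:
        cols[FEMALE] = sex.astype(float)
    for name, col in zip(zcols, z.T if z.size else []):
        cols[name] = col
    if two and interaction:
        cols[INTERACTION] = sex * np.asarray(index, dtype=float)
    return pd.DataFrame(cols)


def fit_index_model(
    index: np.ndarray,
    covariates: pd.DataFrame | None,
    sex: np.ndarray,
    y: np.ndarray,
) -> CoefficientTable:
    """Step (ii): ordinary least squares of y on the frozen-weight index.

    Model: y ~ WQS + Female + covariates + WQS:Female.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    import statsmodels.api as sm

    x = design_matrix(index, sex, covariates, interaction=True)
    mat = x.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [x.columns[j] for j in range(mat.shape[1]) if diag[j] < tol]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(np.asarray(y, dtype=float), x).fit()
    return CoefficientTable(params=res.params.copy(), se=res.bse.copy())


class _ProfiledObjective:
    """RSS profiled over coefficients, with analytic gradient in theta.

    theta parameterizes the simplex via softmax.  For each weight vector the
    coefficients are solved from the normal equations, exploiting that only
    the index column (and its sex interaction) change between evaluations;
    when the index slope violates the sign constraint it is pinned at 0 (the
    active-boundary solution) and the remaining coefficients refit.  The
    gradient uses the envelope theorem: only the explicit dependence of the
    design on the weights contributes.
    """

    def __init__(self, qmask, x0, sex_f, y, dirsign):
        self.qmask = qmask
        self.x0 = x0
        self.sex_f = sex_f
        self.y = y
        self.dirsign = dirsign
        self.p0 = x0.shape[1]
        self.g00 = x0.T @ x0
        self.g0y = x0.T @ y

    def _solve(self, a, rhs):
        try:
            return np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(a, rhs, rcond=None)[0]

    def evaluate(self, theta):
        """Return (rss, grad_theta, coefficients, weights)."""
        t = theta - theta.max()
        ew = np.exp(t)
        w = ew / ew.sum()
        wqs = self.qmask @ w
        p0 = self.p0
        m = 1 if self.sex_f is None else 2
        p = p0 + m
        a = np.empty((p, p))
        rhs = np.empty(p)
        a[:p0, :p0] = self.g00
        rhs[:p0] = self.g0y
        a[:p0, p0] = a[p0, :p0] = self.x0.T @ wqs
        a[p0, p0] = wqs @ wqs
        rhs[p0] = wqs @ self.y
        if m == 2:
            c2 = self.sex_f * wqs
            a[:p0, p0 + 1] = a[p0 + 1, :p0] = self.x0.T @ c2
            a[p0, p0 + 1] = a[p0 + 1, p0] = wqs @ c2
            a[p0 + 1, p0 + 1] = c2 @ c2
            rhs[p0 + 1] = c2 @ self.y
        b = self._solve(a, rhs)
        b1 = b[p0]
        if self.dirsign * b1 < 0:
            # boundary solution: index slope pinned at 0, rest refit
            free = np.delete(np.arange(p), p0)
            bc = self._solve(a[np.ix_(free, free)], rhs[free])
            b = np.zeros(p)
            b[free] = bc
            b1 = 0.0
        r = self.y - self.x0 @ b[:p0] - b1 * wqs
        scale = b1
        if m == 2:
            r -= b[p0 + 1] * c2
            scale = b1 + b[p0 + 1] * self.sex_f
        rss = float(r @ r)
        g_w = -2.0 * ((scale * r) @ self.qmask)
        grad = w * (g_w - g_w @ w)
        return rss, grad, b, w


def _fit_weights(
    qmask,
    x0,
    sex_f,
    y,
    dirsign,
    rng,
    n_restarts: int,
    maxiter: int,
):
    obj = _ProfiledObjective(qmask, x0, sex_f, y, dirsign)

    def fun(theta):
        rss, grad, _, _ = obj.evaluate(theta)
        return rss, grad

    best = None
    for start in range(max(1, n_restarts)):
        # first start from the equi-weighted index, later starts perturbed
        if start == 0:
            theta0 = np.zeros(qmask.shape[1])
        else:
            theta0 = rng.normal(0.0, 0.25, size=qmask.shape[1])
        res = minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    rss, _, b, w = obj.evaluate(best.x)
    return w, b, rss, bool(best.success)


def fit_single_bootstrap(
    q,
    covariates: pd.DataFrame | None,
    sex: np.ndarray,
    y: np.ndarray,
    direction: str = "negative",
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 300,
    resample: bool = True,
) -> BootstrapFit:
    """Step (i) on one bootstrap resample: joint weight/coefficient fit.

    Draws a with-replacement resample of subjects (skipped when
    ``resample=False``, e.g. for oracle comparisons), then minimizes the
    profiled residual sum of squares over the softmax-parameterized simplex
    with ``n_restarts`` random starts.  ``direction`` constrains the sign of
    the boys' slope beta1 only; the girls' slope beta1 + beta12 is free.
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    dirsign = -1.0 if direction == "negative" else 1.0
    scores, chems = _as_scores(q)
    sex = _check_sex(sex)
    y = np.asarray(y, dtype=float)
    n, c = scores.shape
    z, zcols = _covariate_matrix(covariates)
    n_params = 2 * len(chems) + len(zcols) + 4
    if n < n_params:
        raise ValueError(f"need at least {n_params} complete cases, got {n}")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n) if resample else np.arange(n)
    sb, yb = scores[idx], y[idx]
    sexb = sex[idx]
    zb = z[idx] if z.size else z

    two = len(np.unique(sexb)) > 1
    qmask = _stratum_masked_scores(sb, sexb, two)
    x0_parts = [np.ones((len(yb), 1))]
    names = [INTERCEPT]
    if two:
        x0_parts.append(sexb[:, None].astype(float))
        names.append(FEMALE)
    if zb.size:
        x0_parts.append(zb)
        names.extend(zcols)
    x0 = np.hstack(x0_parts)

    w, b, rss, converged = _fit_weights(
        qmask, x0, sexb.astype(float) if two else None, yb, dirsign, rng, n_restarts, maxiter
    )
    if two:
        params = pd.Series(
            dict(zip(names, b[: len(names)])) | {WQS: b[-2], INTERACTION: b[-1]}
        )
        wmat = w.reshape(2, c)
        strata = STRATA
    else:
        params = pd.Series(dict(zip(names, b[:-1])) | {WQS: b[-1]})
        wmat = w.reshape(1, c)
        strata = (STRATA[int(sexb[0])],)
    # slope SE with the fitted weights treated as fixed, for signal weighting
    se = _slope_se(qmask, x0, sexb.astype(float) if two else None, yb, w, b)
    coefs = CoefficientTable(params=params, se=se)
    return BootstrapFit(
        weights=WeightSet(wmat, chemicals=chems, strata=strata),
        coefficients=coefs,
        objective=rss,
        converged=converged,
        seed=seed,
    )


def _slope_se(qmask, x0, sex_f, y, w, b) -> pd.Series | None:
    wqs = qmask @ w
    if sex_f is None:
        x = np.column_stack([x0, wqs])
    else:
        x = np.column_stack([x0, wqs, sex_f * wqs])
    n, p = x.shape
    if n <= p:
        return None
    r = y - x @ b
    sigma2 = float(r @ r) / (n - p)
    # pinv: the interaction column degenerates when one stratum block holds
    # all the weight, leaving X'X singular
    xtx_inv = np.linalg.pinv(x.T @ x)
    var = sigma2 * xtx_inv[x0.shape[1], x0.shape[1]]
    se_wqs = float(np.sqrt(var)) if var > 0 else float("nan")
    return pd.Series({WQS: se_wqs})


def ensemble_weights(fits: list[BootstrapFit], mode: str = "mean") -> WeightSet:
    """Average converged bootstrap weight fits into the final index weights.

    ``mean`` is the plain arithmetic average; ``signal_weighted`` weights
    each fit by the magnitude of its index-slope t statistic.  Either way
    the result is renormalized onto the simplex.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged bootstrap fits to average")
    ref = good[0].weights
    stack = np.stack([f.weights.flat for f in good])
    if mode == "mean":
        avg = stack.mean(axis=0)
    elif mode == "signal_weighted":
        t = np.array([abs(f.coefficients.tvalue(WQS)) for f in good])
        t = np.where(np.isfinite(t), t, 0.0)
        if t.sum() <= 0:
            avg = stack.mean(axis=0)
        else:
            avg = (t[:, None] * stack).sum(axis=0) / t.sum()
    else:
        raise ValueError("mode must be 'mean' or 'signal_weighted'")
    avg = np.clip(avg, 0.0, None)
    avg /= avg.sum()
    return WeightSet(
        avg.reshape(ref.weights.shape), chemicals=list(ref.chemicals), strata=ref.strata
    )
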