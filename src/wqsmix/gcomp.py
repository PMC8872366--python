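"""g-computation: marginal counterfactual contrasts for an exposure metric.

The parametric g-formula specializes here to: fit one linear outcome model
of IQ on the metric (WQS index or nutrition score), sex, their interaction
and covariates; set every subject's metric to each counterfactual level;
predict; average within reporting strata; difference the averages.
Percentile confidence intervals come from a subject-level nonparametric
bootstrap that repeats the whole procedure.

The causal reading rests on the usual identifiability conditions —
consistency, conditional exchangeability given the modeled covariates, and
positivity (counterfactual levels inside the support of the observed
metric) — which are assumptions about the data, not properties the code can
verify.  A level more than one SD outside the observed range triggers a
positivity warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wqs import design_matrix

OVERALL = "overall"
_STRATUM_NAME = {0: "boy", 1: "girl"}


@dataclass
class ExposureMetric:
    """A per-subject exposure metric with optional centering/scaling.

    ``scaled`` values have mean 0 and SD 1; ``center``/``scale`` allow
    back-transformation between the standardized and raw scales.
    """

    name: str
    values: np.ndarray
    center: float
    scale: float
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.standardized:
            if abs(self.values.mean()) > 1e-8 or abs(self.values.std(ddof=1) - 1) > 1e-8:
                raise ValueError("standardized metric must have mean 0 and SD 1")

    def to_raw(self, scaled_value: float) -> float:
        return self.center + scaled_value * self.scale

    def raw(self) -> "ExposureMetric":
        """Raw-scale view (values back-transformed, center/scale kept)."""
        values = self.values * self.scale + self.center if self.standardized else self.values
        return ExposureMetric(
            name=self.name, values=values, center=self.center, scale=self.scale,
            standardized=False,
        )


def scale_metric(values: np.ndarray, name: str = "metric") -> ExposureMetric:
    """Center and scale a metric (sample mean / sample SD, ddof=1)."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("metric has zero variance; cannot scale")
    center = float(values.mean())
    scale = float(values.std(ddof=1))
    return ExposureMetric(
        name=name,
        values=(values - center) / scale,
        center=center,
        scale=scale,
        standardized=True,
    )


def counterfactual_shift(center: float, scale: float, k: float) -> float:
    """Raw metric value k standard deviations from the center."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return center + k * scale


@dataclass
class GCompResult:
    """Counterfactual marginal means, differences and bootstrap CIs.

    ``marginal_means[level][stratum]`` and ``difference[stratum]`` for
    strata 'boy', 'girl', 'overall'; ``ci`` maps the same keys to
    (2.5%, 97.5%) percentile intervals when ``n_boot`` > 0.
    """

    metric_name: str
    levels: tuple[float, float]
    marginal_means: dict[float, dict[str, float]]
    difference: dict[str, float]
    ci_means: dict[float, dict[str, tuple[float, float]]] = field(default_factory=dict)
    ci_difference: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, means in self.marginal_means.items():
            for stratum, m in means.items():
                lo, hi = self.ci_means.get(level, {}).get(stratum, (np.nan, np.nan))
                rows.append(
                    {"quantity": f"mean@{level:g}", "stratum": stratum, "estimate": m,
                     "2.5%": lo, "97.5%": hi}
                )
        for stratum, d in self.difference.items():
            lo, hi = self.ci_difference.get(stratum, (np.nan, np.nan))
            rows.append(
                {"quantity": "difference", "stratum": stratum, "estimate": d,
                 "2.5%": lo, "97.5%": hi}
            )
        return pd.DataFrame(rows)


def _fit_predict(metric_values, sex, covariates, y, levels, interaction):
    """One g-formula pass: fit, predict under each level, average by stratum."""
    x = design_matrix(metric_values, sex, covariates, interaction=interaction)
    mat = x.to_numpy()
    coef, *_ = np.linalg.lstsq(mat, y, rcond=None)
    means = {}
    boys = sex == 0
    for level in levels:
        xcf = design_matrix(np.full(len(y), level), sex, covariates, interaction=interaction)
        pred = xcf.to_numpy() @ coef
        means[level] = {
            "boy": float(pred[boys].mean()) if boys.any() else np.nan,
            "girl": float(pred[~boys].mean()) if (~boys).any() else np.nan,
            OVERALL: float(pred.mean()),
        }
    diff = {
        s: means[levels[1]][s] - means[levels[0]][s] for s in ("boy", "girl", OVERALL)
    }
    return means, diff, x.columns.get_loc("WQS"), coef


def gcomp_marginal(
    metric: ExposureMetric,
    covariates: pd.DataFrame | None,
    sex: np.ndarray,
    y: np.ndarray,
    levels: tuple[float, float],
    n_boot: int = 200,
    seed: int = 0,
    interaction: bool = True,
) -> GCompResult:
    """Marginal counterfactual contrast between two metric levels.

    Fits y ~ metric + sex + metric:sex + covariates by least squares,
    predicts every subject at each of the two ``levels`` (on the metric's
    own scale), averages within boys / girls / overall, and differences
    (level B minus level A).  ``n_boot`` subject-level bootstrap replicates
    give 2.5/97.5 percentile intervals; ``n_boot=0`` returns point
    estimates only.
    """
    sex = np.asarray(sex, dtype=int)
    y = np.asarray(y, dtype=float)
    v = metric.values
    lo, hi = float(v.min()), float(v.max())
    sd = float(v.std(ddof=1))
    for level in levels:
        if level < lo - sd or level > hi + sd:
            warnings.warn(
                f"counterfactual level {level:g} lies more than one SD outside the "
                f"observed metric range [{lo:g}, {hi:g}]; positivity is doubtful",
                stacklevel=2,
            )
    means, diff, _, _ = _fit_predict(v, sex, covariates, y, levels, interaction)
    result = GCompResult(
        metric_name=metric.name,
        levels=tuple(levels),
        marginal_means=means,
        difference=diff,
        n_boot=n_boot,
        seed=seed,
    )
    if n_boot <= 0:
        return result
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_means = {lv: {s: [] for s in ("boy", "girl", OVERALL)} for lv in levels}
    boot_diff = {s: [] for s in ("boy", "girl", OVERALL)}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cov_b = covariates.iloc[idx] if covariates is not None else None
        try:
            m_b, d_b, _, _ = _fit_predict(v[idx], sex[idx], cov_b, y[idx], levels, interaction)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
            continue
        for lv in levels:
            for s in boot_means[lv]:
                boot_means[lv][s].append(m_b[lv][s])
        for s in boot_diff:
            boot_diff[s].append(d_b[s])
    result.ci_means = {
        lv: {
            s: tuple(np.nanpercentile(boot_means[lv][s], [2.5, 97.5]))
            for s in boot_means[lv]
        }
        for lv in levels
    }
    result.ci_difference = {
        s: tuple(np.nanpercentile(boot_diff[s], [2.5, 97.5])) for s in boot_diff
    }
    return result
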