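"""Class decomposition of the weighted index and exposure-reduction scenarios.

Because the index is additive over stratum-chemical terms, each subject's
index splits exactly into chemical-class contributions.  A reduction
scenario multiplies each class contribution by a retention factor in
[0, 1] (1 = untouched, 0 = eliminated) under the fixed weights and frozen
quantile designations, and is judged by the fraction of subjects whose
adjusted index falls strictly below a target — by default one SD below the
observed index mean.  Persistent classes (PFAS, persistent chlorinated)
are the ones a policy cannot readily reduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemicals import CHEMICAL_CLASSES, PERSISTENT_CLASSES
from .wqs import WeightSet, _as_scores, _check_sex

#: the named reduction scenarios evaluated by default, as retain multipliers
NAMED_SCENARIOS = {
    "cut70_nonpersistent": {
        "phenol": 0.30, "plasticizer": 0.30, "short_lived": 0.30,
        "pfas": 1.0, "persistent_chlorinated": 1.0,
    },
    "eliminate_plasticizers": {
        "phenol": 1.0, "plasticizer": 0.0, "short_lived": 1.0,
        "pfas": 1.0, "persistent_chlorinated": 1.0,
    },
    "eliminate_plasticizers_short_lived": {
        "phenol": 1.0, "plasticizer": 0.0, "short_lived": 0.0,
        "pfas": 1.0, "persistent_chlorinated": 1.0,
    },
    "eliminate_plasticizers_phenols": {
        "phenol": 0.0, "plasticizer": 0.0, "short_lived": 1.0,
        "pfas": 1.0, "persistent_chlorinated": 1.0,
    },
}


@dataclass
class ClassDecomposition:
    """Per-subject additive split of the index into class contributions."""

    contributions: pd.DataFrame  # subjects x classes
    index: np.ndarray

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        total = self.contributions.sum(axis=1).to_numpy()
        if not np.allclose(total, self.index, atol=1e-10):
            raise ValueError("class contributions do not sum to the index")

    @property
    def fractions(self) -> pd.DataFrame:
        """Class shares of each subject's index (NaN where the index is 0)."""
        tot = self.contributions.sum(axis=1)
        return self.contributions.div(tot.where(tot > 0), axis=0)

    def persistent_fraction(self) -> pd.Series:
        """Per-subject share of the index due to persistent classes."""
        cols = [c for c in self.contributions.columns if c in PERSISTENT_CLASSES]
        return self.fractions[cols].sum(axis=1)


@dataclass
class ScenarioSpec:
    """Per-class retention multipliers in [0, 1]."""

    retain: dict[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        for cls, mult in self.retain.items():
            if not 0.0 <= mult <= 1.0:
                raise ValueError(f"retain multiplier for {cls!r} must be in [0, 1]")


@dataclass
class ScenarioResult:
    """Adjusted index, below-target fraction and histogram data for one scenario."""

    spec: ScenarioSpec
    adjusted: np.ndarray
    target: float
    fraction_below: float
    histogram: tuple[np.ndarray, np.ndarray] = field(default=None)


def target_value(index: np.ndarray) -> float:
    """Reduction target: one sample SD below the sample mean of the index."""
    index = np.asarray(index, dtype=float)
    if len(np.unique(index)) < 2:
        raise ValueError("index has zero variance; target undefined")
    return float(index.mean() - index.std(ddof=1))


def class_contributions(
    q,
    weights: WeightSet,
    sex: np.ndarray,
    classes: dict[str, str],
) -> ClassDecomposition:
    """Decompose each subject's index into chemical-class contributions.

    contribution_i[class] = sum over chemicals j in that class of
    w[s(i), j] * q_ij — an exact additive decomposition of the index.
    """
    scores, chems = _as_scores(q)
    if chems != list(weights.chemicals):
        raise ValueError("quantile matrix chemicals do not match weight set")
    sex = _check_sex(sex)
    unmapped = [c for c in chems if c not in classes]
    if unmapped:
        raise ValueError(f"chemicals without a class mapping: {unmapped}")
    n = scores.shape[0]
    if len(weights.strata) == 1:
        w_subject = np.tile(weights.weights[0], (n, 1))
    else:
        w_subject = weights.weights[sex]
    per_chem = scores * w_subject  # n x c stratum-specific term contributions
    present = [cl for cl in CHEMICAL_CLASSES if cl in set(classes[c] for c in chems)]
    contrib = {}
    for cl in present:
        cols = [j for j, c in enumerate(chems) if classes[c] == cl]
        contrib[cl] = per_chem[:, cols].sum(axis=1)
    frame = pd.DataFrame(contrib)
    return ClassDecomposition(contributions=frame, index=per_chem.sum(axis=1))


def apply_scenario(decomp: ClassDecomposition, spec: ScenarioSpec) -> np.ndarray:
    """Adjusted index: sum of retain[class] * contribution[class] per subject.

    Contributions are scaled directly — quantile designations and weights
    stay fixed; re-deriving decile scores from reduced concentrations would
    change the population quantiles and is deliberately not done here.
    """
    missing = [c for c in decomp.contributions.columns if c not in spec.retain]
    if missing:
        raise ValueError(f"scenario lacks retain multipliers for classes: {missing}")
    adjusted = np.zeros(len(decomp.index))
    for cl in decomp.contributions.columns:
        adjusted += spec.retain[cl] * decomp.contributions[cl].to_numpy()
    return adjusted


def fraction_below_target(adjusted: np.ndarray, target: float) -> float:
    """Share of subjects with adjusted index strictly below the target."""
    adjusted = np.asarray(adjusted, dtype=float)
    if adjusted.size == 0:
        raise ValueError("empty index vector")
    return float((adjusted < target).mean())


def scenario_battery(
    decomp: ClassDecomposition,
    target: float,
    extra: list[ScenarioSpec] | None = None,
    n_bins: int = 30,
) -> list[ScenarioResult]:
    """Evaluate the named reduction scenarios (plus any user-supplied ones).

    Histograms use fixed-width bins spanning the pooled range of the
    original and all adjusted indices, so panels are directly comparable.
    """
    specs = [
        ScenarioSpec(retain={cl: v for cl, v in retain.items()
                             if cl in decomp.contributions.columns}, name=name)
        for name, retain in NAMED_SCENARIOS.items()
    ] + list(extra or [])
    adjusted = {s.name or f"scenario{i}": apply_scenario(decomp, s) for i, s in enumerate(specs)}
    pooled = np.concatenate([decomp.index, *adjusted.values()])
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    results = []
    for s in specs:
        adj = adjusted[s.name or f"scenario{specs.index(s)}"]
        counts, _ = np.histogram(adj, bins=edges)
        results.append(
            ScenarioResult(
                spec=s,
                adjusted=adj,
                target=target,
                fraction_below=fraction_below_target(adj, target),
                histogram=(counts, edges),
            )
        )
    return results
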