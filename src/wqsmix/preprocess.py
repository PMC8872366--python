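"""Raw concentrations -> decile-scored matrix for the weighted index.

The preprocessing chain is: creatinine adjustment of urinary analytes,
molar/plain summing of related analytes, a minimum-detection-frequency
filter (default 75%, summed variables exempt), and empirical quantile
scoring (deciles by default).  Quantile breakpoints are computed once on the
full cohort and frozen, so new or held-out subjects are scored on the same
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExposurePanel:
    """Subject-by-chemical concentration table with detection metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Positive concentrations, one row per subject, one column per
        chemical.  Nondetects hold their substituted value (e.g. LOD/sqrt(2)).
    nondetect : pandas.DataFrame
        Boolean, same shape as ``values``; True where below detection.
    classes : dict
        Chemical name -> chemical class.
    urinary : frozenset
        Names of urinary analytes (creatinine adjustment applies to these).
    creatinine : pandas.Series or None
        Per-subject creatinine (mmol/L), aligned with ``values.index``.
    """

    values: pd.DataFrame
    nondetect: pd.DataFrame
    classes: dict[str, str]
    urinary: frozenset = frozenset()
    creatinine: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.nondetect.shape:
            raise ValueError("values and nondetect matrices must have the same shape")
        if list(self.values.columns) != list(self.nondetect.columns):
            raise ValueError("values and nondetect must share column order")
        missing = [c for c in self.values.columns if c not in self.classes]
        if missing:
            raise ValueError(f"chemicals without a class label: {missing}")
        detected = self.values.values[~self.nondetect.values]
        if detected.size and not np.all(detected > 0):
            raise ValueError("detected concentrations must be positive")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def chemicals(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def detection_fraction(self) -> pd.Series:
        """Fraction of subjects above the detection limit, per chemical."""
        return 1.0 - self.nondetect.mean(axis=0)


@dataclass
class QuantileMatrix:
    """Integer quantile scores in {0, ..., K-1} with frozen breakpoints.

    ``breakpoints[chem]`` holds the K-1 interior cut values estimated from
    the scoring sample; :meth:`score_new` re-scores new concentrations on
    the same cuts so that train/holdout splits and counterfactual inputs
    share a single quantile designation.
    """

    scores: pd.DataFrame
    k: int
    breakpoints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores.values
        if arr.size and (arr.min() < 0 or arr.max() > self.k - 1):
            raise ValueError(f"scores must lie in [0, {self.k - 1}]")

    @property
    def chemicals(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.scores)

    def score_new(self, values: pd.DataFrame) -> pd.DataFrame:
        """Score new concentrations against the stored breakpoints."""
        out = {}
        for chem in self.scores.columns:
            cuts = self.breakpoints[chem]
            out[chem] = np.searchsorted(cuts, values[chem].to_numpy(), side="left")
        return pd.DataFrame(out, index=values.index)


def creatinine_adjust(panel: ExposurePanel) -> ExposurePanel:
    """Divide urinary analyte concentrations by subject creatinine.

    Serum/plasma analytes pass through unchanged.  Raises if any subject has
    missing or non-positive creatinine while urinary analytes are present.
    """
    urinary_cols = [c for c in panel.chemicals if c in panel.urinary]
    if not urinary_cols:
        return panel
    if panel.creatinine is None:
        raise ValueError("urinary analytes present but no creatinine provided")
    cre = panel.creatinine.reindex(panel.subjects)
    bad = cre.isna() | (cre <= 0)
    if bad.any():
        offenders = list(panel.subjects[bad.to_numpy()][:10])
        raise ValueError(
            f"zero or missing creatinine for subjects {offenders}; "
            "cannot adjust urinary analytes"
        )
    values = panel.values.copy()
    values[urinary_cols] = values[urinary_cols].div(cre, axis=0)
    return ExposurePanel(
        values=values,
        nondetect=panel.nondetect.copy(),
        classes=dict(panel.classes),
        urinary=panel.urinary,
        creatinine=panel.creatinine,
    )


def molar_sum(
    analytes: pd.DataFrame,
    molar_masses: dict[str, float] | None = None,
    mode: str = "molar",
) -> pd.Series:
    """Combine related analyte columns into one summed variable.

    ``mode="molar"`` computes sum(value_k / mass_k) — used for metabolite
    families like DEHP and DINP; ``mode="plain"`` is a straight sum — used
    for DDT plus its metabolite DDE and for PCB congeners.
    """
    if analytes.shape[1] < 2:
        raise ValueError("molar_sum requires at least two analyte columns")
    if mode == "plain":
        return analytes.sum(axis=1)
    if mode != "molar":
        raise ValueError(f"mode must be 'molar' or 'plain', got {mode!r}")
    if molar_masses is None:
        raise ValueError("molar mode requires molar masses")
    parts = []
    for col in analytes.columns:
        mass = molar_masses.get(col)
        if mass is None or mass <= 0:
            raise ValueError(f"missing or non-positive molar mass for analyte {col!r}")
        parts.append(analytes[col] / mass)
    return sum(parts)


def detection_filter(
    panel: ExposurePanel,
    min_rate: float = 0.75,
    keep: list[str] | None = None,
) -> tuple[ExposurePanel, list[str]]:
    """Drop chemicals detected in fewer than ``min_rate`` of subjects.

    Chemicals named in ``keep`` (e.g. summed variables) are retained
    regardless of their detection frequency.  Returns the filtered panel and
    the list of dropped chemical names.
    """
    if not 0 < min_rate <= 1:
        raise ValueError(f"min_rate must be in (0, 1], got {min_rate}")
    keep = set(keep or [])
    frac = panel.detection_fraction()
    dropped = [c for c in panel.chemicals if frac[c] < min_rate and c not in keep]
    if len(dropped) == len(panel.chemicals):
        raise ValueError("detection filter would drop every chemical (empty mixture)")
    retained = [c for c in panel.chemicals if c not in dropped]
    out = ExposurePanel(
        values=panel.values[retained].copy(),
        nondetect=panel.nondetect[retained].copy(),
        classes={c: panel.classes[c] for c in retained},
        urinary=frozenset(c for c in panel.urinary if c in retained),
        creatinine=panel.creatinine,
    )
    return out, dropped


def quantile_score(panel: ExposurePanel, k: int = 10) -> QuantileMatrix:
    """Score each chemical into K empirical quantile bins (default deciles).

    Scores run 0..K-1 so a bottom-decile exposure contributes nothing to the
    weighted index.  Ties are handled by averaging ranks before binning;
    when heavy ties leave fewer than K distinct breakpoints the duplicated
    cuts are collapsed with a warning and the remaining bins keep labels
    within {0, ..., K-1}.
    """
    n = panel.n_subjects
    if k < 2:
        raise ValueError("quantile count K must be at least 2")
    if n < k:
        raise ValueError(f"need at least K={k} subjects to form {k} quantile bins, got {n}")
    scores = {}
    breakpoints = {}
    probs = np.arange(1, k) / k
    for chem in panel.chemicals:
        v = panel.values[chem].to_numpy(dtype=float)
        cuts = np.quantile(v, probs)
        distinct = np.unique(cuts)
        if len(distinct) < len(cuts):
            warnings.warn(
                f"chemical {chem!r}: ties collapse {len(cuts) - len(distinct)} "
                "quantile breakpoints; fewer than K distinct bins",
                stacklevel=2,
            )
        # average ranks first so tied concentrations always share a bin
        binned = pd.qcut(
            pd.Series(v).rank(method="average"), k, labels=False, duplicates="drop"
        )
        scores[chem] = binned.to_numpy()
        breakpoints[chem] = distinct
    return QuantileMatrix(
        scores=pd.DataFrame(scores, index=panel.subjects, dtype=int),
        k=k,
        breakpoints=breakpoints,
    )
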