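"""Delimited-text cohort I/O.

A cohort round-trips through four text artifacts: ``exposures.tsv``
(subject, creatinine, concentrations, nondetect flags), ``covariates.tsv``
(covariates plus child sex), ``outcome.tsv`` and ``meta.yaml`` (chemical
classes, urinary flags, and — for synthetic cohorts — the generating
truth).  Subject identifiers are aligned across files on read; subjects
with any missing field are dropped with a logged count (complete-case
rule).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COVARIATE_COLS, Cohort, TrueModel
from .preprocess import ExposurePanel

logger = logging.getLogger(__name__)

_ND_PREFIX = "nondetect_"


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as delimited text plus a YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cohort.exposures

    exp = panel.values.copy()
    for chem in panel.chemicals:
        exp[_ND_PREFIX + chem] = panel.nondetect[chem].astype(int)
    if panel.creatinine is not None:
        exp.insert(0, "creatinine", panel.creatinine)
    exp.index.name = "subject"

    cov = cohort.covariates.copy()
    cov["sex"] = cohort.sex
    cov.index = panel.subjects
    cov.index.name = "subject"

    out = pd.DataFrame({"IQ": cohort.outcome}, index=panel.subjects)
    out.index.name = "subject"

    meta: dict = {
        "chemicals": [
            {"name": c, "class": panel.classes[c], "urinary": c in panel.urinary}
            for c in panel.chemicals
        ]
    }
    if cohort.truth is not None:
        t = cohort.truth
        meta["truth"] = {
            "beta0": float(t.beta0), "beta1": float(t.beta1),
            "beta2": float(t.beta2), "beta12": float(t.beta12),
            "phi": {k: float(v) for k, v in t.phi.items()},
            "sigma": float(t.sigma),
            "true_weights": [float(w) for w in t.true_weights],
        }

    paths = {
        "exposures": outdir / "exposures.tsv",
        "covariates": outdir / "covariates.tsv",
        "outcome": outdir / "outcome.tsv",
        "meta": outdir / "meta.yaml",
    }
    exp.to_csv(paths["exposures"], sep="\t", float_format="%.10g")
    cov.to_csv(paths["covariates"], sep="\t", float_format="%.10g")
    out.to_csv(paths["outcome"], sep="\t", float_format="%.10g")
    paths["meta"].write_text(yaml.safe_dump(meta, sort_keys=False))
    return paths


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="subject")
    return df


def read_cohort(
    exposures: str | Path,
    covariates: str | Path,
    outcome: str | Path,
    meta: str | Path,
) -> Cohort:
    """Read and validate a cohort from its text artifacts.

    Raises on subject-identifier mismatch (listing orphans) and on
    non-numeric concentrations; subjects with any missing field are dropped
    with a logged count.
    """
    exp = _read_table(exposures)
    cov = _read_table(covariates)
    out = _read_table(outcome)
    meta_d = yaml.safe_load(Path(meta).read_text())

    sets = {"exposures": set(exp.index), "covariates": set(cov.index), "outcome": set(out.index)}
    common = sets["exposures"] & sets["covariates"] & sets["outcome"]
    orphans = {k: sorted(v - common) for k, v in sets.items() if v - common}
    if orphans:
        raise ValueError(f"subject identifiers do not align across tables; orphans: {orphans}")
    order = [s for s in exp.index if s in common]

    chems = [c["name"] for c in meta_d["chemicals"]]
    classes = {c["name"]: c["class"] for c in meta_d["chemicals"]}
    urinary = frozenset(c["name"] for c in meta_d["chemicals"] if c.get("urinary"))

    exp = exp.loc[order]
    cov = cov.loc[order]
    out = out.loc[order]

    values = exp[chems]
    non_numeric = values.apply(lambda s: pd.to_numeric(s, errors="coerce")).isna() & values.notna()
    if non_numeric.any().any():
        rows = values.index[non_numeric.any(axis=1)][:5].tolist()
        cols = values.columns[non_numeric.any(axis=0)].tolist()
        raise ValueError(f"non-numeric concentrations at subjects {rows}, chemicals {cols}")
    values = values.apply(pd.to_numeric)

    nd_cols = [_ND_PREFIX + c for c in chems]
    nondetect = (
        exp[nd_cols].astype(bool).rename(columns=dict(zip(nd_cols, chems)))
        if all(c in exp.columns for c in nd_cols)
        else pd.DataFrame(False, index=values.index, columns=chems)
    )
    creatinine = exp["creatinine"] if "creatinine" in exp.columns else None

    complete = (
        values.notna().all(axis=1)
        & cov[COVARIATE_COLS + ["sex"]].notna().all(axis=1)
        & out.iloc[:, 0].notna()
    )
    if creatinine is not None:
        complete &= creatinine.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d subjects with incomplete data", n_dropped)
    keep = complete[complete].index

    truth = None
    if "truth" in meta_d:
        t = meta_d["truth"]
        truth = TrueModel(
            beta0=t["beta0"], beta1=t["beta1"], beta2=t["beta2"], beta12=t["beta12"],
            phi=t["phi"], true_weights=np.asarray(t["true_weights"]), sigma=t["sigma"],
        )

    panel = ExposurePanel(
        values=values.loc[keep],
        nondetect=nondetect.loc[keep],
        classes=classes,
        urinary=urinary,
        creatinine=None if creatinine is None else creatinine.loc[keep],
    )
    return Cohort(
        exposures=panel,
        covariates=cov.loc[keep, COVARIATE_COLS],
        sex=cov.loc[keep, "sex"].to_numpy(dtype=int),
        outcome=out.loc[keep].iloc[:, 0].to_numpy(dtype=float),
        truth=truth,
    )
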