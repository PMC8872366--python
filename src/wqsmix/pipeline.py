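"""End-to-end orchestration: simulate/read -> preprocess -> holdout ->
g-computation -> scenarios -> report bundle.

Every stage writes its artifacts under the configured output directory
together with a manifest recording the settings and seeds that produced
them; a rerun with the same configuration reproduces the bundle byte for
byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .gcomp import counterfactual_shift, gcomp_marginal, scale_metric
from .holdout import run_repeated_holdout, summarize_ensemble
from .io import read_cohort, write_cohort
from .preprocess import QuantileMatrix, creatinine_adjust, detection_filter, quantile_score
from .scenarios import class_contributions, scenario_battery, target_value
from .synthetic import simulate_cohort
from .wqs import WeightSet, compute_index

logger = logging.getLogger(__name__)

#: summed variables exempt from the detection-frequency filter
SUMMED_VARIABLES = ("DEHP", "DINP", "DDT_DDE", "PCB_sum")


@dataclass
class RunConfig:
    """All pipeline settings; defaults reproduce the reference analysis
    (deciles, 40/60 split, 100 repeated holdouts, negative direction)."""

    # input: either paths to an existing cohort, or synthetic settings
    exposures: str | None = None
    covariates: str | None = None
    outcome: str | None = None
    meta: str | None = None
    n: int = 678
    seed: int = 0
    # preprocessing
    k_quantiles: int = 10
    min_detect: float = 0.75
    keep_chemicals: tuple[str, ...] = SUMMED_VARIABLES
    # WQS estimation
    direction: str = "negative"
    n_boot: int = 100
    n_repeats: int = 100
    split_fraction: float = 0.4
    ensemble_mode: str = "mean"
    n_restarts: int = 3
    # g-computation
    gcomp_n_boot: int = 200
    wqs_shift_sd: float = -1.0
    mni_shift_sd: float = 1.0
    # output
    outdir: str = "wqsmix_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "keep_chemicals" in data:
            data["keep_chemicals"] = tuple(data["keep_chemicals"])
        return cls(**data)


def load_or_simulate(config: RunConfig) -> tuple[Cohort, bool]:
    """Read the configured cohort files, or simulate when none are given."""
    paths = (config.exposures, config.covariates, config.outcome, config.meta)
    if any(paths):
        if not all(paths):
            raise ValueError(
                "either all of exposures/covariates/outcome/meta paths or none must be set"
            )
        return read_cohort(*paths), False
    cohort, _ = simulate_cohort(n=config.n, seed=config.seed, k=config.k_quantiles)
    return cohort, True


def preprocess_cohort(cohort: Cohort, config: RunConfig) -> tuple[QuantileMatrix, list[str]]:
    """Creatinine-adjust, detection-filter and decile-score the panel."""
    panel = creatinine_adjust(cohort.exposures)
    panel, dropped = detection_filter(panel, config.min_detect, keep=list(config.keep_chemicals))
    if dropped:
        logger.info("detection filter dropped: %s", dropped)
    return quantile_score(panel, k=config.k_quantiles), dropped


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle; returns artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        cohort, simulated = load_or_simulate(config)
        if simulated:
            artifacts.update(write_cohort(cohort, outdir / "cohort"))

        stage = "preprocess"
        quantiles, dropped = preprocess_cohort(cohort, config)
        qpath = outdir / "quantile_scores.tsv"
        quantiles.scores.to_csv(qpath, sep="\t")
        artifacts["quantile_scores"] = qpath

        stage = "holdout"
        ensemble = run_repeated_holdout(
            cohort,
            quantiles,
            n_repeats=config.n_repeats,
            n_boot=config.n_boot,
            fraction=config.split_fraction,
            direction=config.direction,
            seed=config.seed,
            ensemble_mode=config.ensemble_mode,
            n_restarts=config.n_restarts,
        )
        summary = summarize_ensemble(ensemble)
        ppath = outdir / "parameters.tsv"
        summary.parameters.to_csv(ppath, sep="\t", float_format="%.6g")
        wpath = outdir / "weights_summary.tsv"
        summary.weights.to_csv(wpath, sep="\t", index=False, float_format="%.6g")
        lpath = outdir / "weights_long.tsv"
        ensemble.weight_frame().to_csv(lpath, sep="\t", index=False, float_format="%.6g")
        artifacts.update(parameters=ppath, weights_summary=wpath, weights_long=lpath)

        stage = "gcomp"
        ref = ensemble.repeats[0].weights
        mean_w = np.mean([r.weights.flat for r in ensemble.repeats], axis=0)
        mean_w /= mean_w.sum()
        final_weights = WeightSet(
            mean_w.reshape(ref.weights.shape), chemicals=list(ref.chemicals), strata=ref.strata
        )
        index = compute_index(
            quantiles.scores[final_weights.chemicals], final_weights, cohort.sex
        )
        wqs_metric = scale_metric(index, name="WQSsc")
        gc_wqs = gcomp_marginal(
            wqs_metric, cohort.covariates, cohort.sex, cohort.outcome,
            levels=(0.0, config.wqs_shift_sd),
            n_boot=config.gcomp_n_boot, seed=config.seed,
        )
        mni_raw = scale_metric(cohort.covariates["MNI"].to_numpy(), name="MNI").raw()
        gc_mni = gcomp_marginal(
            mni_raw,
            cohort.covariates.drop(columns=["MNI"]), cohort.sex, cohort.outcome,
            levels=(
                mni_raw.center,
                counterfactual_shift(mni_raw.center, mni_raw.scale, config.mni_shift_sd),
            ),
            n_boot=config.gcomp_n_boot, seed=config.seed,
        )
        gpath = outdir / "gcomp.tsv"
        gframe = pd.concat(
            [gc_wqs.to_frame().assign(metric="WQSsc"), gc_mni.to_frame().assign(metric="MNI")],
            ignore_index=True,
        )
        gframe.to_csv(gpath, sep="\t", index=False, float_format="%.6g")
        artifacts["gcomp"] = gpath

        stage = "scenarios"
        decomp = class_contributions(
            quantiles.scores[final_weights.chemicals], final_weights, cohort.sex,
            cohort.exposures.classes,
        )
        target = target_value(decomp.index)
        results = scenario_battery(decomp, target)
        rows = [
            {
                "scenario": r.spec.name,
                "fraction_below_target": r.fraction_below,
                "target": r.target,
                **{f"retain_{cl}": v for cl, v in r.spec.retain.items()},
            }
            for r in results
        ]
        spath = outdir / "scenarios.tsv"
        pd.DataFrame(rows).to_csv(spath, sep="\t", index=False, float_format="%.6g")
        hists = []
        for r in results:
            counts, edges = r.histogram
            hists.append(
                pd.DataFrame(
                    {"scenario": r.spec.name, "bin_left": edges[:-1],
                     "bin_right": edges[1:], "count": counts}
                )
            )
        hpath = outdir / "scenario_histograms.tsv"
        pd.concat(hists, ignore_index=True).to_csv(
            hpath, sep="\t", index=False, float_format="%.6g"
        )
        artifacts.update(scenarios=spath, scenario_histograms=hpath)

        stage = "report"
        manifest = {
            "package_version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "n_subjects": int(cohort.n),
            "dropped_chemicals": dropped,
            "n_failed_repeats": ensemble.n_failed,
            "index_mean": float(index.mean()),
            "index_sd": float(index.std(ddof=1)),
            "target": float(target),
            "persistent_fraction_mean": float(decomp.persistent_fraction().mean()),
        }
        mpath = outdir / "manifest.yaml"
        mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
        artifacts["manifest"] = mpath
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; partial outputs in {outdir}"
        ) from exc
    return artifacts
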