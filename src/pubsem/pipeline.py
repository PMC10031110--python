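"""End-to-end pipeline: simulate -> preprocess -> fit series -> compare ->
brain sweep, with a reproducibility manifest.

Every output artifact directory contains ``manifest.json`` recording the
seed, a hash of the configuration, package version and stage record counts,
so a run can be reproduced from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .brain import brain_sweep, summarize_map
from .factory import ModelVariant, loading_table, run_model_series
from .io import (
    read_cohort,
    read_qc_ledger,
    read_thickness,
    write_cohort,
    write_thickness,
)
from .preprocess import apply_mri_qc, clean_hormones, score_composites
from .synthetic import GeneratorConfig, ITEM_COLUMNS, generate_cohort

log = logging.getLogger("pubsem")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    out_dir: str | Path = "pubsem_run"
    seed: int = 1
    simulate: bool = True
    generator: GeneratorConfig | None = None
    cohort_path: str | Path | None = None
    thickness_path: str | Path | None = None
    qc_path: str | Path | None = None
    winsorize_sd: float = 3.0
    winsorize_increment: float = 0.01
    variants: list[ModelVariant] = field(default_factory=lambda: [
        ModelVariant("one_factor", "full_multimethod"),
        ModelVariant("two_factor", "full_multimethod"),
    ])
    estimator: str | None = "ml"
    sweep_method_sets: tuple[str, ...] = ("multimethod",)
    sweep_factor_schemes: tuple[str, ...] = ("one_factor",)
    sweep_age_options: tuple[bool, ...] = (False,)
    run_sweep: bool = True


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dictionary.

    Any stage failure aborts with the stage name; partial outputs written
    before the failure are preserved in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "stages": {},
    }
    t0 = time.time()
    stage = "simulate/load"
    try:
        if config.simulate:
            gen = (config.generator or GeneratorConfig()).replace(
                seed=config.seed)
            cohort, thickness = generate_cohort(gen)
            write_cohort(cohort, out / "cohort.csv")
            write_thickness(thickness, out / "thickness.csv")
        else:
            cohort = read_cohort(config.cohort_path)
            thickness = read_thickness(config.thickness_path)
        manifest["stages"][stage] = {"records": len(cohort)}
        log.info("%s: %d participants", stage, len(cohort))

        stage = "qc"
        if config.qc_path is not None:
            ledger = read_qc_ledger(config.qc_path)
            keep, tally = apply_mri_qc(ledger)
            thickness = thickness[thickness["participant_id"].isin(keep)]
            manifest["stages"][stage] = tally
            manifest["analyzed_mri_participants"] = tally["retained"]
            log.info("qc: %s", tally)
        else:
            manifest["analyzed_mri_participants"] = len(thickness)

        stage = "preprocess"
        clean = clean_hormones(cohort, k_sd=config.winsorize_sd,
                               increment=config.winsorize_increment)
        composites = score_composites(clean[list(ITEM_COLUMNS)])
        pd.concat([clean[["participant_id"]], composites], axis=1).to_csv(
            out / "composites.csv", index=False)
        manifest["stages"][stage] = {
            "records": len(clean),
            "composite_means": composites.mean(numeric_only=True).round(3)
            .to_dict(),
        }
        log.info("preprocess: composites %s",
                 manifest["stages"][stage]["composite_means"])

        stage = "fit_series"
        table, fits = run_model_series(clean, config.variants,
                                       estimator=config.estimator)
        table.to_csv(out / "model_comparison.csv", index=False)
        for name, fit in fits.items():
            fit.parameter_table().to_csv(
                out / f"params_{name.replace('+', '_')}.tsv",
                sep="\t", index=False)
            loading_table(fit).to_csv(
                out / f"loadings_{name.replace('+', '_')}.tsv",
                sep="\t", index=False)
        manifest["stages"][stage] = {
            "models": list(fits),
            "convergence_failures": [k for k, f in fits.items()
                                     if not f.converged],
            "failures": table.attrs.get("failures", {}),
        }
        log.info("fit_series: %d models", len(fits))

        stage = "brain_sweep"
        if config.run_sweep:
            sweep = brain_sweep(
                clean, thickness,
                method_sets=config.sweep_method_sets,
                factor_schemes=config.sweep_factor_schemes,
                age_options=config.sweep_age_options,
            )
            sweep.to_csv(out / "brain_map.tsv", sep="\t", index=False)
            summary = summarize_map(sweep)
            summary.to_csv(out / "brain_map_summary.tsv", sep="\t",
                           index=False)
            manifest["stages"][stage] = {
                "rows": len(sweep),
                "non_converged": int((~sweep["converged"]).sum()),
            }
            log.info("brain_sweep: %d rows", len(sweep))
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
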