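"""End-to-end pipeline: configuration, logging and report generation.

``run_pipeline`` ties the stages together: load (or simulate) a dataset,
fit the per-series rate constants, fit both secondary models, validate the
integrated predictors at a held-out temperature, run the dummy-coded MLR,
and train/select the MLP comparator.  Each stage writes one artifact
(CSV or JSON, all numbers at >= 6 significant digits) into the output
directory; stage parameters are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ann as ann_mod
from .dataset_io import KELVIN_OFFSET, KineticDataset, read_tbars_table, to_percent
from .errors import ConfigurationError
from .mlr import fit_mlr_dummy, write_mlr_table
from .primary_kinetics import rate_table
from .secondary_models import secondary_table, write_secondary_table
from .shelf_life import ARRHENIUS, LOG_LOGISTIC, holdout_pipeline
from .synthetic import StorageDesign, published_like_truth, simulate_dataset

log = logging.getLogger("tbars_kinetics")

ALL_MODELS = ("arrhenius", "log_logistic", "ann", "mlr")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Either ``input_path`` (a tidy TBARS CSV) or ``simulate`` (use the
    study-design generator) must be set.  CLI flags override config-file
    keys of the same name.
    """

    input_path: str | None = None
    simulate: bool = False
    noise_sigma: float = 0.05
    replicates: int = 3
    kelvin_offset: float = KELVIN_OFFSET
    fix_intercept: bool = False
    holdout_temperature_c: float = 12.0
    models: tuple[str, ...] = ALL_MODELS
    seed: int = 0
    output_dir: str = "tbars_reports"
    ann_hidden_range: tuple[int, int] = (3, 10)
    ann_max_epochs: int = 200
    ann_n_keep: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "models" in data:
            data["models"] = tuple(data["models"])
        if "ann_hidden_range" in data:
            data["ann_hidden_range"] = tuple(data["ann_hidden_range"])
        return cls(**data)


def _load_dataset(config: PipelineConfig) -> KineticDataset:
    if config.simulate:
        truth = published_like_truth(
            noise_sigma=config.noise_sigma, replicates=config.replicates,
            seed=config.seed, kelvin_offset=config.kelvin_offset,
        )
        log.info("simulating dataset: sigma=%g replicates=%d seed=%d",
                 config.noise_sigma, config.replicates, config.seed)
        return simulate_dataset(truth, StorageDesign())
    if not config.input_path:
        raise ConfigurationError("config needs input_path or simulate: true")
    log.info("reading dataset from %s", config.input_path)
    return read_tbars_table(config.input_path)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every requested stage; returns {artifact name: path}.

    The holdout temperature is checked against the dataset before any
    fitting, so misconfiguration fails fast.
    """
    unknown = set(config.models) - set(ALL_MODELS)
    if unknown:
        raise ConfigurationError(f"unknown model(s): {sorted(unknown)}")
    dataset = _load_dataset(config)
    needs_holdout = {"arrhenius", "log_logistic"} & set(config.models)
    if needs_holdout and config.holdout_temperature_c not in dataset.temperatures_c:
        raise ConfigurationError(
            f"holdout temperature {config.holdout_temperature_c} degC absent "
            f"from dataset (has {dataset.temperatures_c})"
        )
    if dataset.records and dataset.scale != "percent":
        dataset = to_percent(dataset)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log.info("fitting per-series rate constants (fix_intercept=%s)",
             config.fix_intercept)
    rates = rate_table(dataset, fix_intercept=config.fix_intercept)
    artifacts["rate_table"] = rates.to_csv(outdir / "rate_table.csv")

    agg = rates.aggregated()
    log.info("fitting secondary models for %d treatments",
             agg["treatment"].nunique())
    artifacts["secondary_models"] = write_secondary_table(
        secondary_table(agg, kelvin_offset=config.kelvin_offset),
        outdir / "secondary_models.csv",
    )

    validation = {}
    for model in (ARRHENIUS, LOG_LOGISTIC):
        if model in config.models:
            log.info("external validation: model=%s holdout=%g degC",
                     model, config.holdout_temperature_c)
            report = holdout_pipeline(
                dataset, config.holdout_temperature_c, model,
                fix_intercept=config.fix_intercept,
                kelvin_offset=config.kelvin_offset,
            )
            validation[model] = report.to_dict()
    if validation:
        path = outdir / "validation.json"
        path.write_text(json.dumps(validation, indent=2, sort_keys=True))
        artifacts["validation"] = path

    if "mlr" in config.models:
        log.info("fitting dummy-coded MLR")
        artifacts["mlr_table"] = write_mlr_table(
            fit_mlr_dummy(dataset), outdir / "mlr_table.csv"
        )

    if "ann" in config.models:
        specs = ann_mod.default_spec_grid(
            max_epochs=config.ann_max_epochs, seed=config.seed,
            hidden_range=config.ann_hidden_range,
        )
        log.info("training %d candidate networks, keeping %d",
                 len(specs), config.ann_n_keep)
        enc = ann_mod.encode_features(dataset)
        fits = ann_mod.select_best_networks(
            specs, enc, n_keep=min(config.ann_n_keep, len(specs))
        )
        path = outdir / "ann_table.csv"
        ann_mod.fits_to_table(fits).to_csv(path, index=False, float_format="%.8g")
        artifacts["ann_table"] = path

    log.info("pipeline complete: %d artifact(s) in %s", len(artifacts), outdir)
    return artifacts
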