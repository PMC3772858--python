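"""Run orchestration: configuration, seed hierarchy, manifests, serialization.

All tables are plain delimited text with headers; every stochastic
output directory carries a JSON manifest recording the configuration
snapshot, the master seed and derived sub-seeds, timings and warnings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import analysis, calibration, hemorrhage, target_density
from .errors import ConfigurationError, DataError
from .physiology import ModelParameters, default_parameters, load_parameters

__all__ = ["RunConfig", "RunManifest", "calibrate_run", "hemorrhage_run", "analyze_run"]

# Stage indices of the seed hierarchy (SeedSequence spawn keys), so each
# stage can be re-run independently of the others.
STAGE_SENSITIVITY = 0
STAGE_TARGET = 1
STAGE_CHAINS = 2
STAGE_SPLITS = 3


def stage_seed(master_seed: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(stage,))


@dataclass
class RunConfig:
    """Settings for a full calibrate -> hemorrhage -> analyze run."""

    # target density
    target_file: str | None = None    # two-column CSV of (co, tpr); None -> surrogate
    surrogate_n: int = 1000
    # calibration
    restarts: int = 15
    n_burn: int = 20
    n_keep: int = 20
    sensitive: tuple = calibration.DEFAULT_SENSITIVE
    # hemorrhage protocol
    rate: float = 37.5
    duration: float = 20.0
    horizon: float = 40.0
    threshold: float = 15.0
    # analysis
    n_trials: int = 100
    test_size: int = 75
    mer_repeats: int = 37
    cost_threshold: float = 0.01
    beam: int = 50
    # output
    write_series: bool = False   # per-patient hemorrhage time series as CSVs
    # parameters
    parameter_file: str | None = None

    KNOWN = (
        "target_file", "surrogate_n", "restarts", "n_burn", "n_keep", "sensitive",
        "rate", "duration", "horizon", "threshold",
        "n_trials", "test_size", "mer_repeats", "cost_threshold", "beam",
        "write_series", "parameter_file",
    )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = sorted(set(raw) - set(cls.KNOWN))
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
        if "sensitive" in raw:
            raw["sensitive"] = tuple(raw["sensitive"])
        return cls(**raw)

    def parameters(self) -> ModelParameters:
        if self.parameter_file:
            return load_parameters(self.parameter_file)
        return default_parameters()

    def protocol(self) -> hemorrhage.HemorrhageProtocol:
        return hemorrhage.HemorrhageProtocol(
            rate=self.rate, duration=self.duration,
            horizon=self.horizon, threshold=self.threshold,
        )


@dataclass
class RunManifest:
    """Provenance record written next to every stochastic output file."""

    stage: str
    master_seed: int
    config: dict
    version: str = __version__
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def _target(config: RunConfig, master_seed: int):
    if config.target_file:
        samples = target_density.read_samples(config.target_file)
    else:
        samples = target_density.surrogate_sample(
            config.surrogate_n, stage_seed(master_seed, STAGE_TARGET)
        )
    return samples, target_density.fit_kde(samples)


def calibrate_run(config: RunConfig, master_seed: int, out_dir) -> pd.DataFrame:
    """Calibrate the virtual population; writes population.csv + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    params = config.parameters()
    samples, density = _target(config, master_seed)
    chain_cfg = calibration.ChainConfig(
        names=tuple(config.sensitive), n_burn=config.n_burn, n_keep=config.n_keep,
        restarts=config.restarts,
        seed=stage_seed(master_seed, STAGE_CHAINS).generate_state(1)[0] % (2**31),
    )
    result = calibration.build_population(density, params, chain_cfg, target_samples=samples)
    result.table.to_csv(out / "population.csv", index=False)
    target_density.write_samples(samples, out / "target_samples.csv")
    manifest = RunManifest(
        stage="calibrate", master_seed=master_seed,
        config={**asdict(config), "jump_sds": dict(zip(chain_cfg.names,
                                                       chain_cfg.resolved_sds(params))),
                "unmatched_table_sds": list(calibration.UNMATCHED_TABLE5_SDS)},
        timings={"seconds": time.perf_counter() - t0},
        warnings=result.warnings,
        diagnostics={
            "acceptance_rates": result.acceptance_rates,
            "ks_pvalues_chain_endpoints": result.ks_pvalues,
            "ks_pvalues_pooled": result.ks_pooled_pvalues,
        },
    )
    manifest.write(out / "calibrate_manifest.json")
    # keep the patient objects for the in-process pipeline
    calibrate_run.last_population = result
    return result.table


calibrate_run.last_population = None


def hemorrhage_run(config: RunConfig, master_seed: int, out_dir,
                   population: calibration.PopulationResult | None = None) -> pd.DataFrame:
    """Apply the protocol to every patient; writes the augmented table + summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if population is None:
        population = calibrate_run.last_population
    if population is None:
        raise DataError("no population available: run calibrate first")
    table = population.table
    required = {"co", "tpr", "map"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise DataError(f"population table is missing columns: {', '.join(missing)}")
    proto = config.protocol()
    frame, results, excluded = hemorrhage.run_protocol(
        population.patients, proto, keep_series=config.write_series
    )
    merged = table.merge(frame, on="patient", how="inner")
    merged.to_csv(out / "population_hemorrhage.csv", index=False)
    if config.write_series:
        series_dir = out / "series"
        series_dir.mkdir(exist_ok=True)
        for idx, res in results.items():
            res.series.to_csv(series_dir / f"patient_{idx:04d}.csv", index=False)
    comp_frac = float((merged["outcome"] == "compensator").mean())
    summary = {
        "n": int(len(merged)),
        "compensator_fraction": comp_frac,
        "blood_loss_mean": float(merged["blood_loss"].mean()),
        "blood_loss_sd": float(merged["blood_loss"].std(ddof=1)) if len(merged) > 1 else 0.0,
        "mcfp_mean": float(merged["mcfp"].mean()),
        "rap_mean": float(merged["rap"].mean()),
        "excluded": excluded,
    }
    with open(out / "hemorrhage_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = RunManifest(
        stage="hemorrhage", master_seed=master_seed, config=asdict(config),
        timings={"seconds": time.perf_counter() - t0},
        warnings=[f"patient {i} excluded: {r}" for i, r in excluded],
        diagnostics=summary,
    )
    manifest.write(out / "hemorrhage_manifest.json")
    hemorrhage_run.last_results = results
    return merged


hemorrhage_run.last_results = None


def analyze_run(config: RunConfig, master_seed: int, out_dir,
                table: pd.DataFrame | None = None) -> dict:
    """Correlations, SVM accuracy trials and the MER ensemble; writes reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if table is None:
        path = out / "population_hemorrhage.csv"
        if not path.exists():
            raise DataError("no hemorrhaged population found: run hemorrhage first")
        table = pd.read_csv(path)
    if "outcome" not in table.columns:
        raise DataError("population table lacks the outcome column")
    if table["outcome"].nunique() < 2:
        raise DataError("degenerate outcome: population contains a single class")

    split_seed = stage_seed(master_seed, STAGE_SPLITS).generate_state(2)
    corr = analysis.outcome_correlations(table)
    corr.to_csv(out / "correlations.csv", index=False)
    svm = analysis.svm_accuracy_trials(
        table, n_trials=config.n_trials, test_size=config.test_size,
        seed=int(split_seed[0] % (2**31)),
    )
    pd.DataFrame({"trial": np.arange(len(svm["accuracies"])),
                  "accuracy": svm["accuracies"]}).to_csv(out / "svm_trials.csv", index=False)
    mer = analysis.mer_ensemble(
        table, n_repeats=config.mer_repeats, cost_threshold=config.cost_threshold,
        seed=int(split_seed[1] % (2**31)), test_size=config.test_size, beam=config.beam,
    )
    mer["frequency"].to_csv(out / "mer_frequency.csv", index=False)
    with open(out / "mer_rubrics.json", "w") as fh:
        json.dump([r.as_dict() for r in mer["rubrics"]], fh, indent=2)
    report = {
        "svm_mean_accuracy": svm["mean"],
        "svm_ci95": list(svm["ci95"]),
        "mer_mean_accuracy": mer["mean_accuracy"],
        "mer_mean_size": mer["mean_size"],
        "blood_loss_pressure_corr": float(
            np.corrcoef(table["blood_loss"], table["delta_map"])[0, 1]
        ),
    }
    with open(out / "analysis_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = RunManifest(
        stage="analyze", master_seed=master_seed, config=asdict(config),
        timings={"seconds": time.perf_counter() - t0},
        diagnostics=report,
    )
    manifest.write(out / "analyze_manifest.json")
    return report
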