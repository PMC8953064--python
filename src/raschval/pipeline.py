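"""End-to-end orchestration of a scale-development run.

Stage order follows the standard scale-development narrative: calibrate ->
fit / assumption checks -> iterative item purification -> one person-misfit
round -> DIF screen -> strata / reliability -> validity.  Every stage's
output is written to the bundle directory as CSV/JSON, and a manifest
records the software version, seed and rule set so a bundle is reproducible
from its inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ResponseMatrix, read_item_specs_csv
from .diagnostics import FitReport, assess_assumptions, item_fit
from .dif import dif_results_frame, dif_screen
from .model import EstimationSettings, RaschCalibration, estimate_jmle, score_to_measure_table
from .purify import PurificationRules, person_misfit_round, purify_items
from .reliability import (
    item_separation_reliability,
    kr20,
    person_separation_reliability,
    wright_strata,
)
from .validity import convergent_correlation, criterion_logistic

log = logging.getLogger("raschval.pipeline")


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    responses_path: str
    output_dir: str
    covariates_path: str | None = None
    item_specs_path: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "calibrate": True,
            "purify": True,
            "person_round": True,
            "dif": True,
            "strata": True,
            "validity": True,
        }
    )
    outfit_mnsq_removal_floor: float = 1.5
    zstd_removal_floor: float = 2.0
    person_outfit_removal_floor: float = 2.0
    keep_items: list[str] = field(default_factory=list)
    convergence_tol: float = 1e-4
    max_iterations: int = 200
    seed: int = 0
    log_level: str = "INFO"
    dif_columns: dict = field(
        default_factory=lambda: {"gender": "gender", "age": "age", "ethnicity": "ethnicity"}
    )
    behavior_columns: list[str] = field(default_factory=list)
    convergent_column: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.responses_path).exists():
            raise ConfigError(f"responses file not found: {self.responses_path}")
        for p in (self.covariates_path, self.item_specs_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.outfit_mnsq_removal_floor <= 0 or self.zstd_removal_floor <= 0:
            raise ConfigError("rule floors must be positive")


def emit_item_table(
    calibration: RaschCalibration,
    fit: FitReport,
    composite: tuple[RaschCalibration, FitReport] | None = None,
) -> pd.DataFrame:
    """Item CSV in the conventional reporting layout.

    Columns: difficulty, se, outfit_mnsq, outfit_zstd, pmc — doubled with a
    ``composite_`` prefix when a composite calibration is supplied.
    """
    def _cols(cal: RaschCalibration, f: FitReport, prefix: str = "") -> pd.DataFrame:
        rows = {}
        for i, iid in enumerate(cal.item_ids):
            if iid in cal.excluded_items:
                continue
            rec = {
                f"{prefix}difficulty": float(cal.item_difficulty[i]),
                f"{prefix}se": float(cal.item_se[i]),
            }
            if iid in f.table.index:
                rec[f"{prefix}outfit_mnsq"] = float(f.table.loc[iid, "outfit_mnsq"])
                rec[f"{prefix}outfit_zstd"] = float(f.table.loc[iid, "outfit_zstd"])
                rec[f"{prefix}pmc"] = float(f.table.loc[iid, "pmc"])
            rows[iid] = rec
        out = pd.DataFrame(rows).T
        out.index.name = "item_id"
        return out

    table = _cols(calibration, fit)
    if composite is not None:
        table = table.join(_cols(*composite, prefix="composite_"), how="outer")
    return table


def run_pipeline(config: RunConfig, responses: ResponseMatrix | None = None,
                 covariates: pd.DataFrame | None = None) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the in-memory bundle; all reports are also serialized under
    ``config.output_dir``.  A stage failure raises :class:`StageError`
    carrying the stage name, after writing the partial bundle manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "load"
    try:
        if responses is None:
            specs = (
                read_item_specs_csv(config.item_specs_path)
                if config.item_specs_path
                else None
            )
            try:
                responses = ResponseMatrix.read_csv(config.responses_path, specs)
            except Exception as exc:
                raise DataError(f"cannot read responses: {exc}")
        if covariates is None and config.covariates_path:
            covariates = pd.read_csv(config.covariates_path, index_col=0)
            covariates.index = covariates.index.astype(str)

        settings = EstimationSettings(
            convergence_tol=config.convergence_tol, max_iterations=config.max_iterations
        )
        rules = PurificationRules(
            outfit_mnsq_removal_floor=config.outfit_mnsq_removal_floor,
            zstd_removal_floor=config.zstd_removal_floor,
            person_outfit_removal_floor=config.person_outfit_removal_floor,
        )

        stage = "purify"
        if config.stages.get("purify", True):
            trace = purify_items(responses, rules, settings, keep_items=config.keep_items)
            bundle["purification"] = trace
            working = trace.final_responses
            (outdir / "purification_trace.json").write_text(
                json.dumps(trace.to_dict(), indent=1, default=_json_default)
            )
        else:
            working = responses

        stage = "person_round"
        if config.stages.get("person_round", True):
            record, working, calibration = person_misfit_round(working, rules, settings)
            bundle["person_round"] = record
        else:
            stage = "calibrate"
            calibration = estimate_jmle(working, settings)
        bundle["calibration"] = calibration
        bundle["responses_final"] = working
        calibration.to_json(outdir / "calibration.json")

        stage = "diagnostics"
        fit = item_fit(calibration, working)
        bundle["item_fit"] = fit
        bundle["assumptions"] = assess_assumptions(calibration, working)
        table = emit_item_table(calibration, fit)
        table.to_csv(outdir / "item_table.csv")
        bundle["item_table"] = table

        stage = "dif"
        if config.stages.get("dif", True) and covariates is not None:
            screens = dif_screen(working, covariates, calibration, settings,
                                 groupings=config.dif_columns)
            bundle["dif"] = screens
            for name, results in screens.items():
                dif_results_frame(results).to_csv(outdir / f"dif_{name}.csv")

        stage = "strata"
        if config.stages.get("strata", True):
            score_table = score_to_measure_table(calibration)
            strata = wright_strata(score_table)
            bundle["score_table"] = score_table
            bundle["strata"] = strata
            score_table.to_csv(outdir / "score_table.csv", index=False)
            (outdir / "strata.json").write_text(
                json.dumps(strata.to_dict(), indent=1, default=_json_default)
            )
            bundle["reliability"] = {
                "item_separation": item_separation_reliability(calibration),
                "person_separation": person_separation_reliability(calibration),
                "kr20": kr20(working),
                "wright_sample_independent": strata.sample_independent_reliability,
            }
            (outdir / "reliability.json").write_text(
                json.dumps(bundle["reliability"], indent=1)
            )

        stage = "validity"
        if config.stages.get("validity", True) and covariates is not None:
            totals = pd.Series(
                working.person_totals().astype(float), index=working.person_ids
            )
            cov = covariates.reindex(totals.index)
            records = []
            if config.convergent_column and config.convergent_column in cov:
                r, p = convergent_correlation(totals, cov[config.convergent_column])
                records.append(
                    {"analysis": "convergent", "name": config.convergent_column,
                     "estimate": r, "p_value": p}
                )
            for col in config.behavior_columns:
                if col not in cov:
                    continue
                res = criterion_logistic(cov[col], totals, outcome_name=col)
                records.append(
                    {"analysis": "criterion", "name": col, "estimate": res.odds_ratio,
                     "ci_low": res.ci_low, "ci_high": res.ci_high, "auc": res.auc,
                     "cohens_d": res.cohens_d}
                )
            validity = pd.DataFrame(records)
            bundle["validity"] = validity
            validity.to_csv(outdir / "validity.csv", index=False)

        manifest = {
            "software": "raschval",
            "version": _version(),
            "seed": config.seed,
            "rules": {
                "outfit_mnsq_removal_floor": config.outfit_mnsq_removal_floor,
                "zstd_removal_floor": config.zstd_removal_floor,
                "person_outfit_removal_floor": config.person_outfit_removal_floor,
                "keep_items": config.keep_items,
            },
            "stages": config.stages,
            "n_persons_final": working.n_persons,
            "n_items_final": working.n_items,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        bundle["manifest"] = manifest
        return bundle
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise StageError(stage, exc)


def _version() -> str:
    from . import __version__

    return __version__


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
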