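"""End-to-end orchestration: config -> report bundle.

Stage order: load/generate -> merge duplicates -> vocabulary -> ARR +
trimming -> cross-database ORs + characteristics tests -> SDR detection ->
subgroup stratification -> per-term regression.  Outputs are six CSV files
plus a JSON run manifest; a stage failure aborts with the stage name and
removes partial outputs.  Runs are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .crossdb import cross_db_frame, cross_db_table, compare_characteristics
from .icsr import ICSRCollection, merge_duplicates, read_icsr_table
from .rates import arr_table, rates_frame, trim_rare
from .regression import aor_frame, fit_term
from .signals import signal_table, signals_frame
from .simulate import SimConfig, generate_database
from .subgroup import forest_frame, stratify, subgroup_frame, top_terms
from .vocab import AETermFrame, load_default_frame

logger = logging.getLogger(__name__)

SYNTHETIC = "synthetic"


class PipelineConfig(BaseModel):
    db1_path: str = SYNTHETIC
    db2_path: str = SYNTHETIC
    sim: Optional[SimConfig] = None
    term_frame_path: Optional[str] = None
    exclusions_path: Optional[str] = None
    min_trim: int = Field(default=3, ge=1)
    min_covid: int = Field(default=3, ge=0)
    min_comparator: int = Field(default=1, ge=0)
    top_k: int = Field(default=20, ge=1)
    scope: str = "any_position"
    years: tuple[int, ...] = (2021, 2022, 2023)
    output_dir: str = "oralpv_out"
    seed: int = 0

    @model_validator(mode="after")
    def _sources(self) -> "PipelineConfig":
        if (self.db1_path == SYNTHETIC or self.db2_path == SYNTHETIC) and self.sim is None:
            raise ValueError("synthetic input requires a sim config")
        return self


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_frame(cfg: PipelineConfig) -> AETermFrame:
    if cfg.term_frame_path is None:
        return load_default_frame()
    return AETermFrame.from_csv(cfg.term_frame_path, cfg.exclusions_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"version": __version__, "seed": cfg.seed, "config": cfg.model_dump(), "stages": {}}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    stage = "load"
    try:
        if cfg.db1_path == SYNTHETIC:
            db1 = generate_database(cfg.sim, "db1", cfg.seed)
        else:
            db1 = read_icsr_table(cfg.db1_path, "single_term")
        if cfg.db2_path == SYNTHETIC:
            db2 = generate_database(cfg.sim, "db2", cfg.seed)
        else:
            db2 = read_icsr_table(cfg.db2_path, "multi_term")
        manifest["stages"]["load"] = {"n_db1": db1.n_total, "n_db2": db2.n_total}

        stage = "merge_duplicates"
        db1 = merge_duplicates(db1)
        db2 = merge_duplicates(db2)
        manifest["stages"]["merge_duplicates"] = {
            "n_db1": db1.n_total,
            "n_db1_dropped": manifest["stages"]["load"]["n_db1"] - db1.n_total,
            "n_db2": db2.n_total,
            "n_db2_dropped": manifest["stages"]["load"]["n_db2"] - db2.n_total,
        }

        stage = "classify_terms"
        frame = _load_frame(cfg)
        manifest["stages"]["classify_terms"] = {"n_vocabulary_terms": len(frame)}

        stage = "reporting_rates"
        rows1 = arr_table(db1, frame, scope="any_position")
        kept1, trimmed = trim_rare(rows1, cfg.min_trim)
        kept_terms = [r.term for r in kept1]
        rows2 = arr_table(db2, frame, scope=cfg.scope)
        kept2 = [r for r in rows2 if r.term in set(kept_terms)]
        emit("arr_table.csv", rates_frame(kept1, kept2))
        manifest["stages"]["reporting_rates"] = {
            "n_terms_in": len(rows1),
            "n_kept": len(kept1),
            "n_trimmed": len(trimmed),
            "trimmed_terms": [r.term for r in trimmed],
        }

        stage = "cross_database"
        pairs = cross_db_table(kept1, kept2)
        emit("cross_database.csv", cross_db_frame(pairs))
        char_rows = []
        for variable in ("sex", "age_group", "vaccine_type", "schedule", "year"):
            t = compare_characteristics(db1, db2, variable)
            for cat, c1, c2 in zip(t.categories, t.counts_db1, t.counts_db2):
                char_rows.append(
                    {
                        "variable": variable,
                        "category": cat,
                        "n_db1": c1,
                        "n_db2": c2,
                        "statistic": t.statistic,
                        "df": t.df,
                        "p_value": t.p_value,
                        "method": t.method,
                    }
                )
        emit("characteristics.csv", pd.DataFrame(char_rows))
        manifest["stages"]["cross_database"] = {"n_terms": len(pairs)}

        stage = "disproportionality"
        metrics = signal_table(
            db2, frame, cfg.scope, cfg.min_covid, cfg.min_comparator, terms=kept_terms
        )
        emit("disproportionality.csv", signals_frame(metrics))
        manifest["stages"]["disproportionality"] = {
            "n_terms": len(metrics),
            "n_sdr": sum(m.sdr == "yes" for m in metrics),
            "n_disqualified": sum(m.sdr == "disqualified" for m in metrics),
        }

        stage = "subgroup_analysis"
        top = top_terms(kept1, cfg.top_k)
        tables = []
        for term in top:
            for variable in ("sex", "age3", "year", "vaccine_type", "schedule"):
                tables.append(
                    stratify(db1, term, variable, years=cfg.years, mc_seed=cfg.seed)
                )
        sub = subgroup_frame(tables).merge(
            forest_frame(tables), on=["term", "variable", "stratum", "arr"], how="left"
        )
        emit("subgroups.csv", sub)
        manifest["stages"]["subgroup_analysis"] = {"top_terms": top}

        stage = "regression"
        fits = [fit_term(db1, term) for term in top]
        emit("regression.csv", aor_frame(fits))
        manifest["stages"]["regression"] = {
            "n_fits": len(fits),
            "n_converged": sum(f.converged for f in fits),
        }
    except Exception as exc:  # noqa: BLE001 - abort contract: clean partial outputs
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    manifest["files"] = [p.name for p in written]
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    logger.info("pipeline complete: %d files in %s", len(written) + 1, out_dir)
    return manifest
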