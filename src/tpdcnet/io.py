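"""Plain-text interchange formats, run configuration and orchestration.

Time series travel as TSV (header row of channel labels) with a JSON sidecar
(sampling rate, labels, optional seed and provenance); cohort and EC tables
travel as CSV.  ``run_pipeline`` wires the stages — simulate, TPDC, table
assembly, model selection, statistics — into one reproducible run directory
with a manifest sufficient to re-run deterministic stages bit-identically.

The pipeline's contract starts at extracted ROI time series; imaging formats
(NIfTI, SNIRF) are an extension point, not implemented.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ROITimeSeries, TpdcError
from .mvar import EKFConfig
from .pdc import DEFAULT_BAND, ec_features, tpdc
from .selection import (
    CVConfig,
    SVMConfig,
    exhaustive_search,
    select_optimal,
    shapley_by_fold,
)
from .simulate import CohortSpec, fmri_like_spec, simulate_cohort, simulate_mvar
from .stats import battery_resting_ec

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: ROITimeSeries, path, seed: int | None = None) -> None:
    """Write a series as TSV (header = labels) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ts.labels) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "labels": ts.labels,
        "sampling_rate": ts.sampling_rate,
        "n_samples": int(ts.n_samples),
    }
    if seed is not None:
        meta["seed"] = int(seed)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_timeseries(path) -> ROITimeSeries:
    """Read a TSV + JSON-sidecar series; parse errors name line numbers."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TpdcError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    lines = path.read_text().splitlines()
    if not lines:
        raise TpdcError(f"{path}: empty file")
    labels = lines[0].split("\t")
    if labels != list(meta.get("labels", [])):
        raise TpdcError(f"{path}: header labels do not match sidecar labels")
    n_cols = len(labels)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise TpdcError(
                f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts])
        except ValueError as err:
            raise TpdcError(f"{path}:{lineno}: non-numeric cell ({err})") from err
    return ROITimeSeries(np.array(rows), labels, float(meta["sampling_rate"]))


def write_ectable(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_ectable(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("subject_id", "group", "session"):
        if col not in table.columns:
            raise TpdcError(f"{path}: missing required column {col!r}")
    feats = [
        c
        for c in table.columns
        if c not in ("subject_id", "group", "session", "response")
    ]
    if table[feats].isna().any().any():
        raise TpdcError(f"{path}: missing feature cells")
    return table


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run; unknown keys are rejected."""

    seed: int = 0
    n_subjects: int = 12
    n_samples: int = 266
    order: int = 1
    band: tuple[float, float] = DEFAULT_BAND
    weight_process_noise: float = 1e-4
    task: str = "regression"
    max_features: int = 2
    outer_k: int = 5
    inner_k: int = 5
    stages: tuple[str, ...] = ("simulate", "tpdc", "cohort", "select-model", "stats")
    group_effect: float = 0.15
    response_subset: tuple[str, ...] = ("CB->SC", "MC->SC")
    response_coeffs: tuple[float, ...] = (0.6, 0.4)
    response_noise_sd: float = 0.02

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise TpdcError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("band", "stages", "response_subset", "response_coeffs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yml", ".yaml")
            else json.loads(text)
        )
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the directory.

    Writes every intermediate artifact plus ``manifest.json`` (config echo,
    hash, seeds, stage timings, package version).  A stage failure halts the
    run with the failing stage named; partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "version": __version__,
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    try:
        cohort = None
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            series_dir = out / "series"
            series_dir.mkdir(exist_ok=True)
            for k in range(config.n_subjects):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                ts = simulate_mvar(
                    fmri_like_spec(n_samples=config.n_samples), seed=sub_seed
                )
                write_timeseries(ts, series_dir / f"sub{k + 1:02d}.tsv", seed=sub_seed)
            manifest["stages"]["simulate"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_subjects": config.n_subjects,
            }
        if "tpdc" in config.stages:
            t0 = time.perf_counter()
            rows = []
            cfg = EKFConfig(weight_process_noise=config.weight_process_noise)
            series_files = sorted((out / "series").glob("*.tsv"))
            if not series_files:
                raise TpdcError(f"no input series found under {out / 'series'}")
            for f in series_files:
                ts = read_timeseries(f)
                ec = tpdc(ts, order=config.order, band=config.band, config=cfg)
                ec.to_csv(out / f"{f.stem}_ec.csv")
                rows.append(
                    {"subject_id": f.stem, "group": "PD", "session": "baseline"}
                    | ec_features(ec).to_dict()
                )
            pd.DataFrame(rows).to_csv(out / "ec_table_tpdc.csv", index=False)
            manifest["stages"]["tpdc"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_series": len(rows),
            }
        if "cohort" in config.stages:
            t0 = time.perf_counter()
            spec = CohortSpec(
                n_per_group=max(config.n_subjects, 10),
                group_effects={"CB->SC": -config.group_effect,
                               "MC->SC": -config.group_effect},
                true_subset=config.response_subset,
                response_coeffs=config.response_coeffs,
                noise_sd=config.response_noise_sd,
                seed=config.seed,
            )
            cohort = simulate_cohort(spec)
            write_ectable(cohort, out / "cohort.csv")
            manifest["stages"]["cohort"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_rows": len(cohort),
            }
        if "select-model" in config.stages:
            t0 = time.perf_counter()
            if cohort is None:
                cohort = read_ectable(out / "cohort.csv")
            sub = (
                cohort.query("group == 'PD'")
                if config.task == "regression"
                else cohort.query("session == 'baseline'")
            )
            svm = SVMConfig(task=config.task)
            cv = CVConfig(outer_k=config.outer_k, inner_k=config.inner_k,
                          seed=config.seed)
            ranked = exhaustive_search(
                sub, svm, cv, max_features=config.max_features
            )
            best = select_optimal(ranked)
            shap_table = shapley_by_fold(sub, best.subset, svm, cv,
                                         seed=config.seed)
            result = {
                "subset": list(best.subset),
                "fold_scores": best.fold_scores.tolist(),
                "mean_score": best.mean_score,
                "score_se": best.score_se,
                "shapley_mean_abs": {
                    g: shap_table[g].round(6).to_dict() for g in shap_table.columns
                },
                "n_subsets_evaluated": len(ranked),
            }
            (out / "model_selection.json").write_text(json.dumps(result, indent=2))
            manifest["stages"]["select-model"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_subsets": len(ranked),
            }
        if "stats" in config.stages:
            t0 = time.perf_counter()
            if cohort is None:
                cohort = read_ectable(out / "cohort.csv")
            report = battery_resting_ec(cohort)
            report.table.to_csv(out / "stats_resting_ec.csv", index=False)
            manifest["stages"]["stats"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_tests": len(report.table),
            }
    except Exception as err:
        failed = next(
            (s for s in config.stages if s not in manifest["stages"]), "unknown"
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise TpdcError(f"stage {failed!r} failed: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline run complete: %s", out)
    return out
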