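"""Pipeline orchestration: configuration, stage functions, manifest.

The stages mirror the study workflow: simulate (or ingest) core images →
segment nests → compute the 8 mathematical parameters per core → aggregate
per patient and grade by survival-driven cutpoints → integrated scores and
tiles → survival statistics (KM/log-rank, chi-square, ROC, Cox) → report.

Every stage emits plain CSV/JSON so any stage can be inspected, replaced or
resumed from file; the manifest records the config snapshot, per-stage
output checksums, timings and every warning that changes an n (degenerate
cores, ROC exclusions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (FEATURE_COLUMNS, aggregate_patients, compute_core_features,
                       features_frame, measure_all_nests)
from .grading import (NEGATIVE_MPS, POSITIVE_MPS, TILE_LABELS, integrate,
                      search_cutpoints, tile_scores)
from .segmentation import (NestSegmentation, SegmentationParams, read_core_image,
                           segment_core, write_label_mask)
from .survival import chisq_association, cox_multivariate, km_logrank, roc_for_recurrence
from .synthetic import StudySpec, generate_core_image, write_core_image

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "DataError",
    "StatError",
    "stage_simulate",
    "stage_segment",
    "stage_features",
    "stage_grade",
    "stage_survival",
    "render_report",
    "run_all",
]

logger = logging.getLogger("nestmorph.pipeline")

ALL_MPS = tuple(FEATURE_COLUMNS)


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent input data (CLI exit code 3)."""


class StatError(RuntimeError):
    """Statistical degeneracy (CLI exit code 4)."""


@dataclass
class RunConfig:
    output_dir: str = "nestmorph_out"
    image_dir: str | None = None  # defaults to <output_dir>/images
    clinical_csv: str | None = None  # defaults to <output_dir>/clinical.csv
    study: StudySpec = field(default_factory=StudySpec)
    save_images: bool = True
    denoise_radius: int = 2
    opening_radius: int = 2
    min_size: int = 50
    min_frac: float = 0.10
    core_aggregation: str = "mean"
    horizon: float = 60.0
    covariates: tuple[str, ...] = (
        "t_stage", "n_status", "histological_grade", "hormone_receptor", "her2")
    seed: int = 0

    def validate(self) -> None:
        try:
            SegmentationParams(self.denoise_radius, self.opening_radius,
                               self.min_size).validate()
            self.study.validate()
        except ValueError as err:
            raise ConfigError(str(err)) from err
        if not 0.0 < self.min_frac < 1.0 / 3.0:
            raise ConfigError("min_frac must lie in (0, 1/3)")
        if self.core_aggregation not in ("mean", "max", "first"):
            raise ConfigError("core_aggregation must be mean, max or first")
        if self.horizon <= 0:
            raise ConfigError("horizon must be positive")

    # -- serialization (lossless round-trip) --------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "study" in d and isinstance(d["study"], dict):
            sd = dict(d["study"])
            if "size_range_px" in sd:
                sd["size_range_px"] = tuple(sd["size_range_px"])
            d["study"] = StudySpec(**sd)
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    @property
    def images_path(self) -> Path:
        return Path(self.image_dir) if self.image_dir else Path(self.output_dir) / "images"

    @property
    def clinical_path(self) -> Path:
        return (Path(self.clinical_csv) if self.clinical_csv
                else Path(self.output_dir) / "clinical.csv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[Path], seconds: float,
                  n_in: int | None = None, n_out: int | None = None) -> None:
        self.stages.append({
            "stage": name,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
            "n_in": n_in,
            "n_out": n_out,
        })
        logger.info("stage %s: %s records in, %s out (%.1fs)",
                    name, n_in, n_out, seconds)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)

    def write(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, manifest: RunManifest | None = None):
    """Generate the synthetic study bundle; optionally write images/masks.

    Returns ``(cores, clinical)`` where cores is a list of
    ``(core_id, patient_id, SyntheticImageSpec)``.
    """
    cfg.validate()
    t0 = time.perf_counter()
    from .synthetic import generate_study

    cores, clinical = generate_study(
        dataclasses.replace(cfg.study, seed=cfg.seed))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    if cfg.save_images:
        imdir = out / "images"
        maskdir = out / "truth_masks"
        imdir.mkdir(exist_ok=True)
        maskdir.mkdir(exist_ok=True)
        index_rows = []
        for core_id, pid, ispec in cores:
            image, truth = generate_core_image(ispec)
            write_core_image(imdir / f"{core_id}.png", image)
            write_label_mask(maskdir / f"{core_id}.png", truth.label_mask)
            index_rows.append({"core_id": core_id, "patient_id": pid,
                               "n_nests": truth.n_nests,
                               "spec_json": ispec.to_json()})
        index = pd.DataFrame(index_rows)
        index.to_csv(out / "core_index.csv", index=False)
        outputs.append(out / "core_index.csv")
    clin_path = out / "clinical.csv"
    clinical.to_csv(clin_path, index=False)
    outputs.append(clin_path)
    if manifest is not None:
        manifest.add_stage("simulate", outputs, time.perf_counter() - t0,
                           n_in=cfg.study.n_patients, n_out=len(cores))
    return cores, clinical


def _segment_one(image, params: SegmentationParams) -> NestSegmentation:
    return segment_core(image, params)


def stage_segment(cfg: RunConfig, cores=None, manifest: RunManifest | None = None,
                  write_masks: bool | None = None) -> dict[str, tuple[str, NestSegmentation]]:
    """Segment every core; from in-memory specs if given, else from image files.

    Returns ``{core_id: (patient_id, NestSegmentation)}``.
    """
    cfg.validate()
    t0 = time.perf_counter()
    params = SegmentationParams(cfg.denoise_radius, cfg.opening_radius, cfg.min_size)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_masks is None:
        write_masks = cfg.save_images
    segdir = out / "segmentation"
    if write_masks:
        segdir.mkdir(exist_ok=True)
    results: dict[str, tuple[str, NestSegmentation]] = {}
    outputs: list[Path] = []
    n_in = 0
    if cores is not None:
        for core_id, pid, ispec in cores:
            n_in += 1
            image, _ = generate_core_image(ispec)
            image.core_id, image.patient_id = core_id, pid
            results[core_id] = (pid, _segment_one(image, params))
    else:
        imdir = cfg.images_path
        paths = sorted(imdir.glob("*.png")) + sorted(imdir.glob("*.bmp")) \
            + sorted(imdir.glob("*.tif")) + sorted(imdir.glob("*.tiff"))
        if not paths:
            raise DataError(f"no images found under {imdir}")
        for p in paths:
            n_in += 1
            core_id = p.stem
            pid = core_id.split("_core")[0]
            image = read_core_image(p, core_id=core_id, patient_id=pid)
            results[core_id] = (pid, _segment_one(image, params))
    if write_masks:
        for core_id, (pid, seg) in results.items():
            write_label_mask(segdir / f"{core_id}.png", seg.label_mask)
            (segdir / f"{core_id}.params.json").write_text(seg.params_json())
    params_path = out / "segmentation_params.json"
    params_path.write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
    outputs.append(params_path)
    if manifest is not None:
        manifest.add_stage("segment", outputs, time.perf_counter() - t0,
                           n_in=n_in, n_out=len(results))
    return results


def stage_features(cfg: RunConfig, segmentations,
                   manifest: RunManifest | None = None) -> pd.DataFrame:
    """Per-core 8-parameter table; degenerate (zero-nest) cores are flagged."""
    t0 = time.perf_counter()
    feats, pids = [], []
    n_degenerate = 0
    for core_id, (pid, seg) in segmentations.items():
        shapes = measure_all_nests(seg)
        cf = compute_core_features(shapes, core_id=core_id)
        if cf.degenerate:
            n_degenerate += 1
        feats.append(cf)
        pids.append(pid)
    df = features_frame(feats, patient_ids=pids)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "features.csv"
    df.to_csv(path, index=False)
    if manifest is not None:
        if n_degenerate:
            manifest.warn(f"features: {n_degenerate} degenerate (zero-nest) "
                          "cores excluded from grading")
        manifest.add_stage("features", [path], time.perf_counter() - t0,
                           n_in=len(segmentations), n_out=len(df))
    return df


def stage_grade(cfg: RunConfig, features_df: pd.DataFrame,
                clinical_df: pd.DataFrame,
                manifest: RunManifest | None = None):
    """Aggregate cores per patient, grade all 8 parameters, build scores/tiles.

    Returns ``(graded DataFrame, cutpoints dict)``.
    """
    cfg.validate()
    t0 = time.perf_counter()
    per_patient = aggregate_patients(features_df, how=cfg.core_aggregation)
    clin_ids = set(clinical_df["patient_id"])
    feat_ids = set(per_patient["patient_id"])
    missing_clin = sorted(feat_ids - clin_ids)
    if missing_clin:
        raise DataError("clinical table is missing patient ids present in the "
                        f"image set: {', '.join(missing_clin[:10])}")
    dropped = sorted(clin_ids - feat_ids)
    merged = per_patient.merge(clinical_df, on="patient_id", how="inner")
    if manifest is not None and dropped:
        manifest.warn(f"grade: {len(dropped)} patients had no usable core "
                      f"features and were dropped: {', '.join(dropped[:10])}")

    times = merged["time"].to_numpy(float)
    events = merged["event"].to_numpy(int)
    cutpoints: dict[str, dict] = {}
    grades: dict[str, np.ndarray] = {}
    for mp in ALL_MPS:
        try:
            res = search_cutpoints(merged[mp].to_numpy(float), times, events,
                                   min_frac=cfg.min_frac, parameter_name=mp)
        except ValueError as err:
            raise StatError(f"cutpoint search failed for {mp!r}: {err}") from err
        cutpoints[mp] = res.to_dict()
        grades[mp] = res.grade_assignment
        merged[f"grade_{mp}"] = res.grade_assignment

    merged["score1"] = integrate(grades, NEGATIVE_MPS)
    merged["score2"] = integrate(grades, POSITIVE_MPS)
    for score_col in ("score1", "score2"):
        try:
            tiles, res = tile_scores(merged[score_col].to_numpy(), times, events,
                                     min_frac=cfg.min_frac,
                                     parameter_name=score_col)
        except ValueError as err:
            raise StatError(f"tiling failed for {score_col!r}: {err}") from err
        merged[f"tile_{score_col}"] = tiles
        merged[f"tile_{score_col}_label"] = [TILE_LABELS[t] for t in tiles]
        cutpoints[score_col] = res.to_dict()

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    graded_path = out / "graded.csv"
    merged.to_csv(graded_path, index=False)
    cuts_path = out / "cutpoints.json"
    cuts_path.write_text(json.dumps(cutpoints, indent=2, sort_keys=True))
    if manifest is not None:
        manifest.add_stage("grade", [graded_path, cuts_path],
                           time.perf_counter() - t0,
                           n_in=len(per_patient), n_out=len(merged))
    return merged, cutpoints


def stage_survival(cfg: RunConfig, graded: pd.DataFrame,
                   manifest: RunManifest | None = None) -> dict:
    """KM/log-rank per grading, ROC per marker, associations, Cox models."""
    cfg.validate()
    t0 = time.perf_counter()
    results: dict = {"horizon_months": cfg.horizon}
    times = graded["time"].to_numpy(float)
    events = graded["event"].to_numpy(int)

    km: dict = {}
    for col, kind in ([(f"grade_{mp}", "grade") for mp in ALL_MPS]
                      + [("tile_score1", "tile"), ("tile_score2", "tile")]):
        levels = sorted(graded[col].unique())
        groups = [graded.loc[graded[col] == lev, ["time", "event"]]
                  for lev in levels]
        curves, chisq, p = km_logrank(groups)
        km[col] = {
            "levels": [int(v) for v in levels],
            "chisq": chisq,
            "p": p,
            "five_year_survival": [c.at(cfg.horizon) for c in curves],
            "n_per_level": [int(len(g)) for g in groups],
        }
    results["km_logrank"] = km

    roc: dict = {}
    for name in list(ALL_MPS) + ["score1", "score2"]:
        try:
            r = roc_for_recurrence(graded[name].to_numpy(float), times, events,
                                   horizon=cfg.horizon)
        except ValueError as err:
            raise StatError(f"ROC failed for {name!r}: {err}") from err
        roc[name] = r.to_dict()
        if manifest is not None and r.n_excluded:
            manifest.warn(f"roc[{name}]: excluded {r.n_excluded} patients "
                          "censored before the horizon")
    results["roc"] = roc

    assoc: dict = {}
    for mp in NEGATIVE_MPS:
        chi2, p = chisq_association(graded[f"grade_{mp}"], graded["tile_score1"])
        assoc[f"grade_{mp}~tile_score1"] = {"chisq": chi2, "p": p}
    for mp in POSITIVE_MPS:
        chi2, p = chisq_association(graded[f"grade_{mp}"], graded["tile_score2"])
        assoc[f"grade_{mp}~tile_score2"] = {"chisq": chi2, "p": p}
    results["chisq_association"] = assoc

    cox_covs = ["tile_score1", "tile_score2"] + [c for c in cfg.covariates
                                                 if c in graded.columns]
    try:
        cox = cox_multivariate(graded, cox_covs)
    except (ValueError, RuntimeError) as err:
        raise StatError(f"Cox fit failed: {err}") from err
    results["cox"] = cox.to_dict()

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "results.json"
    path.write_text(json.dumps(results, indent=2, sort_keys=True))
    if manifest is not None:
        manifest.add_stage("survival", [path], time.perf_counter() - t0,
                           n_in=len(graded), n_out=len(results["roc"]))
    return results


def render_report(results: dict) -> str:
    """Human-readable markdown report of the survival results."""
    if not results:
        raise DataError("empty results: nothing to report")
    lines = ["# Tumor-nest morphometry report", ""]
    lines.append(f"Endpoint horizon: {results['horizon_months']} months.")
    lines.append("")
    lines.append("## Kaplan-Meier / log-rank")
    lines.append("")
    lines.append("| grading | levels | n per level | chi-square | p | "
                 "5-year survival per level |")
    lines.append("|---|---|---|---|---|---|")
    for name, d in sorted(results["km_logrank"].items()):
        surv = ", ".join(f"{s:.3f}" for s in d["five_year_survival"])
        npl = ", ".join(str(v) for v in d["n_per_level"])
        lines.append(f"| {name} | {d['levels']} | {npl} | {d['chisq']:.3f} | "
                     f"{d['p']:.4g} | {surv} |")
    lines.append("")
    lines.append("## ROC for recurrence by the horizon")
    lines.append("")
    lines.append("| marker | AUC | 95% CI | p vs 0.5 | n+/n- | excluded |")
    lines.append("|---|---|---|---|---|---|")
    for name, d in sorted(results["roc"].items()):
        lines.append(f"| {name} | {d['auc']:.3f} | "
                     f"[{d['ci95'][0]:.3f}, {d['ci95'][1]:.3f}] | "
                     f"{d['p_value']:.4g} | {d['n_pos']}/{d['n_neg']} | "
                     f"{d['n_excluded']} |")
    lines.append("")
    lines.append("## Pearson chi-square associations")
    lines.append("")
    for name, d in sorted(results["chisq_association"].items()):
        lines.append(f"- {name}: chi2 = {d['chisq']:.3f}, p = {d['p']:.4g}")
    lines.append("")
    lines.append("## Multivariate Cox model")
    lines.append("")
    cox = results["cox"]
    lines.append(f"n = {cox['n']}, events = {cox['n_events']}, "
                 f"log-likelihood = {cox['log_likelihood']:.3f}")
    lines.append("")
    lines.append("| covariate | HR | 95% CI | p |")
    lines.append("|---|---|---|---|")
    for name, d in cox["covariates"].items():
        lines.append(f"| {name} | {d['hr']:.3f} | "
                     f"[{d['ci_low']:.3f}, {d['ci_high']:.3f}] | {d['p']:.4g} |")
    lines.append("")
    return "\n".join(lines)


def run_all(cfg: RunConfig) -> tuple[dict, RunManifest]:
    """Run simulate → segment → features → grade → survival → report."""
    cfg.validate()
    manifest = RunManifest(config=cfg.to_dict())
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.json")
    cores, clinical = stage_simulate(cfg, manifest)
    segs = stage_segment(cfg, cores=cores, manifest=manifest)
    feats = stage_features(cfg, segs, manifest)
    graded, _ = stage_grade(cfg, feats, clinical, manifest)
    results = stage_survival(cfg, graded, manifest)
    report = render_report(results)
    (out / "report.md").write_text(report)
    manifest.write(out / "manifest.json")
    return results, manifest
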