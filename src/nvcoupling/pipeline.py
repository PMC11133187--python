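"""Subject- and study-level orchestration.

A study is either simulated (a `simulation` block in the config) or read
from files (a `paths` block: per-subject BOLD images plus a shared venous
mask, atlas, and subject table). Every subject run persists its maps and
region table; study-level statistics can be recomputed from the persisted
tables alone.
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
import yaml

from . import __version__
from .errors import DataError, GeometryError
from .icc import IccResult, compute_icc_fast
from .imaging import (BinaryMask, BoldImage, LabelAtlas, extract_reference,
                      load_atlas, load_bold, load_mask, preprocess, save_bold,
                      save_volume)
from .regions import (REGION_COLUMNS, ConjunctionMasks, build_region_table,
                      conjunction_masks, icc_percentile_thresholds)
from .stats import (METRIC_FAMILIES, add_fdr, group_ttest, partial_pearson,
                    pearson_with_behavior, summarize_cohort)
from .synth import BehaviorSpec, SimulationConfig, Subject, simulate_cohort
from .tsa import LagResult, compute_lag_map

logger = logging.getLogger("nvcoupling")

__all__ = ["StudyConfig", "analyze_subject", "run_subject", "run_study",
           "run_stats", "write_table"]


@dataclass
class StudyConfig:
    out_dir: str = "out"
    band: tuple[float, float] = (0.01, 0.08)
    max_lag: int = 3
    lag_threshold_inclusive: bool = False
    equal_var: bool = False
    uncorrected_threshold: float = 0.001
    fdr_threshold: float = 0.01
    families: dict = field(default_factory=lambda: dict(METRIC_FAMILIES))
    correlations: list = field(default_factory=list)  # (metric, score) pairs
    covariate: str = "age"
    cutoffs: dict = field(default_factory=dict)
    seed: int = 0
    simulation: SimulationConfig | None = None
    paths: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.uncorrected_threshold < 1):
            raise ValueError("uncorrected_threshold must lie in (0, 1)")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        self.band = (float(self.band[0]), float(self.band[1]))
        self.correlations = [tuple(c) for c in self.correlations]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            spec = [BehaviorSpec(**b) if isinstance(b, dict) else BehaviorSpec(*b)
                    for b in sim.pop("behavior_spec", [])]
            sim = SimulationConfig(behavior_spec=spec, **sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        payload = enc(self)
        payload.pop("out_dir", None)  # hash covers analysis settings only
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_subject(
    bold: BoldImage,
    venous_mask: BinaryMask,
    atlas: LabelAtlas,
    band: tuple[float, float] = (0.01, 0.08),
    max_lag: int = 3,
    lag_threshold_inclusive: bool = False,
) -> tuple[LagResult, IccResult, ConjunctionMasks, pd.DataFrame]:
    """Full per-subject chain: preprocess, venous reference, lag map, ICC,
    conjunction masks, region table."""
    pre = preprocess(bold, band)
    reference = extract_reference(pre, venous_mask)
    lag = compute_lag_map(pre, reference, atlas.analysis_mask, max_lag=max_lag)
    icc = compute_icc_fast(pre, atlas.analysis_mask)
    p25, p75 = icc_percentile_thresholds(icc)
    masks = conjunction_masks(lag, icc, p25, p75)
    table = build_region_table(lag, icc, atlas, lag_threshold_inclusive)
    return lag, icc, masks, table


def write_table(df: pd.DataFrame, path, config: StudyConfig | None = None) -> None:
    """TSV with a provenance header (config hash, seed, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# nvcoupling {__version__} config={config.config_hash()} "
                     f"seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")


def run_subject(
    config: StudyConfig,
    subject_id: str,
    bold: BoldImage,
    venous_mask: BinaryMask,
    atlas: LabelAtlas,
) -> pd.DataFrame:
    """Analyze one subject and persist maps + region table under
    <out>/<subject>/. Returns the region table (with subject_id column)."""
    t0 = time.perf_counter()
    lag, icc, masks, table = analyze_subject(
        bold, venous_mask, atlas, config.band, config.max_lag,
        config.lag_threshold_inclusive)
    sub_dir = Path(config.out_dir) / subject_id
    maps_dir = sub_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    save_volume(lag.lag_map, bold.affine, maps_dir / "lag_tr.nii.gz")
    save_volume(lag.lag_seconds, bold.affine, maps_dir / "lag_seconds.nii.gz")
    save_volume(lag.peak_corr, bold.affine, maps_dir / "peak_corr.nii.gz")
    save_volume(icc.icc_map, bold.affine, maps_dir / "icc.nii.gz")
    save_volume(masks.labelled(), bold.affine, maps_dir / "conjunction.nii.gz")
    table = table.copy()
    table.insert(0, "subject_id", subject_id)
    write_table(table, sub_dir / "regions.tsv", config)
    manifest = {"subject_id": subject_id, "config": config.config_hash(),
                "version": __version__,
                "elapsed_s": round(time.perf_counter() - t0, 3)}
    (sub_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("subject %s done in %.2fs", subject_id, manifest["elapsed_s"])
    return table


def _load_file_study(config: StudyConfig):
    paths = config.paths
    records = read_table(paths["subject_table"])
    subjects = []
    for sid in records["subject_id"]:
        bold = load_bold(paths["bold_pattern"].format(subject_id=sid))
        mask = load_mask(paths["venous_mask"], bold)
        atlas = load_atlas(paths["atlas"], bold)
        subjects.append((sid, bold, mask, atlas))
    return subjects, records


def run_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run all subjects then the statistics layer; persist everything under
    the configured output directory. Subjects that fail are skipped and
    listed in a skip report; the study aborts only if a group drops below
    two analyzable subjects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort, records = simulate_cohort(sim)
        subjects = [(s.subject_id, s.bold, s.venous_mask, s.atlas) for s in cohort]
    elif config.paths is not None:
        subjects, records = _load_file_study(config)
    else:
        raise ValueError("config needs either a 'simulation' or a 'paths' block")

    tables, skipped = [], []
    for sid, bold, mask, atlas in subjects:
        try:
            tables.append(run_subject(config, sid, bold, mask, atlas))
        except (GeometryError, DataError, ValueError) as exc:
            logger.error("subject %s failed: %s", sid, exc)
            skipped.append({"subject_id": sid, "error": str(exc)})
    if skipped:
        write_table(pd.DataFrame(skipped), out / "study" / "skipped.tsv", config)
    region_tables = pd.concat(tables, ignore_index=True)
    kept = records[records["subject_id"].isin(region_tables["subject_id"])]
    for grp in ("patient", "control"):
        if (kept["group"] == grp).sum() < 2:
            raise DataError(f"fewer than 2 analyzable subjects in group {grp!r}")

    results = run_stats(config, region_tables, records)
    study_dir = out / "study"
    write_table(region_tables, study_dir / "regions_all.tsv", config)
    write_table(records, study_dir / "subjects.tsv", config)
    for name, df in results.items():
        write_table(df, study_dir / f"{name}.tsv", config)
    results["regions_all"] = region_tables
    results["subjects"] = records
    return results


def run_stats(config: StudyConfig, region_tables: pd.DataFrame,
              records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Statistics layer only: group tests per metric family (FDR within
    family), configured brain-behavior correlations (zero-order + partial),
    and cohort descriptives."""
    results: dict[str, pd.DataFrame] = {}
    for family, metrics in config.families.items():
        frames = [group_ttest(region_tables, records, m, config.equal_var)
                  for m in metrics if m in region_tables.columns]
        if not frames:
            continue
        fam = pd.concat(frames, ignore_index=True)
        results[f"ttest_{family}"] = add_fdr(
            fam, config.uncorrected_threshold, config.fdr_threshold)
    corr_frames, partial_frames = [], []
    for metric, score in config.correlations:
        corr_frames.append(pearson_with_behavior(
            region_tables, records, metric, score, group="patient"))
        partial_frames.append(partial_pearson(
            region_tables, records, metric, score, covariate=config.covariate,
            group="patient"))
    if corr_frames:
        results["correlations"] = add_fdr(
            pd.concat(corr_frames, ignore_index=True),
            config.uncorrected_threshold, config.fdr_threshold)
        results["partial_correlations"] = add_fdr(
            pd.concat(partial_frames, ignore_index=True),
            config.uncorrected_threshold, config.fdr_threshold)
    results["cohort"] = summarize_cohort(records, config.cutoffs or None,
                                         group="patient")
    return results
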