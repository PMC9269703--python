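"""End-to-end pipeline orchestration and run configuration.

``run_pipeline`` executes the whole analysis — trim, derived channels,
SampEn/complexity factors, cycle segmentation, feature tables, group
statistics, classifier benchmark and sequential feature ranking — on either
a directory of recording files or a named synthetic preset, and writes all
tabular reports as delimited text plus a reproducibility manifest (config,
seeds, package versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .entropy import SampEnParams, complexity_factors, sample_entropy
from .features import build_feature_table, cycle_feature_table
from .imu_io import Group, Recording, read_layout, read_recording, trim_warmup
from .ml import EvalProtocol, default_specs, evaluate_classifiers, reduced_specs, sfs_rank
from .segmentation import SegmentationParams, segment_recording
from .stats import compare_groups, difference_metrics
from .synth import clbp_params, generate_cohort, nlbp_params

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_cohort"]

log = logging.getLogger("bendreturn")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the published protocol: a 10-70 s analysis window,
    SampEn with m=2 / r=0.2 SD, a 25-sample smoothing window with a 40%
    threshold and 450-point cycles, and 100 training repetitions of 5-fold
    cross-validation.
    """

    data_dir: str | None = None        # directory of recordings + labels.csv
    synth_preset: str | None = "paper-like"  # "paper-like" | "null"
    n_per_group: int = 20
    synth_duration: float = 70.0       # per-subject recording length, s
    t0: float = 10.0
    t1: float = 70.0
    sampen: SampEnParams = field(default_factory=SampEnParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    feature_set: str = "raw"
    mode: str = "whole"                # "whole" | "cycle"
    protocol: EvalProtocol = field(default_factory=EvalProtocol)
    sfs_directions: tuple[str, ...] = ("forward",)
    out_dir: str = "bendreturn_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.data_dir is None and self.synth_preset is None:
            raise ValueError("either data_dir or synth_preset must be given")
        if self.synth_preset not in (None, "paper-like", "null"):
            raise ValueError(f"unknown synth preset {self.synth_preset!r}")
        if self.mode not in ("whole", "cycle"):
            raise ValueError(f"mode must be 'whole' or 'cycle', got {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sampen" in raw:
            raw["sampen"] = SampEnParams(**raw["sampen"])
        if "segmentation" in raw:
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "protocol" in raw:
            raw["protocol"] = EvalProtocol(**raw["protocol"])
        if "sfs_directions" in raw:
            raw["sfs_directions"] = tuple(raw["sfs_directions"])
        return RunConfig(**raw)


def load_cohort(data_dir: str | Path, layout_path: str | Path | None = None
                ) -> list[Recording]:
    """Read every recording in *data_dir* using its ``labels.csv``.

    ``labels.csv`` has columns ``file,subject_id,group``; the optional
    layout file maps non-canonical column headers.
    """
    data_dir = Path(data_dir)
    labels_file = data_dir / "labels.csv"
    if not labels_file.exists():
        raise PipelineError(f"stage load: {labels_file} not found")
    layout = read_layout(layout_path) if layout_path else None
    labels = pd.read_csv(labels_file)
    recs = []
    for row in labels.itertuples():
        recs.append(
            read_recording(
                data_dir / row.file, layout,
                subject_id=str(row.subject_id), group=Group(row.group),
            )
        )
    return recs


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named rewrap
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a mapping of report names to file paths.  Any stage failure
    aborts with a :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- load or synthesise -------------------------------------------------
    @_stage("load")
    def _load() -> list[Recording]:
        if config.data_dir is not None:
            return load_cohort(config.data_dir)
        healthy = nlbp_params(duration=config.synth_duration)
        patient = healthy if config.synth_preset == "null" \
            else clbp_params(duration=config.synth_duration)
        recs, _ = generate_cohort(
            healthy, patient, n_per_group=config.n_per_group, seed=config.seed
        )
        return recs

    recs = _load()

    @_stage("trim")
    def _trim() -> list[Recording]:
        return [trim_warmup(r, config.t0, config.t1) for r in recs]

    recs = _trim()

    # --- SampEn / CF group statistics --------------------------------------
    @_stage("sampen")
    def _sampen() -> pd.DataFrame:
        rows = []
        for rec in recs:
            row: dict[str, object] = {"subject": rec.subject_id,
                                      "group": rec.group.value}
            for sid, name, series in rec.iter_channels():
                res = sample_entropy(series, config.sampen)
                row[f"{name} {sid.value}"] = res.value if res.defined else np.nan
            cf = complexity_factors(rec, config.sampen)
            row["LCF"] = cf.lcf.value if cf.lcf.defined else np.nan
            row["HCF"] = cf.hcf.value if cf.hcf.defined else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    sampen_df = _sampen()
    written["sampen"] = out / "sampen.csv"
    sampen_df.to_csv(written["sampen"], index=False)

    @_stage("stats")
    def _stats() -> pd.DataFrame:
        rows = []
        value_cols = [c for c in sampen_df.columns if c not in ("subject", "group")]
        for col in value_cols:
            a = sampen_df.loc[sampen_df.group == "NLBP", col].to_numpy()
            b = sampen_df.loc[sampen_df.group == "CLBP", col].to_numpy()
            cmp = compare_groups(a, b)
            diff = a.mean() - b.mean()
            sd_diff = float(np.std(
                a[: min(len(a), len(b))] - b[: min(len(a), len(b))], ddof=1
            )) if len(a) == len(b) else float("nan")
            row = {
                "parameter": col, "test": cmp.test, "p_value": cmp.p_value,
                "mean_diff_NLBP_minus_CLBP": diff,
            }
            if len(a) == len(b):
                dm = difference_metrics(sd_diff, len(a)).rounded()
                row.update({"SD_diff": round(sd_diff, 3), "SEM": dm.sem,
                            "CI": dm.ci, "MDC": dm.mdc})
            rows.append(row)
        return pd.DataFrame(rows)

    stats_df = _stats()
    written["group_stats"] = out / "group_stats.csv"
    stats_df.to_csv(written["group_stats"], index=False)

    # --- segmentation + cycle dataset ---------------------------------------
    @_stage("segment")
    def _segment():
        sets = [segment_recording(r, config.segmentation) for r in recs]
        tidy = [
            {"subject": cs.subject_id, "group": cs.group, "n_cycles": cs.n_cycles}
            for cs in sets
        ]
        return sets, pd.DataFrame(tidy)

    cycle_sets, cycle_summary = _segment()
    written["cycles"] = out / "cycle_counts.csv"
    cycle_summary.to_csv(written["cycles"], index=False)

    # --- features ------------------------------------------------------------
    @_stage("features")
    def _features():
        if config.mode == "cycle":
            return cycle_feature_table(cycle_sets)
        return build_feature_table(
            recs, feature_set=config.feature_set, sampen_params=config.sampen
        )

    table = _features()
    written["features"] = out / "features.csv"
    table.to_csv(written["features"])

    # --- benchmark -----------------------------------------------------------
    @_stage("benchmark")
    def _benchmark():
        return evaluate_classifiers(
            table, config.protocol, default_specs(),
            feature_set=config.feature_set,
        )

    bench = _benchmark()
    written["benchmark"] = out / "benchmark.csv"
    bench.report().to_csv(written["benchmark"])

    # --- SFS -----------------------------------------------------------------
    for direction in config.sfs_directions:
        @_stage(f"sfs-{direction}")
        def _sfs(direction=direction):
            return sfs_rank(table, reduced_specs(), config.protocol, direction)

        ranking = _sfs()
        written[f"sfs_{direction}"] = out / f"sfs_{direction}.csv"
        ranking.report().to_csv(written[f"sfs_{direction}"], index=False)

    # --- manifest ------------------------------------------------------------
    manifest = {
        "package": "bendreturn",
        "version": __version__,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "n_recordings": len(recs),
        "outputs": {k: str(v) for k, v in written.items()},
    }
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=1))
    return written
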