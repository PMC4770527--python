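"""End-to-end orchestration: normalize -> select sites -> cluster -> classify
-> extract patterns -> summarize, from a single YAML-able configuration.

The discovery/validation split is modeled as two cohort inputs: epitypes are
discovered by bootstrap consensus clustering on the discovery cohort and a
second cohort, when given, is classified against the discovery centroids.
Every run writes its resolved configuration next to the outputs, and reruns
with the same configuration and seed reproduce all outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import BetaMatrix, compute_beta_and_mask, peak_normalize, hypermethylation_score, qc_report
from .site_selection import call_normal_status, select_tumor_specific
from .epityping import bootstrap_consensus, choose_k, build_centroids, classify_by_centroid, relabel
from .patterns import extract_epitype_patterns, DEFAULT_ROLES
from .synthetic import read_beta_tsv

log = logging.getLogger("epityper")


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters.

    Threshold defaults are the published analysis values: detection p 0.05
    and 3 beads for masking; beta 0.7/0.3 with 2 missing values allowed for
    the normal-status calls; a 5% switch fraction for tumor-specific sites;
    2000 bootstrap iterations over k = 3..10 with a 5-sample minimum cluster
    size; 0.5/0.1/0.7 pattern cutoffs.
    """

    # inputs (TSV paths); tumor/normal/validation beta may be raw or normalized
    tumor_beta: str | None = None
    normal_beta: str | None = None
    validation_beta: str | None = None
    annotation: str | None = None
    output_dir: str = "epityper_run"

    # preprocessing
    already_normalized: bool = False
    p_max: float = 0.05
    min_beads: int = 3
    kde_bandwidth: float = 0.04
    kde_grid_size: int = 1001

    # site selection
    meth_min: float = 0.7
    unmeth_max: float = 0.3
    max_missing_normals: int = 2
    min_switch_fraction: float = 0.05

    # clustering
    n_boot: int = 2000
    k_min: int = 3
    k_max: int = 10
    min_cluster_size: int = 5
    stability_threshold: float = 0.6
    min_overlap: int = 100

    # pattern roles (labels under the normal-similarity ordering convention)
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_beta(path, stage: str) -> pd.DataFrame:
    if path is None:
        raise PipelineError(stage, "no input path configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"input not found: {p}")
    return read_beta_tsv(p)


def report_schema() -> dict:
    with resources.files("epityper").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Minimal structural validation of a run report against the shipped schema.

    Checks required keys and primitive types (a deliberately small validator;
    the schema file itself follows JSON-Schema conventions for readers).
    """
    schema = schema or report_schema()
    _validate_node(report, schema, path="report")


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float),
          "integer": int, "boolean": bool}


def _validate_node(node, schema, path):
    expected = schema.get("type")
    if expected and not isinstance(node, _TYPES[expected]):
        raise ValueError(f"{path}: expected {expected}, got {type(node).__name__}")
    for key in schema.get("required", []):
        if key not in node:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in node:
            _validate_node(node[key], sub, f"{path}.{key}")


def run_pipeline(config: PipelineConfig):
    """Run the full analysis from file inputs; returns the report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("epityper %s, seed %d", __version__, config.seed)
        tumor = _load_beta(config.tumor_beta, "load-tumor")
        normal = _load_beta(config.normal_beta, "load-normal")
        if config.annotation is None or not Path(config.annotation).exists():
            raise PipelineError("load-annotation", f"input not found: {config.annotation}")
        annotation = pd.read_csv(config.annotation, sep="\t", index_col=0,
                                 keep_default_na=False, na_values=[])
        report = run_pipeline_frames(
            config,
            tumor_beta=tumor,
            normal_beta=normal,
            annotation=annotation,
            validation_beta=(
                _load_beta(config.validation_beta, "load-validation")
                if config.validation_beta
                else None
            ),
            output_dir=out,
        )
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def run_pipeline_frames(
    config: PipelineConfig,
    tumor_beta: pd.DataFrame,
    normal_beta: pd.DataFrame,
    annotation: pd.DataFrame,
    validation_beta: pd.DataFrame | None = None,
    output_dir: Path | None = None,
):
    """The pipeline on in-memory frames (the library path under the CLI)."""

    def _stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(name, str(exc)) from exc

    assay = annotation["assay_type"]

    def _prep(df: pd.DataFrame, label: str) -> BetaMatrix:
        bm = BetaMatrix(df, assay.reindex(df.index), normalized=config.already_normalized)
        if not config.already_normalized:
            bm = _stage(
                f"normalize-{label}", peak_normalize, bm,
                bandwidth=config.kde_bandwidth, grid_size=config.kde_grid_size,
            )
        return bm

    tumor = _prep(tumor_beta, "tumor")
    normal = _prep(normal_beta, "normal")

    status = _stage(
        "normal-status", call_normal_status, normal,
        meth_min=config.meth_min, unmeth_max=config.unmeth_max,
        max_missing=config.max_missing_normals,
    )
    sets = _stage(
        "select-sites", select_tumor_specific, tumor, status,
        min_fraction=config.min_switch_fraction,
        meth_min=config.meth_min, unmeth_max=config.unmeth_max,
    )
    selected = sets.all_selected
    if len(selected) == 0:
        raise PipelineError("select-sites", "no tumor-specific CpG sites selected")

    consensus = _stage(
        "cluster", bootstrap_consensus, tumor.values.loc[selected],
        k_range=range(config.k_min, config.k_max + 1),
        n_boot=config.n_boot, seed=config.seed, min_overlap=config.min_overlap,
    )
    choice = _stage(
        "choose-k", choose_k, consensus,
        min_cluster_size=config.min_cluster_size,
        stability_threshold=config.stability_threshold,
    )
    raw_labels = consensus.labels_by_k[choice.k]
    normal_profile = normal.values.loc[selected].mean(axis=1)
    model = _stage(
        "centroids", build_centroids, tumor.values.loc[selected], raw_labels,
        reference_profile=normal_profile,
    )
    labels = relabel(raw_labels, model)

    pattern = _stage(
        "patterns", extract_epitype_patterns, tumor.values.loc[selected], labels,
        sets, roles=config.roles,
    )
    scores = _stage("hypermethylation-scores", hypermethylation_score, tumor, annotation)

    validation_assignment = None
    if validation_beta is not None:
        vb = _prep(validation_beta, "validation")
        validation_assignment = _stage(
            "classify-validation", classify_by_centroid, vb.values, model,
            min_overlap=config.min_overlap,
        )

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_tumors": int(tumor.values.shape[1]),
        "n_normals": int(normal.values.shape[1]),
        "n_probes": int(tumor.values.shape[0]),
        "selected_sites": {
            "cancer_methylated": int(len(sets.cancer_methylated)),
            "cancer_unmethylated": int(len(sets.cancer_unmethylated)),
            "min_count": int(sets.min_count),
        },
        "chosen_k": int(choice.k),
        "k_diagnostics": json.loads(choice.diagnostics.to_json(orient="index")),
        "epitype_sizes": {k: int(v) for k, v in model.sizes().items()},
        "pattern_set_sizes": {k: int(v) for k, v in pattern.sizes().items()},
        "hypermethylation_score_mean": {
            "global": float(scores.global_score.mean()),
            "promoter_island": float(scores.promoter_island_score.mean()),
        },
    }
    if validation_assignment is not None:
        report["validation_epitype_sizes"] = {
            k: int(v) for k, v in validation_assignment.labels.value_counts().items()
        }

    artifacts = {
        "labels": labels,
        "model": model,
        "sets": sets,
        "patterns": pattern,
        "consensus": consensus,
        "scores": scores,
        "validation": validation_assignment,
        "report": report,
    }
    if output_dir is not None:
        _write_artifacts(output_dir, config, artifacts, tumor)
    validate_report(report)
    return artifacts


def _write_artifacts(out: Path, config: PipelineConfig, artifacts, tumor: BetaMatrix) -> None:
    out.mkdir(parents=True, exist_ok=True)
    artifacts["labels"].rename("epitype").to_csv(out / "epitype_labels.tsv", sep="\t")
    artifacts["model"].centroids.to_csv(out / "centroids.tsv", sep="\t", index_label="probe_id")
    (out / "model_metadata.json").write_text(
        json.dumps(artifacts["model"].metadata, indent=1, sort_keys=True)
    )
    artifacts["sets"].to_frame().to_csv(out / "selected_sites.tsv", sep="\t", index=False)
    artifacts["patterns"].to_frame().to_csv(out / "pattern_sets.tsv", sep="\t", index=False)
    artifacts["scores"].to_frame().to_csv(out / "hypermethylation_scores.tsv", sep="\t")
    qc_report(tumor).to_csv(out / "qc_tumor.tsv", sep="\t")
    if artifacts["validation"] is not None:
        artifacts["validation"].to_frame().to_csv(out / "validation_assignment.tsv", sep="\t")
    (out / "report.json").write_text(json.dumps(artifacts["report"], indent=1, sort_keys=True))
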