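"""End-to-end orchestration: simulate/load -> rank -> IFS -> evaluate -> overlap.

A run is fully described by a :class:`RunConfig`; the resolved config is
serialized into the run directory and into every output header, so any
result file can be traced back to, and re-run from, its exact parameters.
One top-level seed drives the synthetic generator and the CV fold
shuffling through independent derived streams: changing the CV behaviour
never changes the simulated data.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (
    ClassifierSpec,
    CVScheme,
    accuracy,
    confusion,
    cross_validated_predictions,
    mcc,
    sensitivity,
    specificity,
)
from .enrichment import gene_set, hypergeometric_overlap_test, read_gene_set
from .ifs import build_panel, ifs_curve, plot_curve, select_peak
from .io import (
    ExpressionMatrix,
    LabelVector,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    write_labels,
    write_panel,
    write_ranked_list,
    write_table,
)
from .mrmr import mrmr_rank
from .simulate import SyntheticSpec, generate

logger = logging.getLogger("scmrmr")


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Every knob of a pipeline run, with defaults for each field."""

    # inputs: either a matrix+labels pair on disk, or synthetic generation
    matrix_path: str | None = None
    matrix_format: str = "dense_tsv"
    labels_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "scmrmr_run"
    # synthetic generation (used when matrix_path is None)
    synthetic: dict = field(default_factory=dict)
    # transform and discretization
    log1p: bool = True
    scheme: str = "mean_sigma"
    alpha: float = 0.5
    n_bins: int = 3
    min_cells_expressed: int = 0
    # ranking and IFS
    n_select: int = 100
    ifs_k: int | None = None
    # classifier and CV
    kernel: str = "rbf"
    cost: float = 1.0
    gamma: str | float = "reciprocal_n_features"
    standardize: bool = True
    cv_kind: str = "loocv"
    cv_folds: int = 5
    # enrichment
    universe_size: int | None = None
    # master seed
    seed: int = 0

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            kernel=self.kernel,
            cost=self.cost,
            gamma=self.gamma,
            standardize=self.standardize,
        )

    def cv_scheme(self) -> CVScheme:
        return CVScheme(kind=self.cv_kind, k=self.cv_folds, seed=derived_seed(self.seed, "cv"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def derived_seed(master: int, stream: str) -> int:
    """Independent child seed (< 2**31) for a named stream of one run."""
    tag = zlib.crc32(stream.encode())
    ss = np.random.SeedSequence([int(master), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunResult:
    run_dir: Path
    ranked: object
    curve: object
    panel: object
    metrics: dict
    overlaps: list


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("input")
def _load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, LabelVector]:
    if config.matrix_path:
        matrix = read_expression_matrix(config.matrix_path, config.matrix_format)
        if not config.labels_path:
            raise ValueError("labels_path required when matrix_path is given")
        labels = read_labels(config.labels_path, cell_ids=matrix.cell_ids)
    else:
        sim = dict(config.synthetic)
        sim.setdefault("seed", derived_seed(config.seed, "simulate"))
        spec = SyntheticSpec(**sim)
        matrix, labels, _truth = generate(spec)
        logger.info("simulated matrix from spec %s", spec)
    logger.info(
        "input: %d genes x %d cells (%d %s / %d %s)",
        matrix.n_genes, matrix.n_cells,
        labels.n_positive, labels.positive_name,
        labels.n_negative, labels.negative_name,
    )
    return matrix, labels


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages into ``config.out_dir``; returns in-memory results."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, run_dir: Path) -> RunResult:
    config.to_yaml(run_dir / "run_config.yaml")
    meta = {"seed": config.seed, "config": run_dir / "run_config.yaml"}

    matrix, labels = _load_inputs(config)
    if config.matrix_path is None:
        write_expression_matrix(matrix, run_dir / "matrix.tsv")
        write_labels(labels, run_dir / "labels.tsv", meta)

    work = matrix.log1p() if config.log1p else matrix
    logger.info("transform: %s", "log1p" if config.log1p else "none")

    ranked = _stage("rank")(mrmr_rank)(
        work,
        labels,
        n_select=config.n_select,
        scheme=config.scheme,
        alpha=config.alpha,
        n_bins=config.n_bins,
        min_cells_expressed=config.min_cells_expressed,
    )
    write_ranked_list(ranked, run_dir / "ranked_genes.tsv", meta)

    K = config.ifs_k if config.ifs_k is not None else config.n_select
    spec = config.classifier_spec()
    cv = config.cv_scheme()
    curve = _stage("ifs")(ifs_curve)(work, labels, ranked, K=K, spec=spec, cv=cv)
    write_table(curve.table, run_dir / "ifs_curve.tsv", meta)
    plot_curve(curve, run_dir / "ifs_curve.png")

    k_star, peak = select_peak(curve)
    panel = build_panel(
        ranked, k_star, peak,
        provenance={"seed": config.seed, "cv": cv.kind, "scheme": config.scheme},
    )
    write_panel(panel, run_dir / "panel.tsv", meta)

    cm = _stage("evaluate")(lambda: curve.point(k_star))()
    metrics = {
        "k": k_star,
        "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
        "mcc": mcc(cm),
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "accuracy": accuracy(cm),
    }
    import pandas as pd

    write_table(pd.DataFrame([metrics]), run_dir / "metrics.tsv", meta)
    logger.info("panel: %d genes, MCC %.4f", k_star, metrics["mcc"])

    overlaps = []
    if config.gmt_path:
        universe = config.universe_size or matrix.n_genes
        panel_set = gene_set("panel", panel.gene_ids)
        rows = []
        for ref in _stage("overlap")(read_gene_set)(config.gmt_path):
            ov, p = hypergeometric_overlap_test(panel_set, ref, universe)
            rows.append({"set": ref.name, "size": len(ref), "overlap": ov, "p_value": p})
            overlaps.append((ref.name, ov, p))
        write_table(pd.DataFrame(rows), run_dir / "overlap.tsv", {**meta, "universe": universe})

    return RunResult(run_dir, ranked, curve, panel, metrics, overlaps)
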