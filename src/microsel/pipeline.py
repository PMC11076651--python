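"""End-to-end pipeline: generate/load → extract → select → classify → evaluate.

Every (extraction, selection, classifier) combination is evaluated by
pooled stratified k-fold cross-validation with fold-safe fitting: the
extractor's retention rule and the wrapper search see only training
folds, and each sample's prediction comes from a model that never saw
it.  Runs are fully reproducible from the global seed; completed cells
can be resumed from an on-disk cache keyed by the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import KINDS, ClassifierSpec, stratified_folds, train_classifier
from .datasets import (ExpressionDataset, SyntheticConfig, generate_dataset,
                       read_expression_csv)
from .extraction import METHODS, Extractor
from .metrics import (REPORT_COLUMNS, MetricSet, aggregate_report,
                      compute_metrics, confusion)
from .selection import DEFAULT_CONFIGS, binarize_position, select_features

log = logging.getLogger("microsel")

SELECTION_ALGORITHMS = ("none", "HS", "FF", "EHO")
#: report labels for the selection stage
SELECTION_LABELS = {"none": "none", "HS": "harmony_search",
                    "FF": "firefly", "EHO": "eho"}


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    ``dataset`` is either a :class:`SyntheticConfig` or a path to an
    expression CSV.  ``fitness_kind`` chooses the wrapper's fitness
    classifier: ``None`` uses the downstream classifier under test
    (wrapper semantics); a kind name (e.g. ``"QDA"``) acts as a cheap
    shared surrogate.
    """

    dataset: SyntheticConfig | str = field(default_factory=SyntheticConfig)
    extraction_methods: tuple = ("DCT", "PCA")
    k_features: int = 6_000
    selection_algorithms: tuple = ("none", "EHO")
    selection_overrides: dict = field(default_factory=dict)  # algorithm -> config kwargs
    classifiers: tuple = KINDS
    k_folds: int = 10
    fitness_kind: str | None = None
    fitness_folds: int = 3
    seed: int = 0
    out_dir: str | None = None
    resume: bool = False

    def __post_init__(self):
        if not self.extraction_methods or not self.selection_algorithms or not self.classifiers:
            raise ValueError("each stage needs at least one method")
        for m in self.extraction_methods:
            if m not in METHODS:
                raise ValueError(f"unknown extraction method {m!r}")
        for a in self.selection_algorithms:
            if a not in SELECTION_ALGORITHMS:
                raise ValueError(f"unknown selection algorithm {a!r}")
        for c in self.classifiers:
            if c not in KINDS:
                raise ValueError(f"unknown classifier kind {c!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if isinstance(self.dataset, str) and not Path(self.dataset).exists():
            raise FileNotFoundError(self.dataset)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        ds = data.get("dataset", {})
        if isinstance(ds, dict):
            data["dataset"] = SyntheticConfig(**ds)
        for key in ("extraction_methods", "selection_algorithms", "classifiers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (yaml.safe_load(text) if str(path).endswith((".yml", ".yaml"))
                else json.loads(text))
        return cls.from_dict(data)

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")
        payload.pop("resume")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    rows: pd.DataFrame
    overall_average_accuracy: dict
    best_configuration: dict
    timings: dict
    failed_cells: list
    seed: int
    version: str = __version__

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "report.csv", index=False, float_format="%.2f")
        for sel, sub in self.rows.groupby("selection", sort=False):
            sub.drop(columns="selection").to_csv(
                out / f"table_{sel}.csv", index=False, float_format="%.2f")
        summary = {
            "overall_average_accuracy": self.overall_average_accuracy,
            "best_configuration": self.best_configuration,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "failed_cells": self.failed_cells,
            "seed": self.seed,
            "version": self.version,
        }
        (out / "run.json").write_text(json.dumps(summary, indent=2))


def _derive_seed(global_seed: int, *parts) -> int:
    """Stable per-cell seed below 2**31, derived from the global seed."""
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0] % (2**31))


def _load_dataset(config: PipelineConfig) -> ExpressionDataset:
    if isinstance(config.dataset, SyntheticConfig):
        return generate_dataset(config.dataset)
    return read_expression_csv(config.dataset)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stage combinations; failures are isolated per cell."""
    t0 = time.perf_counter()
    dataset = _load_dataset(config)
    y = dataset.y
    folds = stratified_folds(y, k=config.k_folds, seed=config.seed)
    splits = list(folds.iter_splits())
    timings: dict[str, float] = {}
    cache_dir = None
    if config.out_dir and config.resume:
        cache_dir = Path(config.out_dir) / "cache"
        cache_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: per-fold fold-safe extraction, shared across cells
    k = min(config.k_features, dataset.n_genes)
    extracted: dict[tuple, np.ndarray] = {}
    for method in config.extraction_methods:
        t = time.perf_counter()
        for fi, (train, _test) in enumerate(splits):
            ex = Extractor(method, k=k, seed=_derive_seed(config.seed, "extract", method, fi))
            ex.fit(dataset.matrix[train], y[train])
            extracted[(method, fi)] = ex.transform(dataset.matrix)
        timings[f"extract/{method}"] = time.perf_counter() - t
        log.info("extracted %s (k=%d) in %.2fs seed=%d", method, k,
                 timings[f"extract/{method}"], config.seed)

    # stage 2+3: per-cell wrapper selection and pooled CV classification
    mask_cache: dict[tuple, np.ndarray] = {}
    results, failed = [], []
    for method in config.extraction_methods:
        for algorithm in config.selection_algorithms:
            for kind in config.classifiers:
                label = SELECTION_LABELS[algorithm]
                cell = (label, method, kind)
                t = time.perf_counter()
                cached_row = _cache_load(cache_dir, config, cell)
                if cached_row is not None:
                    results.append((label, method, kind, cached_row))
                    timings["/".join(cell)] = time.perf_counter() - t
                    continue
                try:
                    ms = _run_cell(config, dataset, y, splits, extracted,
                                   mask_cache, method, algorithm, kind)
                    results.append((label, method, kind, ms))
                    _cache_store(cache_dir, config, cell, ms)
                except Exception as exc:  # isolate per-cell failures
                    log.warning("cell %s failed: %s", cell, exc)
                    failed.append({"cell": list(cell), "error": str(exc)})
                timings["/".join(cell)] = time.perf_counter() - t
                log.info("cell %s done in %.2fs seed=%d", cell,
                         timings["/".join(cell)], config.seed)
    if not results:
        raise RuntimeError("every pipeline cell failed")
    report = aggregate_report(results)
    rows = pd.concat(
        [tbl.assign(selection=sel)[REPORT_COLUMNS]
         for sel, tbl in report["tables"].items()],
        ignore_index=True)
    timings["total"] = time.perf_counter() - t0
    run = RunReport(rows=rows,
                    overall_average_accuracy=report["overall_average_accuracy"],
                    best_configuration=report["best_configuration"],
                    timings=timings, failed_cells=failed, seed=config.seed)
    if config.out_dir:
        run.write(config.out_dir)
    return run


def _run_cell(config, dataset, y, splits, extracted, mask_cache,
              method, algorithm, kind) -> MetricSet:
    preds = np.empty(dataset.n_samples, dtype=int)
    for fi, (train, test) in enumerate(splits):
        features = extracted[(method, fi)]
        if algorithm == "none":
            mask = np.ones(features.shape[1], dtype=int)
        else:
            fitness_kind = config.fitness_kind or kind
            mkey = (method, algorithm, fitness_kind, fi)
            if mkey not in mask_cache:
                sel_seed = _derive_seed(config.seed, "select", *mkey)
                overrides = config.selection_overrides.get(algorithm, {})
                sel_cfg = DEFAULT_CONFIGS[algorithm](**overrides)
                spec = ClassifierSpec(fitness_kind, seed=sel_seed)
                mask, _trace = select_features(
                    features[train], y[train], algorithm, spec,
                    config=sel_cfg, seed=sel_seed,
                    fitness_folds=config.fitness_folds)
                mask_cache[mkey] = mask
            mask = mask_cache[mkey]
        clf_seed = _derive_seed(config.seed, "train", method, algorithm, kind, fi)
        model = train_classifier(ClassifierSpec(kind, seed=clf_seed),
                                 features[train][:, mask.astype(bool)], y[train])
        preds[test] = model.predict(features[test][:, mask.astype(bool)])
    return compute_metrics(confusion(y, preds, positive_label=1))


def _cell_cache_path(cache_dir, config, cell):
    return cache_dir / f"{config.content_hash()}_{'_'.join(cell)}.json"


def _cache_load(cache_dir, config, cell):
    if cache_dir is None:
        return None
    path = _cell_cache_path(cache_dir, config, cell)
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    return MetricSet(**data)


def _cache_store(cache_dir, config, cell, ms: MetricSet) -> None:
    if cache_dir is None:
        return
    _cell_cache_path(cache_dir, config, cell).write_text(json.dumps(asdict(ms)))


def smoke_config(seed: int = 0, out_dir: str | None = None,
                 resume: bool = False) -> PipelineConfig:
    """Small, minutes-scale profile: 40 samples × 200 genes, k=50,
    two extractors × {none, EHO} × three classifiers, 5-fold CV, with a
    reduced search budget and a shared surrogate fitness classifier."""
    return PipelineConfig(
        dataset=SyntheticConfig(n_healthy=17, n_malignant=23, n_genes=200,
                                n_informative=20, effect_size=1.5, seed=seed),
        extraction_methods=("DCT", "PCA"),
        k_features=50,
        selection_algorithms=("none", "EHO"),
        selection_overrides={"EHO": {"population": 12, "n_clans": 3, "max_iter": 10}},
        classifiers=("SVM_RBF", "DECISION_TREE", "QDA"),
        k_folds=5,
        fitness_kind="QDA",
        seed=seed,
        out_dir=out_dir,
        resume=resume,
    )
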