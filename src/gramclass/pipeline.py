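"""End-to-end orchestration: features -> selection -> partition -> ensemble.

The default flow follows the two-stage design: k-mer featurization, the
feature-selection GA on the full labeled matrix, the partition GA on the
reduced matrix, then the six-member ensemble fitted on the train side and
scored on the test side. Because selecting features on the full matrix
risks optimistic bias, a strict mode reserves a stratified test split up
front and runs both GA stages on the development pool only; the reserved
rows are touched exactly once, at final scoring.

A single global seed fans out to per-stage seeds through a fixed offset
table so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from ._cnn import CNNConfig
from .ensemble import EnsembleModel, fit_ensemble, mode_vote
from .metrics import Metrics, evaluate
from .ngram_features import FeatureMatrix, build_feature_matrix
from .partition import (
    PartitionConfig,
    PartitionResult,
    run_partition_ga,
    save_partition,
    save_partition_history,
)
from .selection import GAConfig, SelectionResult, run_selection_ga, save_history, save_mask
from .sequence_io import read_fasta, read_labels
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger("gramclass.pipeline")

_SEED_OFFSETS = {"data": 0, "selection": 1, "partition": 2, "ensemble": 3, "cnn": 4, "split": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1009 + _SEED_OFFSETS[stage]) % (2**31 - 1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs; nested configs keep stage options
    grouped the way the stages consume them."""

    outdir: str
    fasta: str | None = None
    labels: str | None = None
    synthetic: SyntheticSpec | None = None
    k_min: int = 1
    k_max: int = 4
    normalize: bool = False
    selection: GAConfig = field(default_factory=GAConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    rf_tree_cap: int = 200
    mlp_hidden_cap: int = 256
    strict: bool = False
    seed: int = 0
    write_features: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.synthetic is None and self.fasta is None:
            raise ValueError("provide either a FASTA path or a synthetic spec")
        self.selection.validate()
        self.partition.validate()
        self.cnn.validate()


def reserve_test_split(
    y: np.ndarray, p_test: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; every class keeps at least one test row and
    at least one development row."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    test: list[np.ndarray] = []
    for c in np.unique(y):
        rows = np.nonzero(y == c)[0]
        n_test = int(round(p_test * rows.size))
        n_test = min(max(n_test, 1), rows.size - 1)
        test.append(rng.choice(rows, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test))
    mask = np.zeros(y.size, dtype=bool)
    mask[test_idx] = True
    return np.nonzero(~mask)[0], test_idx


def carve_validation(
    train_rows: np.ndarray, y: np.ndarray, frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified carve of a validation slice out of the train rows; classes
    too small to give up a row keep all rows in train."""
    if frac <= 0:
        return np.sort(train_rows), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    train_rows = np.asarray(train_rows)
    yt = y[train_rows]
    val: list[np.ndarray] = []
    for c in np.unique(yt):
        rows = train_rows[yt == c]
        n_val = int(round(frac * rows.size))
        n_val = min(n_val, rows.size - 1)
        if n_val > 0:
            val.append(rng.choice(rows, size=n_val, replace=False))
    val_rows = np.sort(np.concatenate(val)) if val else np.array([], dtype=int)
    keep = np.setdiff1d(train_rows, val_rows)
    return keep, val_rows


def fit_on_development(
    fm: FeatureMatrix, dev_idx: np.ndarray, config: RunConfig
) -> tuple[np.ndarray, EnsembleModel, np.ndarray, np.ndarray, SelectionResult, PartitionResult]:
    """Strict-mode core: run both GA stages and fit the ensemble using only
    the development rows. Returns global row indices for fit and validation.
    """
    fm_dev = fm.subset_rows(dev_idx)
    sel_cfg = _with_seed(config.selection, stage_seed(config.seed, "selection"))
    sel = run_selection_ga(fm_dev, sel_cfg)
    fm_sel_dev = fm_dev.subset_features(sel.best_mask)

    inner_p = config.partition.p_val / (1 - config.partition.p_test)
    inner_p = min(max(inner_p, 0.05), 0.5)
    part_cfg = _with_seed(config.partition, stage_seed(config.seed, "partition"))
    part_cfg.p_test = inner_p
    part = run_partition_ga(fm_sel_dev, part_cfg)

    fit_rows = dev_idx[part.best.train_rows]
    val_rows = dev_idx[part.best.test_idx]
    fm_fit = fm.subset_features(sel.best_mask).subset_rows(fit_rows)
    model = fit_ensemble(
        fm_fit,
        sel_cfg,
        _with_seed(config.cnn, stage_seed(config.seed, "cnn")),
        seed=stage_seed(config.seed, "ensemble"),
        rf_tree_cap=config.rf_tree_cap,
        mlp_hidden_cap=config.mlp_hidden_cap,
    )
    return sel.best_mask, model, fit_rows, val_rows, sel, part


def _with_seed(cfg, seed: int):
    out = type(cfg)(**asdict(cfg))
    out.seed = seed
    return out


def _load_data(config: RunConfig):
    if config.synthetic is not None:
        spec = SyntheticSpec(**{**asdict(config.synthetic)})
        spec.seed = stage_seed(config.seed, "data")
        sset, truth = generate_dataset(spec)
        return sset, truth
    labels = read_labels(config.labels) if config.labels else None
    return read_fasta(config.fasta, labels), None


def _write_predictions(
    path: Path,
    ids: list[str],
    class_names: list[str],
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray,
) -> None:
    with open(path, "w") as fh:
        prob_cols = "\t".join(f"prob_{c}" for c in class_names)
        fh.write(f"id\ttrue_label\tpredicted_label\t{prob_cols}\n")
        for i, rid in enumerate(ids):
            row_probs = "\t".join(f"{p:.6f}" for p in probs[i])
            fh.write(
                f"{rid}\t{class_names[y_true[i]]}\t{class_names[y_pred[i]]}\t{row_probs}\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow for one seed; writes artifacts to ``outdir``
    and returns a report echoing every derived hyperparameter."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    report: dict = {"seed": config.seed, "strict": config.strict, "stages": []}

    def _stage(name: str):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        try:
            _stage("data")
            sset, truth = _load_data(config)
            if truth is not None:
                truth.to_json(outdir / "truth.json")
        except Exception as exc:
            raise PipelineError("data", exc) from exc

        try:
            _stage("features")
            fm = build_feature_matrix(sset, config.k_min, config.k_max, config.normalize)
            if config.write_features:
                fm.to_tsv(outdir / "features.tsv")
        except Exception as exc:
            raise PipelineError("features", exc) from exc

        if config.strict:
            try:
                _stage("strict_split+selection+partition+train")
                dev_idx, test_rows = reserve_test_split(
                    fm.y, config.partition.p_test, stage_seed(config.seed, "split")
                )
                mask, model, fit_rows, val_rows, sel, part = fit_on_development(
                    fm, dev_idx, config
                )
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("strict_fit", exc) from exc
        else:
            try:
                _stage("selection")
                sel_cfg = _with_seed(config.selection, stage_seed(config.seed, "selection"))
                sel = run_selection_ga(fm, sel_cfg)
                mask = sel.best_mask
            except Exception as exc:
                raise PipelineError("selection", exc) from exc

            try:
                _stage("partition")
                fm_sel = fm.subset_features(mask)
                part_cfg = _with_seed(config.partition, stage_seed(config.seed, "partition"))
                part = run_partition_ga(fm_sel, part_cfg)
                test_rows = part.best.test_idx
                val_frac = config.partition.p_val / (1 - config.partition.p_test)
                fit_rows, val_rows = carve_validation(
                    part.best.train_rows, fm.y, val_frac, stage_seed(config.seed, "split")
                )
            except Exception as exc:
                raise PipelineError("partition", exc) from exc

            try:
                _stage("train")
                sel_cfg = _with_seed(config.selection, stage_seed(config.seed, "selection"))
                fm_fit = fm.subset_features(mask).subset_rows(fit_rows)
                model = fit_ensemble(
                    fm_fit,
                    sel_cfg,
                    _with_seed(config.cnn, stage_seed(config.seed, "cnn")),
                    seed=stage_seed(config.seed, "ensemble"),
                    rf_tree_cap=config.rf_tree_cap,
                    mlp_hidden_cap=config.mlp_hidden_cap,
                )
            except Exception as exc:
                raise PipelineError("train", exc) from exc

        save_mask(fm.feature_names, mask, outdir / "mask.tsv")
        save_history(sel, outdir / "selection_history.json")
        save_partition(fm.ids, fit_rows, test_rows, outdir / "partition.tsv", val_rows)
        save_partition_history(part, outdir / "partition_history.json")

        try:
            _stage("evaluate")
            fm_sel = fm.subset_features(mask)
            member_labels, member_probs = model.predict_members(fm_sel.X[test_rows])
            y_pred = mode_vote(member_labels, member_probs)
            probs = member_probs.mean(axis=0)
            y_test = fm.y[test_rows]
            metrics = evaluate(y_test, y_pred, probs, fm.class_names)
            metrics.to_json(outdir / "metrics.json")
            _write_predictions(
                outdir / "predictions.tsv",
                [fm.ids[i] for i in test_rows],
                fm.class_names,
                y_test,
                y_pred,
                probs,
            )
            val_metrics: Metrics | None = None
            if len(val_rows):
                vl, vp = model.predict_members(fm_sel.X[val_rows])
                val_pred = mode_vote(vl, vp)
                val_metrics = evaluate(
                    fm.y[val_rows], val_pred, vp.mean(axis=0), fm.class_names
                )
                val_metrics.to_json(outdir / "val_metrics.json")
        except Exception as exc:
            raise PipelineError("evaluate", exc) from exc

        report.update(
            {
                "class_names": fm.class_names,
                "n_records": fm.n_records,
                "n_features": fm.n_features,
                "n_selected_features": int(mask.sum()),
                "selection_best_fitness": sel.best_fitness,
                "partition_best_fitness": part.best.fitness,
                "partition_clamped_classes": part.clamped_classes,
                "derived_params": model.params.as_dict(),
                "caps_applied": model.params.caps_applied,
                "n_train": int(len(fit_rows)),
                "n_val": int(len(val_rows)),
                "n_test": int(len(test_rows)),
                "metrics": asdict(metrics),
                "val_metrics": asdict(val_metrics) if val_metrics else None,
                "outdir": str(outdir),
                "version": __version__,
                # in-memory handles for callers that want to probe the fitted
                # model; never serialized
                "_model": model,
                "_mask": mask,
                "_test_rows": test_rows,
                "_selected_matrix": fm_sel,
            }
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "class_names": fm.class_names,
                    "derived_params": model.params.as_dict(),
                    "seed": config.seed,
                    "stage_seeds": {s: stage_seed(config.seed, s) for s in _SEED_OFFSETS},
                    "version": __version__,
                    "library_versions": _library_versions(),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        logger.info("run complete: accuracy=%.4f", metrics.accuracy)
        return report
    except PipelineError as exc:
        logger.error("aborted at stage %s: %s", exc.stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _library_versions() -> dict[str, str]:
    import sklearn

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
    }
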