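"""End-to-end pipeline helpers: descriptor dispatch, featurize / cross-validate
/ train / independent-test / predict on FASTA inputs.

These functions are the library face of the command-line tool; each one is a
thin composition of the module-level operations and returns plain objects so
they are equally usable from scripts and notebooks.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import fegs
from .apaac import ApaacParams, apaac_layout, featurize_dataset_apaac
from .evaluation import EvalReport, independent_test, kfold_cv
from .fegs import FeatureLayout
from .hdnet import CascadeConfig, CascadeModel, fit_cascade, load_model, predict_proba, save_model
from .physchem import PhysChemIndexTable, load_default_table, load_table
from .sequence_io import AMINO_ACIDS, LabeledDataset, load_labeled_dataset

logger = logging.getLogger("fegsnet")

DESCRIPTORS = ("fegs", "apaac", "dpc", "aac")

__all__ = [
    "DESCRIPTORS",
    "featurize",
    "run_featurize",
    "run_crossval",
    "run_train",
    "run_independent_test",
    "run_predict",
]


def featurize(
    dataset: LabeledDataset,
    descriptor: str = "fegs",
    table: PhysChemIndexTable | None = None,
    apaac_params: ApaacParams | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    """Feature matrix of ``dataset`` under the chosen descriptor."""
    if descriptor == "fegs":
        if table is None:
            table = load_default_table()
        X, layout = fegs.featurize_dataset(dataset, table)
        logger.info("FEGS featurization: effective P=%d, dimension=%d", len(table), len(layout))
        return X, layout
    if descriptor == "apaac":
        return featurize_dataset_apaac(dataset, apaac_params)
    if descriptor == "dpc":
        X = np.vstack([fegs.dpc(s) for s in dataset.sequences]) if len(dataset) else np.empty((0, 400))
        return X, FeatureLayout("dpc", tuple(f"DPC_{d}" for d in fegs.DIPEPTIDES))
    if descriptor == "aac":
        X = np.vstack([fegs.aac(s) for s in dataset.sequences]) if len(dataset) else np.empty((0, 20))
        return X, FeatureLayout("aac", tuple(f"AAC_{a}" for a in AMINO_ACIDS))
    raise ValueError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTORS}")


def _load(fasta, labels, table_path):
    dataset = load_labeled_dataset(fasta, labels)
    table = load_table(table_path) if table_path else None
    return dataset, table


def run_featurize(
    fasta: str | Path,
    out: str | Path,
    descriptor: str = "fegs",
    table_path: str | Path | None = None,
    apaac_params: ApaacParams | None = None,
) -> FeatureLayout:
    """FASTA -> cleaned sequences -> feature-matrix file."""
    dataset, table = _load(fasta, None, table_path)
    X, layout = featurize(dataset, descriptor, table, apaac_params)
    fegs.write_feature_matrix(out, dataset.ids, X, layout)
    logger.info("wrote %d x %d matrix to %s", X.shape[0], X.shape[1], out)
    return layout


def run_crossval(
    fasta: str | Path,
    labels: str | Path,
    descriptor: str = "fegs",
    k: int = 10,
    seed: int = 0,
    config: CascadeConfig | None = None,
    table_path: str | Path | None = None,
    apaac_params: ApaacParams | None = None,
    pooled: bool = False,
) -> EvalReport:
    """End-to-end stratified k-fold cross-validation on a labeled FASTA."""
    dataset, table = _load(fasta, labels, table_path)
    X, _ = featurize(dataset, descriptor, table, apaac_params)
    if config is None:
        config = CascadeConfig(seed=seed)
    return kfold_cv(X, np.array(dataset.labels), k=k, seed=seed, config=config, pooled=pooled)


def run_train(
    fasta: str | Path,
    labels: str | Path,
    model_out: str | Path,
    descriptor: str = "fegs",
    seed: int = 0,
    config: CascadeConfig | None = None,
    table_path: str | Path | None = None,
    apaac_params: ApaacParams | None = None,
) -> CascadeModel:
    """Fit the cascade on the full labeled FASTA and persist the archive."""
    dataset, table = _load(fasta, labels, table_path)
    X, layout = featurize(dataset, descriptor, table, apaac_params)
    if config is None:
        config = CascadeConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    model = fit_cascade(X, np.array(dataset.labels), config)
    save_model(model, model_out, layout=layout)
    logger.info(
        "trained cascade: %d layer(s), stop layer %d, history %s",
        model.n_layers, model.stop_layer, [f"{h:.4f}" for h in model.history],
    )
    return model


def run_independent_test(
    train_fasta: str | Path,
    train_labels: str | Path,
    test_fasta: str | Path,
    test_labels: str | Path,
    descriptor: str = "fegs",
    seed: int = 0,
    config: CascadeConfig | None = None,
    table_path: str | Path | None = None,
    apaac_params: ApaacParams | None = None,
) -> EvalReport:
    """Train once on the training FASTA, evaluate once on the held-out FASTA
    (ids must be disjoint)."""
    train, table = _load(train_fasta, train_labels, table_path)
    test, _ = _load(test_fasta, test_labels, table_path)
    X_train, _ = featurize(train, descriptor, table, apaac_params)
    X_test, _ = featurize(test, descriptor, table, apaac_params)
    if config is None:
        config = CascadeConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    return independent_test(
        X_train, np.array(train.labels), X_test, np.array(test.labels),
        config=config, train_ids=train.ids, test_ids=test.ids,
    )


def run_predict(
    model_path: str | Path,
    fasta: str | Path,
    out: str | Path,
    descriptor: str = "fegs",
    table_path: str | Path | None = None,
    apaac_params: ApaacParams | None = None,
) -> list[tuple[str, int, float]]:
    """Score a FASTA with a saved model; writes ``id  label  P(positive)``."""
    dataset, table = _load(fasta, None, table_path)
    if len(dataset) == 0:
        Path(out).write_text("")
        return []
    X, layout = featurize(dataset, descriptor, table, apaac_params)
    model, _ = load_model(model_path, expected_layout=layout)
    proba = predict_proba(model, X)
    rows = [
        (name, int(p1 >= p0), float(p1))
        for name, (p0, p1) in zip(dataset.ids, proba)
    ]
    with open(out, "w") as fh:
        fh.write("id\tlabel\tprob_positive\n")
        for name, label, p1 in rows:
            fh.write(f"{name}\t{label}\t{p1:.6f}\n")
    return rows
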