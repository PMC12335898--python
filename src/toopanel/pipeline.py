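"""End-to-end fit/predict pipeline: DE -> panel -> log2 features -> model.

Holds the glue used by cross-validation and the CLI so that every consumer
trains and scores identically: one-vs-rest DE per class on raw counts, panel
construction, size-factor normalization + log2(x+1) features restricted to
the panel union, then one of the three classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionTable, LabelTable, Scale
from .diffexp import DEConfig, de_one_vs_rest, estimate_size_factors
from .feature_panel import FeaturePanel, build_panel, rank_top_k_for_class
from . import classifiers as clf_mod
from .classifiers import (
    LinearOvRModel,
    MLPConfig,
    MLPModel,
    PredictionResult,
    TrainConfig,
    TSPModel,
)

CLASSIFIER_NAMES = ("logreg", "mlp", "ktsp")


@dataclass
class FittedPipeline:
    panel: FeaturePanel
    model: LinearOvRModel | MLPModel | TSPModel
    classifier: str


def log2_panel_features(
    table: ExpressionTable, panel_genes: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Samples x features matrix of log2(normalized count + 1) values
    restricted to the panel genes."""
    sub = table.subset_genes(panel_genes)
    if sub.scale == Scale.LOG2:
        X = sub.values.T
    else:
        s = estimate_size_factors(sub if sub.n_genes >= 50 else table)
        X = np.log2(sub.values / s[None, :] + 1.0).T
    return X, list(sub.sample_ids)


def select_panel(
    table: ExpressionTable,
    labels: LabelTable,
    k: int,
    padj_cutoff: float | None = 0.05,
    de_config: DEConfig | None = None,
) -> FeaturePanel:
    """One-vs-rest DE for every class followed by set-difference panel
    construction."""
    top_k = {}
    for label in labels.class_labels:
        records = de_one_vs_rest(table, labels, label, de_config)
        top_k[label] = rank_top_k_for_class(records, label, k, padj_cutoff)
    return build_panel(top_k, k)


def fit_pipeline(
    table: ExpressionTable,
    labels: LabelTable,
    k: int,
    classifier: str = "logreg",
    seed: int = 0,
    padj_cutoff: float | None = 0.05,
    pairs_per_classifier: int = 5,
    de_config: DEConfig | None = None,
    train_config: TrainConfig | None = None,
    mlp_config: MLPConfig | None = None,
) -> FittedPipeline:
    if classifier not in CLASSIFIER_NAMES:
        raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}")
    panel = select_panel(table, labels, k, padj_cutoff, de_config)
    X, sample_ids = log2_panel_features(table, panel.union)
    y = labels.labels_for(sample_ids)
    if classifier == "logreg":
        cfg = train_config or TrainConfig(seed=seed)
        model = clf_mod.fit_logistic_ovr(X, y, panel.union, cfg)
    elif classifier == "mlp":
        cfg = mlp_config or MLPConfig(seed=seed)
        model = clf_mod.fit_mlp(X, y, panel.union, cfg)
    else:
        model = clf_mod.fit_ktsp_multiclass(X, y, panel.union, pairs_per_classifier)
    return FittedPipeline(panel=panel, model=model, classifier=classifier)


def predict_pipeline(fitted: FittedPipeline, table: ExpressionTable) -> PredictionResult:
    X, sample_ids = log2_panel_features(table, fitted.panel.union)
    if fitted.classifier == "logreg":
        return clf_mod.predict_proba(fitted.model, X, fitted.panel.union, sample_ids)
    if fitted.classifier == "mlp":
        return clf_mod.predict_mlp(fitted.model, X, fitted.panel.union, sample_ids)
    return clf_mod.predict_ktsp(fitted.model, X, fitted.panel.union, sample_ids)
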