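"""Exact Shapley attributions for the linear one-vs-rest model.

For a linear score f(x) = sum_j w_j z_j + b (z the standardized features)
with an independence/interventional value function, the Shapley value of
feature j on sample x has the closed form

    phi_j(x) = w_j * (z_j - z_bg_j)

where z_bg is the standardized background point (training feature means by
default). The decomposition is exact: base_value + sum_j phi_j equals the
raw class score, for every sample. The raw (pre-normalization) per-class
linear score is the explained output so the attribution stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import LinearOvRModel
from .data_io import LabelTable, save_json_artifact


@dataclass
class AttributionMatrix:
    sample_ids: list[str]
    feature_ids: list[str]
    class_label: str
    values: np.ndarray  # samples x features
    base_value: float


@dataclass
class ClassImportance:
    class_label: str
    mean_abs: dict[str, float]
    top_n: list[str]


def linear_shap(
    model: LinearOvRModel,
    X: np.ndarray,
    feature_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    background: np.ndarray | None = None,
) -> dict[str, AttributionMatrix]:
    """Per-class exact Shapley attribution matrices on raw-scale features.

    ``background`` is a raw-scale feature-mean vector; by default the
    model's stored training means (whose standardized image is the origin).
    """
    idx = {f: i for i, f in enumerate(feature_ids)}
    missing = [f for f in model.feature_ids if f not in idx]
    if missing:
        raise ValueError(f"missing model features: {missing[:5]}")
    X = np.asarray(X, dtype=float)[:, [idx[f] for f in model.feature_ids]]
    if background is None:
        background = model.feature_means
    background = np.asarray(background, dtype=float)
    if background.shape != (len(model.feature_ids),):
        raise ValueError(
            f"background has shape {background.shape}, expected ({len(model.feature_ids)},)"
        )
    Z = (X - model.feature_means) / model.feature_sds
    z_bg = (background - model.feature_means) / model.feature_sds
    sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(X))]
    out: dict[str, AttributionMatrix] = {}
    for ci, label in enumerate(model.class_labels):
        w = model.weights[ci]
        phi = (Z - z_bg) * w
        base = float(w @ z_bg + model.intercepts[ci])
        out[label] = AttributionMatrix(
            sample_ids=sample_ids,
            feature_ids=list(model.feature_ids),
            class_label=label,
            values=phi,
            base_value=base,
        )
    return out


def aggregate_class_importance(
    attributions: dict[str, AttributionMatrix],
    labels: LabelTable,
    top_n: int = 10,
) -> dict[str, ClassImportance]:
    """Mean |SHAP| per feature over the samples truly belonging to each
    class, plus the top-n features by that mean (ties lexicographic)."""
    out: dict[str, ClassImportance] = {}
    for label, attr in attributions.items():
        mask = np.array([labels.assignments.get(s) == label for s in attr.sample_ids])
        if not mask.any():
            import warnings

            warnings.warn(f"no samples labelled {label!r}; skipping", stacklevel=2)
            continue
        mean_abs = np.abs(attr.values[mask]).mean(axis=0)
        order = sorted(
            range(len(attr.feature_ids)),
            key=lambda j: (-mean_abs[j], attr.feature_ids[j]),
        )
        out[label] = ClassImportance(
            class_label=label,
            mean_abs={f: float(v) for f, v in zip(attr.feature_ids, mean_abs)},
            top_n=[attr.feature_ids[j] for j in order[:top_n]],
        )
    return out


def export_beeswarm_table(
    attr: AttributionMatrix,
    X: np.ndarray,
    feature_ids: Sequence[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Long-format table for beeswarm-style plots of the top-n features.

    Columns: sample_id, gene_id, shap_value, feature_value, and the
    feature's within-cohort value tercile (low/mid/high, rank-based so group
    sizes differ by at most one).
    """
    idx = {f: i for i, f in enumerate(feature_ids)}
    Xa = np.asarray(X, dtype=float)[:, [idx[f] for f in attr.feature_ids]]
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = sorted(
        range(len(attr.feature_ids)), key=lambda j: (-mean_abs[j], attr.feature_ids[j])
    )[:top_n]
    rows = []
    n = len(attr.sample_ids)
    names = np.array(["low", "mid", "high"])
    for j in order:
        ranks = np.empty(n, dtype=int)
        ranks[np.argsort(Xa[:, j], kind="stable")] = np.arange(n)
        tercile = names[(ranks * 3) // n]
        for s in range(n):
            rows.append(
                {
                    "sample_id": attr.sample_ids[s],
                    "gene_id": attr.feature_ids[j],
                    "shap_value": attr.values[s, j],
                    "feature_value": Xa[s, j],
                    "feature_value_tercile": tercile[s],
                }
            )
    return pd.DataFrame(rows)


def save_attributions_tsv(attributions: dict[str, AttributionMatrix], path) -> None:
    frames = []
    for label in sorted(attributions):
        attr = attributions[label]
        df = pd.DataFrame(attr.values, index=attr.sample_ids, columns=attr.feature_ids)
        long = df.stack().reset_index()
        long.columns = ["sample_id", "gene_id", "shap_value"]
        long.insert(1, "class", label)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def save_class_importance(importance: dict[str, ClassImportance], path) -> None:
    payload = {
        "classes": [
            {
                "label": label,
                "top_n": imp.top_n,
                "scores": {g: imp.mean_abs[g] for g in imp.top_n},
            }
            for label, imp in sorted(importance.items())
        ]
    }
    save_json_artifact(payload, "class_importance", path)
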