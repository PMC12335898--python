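"""Multiclass classifiers over the panel's log2 feature matrix.

Three models share the samples x features convention:

* :func:`fit_logistic_ovr` — one L2-penalized binary logistic regression per
  class, trained by SGD on z-scored features; the headline model. Final
  label is the argmax of the per-class sigmoid scores.
* :func:`fit_mlp` — a single-hidden-layer perceptron (128 sigmoid units,
  softmax output, cross-entropy, SGD) as the nonlinear baseline.
* :func:`fit_ktsp_multiclass` — a rank-based k-top-scoring-pairs classifier:
  for each class pair, gene pairs (i, j) are scored by
  Delta P_ij = |P_ij^1 - P_ij^2| where P_ij^C is the fraction of class-C
  samples with V_i < V_j; prediction is one-vs-one majority voting.

Fitting for the two gradient models is delegated to scikit-learn; scoring is
re-implemented from the serialized weights so models round-trip through JSON
with bit-exact predictions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.neural_network import MLPClassifier

from .data_io import load_json_artifact, save_json_artifact


@dataclass
class TrainConfig:
    """SGD hyperparameters for the linear OvR model."""

    learning_rate: float = 0.01
    epochs: int = 1000
    l2_penalty: float = 1e-4
    tolerance: float = 1e-5
    seed: int = 0


@dataclass
class MLPConfig:
    """Hyperparameters for the MLP baseline.

    The hidden width is fixed at 128; the default epoch budget is far below
    a production 10k-epoch run but converges on desk-scale problems, and
    ``epochs`` is fully configurable. ``batch_size=0`` means full batch.
    """

    learning_rate: float = 0.001
    epochs: int = 500
    l2_penalty: float = 1e-4
    tolerance: float = 1e-5
    batch_size: int = 0
    hidden_units: int = 128
    seed: int = 0


@dataclass
class LinearOvRModel:
    class_labels: list[str]
    feature_ids: list[str]
    weights: np.ndarray       # (classes, features), standardized space
    intercepts: np.ndarray    # (classes,)
    feature_means: np.ndarray
    feature_sds: np.ndarray   # >0 for retained features
    dropped_features: list[str] = field(default_factory=list)
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class linear scores (pre-sigmoid) on raw-scale features."""
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.weights.T + self.intercepts


@dataclass
class MLPModel:
    class_labels: list[str]
    feature_ids: list[str]
    w_hidden: np.ndarray      # (features, hidden)
    b_hidden: np.ndarray
    w_out: np.ndarray         # (hidden, classes)
    b_out: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    loss_curve: list[float] = field(default_factory=list)
    train_config: MLPConfig = field(default_factory=MLPConfig)


@dataclass
class TSPPair:
    gene_low: str   # gene i in the V_i < V_j comparison
    gene_high: str  # gene j
    delta_p: float
    rank_score: float
    p_class1: float
    p_class2: float


@dataclass
class TSPModel:
    class_labels: list[str]
    feature_ids: list[str]
    pairs_per_classifier: int
    # unordered class pair (a, b) with a < b  ->  selected gene pairs
    classifiers: dict[tuple[str, str], list[TSPPair]] = field(default_factory=dict)


@dataclass
class PredictionResult:
    sample_ids: list[str]
    class_labels: list[str]
    class_scores: np.ndarray  # (samples, classes)
    predicted_labels: list[str]


def _argmax_lex(scores: np.ndarray, labels: Sequence[str]) -> list[str]:
    # labels are kept lexicographically sorted, so np.argmax's first-wins
    # tie rule is the lexicographic tie-break
    return [labels[i] for i in np.argmax(scores, axis=1)]


def _standardize_fit(X: np.ndarray, feature_ids: Sequence[str]):
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = [f for f, k in zip(feature_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)", stacklevel=3)
    kept_ids = [f for f, k in zip(feature_ids, keep) if k]
    return kept_ids, dropped, means[keep], sds[keep], X[:, keep]


def _check_features(model_features: Sequence[str], feature_ids: Sequence[str], X: np.ndarray):
    idx = {f: i for i, f in enumerate(feature_ids)}
    missing = [f for f in model_features if f not in idx]
    if missing:
        raise ValueError(f"input is missing {len(missing)} panel feature(s): {missing[:5]}")
    return X[:, [idx[f] for f in model_features]]


# ---------------------------------------------------------------------------
# One-vs-rest logistic regression
# ---------------------------------------------------------------------------

def fit_logistic_ovr(
    X: np.ndarray,
    y: Sequence[str],
    feature_ids: Sequence[str],
    cfg: TrainConfig | None = None,
) -> LinearOvRModel:
    """Fit one binary SGD logistic regression per class against the rest.

    Features are z-scored with training statistics (zero-variance features
    dropped with a warning); training is deterministic given (data, cfg).
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < len(labels):
        raise ValueError("need at least as many samples as classes")
    kept_ids, dropped, means, sds, Z = _standardize_fit(X, feature_ids)
    Z = (Z - means) / sds

    weights = np.zeros((len(labels), len(kept_ids)))
    intercepts = np.zeros(len(labels))
    for ci, label in enumerate(labels):
        target = (y == label).astype(int)
        clf = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            alpha=cfg.l2_penalty,
            learning_rate="invscaling",
            eta0=cfg.learning_rate,
            power_t=0.5,
            max_iter=cfg.epochs,
            tol=cfg.tolerance,
            shuffle=True,
            random_state=cfg.seed + ci,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on tiny toys
            clf.fit(Z, target)
        weights[ci] = clf.coef_[0]
        intercepts[ci] = clf.intercept_[0]
    return LinearOvRModel(
        class_labels=labels,
        feature_ids=kept_ids,
        weights=weights,
        intercepts=intercepts,
        feature_means=means,
        feature_sds=sds,
        dropped_features=dropped,
        train_config=cfg,
    )


def predict_proba(
    model: LinearOvRModel,
    X: np.ndarray,
    feature_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> PredictionResult:
    """Per-class sigmoid scores normalized to sum 1 per sample.

    Normalization preserves the argmax of the raw sigmoids (positive scaling
    per row); missing panel features raise rather than being zero-filled.
    """
    X = _check_features(model.feature_ids, feature_ids, np.asarray(X, dtype=float))
    raw = model.raw_scores(X)
    sig = 1.0 / (1.0 + np.exp(-raw))
    totals = sig.sum(axis=1, keepdims=True)
    scores = np.where(totals > 0, sig / np.maximum(totals, 1e-300), 1.0 / sig.shape[1])
    sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(X))]
    return PredictionResult(
        sample_ids=sample_ids,
        class_labels=list(model.class_labels),
        class_scores=scores,
        predicted_labels=_argmax_lex(scores, model.class_labels),
    )


# ---------------------------------------------------------------------------
# MLP baseline
# ---------------------------------------------------------------------------

def fit_mlp(
    X: np.ndarray,
    y: Sequence[str],
    feature_ids: Sequence[str],
    cfg: MLPConfig | None = None,
) -> MLPModel:
    cfg = cfg or MLPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    kept_ids, dropped, means, sds, Z = _standardize_fit(X, feature_ids)
    Z = (Z - means) / sds
    batch = Z.shape[0] if cfg.batch_size == 0 else min(cfg.batch_size, Z.shape[0])
    clf = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="logistic",
        solver="sgd",
        alpha=cfg.l2_penalty,
        batch_size=batch,
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.epochs,
        tol=cfg.tolerance,
        n_iter_no_change=20,
        momentum=0.9,
        random_state=cfg.seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    if not np.isfinite(clf.loss_):
        raise RuntimeError(f"MLP training diverged (loss={clf.loss_})")
    order = [list(clf.classes_).index(lab) for lab in labels]
    return MLPModel(
        class_labels=labels,
        feature_ids=kept_ids,
        w_hidden=clf.coefs_[0],
        b_hidden=clf.intercepts_[0],
        w_out=clf.coefs_[1][:, order],
        b_out=clf.intercepts_[1][order],
        feature_means=means,
        feature_sds=sds,
        loss_curve=[float(v) for v in clf.loss_curve_],
        train_config=cfg,
    )


def predict_mlp(
    model: MLPModel,
    X: np.ndarray,
    feature_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> PredictionResult:
    """Forward pass from the stored weights: sigmoid hidden layer, softmax
    output; rows sum to 1."""
    X = _check_features(model.feature_ids, feature_ids, np.asarray(X, dtype=float))
    Z = (X - model.feature_means) / model.feature_sds
    H = 1.0 / (1.0 + np.exp(-(Z @ model.w_hidden + model.b_hidden)))
    logits = H @ model.w_out + model.b_out
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    scores = e / e.sum(axis=1, keepdims=True)
    sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(X))]
    return PredictionResult(
        sample_ids=sample_ids,
        class_labels=list(model.class_labels),
        class_scores=scores,
        predicted_labels=_argmax_lex(scores, model.class_labels),
    )


# ---------------------------------------------------------------------------
# k-TSP
# ---------------------------------------------------------------------------

def score_tsp_pairs(
    X: np.ndarray,
    y: Sequence[str],
    feature_ids: Sequence[str],
) -> list[TSPPair]:
    """Score every ordered gene pair (i, j), i != j, for a two-class problem.

    P_ij^C is the fraction of class-C samples with V_i < V_j (strict);
    Delta P_ij = |P_ij^1 - P_ij^2|. The secondary rank score is the absolute
    between-class difference of the mean within-sample rank gap
    rank(V_j) - rank(V_i). Pairs are sorted by Delta P descending, then rank
    score descending, then lexicographic gene ids. class 1 is the
    lexicographically smaller label.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) != 2:
        raise ValueError("score_tsp_pairs requires exactly 2 classes")
    m1, m2 = (y == labels[0]), (y == labels[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    p = X.shape[1]
    # less[s, i, j] = 1 if V_i < V_j in sample s
    less = X[:, :, None] < X[:, None, :]
    P1 = less[m1].mean(axis=0)
    P2 = less[m2].mean(axis=0)
    from scipy.stats import rankdata

    ranks = rankdata(X, axis=1)
    gap = ranks[:, None, :] - ranks[:, :, None]  # rank(j) - rank(i)
    gamma = np.abs(gap[m1].mean(axis=0) - gap[m2].mean(axis=0))
    delta = np.abs(P1 - P2)
    pairs = [
        TSPPair(
            gene_low=feature_ids[i],
            gene_high=feature_ids[j],
            delta_p=float(delta[i, j]),
            rank_score=float(gamma[i, j]),
            p_class1=float(P1[i, j]),
            p_class2=float(P2[i, j]),
        )
        for i in range(p)
        for j in range(p)
        if i != j
    ]
    pairs.sort(key=lambda t: (-t.delta_p, -t.rank_score, t.gene_low, t.gene_high))
    return pairs


def fit_ktsp_multiclass(
    X: np.ndarray,
    y: Sequence[str],
    feature_ids: Sequence[str],
    pairs_per_classifier: int = 5,
) -> TSPModel:
    """One binary TSP classifier per unordered class pair, greedy-disjoint
    top-pair selection."""
    if pairs_per_classifier < 1:
        raise ValueError("pairs_per_classifier must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    model = TSPModel(
        class_labels=labels,
        feature_ids=list(feature_ids),
        pairs_per_classifier=pairs_per_classifier,
    )
    for a, b in itertools.combinations(labels, 2):
        mask = (y == a) | (y == b)
        scored = score_tsp_pairs(X[mask], y[mask], feature_ids)
        chosen: list[TSPPair] = []
        used: set[str] = set()
        for pair in scored:
            if pair.gene_low in used or pair.gene_high in used:
                continue
            chosen.append(pair)
            used.update((pair.gene_low, pair.gene_high))
            if len(chosen) == pairs_per_classifier:
                break
        model.classifiers[(a, b)] = chosen
    return model


def predict_ktsp(
    model: TSPModel,
    X: np.ndarray,
    feature_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> PredictionResult:
    """One-vs-one voting.

    Within a binary classifier, each selected pair votes for class 1 (the
    lexicographically smaller label) when the sample's V_i < V_j indicator
    matches the class-1-dominant direction (P^1 > P^2); majority wins, with
    internal ties resolved by the top-Delta-P pair's vote. The final label
    maximizes binary votes, ties broken by summed Delta P of winning votes,
    then lexicographically.
    """
    X = _check_features(model.feature_ids, feature_ids, np.asarray(X, dtype=float))
    col = {f: i for i, f in enumerate(model.feature_ids)}
    n = X.shape[0]
    labels = model.class_labels
    votes = np.zeros((n, len(labels)))
    strength = np.zeros((n, len(labels)))  # summed delta_p of won binary votes
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), pairs in model.classifiers.items():
        if not pairs:
            continue
        pair_votes_a = np.zeros(n)
        for pair in pairs:
            indicator = X[:, col[pair.gene_low]] < X[:, col[pair.gene_high]]
            favors_a = pair.p_class1 > pair.p_class2
            pair_votes_a += (indicator == favors_a).astype(float)
        half = len(pairs) / 2.0
        winner_a = pair_votes_a > half
        tied = pair_votes_a == half
        if tied.any():
            top = pairs[0]
            ind = X[tied, col[top.gene_low]] < X[tied, col[top.gene_high]]
            winner_a = winner_a.copy()
            winner_a[tied] = ind == (top.p_class1 > top.p_class2)
        total_dp = sum(p.delta_p for p in pairs)
        for s in range(n):
            w = a if winner_a[s] else b
            votes[s, lab_idx[w]] += 1
            strength[s, lab_idx[w]] += total_dp
    # lexicographic final tie-break comes free from argmax-first on sorted labels
    combined = votes + 1e-9 * strength / (1.0 + strength.max())
    sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    return PredictionResult(
        sample_ids=sample_ids,
        class_labels=list(labels),
        class_scores=votes,
        predicted_labels=_argmax_lex(combined, labels),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: LinearOvRModel | MLPModel | TSPModel, path) -> None:
    if isinstance(model, LinearOvRModel):
        cfg = model.train_config
        payload = {
            "model_type": "linear_ovr",
            "class_labels": model.class_labels,
            "feature_ids": model.feature_ids,
            "weights": model.weights.tolist(),
            "intercepts": model.intercepts.tolist(),
            "feature_means": model.feature_means.tolist(),
            "feature_sds": model.feature_sds.tolist(),
            "dropped_features": model.dropped_features,
            "train_config": vars(cfg),
        }
    elif isinstance(model, MLPModel):
        payload = {
            "model_type": "mlp",
            "class_labels": model.class_labels,
            "feature_ids": model.feature_ids,
            "w_hidden": model.w_hidden.tolist(),
            "b_hidden": model.b_hidden.tolist(),
            "w_out": model.w_out.tolist(),
            "b_out": model.b_out.tolist(),
            "feature_means": model.feature_means.tolist(),
            "feature_sds": model.feature_sds.tolist(),
            "loss_curve": model.loss_curve,
            "train_config": vars(model.train_config),
        }
    elif isinstance(model, TSPModel):
        payload = {
            "model_type": "ktsp",
            "class_labels": model.class_labels,
            "feature_ids": model.feature_ids,
            "pairs_per_classifier": model.pairs_per_classifier,
            "classifiers": [
                {
                    "pair": list(key),
                    "gene_pairs": [vars(p) for p in pairs],
                }
                for key, pairs in sorted(model.classifiers.items())
            ],
        }
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    save_json_artifact(payload, "model", path)


def load_model(path) -> LinearOvRModel | MLPModel | TSPModel:
    doc = load_json_artifact(path, "model")
    kind = doc["model_type"]
    if kind == "linear_ovr":
        return LinearOvRModel(
            class_labels=list(doc["class_labels"]),
            feature_ids=list(doc["feature_ids"]),
            weights=np.array(doc["weights"], dtype=float),
            intercepts=np.array(doc["intercepts"], dtype=float),
            feature_means=np.array(doc["feature_means"], dtype=float),
            feature_sds=np.array(doc["feature_sds"], dtype=float),
            dropped_features=list(doc["dropped_features"]),
            train_config=TrainConfig(**doc["train_config"]),
        )
    if kind == "mlp":
        return MLPModel(
            class_labels=list(doc["class_labels"]),
            feature_ids=list(doc["feature_ids"]),
            w_hidden=np.array(doc["w_hidden"], dtype=float),
            b_hidden=np.array(doc["b_hidden"], dtype=float),
            w_out=np.array(doc["w_out"], dtype=float),
            b_out=np.array(doc["b_out"], dtype=float),
            feature_means=np.array(doc["feature_means"], dtype=float),
            feature_sds=np.array(doc["feature_sds"], dtype=float),
            loss_curve=list(doc["loss_curve"]),
            train_config=MLPConfig(**doc["train_config"]),
        )
    if kind == "ktsp":
        model = TSPModel(
            class_labels=list(doc["class_labels"]),
            feature_ids=list(doc["feature_ids"]),
            pairs_per_classifier=doc["pairs_per_classifier"],
        )
        for entry in doc["classifiers"]:
            key = tuple(entry["pair"])
            model.classifiers[key] = [TSPPair(**p) for p in entry["gene_pairs"]]
        return model
    raise ValueError(f"unknown model_type {kind!r}")
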