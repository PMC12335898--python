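"""Synthetic pan-cancer RNA-seq count simulator with planted class markers.

Counts are negative-binomial with var = mu + alpha * mu^2. Each gene has a
baseline mean drawn log2-uniformly from a configurable range; each class has
a fixed set of marker genes whose mean is multiplied by 2^log2FC in samples
of that class; per-sample sequencing depth is a lognormal multiplier. An
optional sibling mechanism shares a fraction of each class's markers with a
designated partner class, emulating the histologically related cancer pairs
(renal, colorectal) that dominate real-world confusion matrices.

The generator returns the ground truth (marker map, sibling pairs) so every
downstream stage can be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionTable, LabelTable, Scale
from .feature_panel import FeaturePanel


@dataclass
class SimConfig:
    n_classes: int = 10
    samples_per_class: list[int] = field(default_factory=lambda: [60] * 10)
    n_genes: int = 2000
    markers_per_class: int = 20
    marker_log2_fc: float = 2.0
    baseline_mean_log_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float = 0.1
    library_size_sigma: float = 0.15
    marker_overlap_fraction: float = 0.0
    sibling_pairs: list[tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be positive")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("not enough genes for the requested marker allocation")
        if not 0 <= self.marker_overlap_fraction < 1:
            raise ValueError("marker_overlap_fraction must be in [0, 1)")
        if self.dispersion < 0 or self.library_size_sigma < 0:
            raise ValueError("dispersion and library_size_sigma must be non-negative")
        if self.marker_log2_fc <= 0:
            raise ValueError("marker_log2_fc must be positive")
        if self.sibling_pairs is not None:
            flat = [c for pair in self.sibling_pairs for c in pair]
            if len(set(flat)) != len(flat):
                raise ValueError("a class may belong to at most one sibling pair")
            if any(not 0 <= c < self.n_classes for c in flat):
                raise ValueError("sibling class index out of range")


@dataclass
class SimTruth:
    marker_map: dict[str, set[str]]
    sibling_pairs: list[tuple[str, str]]


def _class_names(n: int) -> list[str]:
    return [f"class{c:02d}" for c in range(n)]


def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionTable, LabelTable, SimTruth]:
    """Generate (raw-count table, labels, truth) deterministically from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    classes = _class_names(cfg.n_classes)
    gene_ids = [f"g{g:05d}" for g in range(cfg.n_genes)]
    sample_ids = []
    sample_class = []
    for c, n in zip(classes, cfg.samples_per_class):
        for i in range(n):
            sample_ids.append(f"{c}_s{i:03d}")
            sample_class.append(c)

    # disjoint marker blocks at the front of the gene list, then optional
    # sibling sharing: the shared genes REPLACE the tail of each sibling's
    # own block so |marker_map[c]| stays markers_per_class
    m = cfg.markers_per_class
    blocks = {c: set(gene_ids[ci * m : (ci + 1) * m]) for ci, c in enumerate(classes)}
    sibling_pairs: list[tuple[str, str]] = []
    marker_map = {c: set(b) for c, b in blocks.items()}
    n_shared = round(cfg.marker_overlap_fraction * m)
    if n_shared > 0:
        if cfg.sibling_pairs is not None:
            index_pairs = list(cfg.sibling_pairs)
        else:
            index_pairs = [(ci, ci + 1) for ci in range(0, cfg.n_classes - 1, 2)]
        for ai, bi in index_pairs:
            a, b = classes[ai], classes[bi]
            sibling_pairs.append((a, b))
            shared = sorted(blocks[a])[:n_shared]
            own_b = sorted(blocks[b])[: m - n_shared]
            marker_map[b] = set(shared) | set(own_b)

    baseline = 2.0 ** rng.uniform(*cfg.baseline_mean_log_range, size=cfg.n_genes)
    depth = np.exp(rng.normal(0.0, cfg.library_size_sigma, size=len(sample_ids)))

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    partner = {}
    for a, b in sibling_pairs:
        partner[a], partner[b] = b, a
    mult = np.ones((cfg.n_genes, len(sample_ids)))
    for s, c in enumerate(sample_class):
        rows = [gene_index[g] for g in marker_map[c]]
        mult[rows, s] = 2.0 ** cfg.marker_log2_fc
        # shared organ biology: a sibling expresses its partner's remaining
        # markers at a fraction of the full effect, so the pair's profiles
        # converge as the overlap fraction grows
        if c in partner:
            cross = marker_map[partner[c]] - marker_map[c]
            rows = [gene_index[g] for g in cross]
            mult[rows, s] = 2.0 ** (cfg.marker_overlap_fraction * cfg.marker_log2_fc)
    mean = baseline[:, None] * mult * depth[None, :]

    if cfg.dispersion == 0:
        counts = rng.poisson(mean).astype(float)
    else:
        size = 1.0 / cfg.dispersion  # NB "number of successes" parameter
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p).astype(float)

    table = ExpressionTable(gene_ids, sample_ids, counts, Scale.RAW_COUNT)
    labels = LabelTable(dict(zip(sample_ids, sample_class)))
    return table, labels, SimTruth(marker_map=marker_map, sibling_pairs=sibling_pairs)


@dataclass
class RecoveryReport:
    per_class_diff_recall: dict[str, float]
    per_class_union_recall: dict[str, float]
    union_recall: float


def expected_recovery(
    cfg: SimConfig, panel: FeaturePanel, truth: SimTruth
) -> RecoveryReport:
    """Fraction of planted markers recovered in each D_i and in U."""
    union = set(panel.union)
    per_diff: dict[str, float] = {}
    per_union: dict[str, float] = {}
    all_markers: set[str] = set()
    for c, markers in truth.marker_map.items():
        all_markers |= markers
        d = set(panel.difference_sets.get(c, []))
        per_diff[c] = len(markers & d) / len(markers) if markers else 0.0
        per_union[c] = len(markers & union) / len(markers) if markers else 0.0
    union_recall = len(all_markers & union) / len(all_markers) if all_markers else 0.0
    return RecoveryReport(
        per_class_diff_recall=per_diff,
        per_class_union_recall=per_union,
        union_recall=union_recall,
    )
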