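"""Set-difference marker-panel construction.

For each class i, rank its one-vs-rest DE results by signed log2 fold change
and keep the top-k list S_i. The class's difference set is

    D_i = S_i - (S_i intersect union_{j != i} S_j),

i.e. the genes in S_i that appear in no other class's top-k list. The final
feature panel is the union U of all D_i. Because each D_i excludes every
gene present in any other S_j (and D_j is a subset of S_j), the D_i are
pairwise disjoint and |U| = sum_i |D_i|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_io import load_json_artifact, save_json_artifact
from .diffexp import DERecord


@dataclass
class TopKList:
    class_label: str
    k: int
    genes: list[str]

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if len(self.genes) > self.k:
            raise ValueError("top-k list longer than k")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in top-k list")


@dataclass
class FeaturePanel:
    """Per-class top-k lists S_i, difference sets D_i, and their union U."""

    k: int
    top_k: dict[str, TopKList]
    difference_sets: dict[str, list[str]] = field(default_factory=dict)
    union: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for label in sorted(self.difference_sets):
            d = set(self.difference_sets[label])
            s = set(self.top_k[label].genes)
            if not d <= s:
                raise AssertionError(f"D_{label} not a subset of S_{label}")
            if d & seen:
                raise AssertionError(f"D_{label} overlaps another difference set")
            seen |= d
        if seen != set(self.union) or len(self.union) != sum(
            len(d) for d in self.difference_sets.values()
        ):
            raise AssertionError("union does not equal the disjoint union of the D_i")


def rank_top_k(
    records: list[DERecord],
    k: int,
    padj_cutoff: float | None = 0.05,
    min_log2_fc: float | None = 0.0,
) -> TopKList:
    """Top-k genes by signed log2FC (up-regulated first).

    Records are optionally filtered to ``p_adjusted <= padj_cutoff`` and to
    ``log2_fc > min_log2_fc`` first; ties on log2FC break by smaller
    p-value, then lexicographic gene id. Returns fewer than k genes when
    fewer survive the filters.

    The default ``min_log2_fc = 0`` keeps the list to genuinely
    over-expressed genes: a class marker is a gene elevated *in* the class,
    and letting down-regulated genes pad a short list would only evict other
    classes' markers from their difference sets. Pass ``None`` for the pure
    signed ranking.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if padj_cutoff is not None and not 0 < padj_cutoff <= 1:
        raise ValueError("padj_cutoff must be in (0, 1]")
    pool = records
    if padj_cutoff is not None:
        pool = [r for r in pool if r.p_adjusted <= padj_cutoff]
    if min_log2_fc is not None:
        pool = [r for r in pool if r.log2_fc > min_log2_fc]
    ordered = sorted(pool, key=lambda r: (-r.log2_fc, r.p_value, r.gene_id))
    genes = [r.gene_id for r in ordered[:k]]
    label = ""  # caller attaches the class label via build helpers
    return TopKList(class_label=label, k=k, genes=genes)


def rank_top_k_for_class(
    records: list[DERecord],
    class_label: str,
    k: int,
    padj_cutoff: float | None = 0.05,
    min_log2_fc: float | None = 0.0,
) -> TopKList:
    lst = rank_top_k(records, k, padj_cutoff, min_log2_fc)
    lst.class_label = class_label
    return lst


def build_difference_sets(top_k: dict[str, TopKList]) -> dict[str, list[str]]:
    """D_i = S_i minus every gene in any other class's top-k list; each D_i
    keeps S_i's internal order."""
    if len(top_k) < 2:
        raise ValueError("difference sets need at least 2 classes")
    diffs: dict[str, list[str]] = {}
    for label, lst in top_k.items():
        others: set[str] = set()
        for other_label, other in top_k.items():
            if other_label != label:
                others.update(other.genes)
        diffs[label] = [g for g in lst.genes if g not in others]
    return diffs


def build_panel(top_k: dict[str, TopKList], k: int) -> FeaturePanel:
    """Assemble the full panel; U orders classes lexicographically and genes
    by their within-class rank. Raises when U is empty."""
    diffs = build_difference_sets(top_k)
    union: list[str] = []
    for label in sorted(diffs):
        union.extend(diffs[label])
    if not union:
        raise ValueError(
            "feature panel is empty: every top-k gene is shared between classes; "
            "try a larger k or check class separability"
        )
    panel = FeaturePanel(k=k, top_k=dict(top_k), difference_sets=diffs, union=union)
    panel.validate()
    return panel


def save_panel(panel: FeaturePanel, path) -> None:
    payload = {
        "k": panel.k,
        "classes": [
            {
                "label": label,
                "S": panel.top_k[label].genes,
                "D": panel.difference_sets[label],
            }
            for label in sorted(panel.top_k)
        ],
        "union": panel.union,
    }
    save_json_artifact(payload, "feature_panel", path)


def load_panel(path) -> FeaturePanel:
    doc = load_json_artifact(path, "feature_panel")
    top_k = {
        c["label"]: TopKList(c["label"], doc["k"], list(c["S"])) for c in doc["classes"]
    }
    diffs = {c["label"]: list(c["D"]) for c in doc["classes"]}
    panel = FeaturePanel(k=doc["k"], top_k=top_k, difference_sets=diffs, union=list(doc["union"]))
    panel.validate()
    return panel
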