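"""Expression preprocessing: zero-fraction gene filtering, log2 transform,
and gene-set harmonization across tables.

The pipeline order is normalize (upstream, e.g. RSEM) -> zero-filter ->
log2 -> intersect gene sets; filtering therefore only accepts pre-log
scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionTable, Scale


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    max_zero_fraction
        Genes with a zero fraction *strictly greater* than this are dropped
        ("over 25% zeros" by default).
    pseudocount
        Offset added before log2 so zeros map to log2(pseudocount); the
        default +1 maps 0 -> 0.
    """

    max_zero_fraction: float = 0.25
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def filter_zero_genes(
    table: ExpressionTable, cfg: PreprocessConfig | None = None
) -> ExpressionTable:
    """Drop genes whose zero fraction across all samples exceeds the threshold.

    Genes with exactly the threshold fraction of zeros are retained; gene
    order is preserved. Raises if every gene would be removed.
    """
    cfg = cfg or PreprocessConfig()
    if table.scale == Scale.LOG2:
        raise ValueError("zero filtering operates on the pre-log scale")
    zero_frac = (table.values == 0).mean(axis=1)
    keep = zero_frac <= cfg.max_zero_fraction
    if not keep.any():
        raise ValueError(
            "all genes exceed the zero-fraction threshold "
            f"({cfg.max_zero_fraction}); raise max_zero_fraction"
        )
    genes = [g for g, k in zip(table.gene_ids, keep) if k]
    return ExpressionTable(genes, list(table.sample_ids), table.values[keep], table.scale)


def log2_transform(
    table: ExpressionTable, cfg: PreprocessConfig | None = None
) -> ExpressionTable:
    """Apply ``log2(x + pseudocount)`` elementwise and tag the scale."""
    cfg = cfg or PreprocessConfig()
    if table.scale == Scale.LOG2:
        raise ValueError("table is already log2-scaled; refusing double transform")
    values = np.log2(table.values + cfg.pseudocount)
    return ExpressionTable(list(table.gene_ids), list(table.sample_ids), values, Scale.LOG2)


def harmonize_genes(tables: list[ExpressionTable]) -> list[ExpressionTable]:
    """Restrict every table to the common gene set, rows in sorted order."""
    if not tables:
        raise ValueError("need at least one table")
    common: set[str] = set(tables[0].gene_ids)
    for t in tables[1:]:
        common &= set(t.gene_ids)
    if not common:
        raise ValueError("gene intersection across tables is empty")
    order = sorted(common)
    return [t.subset_genes(order) for t in tables]
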