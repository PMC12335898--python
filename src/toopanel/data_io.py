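"""On-disk artifacts: expression tables, label tables, panels, models, metrics.

File dialect is tab-separated UTF-8 with genes as rows (the shape RSEM
gene-level output comes in); matrices are transposed to samples x features
only at model-fitting time. JSON artifacts carry a ``schema_version`` field
and refuse to load on a version mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


class Scale(str, Enum):
    """Value scale of an expression matrix."""

    RAW_COUNT = "raw_count"
    NORMALIZED = "normalized"
    LOG2 = "log2"


class FormatError(ValueError):
    """A file violates the documented dialect or an invariant."""


@dataclass
class ExpressionTable:
    """Dense gene x sample expression matrix with an explicit value scale.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique, ordered identifiers for rows and columns.
    values
        Non-negative float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        One of :class:`Scale`; log2 values follow the log2(x+1) convention,
        so they are non-negative too.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id {dup!r}")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise FormatError(
                f"NaN value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionTable":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in table: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionTable(list(genes), list(self.sample_ids), self.values[rows], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionTable(list(self.gene_ids), list(samples), self.values[:, cols], self.scale)


@dataclass
class LabelTable:
    """Sample-to-class assignment with deterministic class indexing.

    ``class_labels`` is always the lexicographically sorted list of distinct
    labels, so class indices are reproducible across runs and platforms.
    """

    assignments: dict[str, str]
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        observed = sorted(set(self.assignments.values()))
        if not self.class_labels:
            self.class_labels = observed
        else:
            missing = set(observed) - set(self.class_labels)
            if missing:
                raise FormatError(f"labels not in class_labels: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.assignments[s] for s in sample_ids]

    def samples_of(self, label: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == label]


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(path: str | Path, scale: Scale | str) -> ExpressionTable:
    """Read a tab-separated expression table (first column gene id, header row
    of sample ids) and validate it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for gi, g in enumerate(gene_ids):
            for si, s in enumerate(sample_ids):
                try:
                    float(df.iat[gi, si])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {df.iat[gi, si]!r} at gene {g!r}, sample {s!r}"
                    ) from exc
        raise FormatError(f"{path}: non-numeric values") from exc
    try:
        return ExpressionTable(gene_ids, sample_ids, values, Scale(scale))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id")


def read_labels(path: str | Path) -> LabelTable:
    """Read a two-column (sample_id, class_label) TSV, with or without the
    ``sample<TAB>label`` header line."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    if rows and rows[0] == ("sample", "label"):
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: empty label file")
    assignments: dict[str, str] = {}
    for sid, lab in rows:
        if sid in assignments:
            raise FormatError(f"{path}: duplicate sample id {sid!r}")
        assignments[sid] = lab
    return LabelTable(assignments)


def write_labels(labels: LabelTable, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("sample\tlabel\n")
        for sid, lab in labels.assignments.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Generic JSON artifact envelope
# ---------------------------------------------------------------------------

def save_json_artifact(payload: Mapping[str, Any], artifact_type: str, path: str | Path) -> None:
    """Write a JSON artifact wrapped in a versioned envelope.

    Output is byte-deterministic: keys sorted, fixed separators, trailing
    newline. Float values use Python's shortest-repr, which round-trips
    exactly.
    """
    doc = {"schema_version": SCHEMA_VERSION, "artifact_type": artifact_type}
    doc.update(payload)
    text = json.dumps(doc, sort_keys=True, indent=1, separators=(",", ": "))
    Path(path).write_text(text + "\n", encoding="utf-8")


def load_json_artifact(path: str | Path, artifact_type: str) -> dict[str, Any]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema_version {version!r} != supported {SCHEMA_VERSION}"
        )
    found = doc.get("artifact_type")
    if found != artifact_type:
        raise FormatError(f"{path}: artifact_type {found!r}, expected {artifact_type!r}")
    return doc
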