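"""Compare two classified expression datasets gene-by-gene.

Genes are matched by exact, case-sensitive identifier equality.  The
common genes carry both datasets' statistics and classes side by side; a
3x3 contingency table cross-counts their expression classes (rows =
dataset 1, columns = dataset 2, both in the fixed order downregulated /
not differentially expressed / upregulated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from degscope.deg_classify import CLASS_ORDER, ClassifiedTable

logger = logging.getLogger(__name__)

#: fixed axis order for contingency rows and columns
AXIS_LABELS = [c.value for c in CLASS_ORDER]


@dataclass
class MergedTable:
    """Inner join of two classified tables on gene id.

    ``rows`` covers exactly the common genes, in dataset-1 order, with
    columns ``gene_id``, ``log_fc_1``, ``p_value_1``, ``expression_class_1``
    and the ``_2`` counterparts.  Genes found in only one dataset are kept
    as id sets.
    """

    rows: pd.DataFrame
    only_in_1: set[str] = field(default_factory=set)
    only_in_2: set[str] = field(default_factory=set)
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ContingencyTable:
    """3x3 cross-classification counts of the common genes."""

    counts: np.ndarray  # shape (3, 3), rows = dataset 1 class, cols = dataset 2
    row_axis: list[str] = field(default_factory=lambda: list(AXIS_LABELS))
    col_axis: list[str] = field(default_factory=lambda: list(AXIS_LABELS))

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.row_axis, columns=self.col_axis)
        frame.index.name = "data1_expression"
        frame.columns.name = "data2_expression"
        return frame


def _normalize_ids(series: pd.Series, normalize: str | None) -> pd.Series:
    if normalize is None:
        return series
    if normalize == "upper":
        return series.str.upper()
    raise ValueError(f"unknown id normalization: {normalize!r}")


def merge_datasets(
    t1: ClassifiedTable, t2: ClassifiedTable, normalize_ids: str | None = None
) -> MergedTable:
    """Join two classified tables on gene id.

    Both tables must have been classified with the same alpha.  Matching is
    exact string equality by default; ``normalize_ids="upper"`` upper-cases
    ids on both sides first.  An empty intersection is a warning, not an
    error.
    """
    if t1.alpha != t2.alpha:
        raise ValueError(
            f"tables classified with different alphas ({t1.alpha} vs {t2.alpha})"
        )
    cols = ["gene_id", "log_fc", "p_value", "expression_class"]
    f1 = t1.frame[cols].copy()
    f2 = t2.frame[cols].copy()
    f1["gene_id"] = _normalize_ids(f1["gene_id"], normalize_ids)
    f2["gene_id"] = _normalize_ids(f2["gene_id"], normalize_ids)

    merged = f1.merge(f2, on="gene_id", how="inner", suffixes=("_1", "_2"))
    ids1, ids2 = set(f1["gene_id"]), set(f2["gene_id"])
    if merged.empty:
        logger.warning("no common genes between %s and %s", t1.source_label, t2.source_label)
    return MergedTable(
        rows=merged.reset_index(drop=True),
        only_in_1=ids1 - ids2,
        only_in_2=ids2 - ids1,
        alpha=t1.alpha,
    )


def contingency_table(merged: MergedTable) -> ContingencyTable:
    """Cross-count expression classes of the common genes."""
    counts = np.zeros((3, 3), dtype=int)
    index = {label: i for i, label in enumerate(AXIS_LABELS)}
    for c1, c2 in zip(merged.rows["expression_class_1"], merged.rows["expression_class_2"]):
        counts[index[c1], index[c2]] += 1
    return ContingencyTable(counts=counts)


def write_comparison(merged: MergedTable, table: ContingencyTable, outdir) -> dict[str, Path]:
    """Write the combined per-gene CSV, the contingency CSV, and the
    per-dataset specific-gene lists; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "combined": outdir / "combined.csv",
        "contingency": outdir / "contingency.csv",
        "only_in_1": outdir / "only_in_dataset1.csv",
        "only_in_2": outdir / "only_in_dataset2.csv",
    }
    merged.rows.to_csv(paths["combined"], index=False)
    table.to_frame().to_csv(paths["contingency"])
    pd.DataFrame({"gene_id": sorted(merged.only_in_1)}).to_csv(paths["only_in_1"], index=False)
    pd.DataFrame({"gene_id": sorted(merged.only_in_2)}).to_csv(paths["only_in_2"], index=False)
    return paths
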