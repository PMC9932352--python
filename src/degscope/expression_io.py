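"""Read, validate, and write per-gene expression CSV tables.

An expression table is the processed output of an upstream differential
expression analysis: one row per gene with an identifier, a log2 fold
change, and a p-value.  No statistics are computed here — rows are parsed,
invalid ones dropped with a warning, and duplicate gene ids rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default CSV header names for the three column roles
DEFAULT_COLUMN_MAP = {"gene_id": "GeneID", "log_fc": "log2FC", "p_value": "pvalue"}

#: internal canonical column order
_CANONICAL = ["gene_id", "log_fc", "p_value"]


@dataclass
class ExpressionTable:
    """One dataset of per-gene expression records.

    ``frame`` holds columns ``gene_id`` (string), ``log_fc`` (float), and
    ``p_value`` (float in [0, 1]); rows keep file order.  ``n_dropped``
    counts rows discarded at read time for missing or unparseable values.
    """

    frame: pd.DataFrame
    source_label: str = ""
    n_dropped: int = 0
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()


class DuplicateGeneIDError(ValueError):
    """Raised when a table contains the same gene id on more than one row."""


def _validate_frame(frame: pd.DataFrame, source: str) -> None:
    if frame.empty:
        raise ValueError(f"{source}: no valid expression records after filtering")
    bad_p = frame[(frame["p_value"] < 0) | (frame["p_value"] > 1)]
    if len(bad_p):
        raise ValueError(
            f"{source}: {len(bad_p)} p-values outside [0, 1] "
            f"(first offending gene: {bad_p.iloc[0]['gene_id']})"
        )


def read_expression_table(
    path,
    column_map: dict | None = None,
    dedupe: str = "error",
    source_label: str | None = None,
) -> ExpressionTable:
    """Read an expression CSV into an :class:`ExpressionTable`.

    Parameters
    ----------
    path
        CSV file with a header row.  Comma-separated, UTF-8.
    column_map
        Maps the roles ``gene_id``, ``log_fc``, ``p_value`` to header names;
        defaults to ``GeneID``, ``log2FC``, ``pvalue``.
    dedupe
        ``"error"`` (default) raises on duplicate gene ids;
        ``"keep-min-p"`` keeps, per gene, the row with the smallest p-value.

    Rows whose fold change or p-value is missing or unparseable are dropped
    with a logged warning; the dropped count is reported on the result.
    Out-of-range p-values (outside [0, 1]) are an error, not a drop: they
    indicate a mis-mapped column rather than a sporadic bad row.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ValueError(f"unknown column roles: {sorted(unknown)}")
        cmap.update(column_map)
    label = source_label if source_label is not None else str(path)

    raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = [h for h in cmap.values() if h not in raw.columns]
    if missing:
        raise ValueError(
            f"{label}: missing expected column(s) {missing}; found {list(raw.columns)}"
        )

    frame = pd.DataFrame(
        {
            "gene_id": raw[cmap["gene_id"]].astype(str).str.strip(),
            "log_fc": pd.to_numeric(raw[cmap["log_fc"]], errors="coerce"),
            "p_value": pd.to_numeric(raw[cmap["p_value"]], errors="coerce"),
        }
    )
    valid = (
        frame["gene_id"].ne("")
        & frame["gene_id"].notna()
        & np.isfinite(frame["log_fc"].to_numpy(dtype=float, na_value=np.nan))
        & np.isfinite(frame["p_value"].to_numpy(dtype=float, na_value=np.nan))
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing/unparseable values", label, n_dropped)
    frame = frame[valid].reset_index(drop=True)

    dup_mask = frame["gene_id"].duplicated(keep=False)
    if dup_mask.any():
        dups = sorted(frame.loc[dup_mask, "gene_id"].unique())
        if dedupe == "error":
            raise DuplicateGeneIDError(
                f"{label}: duplicate gene id(s) {dups[:5]}{'...' if len(dups) > 5 else ''}; "
                "pass dedupe='keep-min-p' to aggregate by minimum p-value"
            )
        elif dedupe == "keep-min-p":
            order = frame.index
            frame = (
                frame.loc[frame.groupby("gene_id", sort=False)["p_value"].idxmin()]
                .sort_index()
                .reset_index(drop=True)
            )
            logger.warning(
                "%s: collapsed %d duplicate gene id(s) keeping minimum p-value", label, len(dups)
            )
            del order
        else:
            raise ValueError(f"unknown dedupe policy: {dedupe!r}")

    _validate_frame(frame, label)
    return ExpressionTable(frame=frame, source_label=label, n_dropped=n_dropped, column_map=cmap)


def write_expression_table(table, path) -> None:
    """Write a table back to CSV using its original header names.

    Accepts an :class:`ExpressionTable` or a classified table (any object
    with ``frame`` and ``column_map``); extra columns such as
    ``expression_class`` and ``neg_log10_p`` are appended after the three
    mapped columns under their internal names.
    """
    frame = table.frame
    if frame.empty:
        raise ValueError("refusing to write an empty expression table")
    cmap = getattr(table, "column_map", DEFAULT_COLUMN_MAP)
    out = frame.rename(columns={role: header for role, header in cmap.items()})
    out.to_csv(path, index=False, encoding="utf-8")
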