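"""Three-way expression classification and volcano-plot coordinates.

A gene is called differentially expressed when its p-value falls strictly
below the significance threshold alpha (default 5%); the sign of the log2
fold change then splits the calls into up- and down-regulated.  Boundary
cases the rules leave open are resolved conservatively: p exactly equal to
alpha is not significant, and a significant gene with a fold change of
exactly zero is left unclassified as differentially expressed (warned).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from degscope.expression_io import DEFAULT_COLUMN_MAP, ExpressionTable

logger = logging.getLogger(__name__)

#: p-values of exactly zero are clipped to this floor for the volcano
#: y-axis only; classification always uses the raw p-value.
P_FLOOR = 1e-300

DEFAULT_ALPHA = 0.05


class ExpressionClass(str, enum.Enum):
    """The three-way expression call for one gene."""

    UP = "Upregulated"
    DOWN = "Downregulated"
    NOT_DE = "Not differentially expressed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed class order used for contingency axes and summaries
CLASS_ORDER = [ExpressionClass.DOWN, ExpressionClass.NOT_DE, ExpressionClass.UP]


@dataclass
class ClassifiedTable:
    """An expression table with per-gene class and volcano y-coordinate.

    ``frame`` extends the parent table's columns with ``expression_class``
    (the class label string) and ``neg_log10_p`` (= -log10(max(p, floor))).
    """

    frame: pd.DataFrame
    alpha: float
    source_label: str = ""
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))

    def __len__(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        """Counts per class label, zero-filled, in down/not-DE/up order."""
        vc = self.frame["expression_class"].value_counts()
        return {c.value: int(vc.get(c.value, 0)) for c in CLASS_ORDER}

    def genes_in_class(self, cls: ExpressionClass) -> set[str]:
        mask = self.frame["expression_class"] == cls.value
        return set(self.frame.loc[mask, "gene_id"])


def classify_gene(p: float, log_fc: float, alpha: float = DEFAULT_ALPHA) -> ExpressionClass:
    """Classify one gene from its p-value and log2 fold change.

    Rules: p >= alpha -> not differentially expressed; p < alpha with a
    positive fold change -> upregulated; p < alpha with a negative fold
    change -> downregulated.  p < alpha with log_fc == 0 is classed as not
    differentially expressed (direction is undefined) with a warning.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    if not (math.isfinite(p) and math.isfinite(log_fc)):
        raise ValueError(f"non-finite input: p={p}, log_fc={log_fc}")
    if not (0 <= p <= 1):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p >= alpha:
        return ExpressionClass.NOT_DE
    if log_fc > 0:
        return ExpressionClass.UP
    if log_fc < 0:
        return ExpressionClass.DOWN
    logger.warning("significant p=%g with zero log fold change; classed as not DE", p)
    return ExpressionClass.NOT_DE


def classify_table(table: ExpressionTable, alpha: float = DEFAULT_ALPHA) -> ClassifiedTable:
    """Classify every record of a table; vectorized equivalent of
    :func:`classify_gene` applied row-wise."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    frame = table.frame.copy()
    p = frame["p_value"].to_numpy(dtype=float)
    lfc = frame["log_fc"].to_numpy(dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(lfc).all()):
        raise ValueError("non-finite p-value or fold change in table")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-value outside [0, 1] in table")

    sig = p < alpha
    classes = np.where(
        sig & (lfc > 0),
        ExpressionClass.UP.value,
        np.where(sig & (lfc < 0), ExpressionClass.DOWN.value, ExpressionClass.NOT_DE.value),
    )
    n_zero_sig = int((sig & (lfc == 0)).sum())
    if n_zero_sig:
        logger.warning(
            "%d significant gene(s) with zero log fold change classed as not DE", n_zero_sig
        )
    frame["expression_class"] = classes
    frame["neg_log10_p"] = -np.log10(np.maximum(p, P_FLOOR))
    return ClassifiedTable(
        frame=frame,
        alpha=alpha,
        source_label=table.source_label,
        column_map=dict(table.column_map),
    )


def volcano_coordinates(table: ClassifiedTable) -> list[tuple[float, float, str]]:
    """Per-gene volcano points: (log2 fold change, -log10 p, class label)."""
    frame = table.frame
    return list(
        zip(
            frame["log_fc"].astype(float),
            frame["neg_log10_p"].astype(float),
            frame["expression_class"],
        )
    )
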