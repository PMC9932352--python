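"""Volcano plot and per-(direction, namespace) ontology barplots."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only; no display required
import matplotlib.pyplot as plt

from degscope.enrichment import EnrichmentRun
from degscope.go_ontology import NAMESPACES

logger = logging.getLogger(__name__)

CLASS_COLORS = {
    "Upregulated": "#d62728",
    "Downregulated": "#1f77b4",
    "Not differentially expressed": "#7f7f7f",
}

#: short namespace tags used in barplot filenames and titles
NAMESPACE_TAGS = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

DEFAULT_MAX_TERMS = 20


@dataclass
class PlotSpec:
    """Shared rendering options for the figures."""

    title: str = ""
    fmt: str = "png"
    dpi: int = 150

    def check_outfile(self, path: Path) -> None:
        if path.suffix.lstrip(".") != self.fmt:
            raise ValueError(f"outfile {path} does not match format {self.fmt!r}")


def render_volcano(
    points,
    outfile,
    alpha: float = 0.05,
    spec: PlotSpec | None = None,
) -> Path:
    """Scatter log2 fold change (x) against -log10 p (y), colored by class.

    A horizontal guide line marks the significance threshold at
    y = -log10(alpha).  ``points`` are (x, y, class-label) triples from
    :func:`degscope.deg_classify.volcano_coordinates`.
    """
    points = list(points)
    if not points:
        raise ValueError("cannot render a volcano plot from zero points")
    spec = spec or PlotSpec()
    outfile = Path(outfile)
    spec.check_outfile(outfile)

    import math

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, color in CLASS_COLORS.items():
        xs = [x for x, _, c in points if c == label]
        ys = [y for _, y, c in points if c == label]
        if xs:
            ax.scatter(xs, ys, s=8, c=color, label=label, alpha=0.7, linewidths=0)
    ax.axhline(-math.log10(alpha), color="black", linestyle="--", linewidth=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    ax.set_title(spec.title or "Volcano plot")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(outfile, dpi=spec.dpi)
    plt.close(fig)
    return outfile


def render_ontology_barplots(
    run: EnrichmentRun,
    outdir,
    spec: PlotSpec | None = None,
    max_terms: int = DEFAULT_MAX_TERMS,
) -> list[Path]:
    """One horizontal barplot per non-empty (direction, namespace) group.

    ``run`` should already be filtered to significant terms.  The y-axis
    lists term names; the x-axis is the percentage of the direction's
    genes annotated to each term, bars sorted by descending percentage.
    At most ``max_terms`` terms (by ascending p-value) are drawn per plot.
    Files are named ``{direction}_{namespace}.{fmt}``; a group with no
    significant terms produces a logged notice instead of a file.
    """
    spec = spec or PlotSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for direction in ("up", "down"):
        for namespace in NAMESPACES:
            results = run.group(direction, namespace)
            if not results:
                logger.info(
                    "no significant %s terms for %s-regulated genes; no barplot",
                    NAMESPACE_TAGS[namespace],
                    direction,
                )
                continue
            shown = sorted(results, key=lambda r: (r.p_value, r.term_id))[:max_terms]
            shown = sorted(shown, key=lambda r: r.percent)  # ascending -> largest bar on top
            names = [r.term_name for r in shown]
            percents = [r.percent for r in shown]

            fig, ax = plt.subplots(figsize=(7, max(2.0, 0.35 * len(shown) + 1.2)))
            ax.barh(range(len(shown)), percents, color="#2ca02c")
            ax.set_yticks(range(len(shown)))
            ax.set_yticklabels(names, fontsize=8)
            ax.set_xlabel(f"% of {direction}-regulated genes")
            ax.set_title(
                spec.title
                or f"Significant {NAMESPACE_TAGS[namespace]} terms, {direction}-regulated genes"
            )
            fig.tight_layout()
            outfile = outdir / f"{direction}_{namespace}.{spec.fmt}"
            fig.savefig(outfile, dpi=spec.dpi)
            plt.close(fig)
            written.append(outfile)
    return written
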