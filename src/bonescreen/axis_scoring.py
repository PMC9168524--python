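"""Marker-panel Spearman scoring of candidate genes.

For each (gene, axis) pair the gene's expression is correlated (Spearman,
over all samples of the supplied matrix) with every available marker of the
axis panel, and the coefficients are summed into the axis score. Markers
absent from the cohort reduce the marker count rather than contributing a
zero; a gene overlapping its own panel is never correlated with itself.

Cross-axis comparison (top-axis classification) normalises the summed score
by the number of markers actually used, because the five panels differ in
size; ties break on the fixed axis order HOMING, IMMUNE_ESCAPE,
ANGIOGENESIS, OSTEOCLASTIC, OSTEOBLASTIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AXIS_ORDER,
    MARKER_ALIASES,
    ExpressionMatrix,
    MarkerPanel,
    ValidationError,
)
from .stats_core import UndefinedCorrelationError, spearman

__all__ = [
    "AxisScoreRecord",
    "BubbleTable",
    "resolve_marker",
    "axis_score",
    "score_all",
    "rank_by_axis",
    "classify_top_axis",
    "export_bubble",
    "write_bubble",
    "read_bubble",
    "write_marker_table",
]

logger = logging.getLogger(__name__)

# symbol -> synonyms, in both directions
_ALIAS_LOOKUP: dict[str, tuple[str, ...]] = {}
for _primary, _alts in MARKER_ALIASES.items():
    _ALIAS_LOOKUP[_primary] = _alts
    for _a in _alts:
        _ALIAS_LOOKUP[_a] = (_primary,)


@dataclass(frozen=True)
class AxisScoreRecord:
    """Per-gene, per-axis marker correlations and their sum."""

    gene: str
    axis: str
    marker_rhos: dict  # marker symbol -> (rho, p_value)
    summed_score: float
    n_markers_used: int
    missing_markers: tuple


@dataclass(frozen=True)
class BubbleTable:
    """Long-format (gene, axis) table behind the overall-correlation bubble plot."""

    rows: pd.DataFrame  # columns: gene, axis, summed_score, n_significant


def resolve_marker(symbol: str, available: set) -> str | None:
    """Map a panel marker symbol onto a matrix row, trying known synonyms."""
    symbol = symbol.upper()
    if symbol in available:
        return symbol
    for alt in _ALIAS_LOOKUP.get(symbol, ()):
        if alt in available:
            return alt
    return None


def axis_score(
    gene: str, matrix: ExpressionMatrix, panel: MarkerPanel
) -> AxisScoreRecord:
    """Spearman correlation of one gene against one axis panel.

    The summed score is the plain sum of all available marker rhos (no
    significance filter). Markers missing from the matrix — or degenerate
    (constant) — are recorded in ``missing_markers``, never imputed.
    """
    gene = gene.upper()
    gvec = matrix.gene(gene)
    available = set(matrix.gene_ids)
    rhos: dict = {}
    missing: list[str] = []
    for marker in panel.genes:
        row = resolve_marker(marker, available)
        if row is None or row == gene or marker == gene:
            missing.append(marker)
            continue
        try:
            res = spearman(gvec, matrix.gene(row))
        except UndefinedCorrelationError:
            logger.debug("axis_score: marker %s constant, treated as unavailable", marker)
            missing.append(marker)
            continue
        rhos[marker] = (res.rho, res.p_value)
    if not rhos:
        raise ValidationError(
            f"no usable {panel.axis} markers for gene {gene} in cohort {matrix.cohort_id}"
        )
    return AxisScoreRecord(
        gene, panel.axis, rhos, float(sum(r for r, _ in rhos.values())),
        len(rhos), tuple(missing),
    )


def score_all(genes, matrix: ExpressionMatrix, panels) -> list[AxisScoreRecord]:
    """Score every (gene, axis) pair; ordering is gene-major, then panel order.

    A pair that cannot be scored (gene missing, no usable markers) is logged
    and omitted rather than aborting the run.
    """
    records: list[AxisScoreRecord] = []
    for gene in genes:
        for panel in panels:
            try:
                records.append(axis_score(gene, matrix, panel))
            except (KeyError, ValidationError) as exc:
                logger.warning("score_all: skipping (%s, %s): %s", gene, panel.axis, exc)
    return records


def rank_by_axis(records, directions: dict, axis: str, k: int, stratum: str = "UP"):
    """Top-k genes of one direction stratum for one axis.

    UP genes rank by descending summed score (strongest positive first);
    DOWN genes by ascending score (most negative first). Returns at most
    ``k`` genes; a stratum smaller than k is returned whole.
    """
    if stratum not in ("UP", "DOWN"):
        raise ValueError("stratum must be UP or DOWN")
    axis_records = [r for r in records if r.axis == axis]
    for r in axis_records:
        if r.gene not in directions:
            raise ValidationError(f"no direction for gene {r.gene}")
    chosen = [r for r in axis_records if directions[r.gene] == stratum]
    reverse = stratum == "UP"
    chosen.sort(key=lambda r: (-r.summed_score if reverse else r.summed_score, r.gene))
    return [r.gene for r in chosen[:k]]


def classify_top_axis(records) -> str:
    """Dominant axis of one gene: max |summed score| / markers used.

    Requires one record per axis (all five); exact ties resolve to the
    earlier axis in the fixed order.
    """
    by_axis = {r.axis: r for r in records}
    missing = [a for a in AXIS_ORDER if a not in by_axis]
    if missing:
        raise ValidationError(f"classify_top_axis: missing axes {missing}")
    best_axis, best_val = None, -np.inf
    for axis in AXIS_ORDER:
        r = by_axis[axis]
        val = abs(r.summed_score) / r.n_markers_used
        if val > best_val:
            best_axis, best_val = axis, val
    return best_axis


def export_bubble(records, alpha: float = 0.05) -> BubbleTable:
    """Long-format (gene, axis, summed_score, n_significant) table.

    Requires a complete gene x five-axis grid; ``n_significant`` counts
    markers with p < ``alpha``.
    """
    genes = list(dict.fromkeys(r.gene for r in records))
    by_key = {(r.gene, r.axis): r for r in records}
    rows = []
    for gene in genes:
        for axis in AXIS_ORDER:
            r = by_key.get((gene, axis))
            if r is None:
                raise ValidationError(f"export_bubble: incomplete grid at ({gene}, {axis})")
            rows.append(
                {
                    "gene": gene,
                    "axis": axis,
                    "summed_score": r.summed_score,
                    "n_significant": sum(p < alpha for _, p in r.marker_rhos.values()),
                }
            )
    return BubbleTable(pd.DataFrame(rows))


def write_bubble(table: BubbleTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bubble(path) -> BubbleTable:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "axis", "summed_score", "n_significant"}
    if not required.issubset(df.columns):
        raise ValidationError(f"bubble table missing columns {required - set(df.columns)}")
    return BubbleTable(df)


def write_marker_table(records, path) -> None:
    """Long-format per-marker table (gene, axis, marker, rho, p) for heatmaps."""
    rows = [
        {"gene": r.gene, "axis": r.axis, "marker": m, "rho": rho, "p_value": p}
        for r in records
        for m, (rho, p) in r.marker_rhos.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
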