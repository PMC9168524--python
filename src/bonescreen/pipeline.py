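"""End-to-end orchestration of the predisposition and adaptive screens.

The predisposition screen chains the cascade over a discovery and a
validation cohort:

1. per-cohort DEG contrasts (distant-vs-none, bone-vs-none, other-vs-none);
2. cross-cohort intersection of the bone contrast with direction concordance;
3. exclusion of genes that are other-site-metastasis DEGs in either cohort;
4. bone-metastasis-free-survival screen on the discovery cohort;
5. five-axis marker-panel scoring of the survivors.

Results are collected in a :class:`RunSummary` whose stage counts are
non-increasing along the cascade within each direction stratum; with an
output directory the summary JSON and the stage TSV tables are written to
disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .axis_scoring import (
    classify_top_axis,
    export_bubble,
    rank_by_axis,
    score_all,
    write_bubble,
    write_marker_table,
)
from .deg_screen import (
    CandidateGene,
    adaptive_degs,
    bone_specific,
    intersect_concordant,
    run_contrast,
)
from .io_formats import (
    AXIS_ORDER,
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    default_panels,
)
from .survival_filter import survival_screen

__all__ = ["RunConfig", "RunSummary", "run_predisposition", "run_adaptive"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based run configuration (used by the command-line interface)."""

    discovery_expression: str | None = None
    discovery_clinical: str | None = None
    validation_expression: str | None = None
    validation_clinical: str | None = None
    adaptive_expression: str | None = None
    adaptive_clinical: str | None = None
    panels_gmt: str | None = None  # None -> built-in default panels
    alpha: float = 0.05
    alpha_norm: float = 0.05
    bh: bool = False
    cut: str = "median"
    strict_panels: bool = False
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0 < self.alpha_norm < 1):
            raise ValidationError(f"alpha_norm must be in (0,1), got {self.alpha_norm}")


@dataclass
class RunSummary:
    """Stage counts and result tables of one pipeline run."""

    kind: str  # "predisposition" or "adaptive"
    counts: dict
    candidates: list = field(default_factory=list)
    survival_records: list = field(default_factory=list)
    axis_records: list = field(default_factory=list)
    top_axis: dict = field(default_factory=dict)  # gene -> axis
    ranked: dict = field(default_factory=dict)  # axis -> {UP: [...], DOWN: [...]}
    config_echo: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "version": self.version,
            "counts": self.counts,
            "top_axis": self.top_axis,
            "ranked": self.ranked,
            "config": self.config_echo,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_summary.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        if self.candidates:
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "direction": c.direction,
                        "discovery_p": c.discovery_p,
                        "validation_p": c.validation_p,
                        "survival_p": c.survival_p,
                        "passed_stages": ";".join(c.passed_stages),
                    }
                    for c in self.candidates
                ]
            ).to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.17g")
        if self.survival_records:
            pd.DataFrame(
                [
                    {
                        "gene": r.gene,
                        "cutpoint": r.cutpoint,
                        "logrank_stat": r.logrank_stat,
                        "p_value": r.p_value,
                        "risk_direction": r.risk_direction,
                        "significant": r.significant,
                    }
                    for r in self.survival_records
                ]
            ).to_csv(out / "survival_screen.tsv", sep="\t", index=False, float_format="%.17g")
        if self.axis_records:
            write_marker_table(self.axis_records, out / "marker_correlations.tsv")
            genes = {r.gene for r in self.axis_records}
            complete = [
                r for r in self.axis_records
                if sum(x.gene == r.gene for x in self.axis_records) == len(AXIS_ORDER)
            ]
            if complete and len(complete) == len(genes) * len(AXIS_ORDER):
                write_bubble(export_bubble(complete), out / "bubble_table.tsv")


def _direction_counts(items, get_direction) -> dict:
    up = sum(1 for it in items if get_direction(it) == "UP")
    return {"UP": up, "DOWN": len(items) - up, "TOTAL": len(items)}


def run_predisposition(
    discovery: tuple[ExpressionMatrix, ClinicalTable],
    validation: tuple[ExpressionMatrix, ClinicalTable],
    panels=None,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    bh: bool = False,
    cut: str = "median",
    out_dir=None,
) -> RunSummary:
    """Run the full predisposition cascade over a discovery/validation pair."""
    panels = list(panels) if panels is not None else default_panels()
    d_mat, d_clin = discovery
    v_mat, v_clin = validation
    kw = dict(alpha=alpha, alpha_norm=alpha_norm, bh=bh)

    degs = {}
    for label, (mat, clin) in (("discovery", (d_mat, d_clin)), ("validation", (v_mat, v_clin))):
        for contrast in ("DISTANT_VS_NONE", "BONE_VS_NONE", "OTHER_VS_NONE"):
            degs[label, contrast] = run_contrast(mat, clin, contrast, **kw)
            logger.info("%s %s: %d DEGs", label, contrast, len(degs[label, contrast]))

    distant_validated = intersect_concordant(
        degs["discovery", "DISTANT_VS_NONE"], degs["validation", "DISTANT_VS_NONE"]
    )
    bone_candidates = intersect_concordant(
        degs["discovery", "BONE_VS_NONE"], degs["validation", "BONE_VS_NONE"]
    )
    other_union = degs["discovery", "OTHER_VS_NONE"] + degs["validation", "OTHER_VS_NONE"]
    # duplicate genes across the two cohorts are fine here: only the gene set matters
    seen: dict = {}
    other_union = [seen.setdefault(r.gene, r) for r in other_union if r.gene not in seen]
    specific = bone_specific(bone_candidates, other_union)

    surv_records = []
    survivors: list[CandidateGene] = []
    if specific:
        surv_records = survival_screen(
            d_mat, d_clin, [c.gene for c in specific], alpha=alpha, cut=cut
        )
        p_by_gene = {r.gene: r.p_value for r in surv_records}
        for c in specific:
            c.survival_p = p_by_gene.get(c.gene)
            if c.survival_p is not None and c.survival_p < alpha:
                c.passed_stages.append("survival")
                survivors.append(c)

    axis_records = []
    top_axis: dict = {}
    if survivors:
        axis_records = score_all([c.gene for c in survivors], d_mat, panels)
        for c in survivors:
            recs = [r for r in axis_records if r.gene == c.gene]
            if len(recs) == len(AXIS_ORDER):
                top_axis[c.gene] = classify_top_axis(recs)

    counts = {
        "discovery_distant": _direction_counts(
            degs["discovery", "DISTANT_VS_NONE"], lambda r: r.direction),
        "validation_distant": _direction_counts(
            degs["validation", "DISTANT_VS_NONE"], lambda r: r.direction),
        "distant_validated": _direction_counts(distant_validated, lambda c: c.direction),
        "discovery_bone": _direction_counts(
            degs["discovery", "BONE_VS_NONE"], lambda r: r.direction),
        "validation_bone": _direction_counts(
            degs["validation", "BONE_VS_NONE"], lambda r: r.direction),
        "bone_validated": _direction_counts(bone_candidates, lambda c: c.direction),
        "bone_specific": _direction_counts(specific, lambda c: c.direction),
        "survival_passed": _direction_counts(survivors, lambda c: c.direction),
    }
    summary = RunSummary(
        kind="predisposition",
        counts=counts,
        candidates=specific,
        survival_records=surv_records,
        axis_records=axis_records,
        top_axis=top_axis,
        config_echo={"alpha": alpha, "alpha_norm": alpha_norm, "bh": bh, "cut": cut},
    )
    if out_dir is not None:
        summary.write(out_dir)
    return summary


def run_adaptive(
    cohort: tuple[ExpressionMatrix, ClinicalTable],
    panels=None,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    k: int = 10,
    out_dir=None,
) -> RunSummary:
    """Adaptive-phenotype screen: double-contrast DEGs, then axis scoring."""
    panels = list(panels) if panels is not None else default_panels()
    matrix, clinical = cohort
    if not clinical.has_lesions():
        raise ValidationError("adaptive screen needs a cohort with lesion_site labels")
    up, down = adaptive_degs(matrix, clinical, alpha=alpha, alpha_norm=alpha_norm)
    directions = {r.gene: r.direction for r in up + down}
    genes = [r.gene for r in up] + [r.gene for r in down]
    axis_records = score_all(genes, matrix, panels) if genes else []
    ranked = {
        axis: {
            stratum: rank_by_axis(axis_records, directions, axis, k, stratum=stratum)
            for stratum in ("UP", "DOWN")
        }
        for axis in AXIS_ORDER
    }
    counts = {
        "adaptive_degs": {"UP": len(up), "DOWN": len(down), "TOTAL": len(up) + len(down)},
    }
    summary = RunSummary(
        kind="adaptive",
        counts=counts,
        axis_records=axis_records,
        ranked=ranked,
        config_echo={"alpha": alpha, "alpha_norm": alpha_norm, "k": k},
    )
    if out_dir is not None:
        summary.write(out_dir)
    return summary
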