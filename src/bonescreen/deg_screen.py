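"""Differential-expression stages of the screen.

Per-gene two-group testing for a contrast (with the normality-gated choice of
Student/Welch t vs Mann-Whitney), cross-cohort intersection with direction
concordance, exclusion of other-site-metastasis genes (bone specificity), and
the adaptive-lesion double contrast (bone lesion vs primary AND vs other
metastatic sites).

All thresholds are raw p < alpha by default; an optional Benjamini-Hochberg
adjustment can be switched on but is off for fidelity to the original
raw-threshold design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable, ExpressionMatrix, ValidationError
from .stats_core import gated_test

__all__ = [
    "DEGRecord",
    "CandidateGene",
    "CONTRASTS",
    "run_contrast",
    "intersect_concordant",
    "bone_specific",
    "adaptive_degs",
]

logger = logging.getLogger(__name__)

UP, DOWN = "UP", "DOWN"

#: contrast label -> (column, group-of-interest labels, reference labels)
CONTRASTS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "DISTANT_VS_NONE": ("met_status", ("BONE", "OTHER"), ("NONE",)),
    "BONE_VS_NONE": ("met_status", ("BONE",), ("NONE",)),
    "OTHER_VS_NONE": ("met_status", ("OTHER",), ("NONE",)),
    "ADAPTIVE_BONE": ("lesion_site", ("BONE_MET",), ("PRIMARY",)),
}


@dataclass(frozen=True)
class DEGRecord:
    """One gene's result for one contrast."""

    gene: str
    contrast: str
    test_used: str  # T_TEST or MANN_WHITNEY
    statistic: float
    p_value: float
    direction: str  # UP iff effect > 0
    effect: float  # mean log2 difference, group of interest - reference


@dataclass
class CandidateGene:
    """A gene surviving (a prefix of) the filtering cascade."""

    gene: str
    direction: str
    discovery_p: float
    validation_p: float
    bone_p: float | None = None
    survival_p: float | None = None
    passed_stages: list = field(default_factory=list)


def _arm_masks(clinical: ClinicalTable, contrast: str, sample_ids):
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    column, interest, reference = CONTRASTS[contrast]
    if column not in clinical.data.columns:
        raise ValidationError(f"contrast {contrast} needs clinical column {column!r}")
    ann = clinical.data.set_index("sample_id")
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise ValidationError(
            f"matrix samples absent from clinical table: {missing[:10]}"
        )
    status = ann.loc[list(sample_ids), column]
    mask_i = status.isin(interest).to_numpy()
    mask_r = status.isin(reference).to_numpy()
    return mask_i, mask_r


def run_contrast(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    contrast: str,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    equal_var: bool = False,
    bh: bool = False,
    return_all: bool = False,
) -> list[DEGRecord]:
    """Per-gene differential expression for one contrast.

    Each gene is tested with the normality-gated two-group test; genes with
    (adjusted) p < ``alpha`` are returned, direction taken from the sign of
    the mean log2 difference (interest - reference). Genes constant in both
    arms are skipped and logged. ``return_all`` keeps non-significant records
    too (used for diagnostics).
    """
    mask_i, mask_r = _arm_masks(clinical, contrast, matrix.sample_ids)
    n_i, n_r = int(mask_i.sum()), int(mask_r.sum())
    if n_i < 3 or n_r < 3:
        raise ValidationError(
            f"contrast {contrast} needs >=3 samples per arm, got {n_i} vs {n_r}"
        )
    values = matrix.values.to_numpy()
    records: list[DEGRecord] = []
    skipped = 0
    for gi, gene in enumerate(matrix.gene_ids):
        a = values[gi, mask_i]
        b = values[gi, mask_r]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            skipped += 1
            logger.debug("run_contrast(%s): gene %s constant in both arms, skipped", contrast, gene)
            continue
        res, used = gated_test(a, b, alpha_norm=alpha_norm, equal_var=equal_var)
        effect = float(a.mean() - b.mean())
        records.append(
            DEGRecord(gene, contrast, used, res.statistic, res.p_value,
                      UP if effect > 0 else DOWN, effect)
        )
    if skipped:
        logger.info("run_contrast(%s): skipped %d zero-variance genes", contrast, skipped)
    if bh and records:
        adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        records = [replace(r, p_value=float(q)) for r, q in zip(records, adj)]
    if return_all:
        return records
    return [r for r in records if r.p_value < alpha]


def intersect_concordant(
    deg_a: list[DEGRecord], deg_b: list[DEGRecord]
) -> list[CandidateGene]:
    """Genes significant in both cohorts with the same direction.

    Discordant-direction genes and genes present in only one list are dropped
    with a logged count. Duplicate genes within one input list are an error.
    The first list provides ``discovery_p``, the second ``validation_p``.
    """
    by_a = {r.gene: r for r in deg_a}
    by_b = {r.gene: r for r in deg_b}
    if len(by_a) != len(deg_a) or len(by_b) != len(deg_b):
        raise ValidationError("duplicate gene within one DEG list")
    shared = [g for g in by_a if g in by_b]
    dropped_absent = len(by_a) + len(by_b) - 2 * len(shared)
    out: list[CandidateGene] = []
    discordant = 0
    for g in shared:
        ra, rb = by_a[g], by_b[g]
        if ra.direction != rb.direction:
            discordant += 1
            logger.debug("intersect: %s discordant (%s vs %s)", g, ra.direction, rb.direction)
            continue
        out.append(
            CandidateGene(g, ra.direction, ra.p_value, rb.p_value,
                          passed_stages=["discovery", "validation"])
        )
    if discordant or dropped_absent:
        logger.info(
            "intersect: %d concordant, %d discordant dropped, %d single-cohort dropped",
            len(out), discordant, dropped_absent,
        )
    return out


def bone_specific(
    bone_candidates: list[CandidateGene], other_met_degs: list[DEGRecord]
) -> list[CandidateGene]:
    """Exclude candidates that are also other-site-metastasis DEGs.

    The returned gene set is disjoint from ``other_met_degs`` genes by
    construction.
    """
    other_genes = {r.gene for r in other_met_degs}
    out = []
    for c in bone_candidates:
        if c.gene in other_genes:
            logger.debug("bone_specific: %s excluded (other-site DEG)", c.gene)
            continue
        kept = CandidateGene(c.gene, c.direction, c.discovery_p, c.validation_p,
                             bone_p=c.bone_p, survival_p=c.survival_p,
                             passed_stages=[*c.passed_stages, "bone_specific"])
        out.append(kept)
    logger.info("bone_specific: %d of %d candidates kept", len(out), len(bone_candidates))
    return out


def adaptive_degs(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    equal_var: bool = False,
) -> tuple[list[DEGRecord], list[DEGRecord]]:
    """Adaptive-phenotype DEGs: bone lesions vs primary AND vs other sites.

    A gene qualifies when it is significant (p < alpha) with the same
    direction in both contrasts BONE_MET vs PRIMARY and BONE_MET vs
    OTHER_MET. Returns ``(up, down)`` record lists; each record carries the
    BONE_MET-vs-PRIMARY effect and the larger (worst-case) of the two
    contrast p-values.
    """
    if not clinical.has_lesions():
        raise ValidationError("adaptive contrast needs a lesion_site column")
    ann = clinical.data.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise ValidationError(f"matrix samples absent from clinical table: {missing[:10]}")
    site = ann.loc[matrix.sample_ids, "lesion_site"]
    masks = {s: (site == s).to_numpy() for s in ("BONE_MET", "PRIMARY", "OTHER_MET")}
    for s, m in masks.items():
        if int(m.sum()) < 3:
            raise ValidationError(f"adaptive cohort needs >=3 {s} samples, got {int(m.sum())}")
    values = matrix.values.to_numpy()
    up: list[DEGRecord] = []
    down: list[DEGRecord] = []
    for gi, gene in enumerate(matrix.gene_ids):
        bone = values[gi, masks["BONE_MET"]]
        prim = values[gi, masks["PRIMARY"]]
        other = values[gi, masks["OTHER_MET"]]
        if np.ptp(values[gi]) == 0:
            logger.debug("adaptive_degs: gene %s constant, skipped", gene)
            continue
        res_p, used_p = gated_test(bone, prim, alpha_norm=alpha_norm, equal_var=equal_var)
        res_o, _ = gated_test(bone, other, alpha_norm=alpha_norm, equal_var=equal_var)
        if res_p.p_value >= alpha or res_o.p_value >= alpha:
            continue
        eff_p = float(bone.mean() - prim.mean())
        eff_o = float(bone.mean() - other.mean())
        if (eff_p > 0) != (eff_o > 0):
            logger.debug("adaptive_degs: %s discordant across contrasts", gene)
            continue
        rec = DEGRecord(gene, "ADAPTIVE_BONE", used_p, res_p.statistic,
                        max(res_p.p_value, res_o.p_value),
                        UP if eff_p > 0 else DOWN, eff_p)
        (up if rec.direction == UP else down).append(rec)
    logger.info("adaptive_degs: %d up, %d down", len(up), len(down))
    return up, down
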