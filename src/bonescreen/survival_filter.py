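"""Bone-metastasis-free-survival (BMFS) screen over candidate genes.

Each candidate is dichotomised at its median expression (ties to the low
arm) and the two arms compared with the log-rank test on the bone-specific
endpoint: the event is the occurrence of bone metastasis, and samples whose
distant metastasis is at another site are censored at their follow-up time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ClinicalTable, ExpressionMatrix, ValidationError
from .stats_core import km_curve, log_rank, restricted_mean

__all__ = ["SurvivalScreenRecord", "bmfs_label", "survival_screen"]

logger = logging.getLogger(__name__)

HIGH_EXPR_WORSE = "HIGH_EXPR_WORSE"
LOW_EXPR_WORSE = "LOW_EXPR_WORSE"


@dataclass(frozen=True)
class SurvivalScreenRecord:
    gene: str
    cutpoint: float
    logrank_stat: float
    p_value: float
    risk_direction: str
    n_high: int
    n_low: int
    significant: bool


def bmfs_label(clinical: ClinicalTable):
    """Bone-metastasis-free-survival labels ``(sample_ids, times, events)``.

    event = 1 iff bone metastasis occurred (met_status BONE and
    bmfs_event = 1); other-site metastases and metastasis-free samples are
    censored at their recorded time. Rows without survival data are dropped.
    """
    if not clinical.has_survival():
        raise ValidationError("clinical table lacks bmfs_time/bmfs_event columns")
    df = clinical.data.dropna(subset=["bmfs_time", "bmfs_event"])
    times = df["bmfs_time"].to_numpy(dtype=float)
    if np.any(times <= 0):
        raise ValidationError("bmfs_time must be positive")
    events = df["bmfs_event"].to_numpy(dtype=int)
    if "met_status" in df.columns:
        events = np.where(df["met_status"].to_numpy() == "BONE", events, 0)
    return list(df["sample_id"]), times, events


def _split(expr: np.ndarray, rule: str):
    """High/low masks under the chosen dichotomisation rule.

    ``median``: high = strictly above the median (ties at the median go to
    the low arm). ``quartile``: top vs bottom quartile, middle half dropped.
    """
    if rule == "median":
        cut = float(np.median(expr))
        high = expr > cut
        low = ~high
    elif rule == "quartile":
        lo_q, hi_q = np.quantile(expr, [0.25, 0.75])
        cut = float(hi_q)
        high = expr > hi_q
        low = expr <= lo_q
    else:
        raise ValueError(f"unknown cut rule {rule!r}")
    return cut, high, low


def survival_screen(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    genes,
    alpha: float = 0.05,
    cut: str = "median",
) -> list[SurvivalScreenRecord]:
    """Median-split log-rank screen of ``genes`` against BMFS.

    Returns one record per screenable gene (constant genes — one empty arm —
    are skipped with a log entry), flagged ``significant`` at p < ``alpha``.
    ``risk_direction`` compares the arms' restricted mean survival up to the
    shorter arm's last observed time.
    """
    sample_ids, times, events = bmfs_label(clinical)
    usable = [s for s in sample_ids if s in set(matrix.sample_ids)]
    if len(usable) < 4:
        raise ValidationError("survival screen needs >=4 samples with survival data")
    idx = [sample_ids.index(s) for s in usable]
    times = times[idx]
    events = events[idx]
    sub = matrix.subset_samples(usable)
    records: list[SurvivalScreenRecord] = []
    for gene in genes:
        expr = sub.gene(gene)
        cutpoint, high, low = _split(expr, cut)
        if high.sum() == 0 or low.sum() == 0:
            logger.info("survival_screen: gene %s constant at cut, skipped", gene)
            continue
        th, eh = times[high], events[high]
        tl, el = times[low], events[low]
        res = log_rank(th, eh, tl, el)
        tau = min(th.max(), tl.max())
        rm_high = restricted_mean(km_curve(th, eh), tau)
        rm_low = restricted_mean(km_curve(tl, el), tau)
        direction = HIGH_EXPR_WORSE if rm_high <= rm_low else LOW_EXPR_WORSE
        records.append(
            SurvivalScreenRecord(gene, cutpoint, res.statistic, res.p_value,
                                 direction, int(high.sum()), int(low.sum()),
                                 res.p_value < alpha)
        )
    return records
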