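"""Synthetic expression cohorts with the statistical structure the screen assumes.

The generative model is deliberately minimal: log2 expression is Gaussian
around a cohort baseline, with three optional layers planted on top of the
noise —

* class shifts: BONE_SPECIFIC genes gain a log2 shift in BONE samples only,
  PAN_METASTATIC genes in BONE and OTHER samples;
* latent axis factors: each sample draws one standard-normal factor per
  biological axis; axis marker genes load on their own axis factor with
  ``marker_loading`` and AXIS_LINKED genes with their own loading, inducing
  a closed-form marker correlation
  rho_pearson = lg*lm / sqrt((lg^2 + s^2) (lm^2 + s^2)) and, for bivariate
  normal data, rho_spearman = (6/pi) * arcsin(rho_pearson / 2);
* survival: a latent bone-metastasis time per sample, exponential with
  hazard base_hazard * exp(sum_g log_hr_g * z_g) over SURVIVAL_LINKED genes
  (z = standardised expression), under uniform administrative censoring
  calibrated to the requested censoring fraction.

Two class-assignment modes exist. The default fixes NONE/OTHER/BONE counts
and only BONE samples can experience the bone event. With
``met_from_hazard=True`` the realised event itself determines met_status
(event -> BONE, otherwise NONE/OTHER in proportion), so expression-linked
hazards remain visible to the bone-specific endpoint after censoring of
other-site samples.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    AXIS_ORDER,
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    default_panels,
    write_clinical,
    write_expression,
    write_gmt,
)

__all__ = [
    "PlantedGene",
    "SimConfig",
    "SimTruth",
    "closed_form_spearman",
    "generate_cohort",
    "generate_pair",
    "generate_adaptive",
    "write_cohort",
]

ROLES = ("BONE_SPECIFIC", "PAN_METASTATIC", "NULL", "AXIS_LINKED", "SURVIVAL_LINKED")


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth role of one non-background gene."""

    gene: str
    role: str
    effect: float = 0.0  # log2 shift for DEG roles; sign sets direction
    axis: str | None = None  # AXIS_LINKED only
    loading: float = 0.0  # AXIS_LINKED only, >= 0
    log_hr: float = 0.0  # SURVIVAL_LINKED only, per-sd hazard coefficient

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown planted role {self.role!r}")
        if self.role == "AXIS_LINKED":
            if self.axis not in AXIS_ORDER:
                raise ValidationError(f"AXIS_LINKED gene needs an axis, got {self.axis!r}")
            if self.loading < 0:
                raise ValidationError("loading must be >= 0")
        if self.role in ("BONE_SPECIFIC", "PAN_METASTATIC") and self.effect == 0.0:
            raise ValidationError(f"{self.role} gene needs a non-zero effect")

    @property
    def direction(self) -> str:
        return "UP" if self.effect > 0 else ("DOWN" if self.effect < 0 else "NA")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (defaults mirror a mid-size
    predisposition cohort: 150 tumours, ~13% bone metastases)."""

    n_none: int = 100
    n_other: int = 30
    n_bone: int = 20
    n_background_genes: int = 1000
    planted: tuple = ()
    noise_sd: float = 1.0
    baseline_mean: float = 8.0  # log2 units
    marker_loading: float = 1.0
    censor_rate: float = 0.4
    base_hazard: float = 0.02  # per month
    met_from_hazard: bool = False
    include_markers: bool = True
    cohort_id: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.base_hazard <= 0:
            raise ValidationError("base_hazard must be > 0")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be >= 0")
        for count, name in ((self.n_none, "n_none"), (self.n_other, "n_other"),
                            (self.n_bone, "n_bone")):
            if 0 < count < 3:
                raise ValidationError(f"{name} must be 0 or >= 3, got {count}")
        object.__setattr__(self, "planted", tuple(self.planted))
        names = [p.gene for p in self.planted]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate planted gene names")


@dataclass
class SimTruth:
    """Ground truth for recovery tests: per-gene roles and per-sample factors."""

    genes: pd.DataFrame  # gene, role, effect, axis, loading, log_hr, direction
    factors: pd.DataFrame  # samples x axes, the latent factor draws


def closed_form_spearman(loading_gene: float, loading_marker: float, noise_sd: float) -> float:
    """Population Spearman between an AXIS_LINKED gene and an own-axis marker.

    Pearson under the factor model is lg*lm / sqrt((lg^2+s^2)(lm^2+s^2));
    the bivariate-normal identity converts it to Spearman.
    """
    s2 = noise_sd**2
    rho = (loading_gene * loading_marker) / np.sqrt(
        (loading_gene**2 + s2) * (loading_marker**2 + s2)
    )
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


def _calibrate_censoring(latent_t: np.ndarray, censor_rate: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0, tau) administrative censoring with tau solved so the
    expected censored fraction matches ``censor_rate``; returns (time, event)."""
    if censor_rate == 0:
        return latent_t.copy(), np.ones(latent_t.size, dtype=int)

    def expected_censored(tau: float) -> float:
        # P(C < T) for C ~ U(0, tau), conditioning on the realised T draws
        return float(np.mean(np.minimum(latent_t / tau, 1.0)))

    lo, hi = 1e-9, float(latent_t.max()) * 2 + 1.0
    while expected_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_censored(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    c = rng.uniform(0.0, tau, size=latent_t.size)
    event = (latent_t <= c).astype(int)
    time = np.where(event == 1, latent_t, c)
    return time, event


def _gene_roster(config: SimConfig) -> tuple[list[str], dict[str, PlantedGene], list[str]]:
    planted_names = [p.gene.upper() for p in config.planted]
    marker_genes: list[str] = []
    if config.include_markers:
        for panel in default_panels():
            marker_genes.extend(g for g in panel.genes if g not in planted_names)
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    all_genes = planted_names + marker_genes + background
    if len(set(all_genes)) != len(all_genes):
        raise ValidationError("gene name collision between planted, marker and background sets")
    return all_genes, {p.gene.upper(): p for p in config.planted}, marker_genes


def _marker_axis_index() -> dict[str, int]:
    idx: dict[str, int] = {}
    for ai, panel in enumerate(default_panels()):
        for g in panel.genes:
            idx.setdefault(g, ai)
    return idx


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Simulate one predisposition cohort (expression, clinical, truth)."""
    n = config.n_none + config.n_other + config.n_bone
    if n < 4:
        raise ValidationError("cohort needs at least 4 samples")
    ss = np.random.SeedSequence(config.seed)
    rng_factors, rng_noise, rng_surv, rng_class = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    sample_ids = [f"{config.cohort_id}-S{i:04d}" for i in range(n)]
    factors = rng_factors.standard_normal((n, len(AXIS_ORDER)))
    genes, planted_by_name, _ = _gene_roster(config)
    axis_of_marker = _marker_axis_index() if config.include_markers else {}
    axis_pos = {a: i for i, a in enumerate(AXIS_ORDER)}

    # provisional class assignment (fixed counts); may be overridden below
    met = np.array(
        ["NONE"] * config.n_none + ["OTHER"] * config.n_other + ["BONE"] * config.n_bone
    )

    survival_genes = [p for p in planted_by_name.values() if p.role == "SURVIVAL_LINKED"]

    # class shifts are deferred in hazard mode (classes not yet known there)
    values = np.empty((len(genes), n))
    for gi, gene in enumerate(genes):
        row = config.baseline_mean + config.noise_sd * rng_noise.standard_normal(n)
        p = planted_by_name.get(gene)
        if p is not None:
            if p.role == "BONE_SPECIFIC" and not config.met_from_hazard:
                row = row + p.effect * (met == "BONE")
            elif p.role == "PAN_METASTATIC" and not config.met_from_hazard:
                row = row + p.effect * np.isin(met, ("BONE", "OTHER"))
            elif p.role == "AXIS_LINKED":
                row = row + p.loading * factors[:, axis_pos[p.axis]]
        elif gene in axis_of_marker:
            row = row + config.marker_loading * factors[:, axis_of_marker[gene]]
        values[gi] = row

    gene_index = {g: i for i, g in enumerate(genes)}
    log_risk = np.zeros(n)
    for p in survival_genes:
        x = values[gene_index[p.gene.upper()]]
        z = (x - x.mean()) / x.std()
        log_risk += p.log_hr * z
    hazard = config.base_hazard * np.exp(log_risk)
    latent_t = rng_surv.exponential(1.0 / hazard)
    time, event = _calibrate_censoring(latent_t, config.censor_rate, rng_surv)

    if config.met_from_hazard:
        # realised bone event defines the class; non-events split NONE/OTHER
        p_other = config.n_other / max(config.n_none + config.n_other, 1)
        other_draw = rng_class.random(n) < p_other
        met = np.where(event == 1, "BONE", np.where(other_draw, "OTHER", "NONE"))
        # class shifts now follow the realised classes
        for gi, gene in enumerate(genes):
            p = planted_by_name.get(gene)
            if p is None:
                continue
            if p.role == "BONE_SPECIFIC":
                values[gi] = values[gi] + p.effect * (met == "BONE")
            elif p.role == "PAN_METASTATIC":
                values[gi] = values[gi] + p.effect * np.isin(met, ("BONE", "OTHER"))
        bmfs_event = event
    else:
        # only BONE-class samples can experience the bone event
        bmfs_event = np.where(met == "BONE", event, 0)

    matrix = ExpressionMatrix(config.cohort_id, pd.DataFrame(values, index=genes, columns=sample_ids))
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "met_status": met,
                "bmfs_time": time,
                "bmfs_event": bmfs_event,
            }
        )
    )
    truth_rows = [
        {
            "gene": p.gene.upper(),
            "role": p.role,
            "effect": p.effect,
            "axis": p.axis or "",
            "loading": p.loading,
            "log_hr": p.log_hr,
            "direction": p.direction,
        }
        for p in config.planted
    ]
    truth = SimTruth(
        pd.DataFrame(truth_rows, columns=["gene", "role", "effect", "axis", "loading", "log_hr", "direction"]),
        pd.DataFrame(factors, index=sample_ids, columns=list(AXIS_ORDER)),
    )
    return matrix, clinical, truth


def generate_pair(
    config_a: SimConfig, config_b: SimConfig, shared_truth: bool = True
):
    """Discovery/validation pair: same planted roster, independent samples."""
    if shared_truth:
        roster_a = [(p.gene, p.role) for p in config_a.planted]
        roster_b = [(p.gene, p.role) for p in config_b.planted]
        if roster_a != roster_b:
            raise ValidationError("shared_truth requires identical planted rosters")
    if config_a.seed == config_b.seed:
        config_b = replace(config_b, seed=config_b.seed + 104729)  # force independence
    return generate_cohort(config_a), generate_cohort(config_b)


def generate_adaptive(config: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Simulate an adaptive (lesion-site) cohort.

    ``n_none``/``n_other``/``n_bone`` map onto PRIMARY / OTHER_MET /
    BONE_MET lesion counts. BONE_SPECIFIC genes shift only BONE_MET lesions,
    PAN_METASTATIC genes shift both metastatic lesion types.
    """
    for count, name in ((config.n_none, "PRIMARY"), (config.n_other, "OTHER_MET"),
                        (config.n_bone, "BONE_MET")):
        if count < 3:
            raise ValidationError(f"adaptive cohort needs >=3 {name} samples")
    n = config.n_none + config.n_other + config.n_bone
    ss = np.random.SeedSequence(config.seed)
    rng_factors, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    sample_ids = [f"{config.cohort_id}-L{i:04d}" for i in range(n)]
    site = np.array(
        ["PRIMARY"] * config.n_none + ["OTHER_MET"] * config.n_other + ["BONE_MET"] * config.n_bone
    )
    factors = rng_factors.standard_normal((n, len(AXIS_ORDER)))
    genes, planted_by_name, _ = _gene_roster(config)
    axis_of_marker = _marker_axis_index() if config.include_markers else {}
    axis_pos = {a: i for i, a in enumerate(AXIS_ORDER)}
    values = np.empty((len(genes), n))
    for gi, gene in enumerate(genes):
        row = config.baseline_mean + config.noise_sd * rng_noise.standard_normal(n)
        p = planted_by_name.get(gene)
        if p is not None:
            if p.role == "BONE_SPECIFIC":
                row = row + p.effect * (site == "BONE_MET")
            elif p.role == "PAN_METASTATIC":
                row = row + p.effect * np.isin(site, ("BONE_MET", "OTHER_MET"))
            elif p.role == "AXIS_LINKED":
                row = row + p.loading * factors[:, axis_pos[p.axis]]
        elif gene in axis_of_marker:
            row = row + config.marker_loading * factors[:, axis_of_marker[gene]]
        values[gi] = row
    matrix = ExpressionMatrix(config.cohort_id, pd.DataFrame(values, index=genes, columns=sample_ids))
    clinical = ClinicalTable(pd.DataFrame({"sample_id": sample_ids, "lesion_site": site}))
    truth_rows = [
        {
            "gene": p.gene.upper(), "role": p.role, "effect": p.effect,
            "axis": p.axis or "", "loading": p.loading, "log_hr": p.log_hr,
            "direction": p.direction,
        }
        for p in config.planted
    ]
    truth = SimTruth(
        pd.DataFrame(truth_rows, columns=["gene", "role", "effect", "axis", "loading", "log_hr", "direction"]),
        pd.DataFrame(factors, index=sample_ids, columns=list(AXIS_ORDER)),
    )
    return matrix, clinical, truth


def write_cohort(outdir, prefix: str, matrix: ExpressionMatrix,
                 clinical: ClinicalTable, truth: SimTruth) -> dict:
    """Write a generated cohort as the TSV/GMT files the readers consume."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / f"{prefix}_expression.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
        "truth": outdir / f"{prefix}_truth.tsv",
        "panels": outdir / "panels.gmt",
    }
    write_expression(matrix, paths["expression"])
    write_clinical(clinical, paths["clinical"])
    truth.genes.to_csv(paths["truth"], sep="\t", index=False)
    write_gmt(default_panels(), paths["panels"])
    return {k: str(v) for k, v in paths.items()}
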