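"""Readers, writers and validated containers for the tabular formats the screen touches.

Three on-disk formats are supported, all plain text:

* expression — TSV, one row per gene, first column the gene symbol, header
  row of sample identifiers, cells log2-scale expression;
* clinical — TSV with columns ``sample_id``, ``met_status``, ``bmfs_time``,
  ``bmfs_event`` and optionally ``lesion_site``;
* marker panels — standard GMT (set name, description, member symbols,
  tab-separated, one set per line).

Gene identity throughout the package is the uppercased symbol string; no
alias resolution is attempted beyond a small table of common/HGNC synonym
pairs for the default marker panels (e.g. RANKL/TNFSF11).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "ClinicalTable",
    "MarkerPanel",
    "MET_STATUSES",
    "LESION_SITES",
    "AXIS_ORDER",
    "MARKER_ALIASES",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "default_panels",
]

#: Metastasis-site status of a primary tumour sample.
MET_STATUSES = ("NONE", "OTHER", "BONE")

#: Lesion type of a sample in an adaptive (site-of-lesion) cohort.
LESION_SITES = ("PRIMARY", "BONE_MET", "OTHER_MET")

#: Fixed axis order; also the tie-break order for top-axis classification.
AXIS_ORDER = ("HOMING", "IMMUNE_ESCAPE", "ANGIOGENESIS", "OSTEOCLASTIC", "OSTEOBLASTIC")

#: Common-name/HGNC synonym pairs used when matching panel markers to a matrix.
MARKER_ALIASES: dict[str, tuple[str, ...]] = {
    "TNFSF11": ("RANKL",),
    "TNFRSF11B": ("OPG",),
    "CXCR7": ("ACKR3",),
    "CTGF": ("CCN2",),
}

# float format preserving round trips to < 1e-12
_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """A file or container violated a structural invariant."""


def _check_unique(items, what: str) -> None:
    seen: set = set()
    dups = []
    for it in items:
        if it in seen:
            dups.append(it)
        seen.add(it)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression for one cohort.

    ``values`` is a genes x samples DataFrame; gene symbols are uppercased on
    construction and must be unique afterwards, all cells must be finite, and
    the matrix must contain at least one gene and two samples.
    """

    cohort_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a DataFrame (genes x samples)")
        df = self.values.copy()
        df.index = [str(g).upper() for g in df.index]
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        _check_unique(df.index, "gene symbols (after uppercasing)")
        _check_unique(df.columns, "sample ids")
        try:
            arr = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression cell: {exc}") from exc
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        df = df.astype(float)
        object.__setattr__(self, "values", df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, symbol: str) -> np.ndarray:
        """Expression vector of one gene (samples in column order)."""
        symbol = symbol.upper()
        if symbol not in self.values.index:
            raise KeyError(f"gene {symbol!r} not in cohort {self.cohort_id!r}")
        return self.values.loc[symbol].to_numpy()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.cohort_id, self.values.loc[:, list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    Predisposition cohorts carry ``met_status`` (NONE/OTHER/BONE) plus the
    bone-metastasis-free-survival columns ``bmfs_time`` (months, > 0) and
    ``bmfs_event`` (0/1). Adaptive cohorts carry ``lesion_site``
    (PRIMARY/BONE_MET/OTHER_MET) instead. Sample ids must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "sample_id" not in df.columns:
            raise ValidationError("clinical table requires a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        if "met_status" not in df.columns and "lesion_site" not in df.columns:
            raise ValidationError(
                "clinical table needs met_status (predisposition) or lesion_site (adaptive)"
            )
        if "met_status" in df.columns:
            bad = set(df["met_status"].dropna()) - set(MET_STATUSES)
            if bad:
                raise ValidationError(f"unknown met_status values: {sorted(bad)}")
        if "lesion_site" in df.columns:
            bad = set(df["lesion_site"].dropna()) - set(LESION_SITES)
            if bad:
                raise ValidationError(f"unknown lesion_site values: {sorted(bad)}")
        if "bmfs_time" in df.columns:
            t = pd.to_numeric(df["bmfs_time"], errors="raise")
            if (t.dropna() <= 0).any():
                raise ValidationError("bmfs_time must be > 0 where present")
            df["bmfs_time"] = t
        if "bmfs_event" in df.columns:
            e = pd.to_numeric(df["bmfs_event"], errors="raise")
            bad_e = set(e.dropna().unique()) - {0, 1}
            if bad_e:
                raise ValidationError(f"bmfs_event must be 0/1, got {sorted(bad_e)}")
            df["bmfs_event"] = e
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def has_survival(self) -> bool:
        return {"bmfs_time", "bmfs_event"}.issubset(self.data.columns)

    def has_lesions(self) -> bool:
        return "lesion_site" in self.data.columns

    def met_status_of(self, sample_ids) -> pd.Series:
        sub = self.data.set_index("sample_id").loc[list(sample_ids)]
        return sub["met_status"]


@dataclass(frozen=True)
class MarkerPanel:
    """A named biological axis and its curated marker gene symbols."""

    axis: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(dict.fromkeys(g.upper() for g in self.genes))
        if not genes:
            raise ValidationError(f"panel {self.axis!r} has no genes")
        object.__setattr__(self, "axis", self.axis.upper())
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path, cohort_id: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene symbols, header samples)."""
    # pandas silently renames duplicate header columns, so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample ids")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed file surfaces as ValidationError
        raise ValidationError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty expression matrix in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric expression cells in column {col!r}: {list(bad)[:5]}"
            )
    if df.isna().any().any():
        raise ValidationError(f"missing expression values in {path}")
    return ExpressionMatrix(cohort_id, df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# clinical TSV


def read_clinical(path, kind: str | None = None) -> ClinicalTable:
    """Read a clinical TSV.

    ``kind`` may be "predisposition" (requires met_status + survival columns),
    "adaptive" (requires lesion_site) or None (either shape accepted).
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValidationError(f"cannot parse clinical TSV {path}: {exc}") from exc
    required = {"sample_id"}
    if kind == "predisposition":
        required |= {"met_status", "bmfs_time", "bmfs_event"}
    elif kind == "adaptive":
        required |= {"lesion_site"}
    elif kind is not None:
        raise ValueError(f"unknown clinical kind {kind!r}")
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    try:
        return ClinicalTable(df)
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"invalid clinical table {path}: {exc}") from exc


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# GMT marker panels


def read_gmt(path, strict_axes: bool = False) -> list[MarkerPanel]:
    """Read marker panels from a GMT file (one panel per line).

    With ``strict_axes`` the set name must be one of the five closed-set axis
    labels; otherwise arbitrary set names are accepted.
    """
    panels: list[MarkerPanel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            axis, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: GMT line has no genes")
            if strict_axes and axis.upper() not in AXIS_ORDER:
                raise ValidationError(
                    f"{path}:{lineno}: unknown axis {axis!r}; expected one of {AXIS_ORDER}"
                )
            panels.append(MarkerPanel(axis, description, tuple(genes)))
    if not panels:
        raise ValidationError(f"no panels in {path}")
    return panels


def write_gmt(panels, path) -> None:
    with open(path, "w") as fh:
        for p in panels:
            fh.write("\t".join([p.axis, p.description, *p.genes]) + "\n")


def default_panels() -> list[MarkerPanel]:
    """The five curated marker panels of the bone-metastasis cascade.

    Homing (adhesion/chemotaxis of disseminated cells to bone marrow), immune
    escape (evasion of NK/T surveillance), neo-angiogenesis, osteoclastic
    (bone-resorbing, osteolytic lesions) and osteoblastic (bone-forming
    lesions) marker sets. RANKL/OPG and CXCR7/CTGF are stored under their
    HGNC symbols; :data:`MARKER_ALIASES` lets scoring match either spelling.
    """
    return [
        MarkerPanel(
            "HOMING",
            "bone-marrow homing / adhesion markers",
            ("CXCR4", "CXCR7", "CDH2", "ITGB3", "ANXA2", "CD44", "CTGF", "ITGA2"),
        ),
        MarkerPanel(
            "IMMUNE_ESCAPE",
            "immune-surveillance escape markers",
            ("ITGB2", "IRF7", "CD47", "CD274", "HSPA5", "KRT19", "ADAM10"),
        ),
        MarkerPanel(
            "ANGIOGENESIS",
            "tumour neo-angiogenesis markers",
            ("VEGFB", "VEGFC", "PECAM1", "CD34", "SPHK1", "HIF1A", "S1PR1", "FGF2"),
        ),
        MarkerPanel(
            "OSTEOCLASTIC",
            "osteoclastogenesis / osteolytic signature",
            ("TNFSF11", "TNFRSF11B", "CTSK", "SRC", "IL6", "NFATC4", "FOS", "DKK1", "SOST", "IL1B"),
        ),
        MarkerPanel(
            "OSTEOBLASTIC",
            "osteoblastogenesis / bone-forming signature",
            ("BMP4", "BMP7", "EDN1", "PDGFA", "PDGFB", "WNT10B", "PLAU", "CDH11", "RUNX2"),
        ),
    ]
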