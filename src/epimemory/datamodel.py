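"""Typed tables, readers/writers and shared configuration.

All tabular data are pandas DataFrames validated against the schemas
below; matrices (methylation beta, log2 expression) are DataFrames with
probe ids as the index and sample ids as columns.  Writers emit
tab-delimited, header-first text with a fixed column order so outputs
are bit-stable across runs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("epimemory")


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class SchemaError(ValidationError):
    """Input table is missing mandatory columns or uses unknown labels."""


# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

TISSUES = ("cord", "postnatal")
SEXES = ("male", "female")

GENE_REGIONS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3", "IGR")
PROMOTER_REGIONS = ("TSS200", "TSS1500", "UTR5", "FirstExon")
GENE_BODY_REGIONS = ("Body", "UTR3")

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

# 25-state chromatin vocabulary (imputed blood-cell segmentation labels).
CHROM_STATES = (
    "TssA", "PromU", "PromD1", "PromD2",
    "Tx5", "Tx", "Tx3", "TxWk", "TxReg",
    "TxEnh5", "TxEnh3", "TxEnhW",
    "EnhA1", "EnhA2", "EnhAF", "EnhW1", "EnhW2", "EnhAc",
    "DNase", "ZNF_Rpts", "Het", "PromP", "PromBiv", "ReprPC", "Quies",
)

CELL_TYPES = ("CD4T", "CD8T", "NK", "B", "Gran", "Mono", "nRBC")

CONTINUOUS_COVARIATES = ("maternal_age", "maternal_bmi", "paternal_age", "paternal_bmi")
BINARY_COVARIATES = (
    "parity_gt0", "cesarean", "art", "smoke_before", "gdm",
    "cam", "iprom", "preeclampsia", "previa",
)

# Prenatal covariates carried into the fully adjusted EWAS model.
MODEL2_EXTRA_COVARIATES = (
    "cam", "iprom", "preeclampsia", "smoke_before", "maternal_bmi", "cesarean",
)

SAMPLE_SHEET_COLUMNS = (
    ("sample_id", "subject_id", "tissue", "ga_weeks", "bw_sd_score", "sex", "batch")
    + CONTINUOUS_COVARIATES
    + BINARY_COVARIATES
    + ("postmenstrual_age_at_draw", "interval_weeks")
)

MANIFEST_COLUMNS = (
    "probe_id", "chrom", "pos", "gene", "gene_region",
    "island_relation", "chromstate_T", "chromstate_B",
)
EXPR_MANIFEST_COLUMNS = ("expr_probe_id", "chrom", "pos", "gene")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and scales shared across stages."""

    fdr_alpha: float = 0.05
    nominal_alpha: float = 0.05
    memory_r_threshold: float = 0.7
    cis_window_bp: int = 250_000
    enrichment_fdr: float = 0.1
    bonferroni_family: int = 25
    min_cpgs_per_gene: int = 2
    meth_scale: str = "percent"  # or "proportion"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "nominal_alpha", "memory_r_threshold", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")
        if self.cis_window_bp <= 0:
            raise ValidationError("cis_window_bp must be positive")
        if self.meth_scale not in ("percent", "proportion"):
            raise ValidationError(f"unknown meth_scale {self.meth_scale!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def meth_multiplier(self) -> float:
        return 100.0 if self.meth_scale == "percent" else 1.0


# ---------------------------------------------------------------------------
# Matrix IO
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated probe ids: {dupes}")
    if pd.Index(df.columns).duplicated().any():
        raise ValidationError("duplicated sample ids in header")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"malformed numeric cell at probe {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValidationError(f"missing value at probe {row!r}, sample {col!r}")
        out[col] = converted
    return out


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Load a probes x samples methylation matrix; values must lie in [0, 1).

    The +100 offset in the beta formula makes exactly 1.0 unreachable, so
    it is rejected as evidence of a malformed input.
    """
    df = _read_matrix(path)
    vals = df.to_numpy()
    if vals.size and (vals.min() < 0.0 or vals.max() >= 1.0):
        r, c = np.argwhere((vals < 0.0) | (vals >= 1.0))[0]
        raise ValidationError(
            f"beta value {vals[r, c]!r} outside [0, 1) at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def write_beta_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", lineterminator="\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Load a probes x samples log2 expression matrix; values must be >= 0."""
    df = _read_matrix(path)
    vals = df.to_numpy()
    if vals.size and vals.min() < 0.0:
        r, c = np.argwhere(vals < 0.0)[0]
        raise ValidationError(
            f"negative expression value at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="expr_probe_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet is missing columns: {missing}")
    bad_tissue = set(df["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise SchemaError(f"unknown tissue labels: {sorted(bad_tissue)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")
    ga = df["ga_weeks"].astype(float)
    if ((ga < 22) | (ga > 42)).any():
        raise ValidationError("ga_weeks outside [22, 42]")
    dup = df.duplicated(subset=["subject_id", "tissue"])
    if dup.any():
        pair = df.loc[dup, ["subject_id", "tissue"]].iloc[0]
        raise ValidationError(
            f"duplicate (subject_id, tissue) pair: ({pair.subject_id!r}, {pair.tissue!r})"
        )
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id")
    cord = df["tissue"] == "cord"
    if df.loc[cord, "interval_weeks"].notna().any():
        raise ValidationError("interval_weeks must be absent for cord rows")
    if df.loc[~cord, "interval_weeks"].isna().any():
        raise ValidationError("interval_weeks required for postnatal rows")
    for col in BINARY_COVARIATES:
        vals = set(pd.unique(df[col].astype(float)))
        if not vals <= {0.0, 1.0}:
            raise ValidationError(f"binary covariate {col!r} has non-0/1 values")
    return df.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path))


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(SAMPLE_SHEET_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"probe manifest is missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe_id in manifest")
    if (df["pos"].astype(int) <= 0).any():
        raise ValidationError("manifest positions must be positive")
    bad_region = set(df["gene_region"]) - set(GENE_REGIONS)
    if bad_region:
        raise SchemaError(f"unknown gene_region labels: {sorted(bad_region)}")
    bad_rel = set(df["island_relation"]) - set(ISLAND_RELATIONS)
    if bad_rel:
        raise SchemaError(f"unknown island_relation labels: {sorted(bad_rel)}")
    for col in ("chromstate_T", "chromstate_B"):
        bad = set(df[col]) - set(CHROM_STATES)
        if bad:
            raise SchemaError(f"unknown chromatin states in {col}: {sorted(bad)}")
    gene = df["gene"].fillna("").astype(str)
    igr = df["gene_region"] == "IGR"
    if (igr != (gene == "")).any():
        raise ValidationError("gene_region must be IGR exactly when gene is empty")
    out = df.copy()
    out["gene"] = gene
    return out.reset_index(drop=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return validate_manifest(df)


def validate_expr_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EXPR_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"expression manifest is missing columns: {missing}")
    if df["expr_probe_id"].duplicated().any():
        raise ValidationError("duplicate expr_probe_id in manifest")
    if (df["pos"].astype(int) <= 0).any():
        raise ValidationError("expression manifest positions must be positive")
    return df.reset_index(drop=True)


def read_expr_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return validate_expr_manifest(df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited, header-first writer used for every record table."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def bed_to_point(start0: int) -> int:
    """Convert a 0-based half-open BED start to a 1-based point coordinate."""
    pos = int(start0) + 1
    logger.debug("converted BED start %d to 1-based position %d", start0, pos)
    return pos


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection: one set per line (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line {ln} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
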