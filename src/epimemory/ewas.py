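"""Per-CpG dual-model EWAS of GA and birth-weight SD score.

Every probe is fit by OLS of (percent) methylation on GA + SD score plus
the model's adjustment set; p-values come from two-sided t-tests and are
converted to q-values by Benjamini-Hochberg step-up, separately for the
GA and SD coefficient families.  Candidate CpGs are those FDR-significant
in both models with the same coefficient sign.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from epimemory.datamodel import (
    CELL_TYPES,
    ISLAND_RELATIONS,
    MODEL2_EXTRA_COVARIATES,
    PipelineConfig,
    ValidationError,
)

DEFAULT_DROPPED_CELL_TYPE = "Gran"


@dataclasses.dataclass
class EwasModelSpec:
    model_id: str
    adjustments: tuple[str, ...] = ()  # prenatal covariates beyond sex/batch/cells


def model1_spec() -> EwasModelSpec:
    return EwasModelSpec(model_id="model1")


def model2_spec() -> EwasModelSpec:
    return EwasModelSpec(model_id="model2", adjustments=MODEL2_EXTRA_COVARIATES)


def sensitivity_specs(covars=MODEL2_EXTRA_COVARIATES) -> list[EwasModelSpec]:
    return [EwasModelSpec(model_id=f"sensitivity_{c}", adjustments=(c,))
            for c in covars]


@dataclasses.dataclass
class ConsensusCpGs:
    """Probes FDR-significant in both models with consistent sign."""

    ga_related: pd.DataFrame  # probe_id, sign
    sd_related: pd.DataFrame


# ---------------------------------------------------------------------------
# Design matrix and mass OLS
# ---------------------------------------------------------------------------

def build_design_matrix(
    rows: pd.DataFrame,
    fractions: pd.DataFrame | None = None,
    extra_covariates: tuple[str, ...] = (),
    drop_cell_type: str = DEFAULT_DROPPED_CELL_TYPE,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + GA + SDscore + sex + batch dummies (+ K-1 cell fractions
    + extra covariates), treatment-coded against the first batch label."""
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(rows)),
        "ga_weeks": rows["ga_weeks"].to_numpy(float),
        "bw_sd_score": rows["bw_sd_score"].to_numpy(float),
        "sex_male": (rows["sex"] == "male").to_numpy(float),
    }
    batches = sorted(rows["batch"].astype(str).unique())
    for b in batches[1:]:
        cols[f"batch_{b}"] = (rows["batch"].astype(str) == b).to_numpy(float)
    if fractions is not None:
        frac = fractions.set_index("sample_id") if "sample_id" in fractions else fractions
        missing = [s for s in rows["sample_id"] if s not in frac.index]
        if missing:
            raise ValidationError(f"cell fractions missing for samples: {missing[:5]}")
        for ct in CELL_TYPES:
            if ct == drop_cell_type:
                continue
            cols[f"frac_{ct}"] = frac.loc[rows["sample_id"], ct].to_numpy(float)
    for c in extra_covariates:
        if c not in rows.columns:
            raise ValidationError(f"covariate {c!r} missing from sample sheet")
        cols[c] = rows[c].to_numpy(float)

    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValidationError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X, names


def mass_ols(Y: np.ndarray, X: np.ndarray):
    """OLS of many outcomes (columns of Y) on one design matrix.

    Returns (coef p x m, se p x m, p-values p x m, dof).
    """
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValidationError("Y and X row counts differ")
    dof = n - p
    if dof <= 0:
        raise ValidationError("not enough samples for the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    coef = H @ Y
    resid = Y - X @ coef
    sigma2 = (resid * resid).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return coef, se, pvals, dof


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-d vector")
    if np.isnan(p).any():
        raise ValidationError("p vector contains NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# EWAS fits
# ---------------------------------------------------------------------------

def fit_ewas(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    fractions: pd.DataFrame | None,
    spec: EwasModelSpec,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fit the model for every probe; outcome scale set by config.meth_scale."""
    config = config or PipelineConfig()
    rows = sheet[sheet["sample_id"].isin(beta.columns)].reset_index(drop=True)
    if rows.empty:
        raise ValidationError("no sheet rows match the beta matrix columns")
    tissues = rows["tissue"].unique()
    if len(tissues) != 1:
        raise ValidationError(f"samples span multiple tissues: {sorted(tissues)}")
    if len(rows) != beta.shape[1]:
        unknown = set(beta.columns) - set(rows["sample_id"])
        raise ValidationError(f"beta columns missing from sheet: {sorted(unknown)[:5]}")

    X, names = build_design_matrix(rows, fractions, spec.adjustments)
    Y = beta.loc[:, rows["sample_id"]].to_numpy().T * config.meth_multiplier
    coef, se, pvals, _ = mass_ols(Y, X)
    i_ga, i_sd = names.index("ga_weeks"), names.index("bw_sd_score")

    out = pd.DataFrame({
        "probe_id": beta.index,
        "beta_ga": coef[i_ga], "se_ga": se[i_ga], "p_ga": pvals[i_ga],
        "q_ga": bh_adjust(pvals[i_ga]),
        "beta_sd": coef[i_sd], "se_sd": se[i_sd], "p_sd": pvals[i_sd],
        "q_sd": bh_adjust(pvals[i_sd]),
    })
    out["model_id"] = spec.model_id
    out["n"] = len(rows)
    return out


def intersect_models(
    r1: pd.DataFrame, r2: pd.DataFrame, alpha: float = 0.05,
) -> ConsensusCpGs:
    """Probes with q < alpha in both models and equal coefficient sign."""
    if set(r1["probe_id"]) != set(r2["probe_id"]):
        raise ValidationError("probe universes differ between the two results")
    a = r1.set_index("probe_id").sort_index()
    b = r2.set_index("probe_id").sort_index()

    def consensus(prefix: str) -> pd.DataFrame:
        sig = ((a[f"q_{prefix}"] < alpha) & (b[f"q_{prefix}"] < alpha)
               & (np.sign(a[f"beta_{prefix}"]) == np.sign(b[f"beta_{prefix}"]))
               & (np.sign(a[f"beta_{prefix}"]) != 0))
        return pd.DataFrame({
            "probe_id": a.index[sig],
            "sign": np.sign(a.loc[sig, f"beta_{prefix}"]).astype(int),
        }).reset_index(drop=True)

    return ConsensusCpGs(ga_related=consensus("ga"), sd_related=consensus("sd"))


def sensitivity_overlap(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    fractions: pd.DataFrame | None,
    consensus: ConsensusCpGs,
    covars=MODEL2_EXTRA_COVARIATES,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One extra fit per single-added covariate; count consensus CpGs that
    stay significant with the same sign in every sensitivity fit."""
    config = config or PipelineConfig()
    alpha = config.fdr_alpha

    surviving = {
        "ga": dict(zip(consensus.ga_related["probe_id"], consensus.ga_related["sign"])),
        "sd": dict(zip(consensus.sd_related["probe_id"], consensus.sd_related["sign"])),
    }
    keep = {k: set(v) for k, v in surviving.items()}
    for spec in sensitivity_specs(covars):
        res = fit_ewas(beta, sheet, fractions, spec, config).set_index("probe_id")
        for fam in ("ga", "sd"):
            ok = set()
            for pid in keep[fam]:
                row = res.loc[pid]
                if (row[f"q_{fam}"] < alpha
                        and np.sign(row[f"beta_{fam}"]) == surviving[fam][pid]):
                    ok.add(pid)
            keep[fam] = ok

    rows = []
    for fam, label in (("ga", "GA"), ("sd", "SDscore")):
        total = len(surviving[fam])
        rows.append({
            "family": label, "consensus": total, "stable": len(keep[fam]),
            "fraction": len(keep[fam]) / total if total else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Island-relation enrichment
# ---------------------------------------------------------------------------

def enrich_island_relation(
    cpg_set, manifest: pd.DataFrame, background: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fold change and Fisher p of each island-relation label in the set
    relative to the background manifest universe."""
    cpg_set = set(cpg_set)
    if not cpg_set:
        raise ValidationError("empty CpG set")
    bg = manifest if background is None else background
    in_set = bg["probe_id"].isin(cpg_set)
    n_set, n_bg = int(in_set.sum()), len(bg)
    rows = []
    for rel in ISLAND_RELATIONS:
        is_rel = bg["island_relation"] == rel
        a = int((in_set & is_rel).sum())
        prop_set = a / n_set
        prop_bg = int(is_rel.sum()) / n_bg
        table = [[a, n_set - a],
                 [int(is_rel.sum()) - a, n_bg - n_set - (int(is_rel.sum()) - a)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "island_relation": rel, "n_in_set": a, "prop_set": prop_set,
            "prop_background": prop_bg,
            "fold": prop_set / prop_bg if prop_bg > 0 else float("nan"),
            "p": p,
        })
    return pd.DataFrame(rows)
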