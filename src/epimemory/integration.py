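"""cis CpG-transcript matching, transcript association and
methylation-expression correlation with concordant/discordant calling.

A promoter CpG whose methylation correlates *negatively* with its matched
transcript is "concordant" (the canonical repressive relation); a
positive correlation is "discordant".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from epimemory.datamodel import (
    GENE_BODY_REGIONS,
    PROMOTER_REGIONS,
    PipelineConfig,
    ValidationError,
)
from epimemory.ewas import EwasModelSpec, bh_adjust, fit_ewas


def match_cis_pairs(
    cpgs,
    cpg_manifest: pd.DataFrame,
    expr_manifest: pd.DataFrame,
    window: int = 250_000,
) -> pd.DataFrame:
    """All (CpG, expression probe) pairs on the same chromosome with
    |expr pos - CpG pos| <= window (boundary inclusive); many-to-many.

    CpGs without manifest coordinates are skipped and counted in the
    ``n_skipped`` attribute of the returned frame.
    """
    cpgs = list(dict.fromkeys(cpgs))
    ann = cpg_manifest.set_index("probe_id")
    present = [c for c in cpgs if c in ann.index]
    n_skipped = len(cpgs) - len(present)

    rows = []
    expr_by_chrom = {
        chrom: sub.sort_values("pos").reset_index(drop=True)
        for chrom, sub in expr_manifest.groupby("chrom")
    }
    for c in present:
        chrom, pos = ann.at[c, "chrom"], int(ann.at[c, "pos"])
        sub = expr_by_chrom.get(chrom)
        if sub is None:
            continue
        positions = sub["pos"].to_numpy()
        lo = np.searchsorted(positions, pos - window, side="left")
        hi = np.searchsorted(positions, pos + window, side="right")
        for i in range(lo, hi):
            rows.append({
                "cpg_id": c,
                "expr_probe_id": sub.at[i, "expr_probe_id"],
                "gene": sub.at[i, "gene"],
                "distance": int(positions[i]) - pos,
            })
    out = pd.DataFrame(rows, columns=["cpg_id", "expr_probe_id", "gene", "distance"])
    out.attrs["n_skipped"] = n_skipped
    return out


def fit_transcript_assoc(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    fractions: pd.DataFrame | None,
    probes=None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """OLS of log2 expression on GA + SDscore (sex/batch/cell-fraction
    adjusted) over the matched probe set; BH q within that set only."""
    config = config or PipelineConfig()
    if probes is not None:
        probes = list(dict.fromkeys(probes))
        missing = set(probes) - set(expr.index)
        if missing:
            raise ValidationError(f"expression matrix lacks probes: {sorted(missing)[:5]}")
        expr = expr.loc[probes]
    # expression is already log2; reuse the shared OLS machinery at scale 1
    cfg = PipelineConfig(**{**config.__dict__, "meth_scale": "proportion"})
    res = fit_ewas(expr, sheet, fractions, EwasModelSpec(model_id="transcript"), cfg)
    res["nominal_ga"] = res["p_ga"] < config.nominal_alpha
    res["nominal_sd"] = res["p_sd"] < config.nominal_alpha
    return res.rename(columns={"probe_id": "expr_probe_id"})


def _region_class(gene_region: str) -> str:
    if gene_region in PROMOTER_REGIONS:
        return "Promoter"
    if gene_region in GENE_BODY_REGIONS:
        return "GeneBody"
    return "IGR"


def correlate_meth_expr(
    pairs: pd.DataFrame,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    cpg_manifest: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of methylation and log2 expression per pair on
    the shared samples, with promoter concordant/discordant calling."""
    shared = [s for s in beta.columns if s in set(expr.columns)]
    ann = cpg_manifest.set_index("probe_id")

    rows, n_skipped = [], 0
    for row in pairs.itertuples(index=False):
        if row.cpg_id not in beta.index or row.expr_probe_id not in expr.index:
            n_skipped += 1
            continue
        x = beta.loc[row.cpg_id, shared].to_numpy(float)
        y = expr.loc[row.expr_probe_id, shared].to_numpy(float)
        n = len(shared)
        if n < min_n:
            n_skipped += 1
            continue
        r, p = _pearson(x, y)
        region = _region_class(ann.at[row.cpg_id, "gene_region"])
        if region == "Promoter":
            relation = "discordant" if r > 0 else ("concordant" if r < 0 else "NA")
        else:
            relation = "NA"
        rows.append({
            "cpg_id": row.cpg_id, "expr_probe_id": row.expr_probe_id,
            "gene": row.gene, "r": r, "p": p, "n": n,
            "region_class": region, "relation": relation,
        })
    out = pd.DataFrame(rows, columns=["cpg_id", "expr_probe_id", "gene", "r", "p",
                                      "n", "region_class", "relation"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["n_skipped"] = n_skipped
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact t-transform p-value on n-2 df."""
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)
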