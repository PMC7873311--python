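"""Cord-to-postnatal methylation persistence and chromatin-state statistics.

A GA-related CpG is a "memory" candidate when its cord-blood methylation
correlates with the same subjects' postnatal methylation at Pearson
r >= the configured threshold (0.7, inclusive).  Chromatin-state
enrichment uses two-sided Fisher tests with Bonferroni 0.05/25 and
Haldane-Anscombe-corrected confidence intervals for zero cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from epimemory.datamodel import CHROM_STATES, ValidationError


# ---------------------------------------------------------------------------
# Pairing and correlation
# ---------------------------------------------------------------------------

def _paired_samples(
    cord: pd.DataFrame, post: pd.DataFrame, sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Subjects with one cord and one postnatal sample present in both
    matrices; returns subject_id, cord sample, post sample, interval."""
    c = sheet[(sheet["tissue"] == "cord") & sheet["sample_id"].isin(cord.columns)]
    p = sheet[(sheet["tissue"] == "postnatal") & sheet["sample_id"].isin(post.columns)]
    merged = c.merge(p, on="subject_id", suffixes=("_cord", "_post"))
    if merged.empty:
        raise ValidationError("no paired subjects between the two matrices")
    return merged[["subject_id", "sample_id_cord", "sample_id_post",
                   "interval_weeks_post"]].rename(
        columns={"interval_weeks_post": "interval_weeks"})


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r (and t-transform p) between matching rows of A and B."""
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac * Ac).sum(axis=1) * (Bc * Bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Ac * Bc).sum(axis=1) / denom, -1.0, 1.0)
    r[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def cord_post_correlation(
    cord: pd.DataFrame,
    post: pd.DataFrame,
    sheet: pd.DataFrame,
    cpgs=None,
    r_threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-CpG Pearson r across paired subjects; candidate at r >= threshold."""
    pairs = _paired_samples(cord, post, sheet)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 paired subjects")
    ids = list(cpgs) if cpgs is not None else list(cord.index)
    missing = [c for c in ids if c not in cord.index or c not in post.index]
    if missing:
        raise ValidationError(f"CpGs absent from a matrix: {missing[:5]}")
    A = cord.loc[ids, pairs["sample_id_cord"]].to_numpy(float)
    B = post.loc[ids, pairs["sample_id_post"]].to_numpy(float)
    r, p = _rowwise_pearson(A, B)
    return pd.DataFrame({
        "cpg_id": ids, "r_cord_post": r, "p": p, "n_pairs": len(pairs),
        "is_candidate": r >= r_threshold,
    })


def interval_check(
    cord: pd.DataFrame,
    post: pd.DataFrame,
    sheet: pd.DataFrame,
    cpgs=None,
    drop_median_when_odd: bool = True,
) -> dict:
    """Short- vs long-interval subgroup comparison of the correlations.

    Paired subjects are split into bottom/top halves by interval_weeks
    (the median subject is dropped when the count is odd so halves are
    equal); per-CpG correlations are recomputed within each half and
    compared across CpGs by a paired t-test (bottom minus top).
    """
    pairs = _paired_samples(cord, post, sheet).sort_values(
        ["interval_weeks", "subject_id"], kind="stable").reset_index(drop=True)
    if len(pairs) < 6:
        raise ValidationError("need at least 6 paired subjects")
    n = len(pairs)
    half = n // 2
    if n % 2 == 1 and drop_median_when_odd:
        pairs = pairs.drop(index=half).reset_index(drop=True)
    bottom, top = pairs.iloc[:half], pairs.iloc[-half:]
    if len(bottom) < 3 or len(top) < 3:
        raise ValidationError("interval halves must contain at least 3 subjects")

    ids = list(cpgs) if cpgs is not None else list(cord.index)

    def half_r(sub: pd.DataFrame) -> np.ndarray:
        A = cord.loc[ids, sub["sample_id_cord"]].to_numpy(float)
        B = post.loc[ids, sub["sample_id_post"]].to_numpy(float)
        return _rowwise_pearson(A, B)[0]

    rb, rt = half_r(bottom), half_r(top)
    diff = rb - rt
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    m = len(diff)
    if sd == 0.0:
        return {"mean_diff": mean_diff, "ci_low": mean_diff, "ci_high": mean_diff,
                "p": 1.0, "n_cpgs": m, "zero_variance": True}
    se = sd / np.sqrt(m)
    tcrit = stats.t.ppf(0.975, m - 1)
    t = mean_diff / se
    return {
        "mean_diff": mean_diff,
        "ci_low": mean_diff - tcrit * se, "ci_high": mean_diff + tcrit * se,
        "p": float(2.0 * stats.t.sf(abs(t), m - 1)),
        "n_cpgs": m, "zero_variance": False,
    }


def region_correlation_map(
    cord: pd.DataFrame,
    post: pd.DataFrame,
    sheet: pd.DataFrame,
    cpg_ids,
) -> pd.DataFrame:
    """Cross-correlation matrix: r(cord CpG i, postnatal CpG j) over paired
    subjects.  Its diagonal equals ``cord_post_correlation``."""
    pairs = _paired_samples(cord, post, sheet)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 paired subjects")
    ids = list(cpg_ids)
    A = cord.loc[ids, pairs["sample_id_cord"]].to_numpy(float)
    B = post.loc[ids, pairs["sample_id_post"]].to_numpy(float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac * Ac).sum(axis=1))
    nb = np.sqrt((Bc * Bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (Ac @ Bc.T) / np.outer(na, nb)
    return pd.DataFrame(M, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Chromatin states
# ---------------------------------------------------------------------------

def _state_column(annotation: str) -> str:
    if annotation not in ("T", "B"):
        raise ValidationError(f"annotation must be 'T' or 'B'; got {annotation!r}")
    return f"chromstate_{annotation}"


def state_distribution(
    cpg_set, manifest: pd.DataFrame, annotation: str = "T",
) -> pd.DataFrame:
    """Counts and proportions over the fixed 25-state vocabulary."""
    cpg_set = set(cpg_set)
    if not cpg_set:
        raise ValidationError("empty CpG set")
    col = _state_column(annotation)
    sub = manifest[manifest["probe_id"].isin(cpg_set)]
    unknown = set(sub[col]) - set(CHROM_STATES)
    if unknown:
        raise ValidationError(f"unknown chromatin states: {sorted(unknown)}")
    counts = sub[col].value_counts()
    total = int(counts.sum())
    return pd.DataFrame({
        "state": CHROM_STATES,
        "count": [int(counts.get(s, 0)) for s in CHROM_STATES],
        "proportion": [counts.get(s, 0) / total for s in CHROM_STATES],
    })


def _fisher_or_row(a: int, b: int, c: int, d: int) -> dict:
    """Odds ratio, Fisher p and 95% CI for a 2x2 table; Haldane-Anscombe
    0.5 correction (flagged) when any cell is zero."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero_cell = 0 in (a, b, c, d)
    if zero_cell:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    orx = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return {
        "odds_ratio": (a * d) / (b * c) if not zero_cell else orx,
        "ci_low": float(orx * np.exp(-1.959963984540054 * se)),
        "ci_high": float(orx * np.exp(1.959963984540054 * se)),
        "p": float(p), "zero_cell": zero_cell,
    }


def state_enrichment(
    cpg_set,
    manifest: pd.DataFrame,
    background: pd.DataFrame | None = None,
    annotation: str = "T",
    alpha: float = 0.05,
    family: int = 25,
    disjoint_background: bool = True,
) -> pd.DataFrame:
    """Per-state 2x2 Fisher enrichment of the set against the background.

    Default rows are set vs background-minus-set; ``disjoint_background=
    False`` compares against the full background instead.  Significance
    requires p < alpha/family and odds ratio >= 1.
    """
    cpg_set = set(cpg_set)
    if not cpg_set:
        raise ValidationError("empty CpG set")
    bg = manifest if background is None else background
    col = _state_column(annotation)
    in_set = bg["probe_id"].isin(cpg_set)
    n_set = int(in_set.sum())
    if n_set == len(bg) and disjoint_background:
        raise ValidationError("set equals background; enrichment is degenerate")
    dist = state_distribution(cpg_set, bg, annotation)

    rows = []
    for _, drow in dist.iterrows():
        state = drow["state"]
        is_state = bg[col] == state
        a = int((in_set & is_state).sum())
        b = n_set - a
        if disjoint_background:
            c = int(is_state.sum()) - a
            d = (len(bg) - n_set) - c
        else:
            c = int(is_state.sum())
            d = len(bg) - c
        fr = _fisher_or_row(a, b, c, d)
        rows.append({
            "state": state, "count": a, "proportion": drow["proportion"],
            "background_proportion": int(is_state.sum()) / len(bg),
            **fr,
            "significant": fr["p"] < alpha / family and fr["odds_ratio"] >= 1.0,
        })
    return pd.DataFrame(rows)


def decile_trend(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    states,
    annotation: str = "T",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-decile enrichment odds ratio of the requested states.

    The record universe is ordered by r_cord_post (ties broken by cpg_id
    so bins are deterministic) and split into ``n_bins`` bins whose sizes
    differ by at most 1; each bin is tested against the full manifest
    background.
    """
    if len(records) < n_bins:
        raise ValidationError(f"universe smaller than {n_bins} CpGs")
    ordered = records.sort_values(
        ["r_cord_post", "cpg_id"], kind="stable").reset_index(drop=True)
    bins = np.array_split(np.arange(len(ordered)), n_bins)
    col = _state_column(annotation)
    ann = manifest.set_index("probe_id")[col]
    n_bg = len(manifest)

    rows = []
    for b, idx in enumerate(bins):
        ids = ordered.loc[idx, "cpg_id"]
        states_in_bin = ann.loc[ids]
        for state in states:
            a = int((states_in_bin == state).sum())
            bb = len(idx) - a
            c = int((manifest[col] == state).sum())
            d = n_bg - c
            fr = _fisher_or_row(a, bb, c, d)
            rows.append({
                "bin": b + 1, "state": state, "n_bin": len(idx), "count": a,
                "odds_ratio": fr["odds_ratio"], "ci_low": fr["ci_low"],
                "ci_high": fr["ci_high"], "zero_cell": fr["zero_cell"],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlap and gene ranking
# ---------------------------------------------------------------------------

def overlap_and_rank(
    memory: pd.DataFrame,
    methexpr: pd.DataFrame,
    manifest: pd.DataFrame,
    nominal_alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Intersect memory candidates with expression-correlated CpGs and rank
    genes by their count of qualifying CpGs (ties alphabetical)."""
    candidates = set(memory.loc[memory["is_candidate"], "cpg_id"])
    correlated = methexpr[methexpr["p"] < nominal_alpha]
    overlap = sorted(candidates & set(correlated["cpg_id"]))

    ann = manifest.set_index("probe_id")["gene"]
    sub = correlated[correlated["cpg_id"].isin(overlap)].drop_duplicates("cpg_id")
    genes = ann.reindex(sub["cpg_id"]).fillna("")
    frame = pd.DataFrame({
        "cpg_id": sub["cpg_id"].to_numpy(), "gene": genes.to_numpy(),
        "relation": sub["relation"].to_numpy(),
    })
    frame = frame[frame["gene"] != ""]
    grouped = frame.groupby("gene").agg(
        n_cpgs=("cpg_id", "nunique"),
        n_concordant=("relation", lambda s: int((s == "concordant").sum())),
        n_discordant=("relation", lambda s: int((s == "discordant").sum())),
    ).reset_index()
    ranked = grouped.sort_values(
        ["n_cpgs", "gene"], ascending=[False, True], kind="stable",
    ).reset_index(drop=True)
    return overlap, ranked
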