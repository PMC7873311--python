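"""Beta computation, probe filtering and reference-based cell deconvolution."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from epimemory.datamodel import CELL_TYPES, ValidationError

FILTER_RULES = (
    "non_cpg", "sex_chromosome", "detection", "beadcount",
    "multi_mapping", "cross_reactive",
)


@dataclasses.dataclass
class FilterReport:
    """Per-rule removal counts; each probe is charged to the first rule
    that removes it, in the fixed order of ``FILTER_RULES``."""

    removed: dict[str, int]
    survivors: int

    @property
    def total_input(self) -> int:
        return self.survivors + sum(self.removed.values())


def compute_beta(M, U):
    """Methylation proportion ``M / (U + M + 100)``; always in [0, 1)."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValidationError("intensities must be non-negative")
    return M / (U + M + 100.0)


def filter_probes(
    manifest: pd.DataFrame,
    qc: pd.DataFrame,
    blacklists: dict[str, set[str]] | None = None,
    detection_policy: str | tuple[str, float] = "any",
    beadcount_policy: str | tuple[str, float] = "any",
    detection_p_threshold: float = 0.01,
    min_beadcount: int = 3,
) -> tuple[list[str], FilterReport]:
    """Apply the QC removal rules in fixed order and reconcile counts.

    ``qc`` is a long table (probe_id, sample_id, detection_p, beadcount).
    Policies: ``"any"`` removes a probe failing in any sample;
    ``("fraction", f)`` removes it when the failing-sample fraction
    exceeds ``f``.
    """
    blacklists = blacklists or {}

    def _fails(per_sample_fail: pd.Series, policy) -> pd.Index:
        frac = per_sample_fail.groupby(level=0).mean()
        if policy == "any":
            return frac.index[frac > 0]
        if isinstance(policy, tuple) and policy[0] == "fraction":
            return frac.index[frac > policy[1]]
        raise ValidationError(f"unknown policy {policy!r}")

    probes = manifest["probe_id"].tolist()
    if "is_cpg" in manifest.columns:
        non_cpg = set(manifest.loc[manifest["is_cpg"].astype(int) == 0, "probe_id"])
    else:
        non_cpg = {p for p in probes if not p.startswith("cg")}
    sex = set(manifest.loc[manifest["chrom"].isin(("chrX", "chrY", "X", "Y")),
                           "probe_id"])

    qc_idx = qc.set_index("probe_id")
    det_fail = set(_fails(qc_idx["detection_p"] > detection_p_threshold,
                          detection_policy))
    bead_fail = set(_fails(qc_idx["beadcount"] < min_beadcount, beadcount_policy))
    multi = set(blacklists.get("multi_mapping", set()))
    cross = set(blacklists.get("cross_reactive", set()))

    rule_sets = {
        "non_cpg": non_cpg, "sex_chromosome": sex, "detection": det_fail,
        "beadcount": bead_fail, "multi_mapping": multi, "cross_reactive": cross,
    }
    removed = {rule: 0 for rule in FILTER_RULES}
    kept: list[str] = []
    for p in probes:
        for rule in FILTER_RULES:
            if p in rule_sets[rule]:
                removed[rule] += 1
                break
        else:
            kept.append(p)
    return kept, FilterReport(removed=removed, survivors=len(kept))


def estimate_cell_fractions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    sum_to_one: bool = False,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Constrained projection of each sample's betas onto reference profiles.

    Solves ``min ||R w - b||^2`` subject to ``w >= 0`` and ``sum(w) <= 1``
    (or ``== 1`` with ``sum_to_one``) for each sample.  ``beta`` must be
    restricted to the reference CpGs; ``reference`` is CpGs x cell types.
    Returns one row per sample with the 7 fractions and the residual norm.
    """
    missing = reference.index.difference(beta.index)
    if len(missing):
        raise ValidationError(f"beta matrix lacks reference CpGs: {list(missing)[:5]}")
    if list(reference.columns) != list(CELL_TYPES):
        raise ValidationError(f"reference columns must be {CELL_TYPES}")
    R = reference.to_numpy()
    if R.shape[0] < R.shape[1]:
        raise ValidationError("need at least as many reference CpGs as cell types")
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValidationError(
            "reference profile matrix is rank-deficient; supply more or "
            "better-separating reference CpGs")

    B = beta.loc[reference.index].to_numpy()
    K = R.shape[1]
    RtR = R.T @ R

    rows = []
    for j, sample in enumerate(beta.columns):
        b = B[:, j]
        Rtb = R.T @ b

        def objective(w):
            return float(w @ RtR @ w - 2.0 * Rtb @ w + b @ b)

        def grad(w):
            return 2.0 * (RtR @ w - Rtb)

        cons = ({"type": "eq", "fun": lambda w: w.sum() - 1.0,
                 "jac": lambda w: np.ones(K)} if sum_to_one else
                {"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                 "jac": lambda w: -np.ones(K)})
        w0 = np.full(K, 1.0 / K if sum_to_one else 0.9 / K)
        res = optimize.minimize(
            objective, w0, jac=grad, method="SLSQP",
            bounds=[(0.0, 1.0)] * K, constraints=[cons],
            options={"maxiter": 200, "ftol": tol})
        w = np.clip(res.x, 0.0, None)
        if sum_to_one:
            w = w / w.sum()
        rows.append([sample, *w, float(np.linalg.norm(R @ w - b))])

    return pd.DataFrame(rows, columns=["sample_id", *CELL_TYPES, "residual_norm"])


def renormalize_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc rescale of the fractions to sum exactly to 1 per sample."""
    out = fractions.copy()
    vals = out.loc[:, list(CELL_TYPES)].to_numpy()
    out.loc[:, list(CELL_TYPES)] = vals / vals.sum(axis=1, keepdims=True)
    return out
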