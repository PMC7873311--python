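"""Prenatal covariate association with GA and birth-weight SD score.

Continuous covariates are standardized to SD 0.5 (two-SD scaling) so their
estimates are comparable with the unscaled binary covariates; each
estimate is then the outcome change per two-SD increase of a continuous
covariate or per category switch of a binary one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from epimemory.datamodel import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    ValidationError,
)

DEFAULT_MULTIVARIATE_SET = (
    "cesarean", "maternal_bmi", "smoke_before", "cam", "iprom", "preeclampsia",
)


def sga_sd_cutoff(percentile: float = 0.10) -> float:
    """|z| cutoff equivalent to a birth-weight percentile threshold.

    The 10th percentile of the standard normal gives the small-for-GA
    SD-score boundary (1.28 after rounding to two decimals).
    """
    return abs(float(stats.norm.ppf(percentile)))


def gelman_scale(values) -> np.ndarray:
    """Center and rescale a continuous vector to mean 0 and sample SD 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValidationError("cannot scale a constant vector")
    sd = x.std(ddof=1)
    return (x - x.mean()) / (2.0 * sd)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValidationError("design matrix is rank-deficient")
    resid = y - X @ coef
    dof = n - p
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
    return coef, se, dof


def _effect_row(name, est, se, dof, model):
    tcrit = stats.t.ppf(0.975, dof)
    p = 2.0 * stats.t.sf(abs(est / se), dof)
    return {
        "covariate": name, "estimate": est,
        "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
        "p": p, "model": model,
    }


def covariate_screen(
    sheet: pd.DataFrame,
    outcome: str = "GA",
    screen_p: float = 0.05,
    multivariate_set: tuple[str, ...] | None = None,
    include_sd_score: bool = False,
) -> pd.DataFrame:
    """Univariate OLS per covariate, then one multivariate adjustment model.

    The multivariate model includes infant sex plus either the configured
    covariate set (default: the six carried into the adjusted EWAS model)
    or, when ``multivariate_set=()``, the covariates passing the p screen.
    """
    if outcome not in ("GA", "SDscore"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    cord = sheet[sheet["tissue"] == "cord"]
    y = (cord["ga_weeks"] if outcome == "GA" else cord["bw_sd_score"]).to_numpy(float)
    if np.unique(y).size < 2:
        raise ValidationError("outcome is constant")
    n = len(cord)
    ones = np.ones(n)

    predictors: dict[str, np.ndarray] = {
        "sex_male": (cord["sex"] == "male").to_numpy(float)}
    for c in CONTINUOUS_COVARIATES:
        predictors[c] = gelman_scale(cord[c].to_numpy(float))
    for c in BINARY_COVARIATES:
        predictors[c] = cord[c].to_numpy(float)
    if outcome == "GA":
        predictors["bw_sd_score"] = cord["bw_sd_score"].to_numpy(float)
    else:
        predictors["ga_weeks"] = cord["ga_weeks"].to_numpy(float)

    rows = []
    for name, x in predictors.items():
        if np.unique(x).size < 2:
            continue
        coef, se, dof = _ols(y, np.column_stack([ones, x]))
        rows.append(_effect_row(name, coef[1], se[1], dof, "univariate"))
    uni = pd.DataFrame(rows)

    if multivariate_set is None:
        selected = list(DEFAULT_MULTIVARIATE_SET)
    elif len(multivariate_set) == 0:
        passed = uni[(uni["p"] < screen_p) & (uni["covariate"] != "sex_male")]
        selected = [c for c in passed["covariate"]
                    if c not in ("bw_sd_score", "ga_weeks")]
    else:
        selected = list(multivariate_set)
    if include_sd_score and outcome == "GA" and "bw_sd_score" not in selected:
        selected.append("bw_sd_score")

    # constant covariates carry no information and would break the fit
    names = [c for c in ["sex_male"] + [c for c in selected if c in predictors]
             if np.unique(predictors[c]).size > 1]
    X = np.column_stack([ones] + [predictors[c] for c in names])
    coef, se, dof = _ols(y, X)
    multi_rows = [_effect_row(nm, coef[i + 1], se[i + 1], dof, "multivariate")
                  for i, nm in enumerate(names)]
    return pd.concat([uni, pd.DataFrame(multi_rows)], ignore_index=True)
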