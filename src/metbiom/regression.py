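"""Multiple linear regression of fresh yield on component traits.

Fitted per environment on replicate-averaged genotype means (one
observation per genotype) via ordinary least squares, with per-slope
two-sided t p-values, the model F p-value, and a sequential (type-I)
contribution profile whose shares sum to the model R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import TraitTable, genotype_env_means

__all__ = ["RegressionResult", "CollinearityError", "fit_fy_regression",
           "contribution_profile"]

log = logging.getLogger(__name__)


class CollinearityError(ValueError):
    pass


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    slopes: pd.Series
    intercept: float
    p_values: pd.Series
    r2_percent: float
    model_p: float
    n: int
    design: pd.DataFrame     # genotype means used for the fit (incl. response)


def _design_frame(table: TraitTable, response: str, predictors, environment,
                  plot_level: bool) -> pd.DataFrame:
    if plot_level:
        df = table.data
        if environment is not None:
            df = df[df["environment"] == environment]
        wide = df.pivot_table(
            index=["genotype", "environment", "replicate"], columns="trait",
            values="value", aggfunc="first",
        )
        return wide[[response, *predictors]].dropna()
    cols = {}
    for trait in [response, *predictors]:
        means = genotype_env_means(table, trait)
        cols[trait] = (
            means[environment] if environment is not None else means["overall"]
        )
    return pd.DataFrame(cols)


def fit_fy_regression(
    table: TraitTable,
    environment: str | None = None,
    response: str = "FY",
    predictors=None,
    *,
    plot_level: bool = False,
) -> RegressionResult:
    """OLS of ``response`` on ``predictors`` (default: all other traits)."""
    predictors = (
        list(predictors)
        if predictors is not None
        else [t for t in table.traits if t != response]
    )
    if response in predictors:
        raise ValueError("response cannot also be a predictor")
    if "YPP" in predictors and response == "FY":
        log.warning(
            "predictor YPP is nearly definitional for FY; expect structural "
            "collinearity in the fitted slopes"
        )
    frame = _design_frame(table, response, predictors, environment, plot_level)
    n = len(frame)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} observations, have {n}"
        )
    x = sm.add_constant(frame[predictors].to_numpy(float))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify dependent columns for the error message
        dep = []
        for i, name in enumerate(predictors):
            sub = np.delete(x, i + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                dep.append(name)
        raise CollinearityError(f"rank-deficient design; dependent columns: {dep}")
    fit = sm.OLS(frame[response].to_numpy(float), x).fit()
    slopes = pd.Series(fit.params[1:], index=predictors)
    pvals = pd.Series(fit.pvalues[1:], index=predictors)
    return RegressionResult(
        response=response,
        predictors=predictors,
        slopes=slopes,
        intercept=float(fit.params[0]),
        p_values=pvals,
        r2_percent=float(100.0 * fit.rsquared),
        model_p=float(fit.f_pvalue),
        n=n,
        design=frame,
    )


def contribution_profile(result: RegressionResult) -> pd.DataFrame:
    """Sequential (type-I) R^2 share per predictor, in the fitted order.

    Shares sum to the model ``r2_percent`` by construction.  Standardized
    coefficients are emitted alongside as an order-free alternative view.
    """
    frame = result.design
    y = frame[result.response].to_numpy(float)
    shares = []
    prev_r2 = 0.0
    for i in range(1, len(result.predictors) + 1):
        x = sm.add_constant(frame[result.predictors[:i]].to_numpy(float))
        r2 = sm.OLS(y, x).fit().rsquared * 100.0
        shares.append(r2 - prev_r2)
        prev_r2 = r2
    sd_y = frame[result.response].std()
    std_coef = [
        result.slopes[p] * frame[p].std() / sd_y for p in result.predictors
    ]
    return pd.DataFrame(
        {
            "predictor": result.predictors,
            "share_r2_percent": shares,
            "standardized_b": std_coef,
        }
    )
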