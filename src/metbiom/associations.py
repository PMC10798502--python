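"""Genotypic and phenotypic trait correlations from paired covariance analysis.

The mean cross-product decomposition mirrors the ANOVA: the error
covariance is the error mean cross-product, the genotypic covariance is
(genotype mean cross-product - error mean cross-product) / r, and the
phenotypic covariance is their sum.  Genotypic correlations whose absolute
value exceeds 1 (a known quirk of the moment estimator) are capped at 0.99
and flagged; pairs with a non-positive genotypic variance on either side
are reported not-estimable, as in published practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitTable

__all__ = [
    "CorrelationPair",
    "covariance_components",
    "correlation_matrices",
    "correlation_long",
]

CAP = 0.99


@dataclass
class CorrelationPair:
    trait_x: str
    trait_y: str
    r_g: float          # NaN when not estimable
    r_p: float
    p_g: float
    p_p: float
    capped: bool


def _paired_matrices(table: TraitTable, trait_x: str, trait_y: str,
                     environment: str | None):
    """Aligned observation matrices (genotype x unit) for two traits.

    Units are replicates within one environment, or environment-replicate
    combinations in pooled mode.
    """
    def pivot(trait):
        df = table.subset(trait, environment)
        cols = (
            "replicate" if environment is not None else ["environment", "replicate"]
        )
        mat = df.pivot_table(index="genotype", columns=cols, values="value",
                             aggfunc="first")
        if mat.isna().any().any():
            raise ValueError(f"unbalanced slice for trait {trait!r}")
        return mat.reindex(index=table.genotypes)

    mx, my = pivot(trait_x), pivot(trait_y)
    if not mx.columns.equals(my.columns):
        raise ValueError(
            f"design mismatch between {trait_x!r} and {trait_y!r}"
        )
    return mx.to_numpy(float), my.to_numpy(float)


def covariance_components(
    table: TraitTable, trait_x: str, trait_y: str,
    environment: str | None = None,
) -> dict:
    """Moment cross-product components {cov_g, cov_e, cov_p}.

    With ``environment=None`` the components come from the pooled (all
    environments) genotype decomposition; the per-genotype-mean replication
    factor is then n_environments * n_replicates.
    """
    x, y = _paired_matrices(table, trait_x, trait_y, environment)
    g, r = x.shape
    # genotype mean cross-products
    dx = x.mean(axis=1) - x.mean()
    dy = y.mean(axis=1) - y.mean()
    mcp_gen = r * (dx @ dy) / (g - 1)
    # residual cross-products after removing genotype and unit (block) effects
    rx = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    ry = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    mcp_err = (rx * ry).sum() / ((g - 1) * (r - 1))
    cov_e = float(mcp_err)
    cov_g = float((mcp_gen - mcp_err) / r)
    return {"cov_g": cov_g, "cov_e": cov_e, "cov_p": cov_g + cov_e}


def _correlation_p(r: float, df: int) -> float:
    if not np.isfinite(r) or abs(r) >= 1.0:
        return 0.0 if np.isfinite(r) else np.nan
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def correlation_matrices(
    table: TraitTable, traits=None, environment: str | None = None,
    cap: float = CAP,
) -> dict:
    """Genotypic and phenotypic correlation matrices over trait pairs.

    Returns ``{"r_g": DataFrame, "r_p": DataFrame, "pairs": [CorrelationPair]}``.
    """
    traits = list(traits) if traits is not None else table.traits
    n = len(traits)
    comp = {}
    for i, tx in enumerate(traits):
        for j in range(i, n):
            comp[(i, j)] = covariance_components(table, tx, traits[j], environment)
    rg = np.eye(n)
    rp = np.eye(n)
    pairs = []
    df_sig = table.n_genotypes - 2
    for i in range(n):
        for j in range(i + 1, n):
            vx, vy = comp[(i, i)], comp[(j, j)]
            c = comp[(i, j)]
            # phenotypic
            r_p = c["cov_p"] / np.sqrt(vx["cov_p"] * vy["cov_p"])
            r_p = float(np.clip(r_p, -1.0, 1.0))
            # genotypic: only when both genotypic variances positive
            capped = False
            if vx["cov_g"] > 0 and vy["cov_g"] > 0:
                r_g = c["cov_g"] / np.sqrt(vx["cov_g"] * vy["cov_g"])
                if abs(r_g) > 1.0:
                    r_g = float(np.sign(r_g) * cap)
                    capped = True
            else:
                r_g = np.nan
            rg[i, j] = rg[j, i] = r_g
            rp[i, j] = rp[j, i] = r_p
            pairs.append(
                CorrelationPair(
                    trait_x=traits[i], trait_y=traits[j],
                    r_g=r_g, r_p=r_p,
                    p_g=_correlation_p(r_g, df_sig),
                    p_p=_correlation_p(r_p, df_sig),
                    capped=capped,
                )
            )
    return {
        "r_g": pd.DataFrame(rg, index=traits, columns=traits),
        "r_p": pd.DataFrame(rp, index=traits, columns=traits),
        "pairs": pairs,
    }


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_long(result: dict) -> pd.DataFrame:
    """Long-format pair table with significance stars."""
    rows = []
    for pr in result["pairs"]:
        rows.append(
            {
                "trait_x": pr.trait_x,
                "trait_y": pr.trait_y,
                "r_g": pr.r_g,
                "sig_g": _stars(pr.p_g) if np.isfinite(pr.r_g) else "-",
                "r_p": pr.r_p,
                "sig_p": _stars(pr.p_p),
                "capped": pr.capped,
            }
        )
    return pd.DataFrame(rows)
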