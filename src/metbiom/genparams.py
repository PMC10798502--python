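"""Genetic-parameter suite per trait and environment.

From the RCBD variance components: environmental/genotypic/phenotypic
coefficients of variation, broad-sense heritability with its conventional
classification, genetic advance under truncation selection, and genetic
gain (advance as a percent of the trait mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import VarianceComponents, fit_rcbd_anova, precision_stats, variance_components
from .io import TraitTable, genotype_env_means

__all__ = [
    "DEFAULT_K",
    "GeneticParamRow",
    "coefficients_of_variation",
    "broad_sense_heritability",
    "heritability_class",
    "cv_class",
    "genetic_advance",
    "row_from_components",
    "build_table1",
]

#: standardized selection differential at 5% selection intensity
DEFAULT_K = 2.06


@dataclass
class GeneticParamRow:
    trait: str
    environment: str
    max: float
    min: float
    mean: float
    SE: float
    CV_percent: float
    CD5: float
    CD1: float
    sigma2_e: float
    sigma2_g: float
    sigma2_p: float
    ECV: float
    GCV: float
    PCV: float
    h2b: float
    h2b_class: str
    GA: float
    GG: float
    k: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def coefficients_of_variation(vc: VarianceComponents) -> dict:
    """ECV/GCV/PCV: component standard deviations as percent of the mean."""
    if vc.grand_mean <= 0:
        raise ValueError("coefficients of variation undefined for non-positive mean")
    m = vc.grand_mean
    return {
        "ECV": 100.0 * np.sqrt(vc.sigma2_e) / m,
        "GCV": 100.0 * np.sqrt(vc.sigma2_g) / m,
        "PCV": 100.0 * np.sqrt(vc.sigma2_p) / m,
    }


def heritability_class(h2b: float) -> str:
    """Low (0-30%), moderate (30-60%) and high (>60%) bands on 100*h2b."""
    pct = 100.0 * h2b
    if pct <= 30.0:
        return "low"
    if pct <= 60.0:
        return "moderate"
    return "high"


def cv_class(cv_percent: float, *, low: float = 10.0, high: float = 20.0) -> str:
    if cv_percent < low:
        return "low"
    if cv_percent <= high:
        return "moderate"
    return "high"


def broad_sense_heritability(vc: VarianceComponents) -> tuple[float, str]:
    if vc.sigma2_p <= 0:
        raise ValueError("heritability undefined: phenotypic variance is zero")
    h2b = vc.sigma2_g / vc.sigma2_p
    return h2b, heritability_class(h2b)


def genetic_advance(vc: VarianceComponents, k: float = DEFAULT_K) -> dict:
    """GA = k * h2b * sigma_p (trait units); GG = 100 * GA / mean (percent)."""
    if vc.sigma2_p <= 0:
        return {"GA": 0.0, "GG": 0.0}
    h2b = vc.sigma2_g / vc.sigma2_p
    ga = k * h2b * np.sqrt(vc.sigma2_p)
    if vc.grand_mean <= 0:
        raise ValueError("genetic gain undefined for non-positive mean")
    return {"GA": float(ga), "GG": float(100.0 * ga / vc.grand_mean)}


def row_from_components(
    trait: str,
    environment: str,
    vc: VarianceComponents,
    *,
    k: float = DEFAULT_K,
    max_value: float = np.nan,
    min_value: float = np.nan,
) -> GeneticParamRow:
    """Derive the full parameter row from variance components alone.

    This is the path used to check published summary rows: feed a printed
    (mean, sigma2_e, sigma2_g, r, df_error) and every derived column follows.
    """
    prec = precision_stats(vc)
    cvs = coefficients_of_variation(vc)
    if vc.sigma2_p > 0:
        h2b, h2cls = broad_sense_heritability(vc)
    else:
        h2b, h2cls = np.nan, "undefined"  # constant trait: flagged, not propagated
    adv = genetic_advance(vc, k=k)
    return GeneticParamRow(
        trait=trait,
        environment=environment,
        max=max_value,
        min=min_value,
        mean=vc.grand_mean,
        SE=prec["SE"],
        CV_percent=prec["CV_percent"],
        CD5=prec["CD"][0.05],
        CD1=prec["CD"][0.01],
        sigma2_e=vc.sigma2_e,
        sigma2_g=vc.sigma2_g,
        sigma2_p=vc.sigma2_p,
        ECV=cvs["ECV"],
        GCV=cvs["GCV"],
        PCV=cvs["PCV"],
        h2b=h2b,
        h2b_class=h2cls,
        GA=adv["GA"],
        GG=adv["GG"],
        k=k,
    )


def build_table1(table: TraitTable, *, k: float = DEFAULT_K, traits=None,
                 environments=None) -> pd.DataFrame:
    """One genetic-parameter row per trait per environment.

    Max/min/mean are taken over replicate-averaged genotype means; the
    variance components come from the per-environment RCBD fit.
    """
    table.validate_balance()
    traits = list(traits) if traits is not None else table.traits
    environments = (
        list(environments) if environments is not None else table.environments
    )
    rows = []
    for env in environments:
        for trait in traits:
            anova = fit_rcbd_anova(table, trait, env)
            means = genotype_env_means(table, trait)[env]
            vc = variance_components(
                anova, r=table.n_replicates, grand_mean=float(means.mean())
            )
            row = row_from_components(
                trait, env, vc, k=k,
                max_value=float(means.max()), min_value=float(means.min()),
            )
            rows.append(row.as_dict())
    return pd.DataFrame(rows)
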