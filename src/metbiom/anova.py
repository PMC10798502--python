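"""RCBD and combined genotype x environment analysis of variance.

Moment (expected-mean-square) machinery only: per-environment randomized
complete block fits, variance-component extraction, precision statistics,
and the multi-year genotype x year decomposition with a percent-of-total-SS
partition.  No REML or mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitTable

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "DesignError",
    "fit_rcbd_anova",
    "variance_components",
    "precision_stats",
    "combined_gxy_anova",
]


class DesignError(ValueError):
    """The data slice does not support the requested decomposition."""


@dataclass
class AnovaTable:
    """Ordered source decomposition with df/SS/MS and optional F/p."""

    sources: pd.DataFrame  # columns: source, df, SS, MS, F, p
    total_df: int
    total_SS: float

    def __post_init__(self) -> None:
        df_sum = int(self.sources["df"].sum())
        ss_sum = float(self.sources["SS"].sum())
        if df_sum != self.total_df:
            raise AssertionError(f"df do not add up: {df_sum} != {self.total_df}")
        denom = max(abs(self.total_SS), 1.0)
        if abs(ss_sum - self.total_SS) > 1e-9 * denom:
            raise AssertionError(f"SS do not add up: {ss_sum} != {self.total_SS}")

    def __getitem__(self, source: str) -> pd.Series:
        row = self.sources[self.sources["source"] == source]
        if row.empty:
            raise KeyError(source)
        return row.iloc[0]

    def with_percent_total(self) -> pd.DataFrame:
        out = self.sources.copy()
        out["pct_total_SS"] = 100.0 * out["SS"] / self.total_SS
        return out


@dataclass
class VarianceComponents:
    """Moment estimates: sigma2_e = error MS, sigma2_g = (MS_gen - MS_err)/r."""

    sigma2_e: float
    sigma2_g: float
    r: int
    df_error: int
    grand_mean: float
    truncated: bool = field(default=False)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e


def _cell_matrix(table: TraitTable, trait: str, environment: str) -> pd.DataFrame:
    """Genotype x replicate value matrix for one environment slice."""
    df = table.subset(trait, environment)
    if df.empty:
        raise DesignError(f"no data for trait {trait!r} in {environment!r}")
    mat = df.pivot_table(index="genotype", columns="replicate", values="value",
                         aggfunc="first")
    if mat.isna().any().any():
        raise DesignError(
            f"unbalanced slice for trait {trait!r} in {environment!r}: missing cells"
        )
    counts = df.groupby(["genotype", "replicate"], observed=True).size()
    if (counts != 1).any():
        raise DesignError("duplicate plot observations in slice")
    return mat.reindex(index=[g for g in table.genotypes if g in mat.index])


def fit_rcbd_anova(table: TraitTable, trait: str, environment: str) -> AnovaTable:
    """Two-way fixed-effects RCBD decomposition for one environment.

    Sources: replication (R-1), genotype (G-1), error ((G-1)(R-1)).
    Genotype and replication F-ratios are tested against the error MS.
    """
    mat = _cell_matrix(table, trait, environment)
    y = mat.to_numpy(dtype=float)
    g, r = y.shape
    if g < 2 or r < 2:
        raise DesignError(f"need >=2 genotypes and >=2 replicates, got {g}x{r}")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_gen = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_rep = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_gen - ss_rep
    df_gen, df_rep = g - 1, r - 1
    df_err = df_gen * df_rep
    ms_gen, ms_rep, ms_err = ss_gen / df_gen, ss_rep / df_rep, ss_err / df_err

    def ftest(ms, df):
        if ms_err <= 0:
            return np.nan, np.nan
        f = ms / ms_err
        return f, float(stats.f.sf(f, df, df_err))

    f_rep, p_rep = ftest(ms_rep, df_rep)
    f_gen, p_gen = ftest(ms_gen, df_gen)
    sources = pd.DataFrame(
        {
            "source": ["Replication", "Genotype", "Error"],
            "df": [df_rep, df_gen, df_err],
            "SS": [ss_rep, ss_gen, ss_err],
            "MS": [ms_rep, ms_gen, ms_err],
            "F": [f_rep, f_gen, np.nan],
            "p": [p_rep, p_gen, np.nan],
        }
    )
    return AnovaTable(sources, total_df=g * r - 1, total_SS=ss_total)


def variance_components(anova: AnovaTable, r: int, grand_mean: float) -> VarianceComponents:
    if r < 2:
        raise DesignError("sigma2_g is not estimable with fewer than 2 replicates")
    ms_err = float(anova["Error"]["MS"])
    ms_gen = float(anova["Genotype"]["MS"])
    sigma2_g = (ms_gen - ms_err) / r
    truncated = sigma2_g < 0
    if truncated:
        sigma2_g = 0.0
    return VarianceComponents(
        sigma2_e=ms_err,
        sigma2_g=sigma2_g,
        r=r,
        df_error=int(anova["Error"]["df"]),
        grand_mean=grand_mean,
        truncated=truncated,
    )


def precision_stats(vc: VarianceComponents, alpha_levels=(0.05, 0.01)) -> dict:
    """Standard error of a genotype mean, CV%, and critical differences.

    SE = sqrt(sigma2_e / r); CV% = 100 * sqrt(sigma2_e) / mean;
    CD(alpha) = t(1 - alpha/2, df_error) * sqrt(2 * sigma2_e / r).
    """
    if vc.grand_mean <= 0:
        raise ValueError("CV% undefined for non-positive grand mean")
    se = float(np.sqrt(vc.sigma2_e / vc.r))
    cv = float(100.0 * np.sqrt(vc.sigma2_e) / vc.grand_mean)
    sed = np.sqrt(2.0 * vc.sigma2_e / vc.r)
    cd = {
        a: float(stats.t.ppf(1.0 - a / 2.0, vc.df_error) * sed) for a in alpha_levels
    }
    return {"SE": se, "CV_percent": cv, "CD": cd}


def combined_gxy_anova(table: TraitTable, trait: str) -> AnovaTable:
    """Multi-year decomposition with replication nested within year.

    Sources: replication-within-year (Y(R-1)), genotype (G-1), year (Y-1),
    genotype x year ((G-1)(Y-1)), residual.  Genotype, year and interaction
    are tested against the residual MS.
    """
    envs = table.environments
    if len(envs) < 2:
        raise DesignError("combined ANOVA needs >=2 environments")
    df = table.subset(trait)
    cube = df.pivot_table(
        index="genotype", columns=["environment", "replicate"], values="value",
        aggfunc="first",
    )
    if cube.isna().any().any():
        raise DesignError(f"unbalanced table for trait {trait!r}")
    cube = cube.reindex(index=table.genotypes)
    g = len(table.genotypes)
    yn = len(envs)
    reps = sorted({rep for (_, rep) in cube.columns})
    r = len(reps)
    # genotype x year x replicate array
    arr = np.empty((g, yn, r))
    for j, env in enumerate(envs):
        for k, rep in enumerate(reps):
            arr[:, j, k] = cube[(env, rep)].to_numpy(dtype=float)

    grand = arr.mean()
    ss_total = float(((arr - grand) ** 2).sum())
    gm = arr.mean(axis=(1, 2))          # genotype means
    ym = arr.mean(axis=(0, 2))          # year means
    gym = arr.mean(axis=2)              # genotype x year cell means
    repm = arr.mean(axis=0)             # year x replicate means
    ss_gen = float(yn * r * ((gm - grand) ** 2).sum())
    ss_year = float(g * r * ((ym - grand) ** 2).sum())
    ss_gy = float(r * ((gym - gm[:, None] - ym[None, :] + grand) ** 2).sum())
    ss_rep = float(g * ((repm - ym[:, None]) ** 2).sum())
    ss_res = ss_total - ss_gen - ss_year - ss_gy - ss_rep
    dfs = {
        "Rep(Year)": yn * (r - 1),
        "Genotype": g - 1,
        "Year": yn - 1,
        "Genotype x Year": (g - 1) * (yn - 1),
    }
    dfs["Residual"] = (g * yn * r - 1) - sum(dfs.values())
    sss = {
        "Rep(Year)": ss_rep,
        "Genotype": ss_gen,
        "Year": ss_year,
        "Genotype x Year": ss_gy,
        "Residual": ss_res,
    }
    ms = {k: sss[k] / dfs[k] for k in sss}
    ms_res, df_res = ms["Residual"], dfs["Residual"]
    rows = []
    for name in ["Rep(Year)", "Genotype", "Year", "Genotype x Year", "Residual"]:
        if name != "Residual" and ms_res > 0:
            f = ms[name] / ms_res
            p = float(stats.f.sf(f, dfs[name], df_res))
        else:
            f = p = np.nan
        rows.append((name, dfs[name], sss[name], ms[name], f, p))
    sources = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
    return AnovaTable(sources, total_df=g * yn * r - 1, total_SS=ss_total)
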