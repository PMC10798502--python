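"""Geometric adaptability index and rank-based genotype selection.

The index for a genotype and trait is the geometric mean of its
environment means.  Genotypes are ranked per trait (rank 1 = highest
index, ties averaged), ranks are consolidated into a mean rank (MR), MR is
re-ranked (R.MR), and top-ten occurrences feed a minimum-occurrence
selection rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import TraitTable, genotype_env_means

__all__ = [
    "GaiMatrix",
    "RankReport",
    "geometric_adaptability_index",
    "gai_from_table",
    "rank_by_gai",
    "consolidate_ranks",
    "select_superior",
]

log = logging.getLogger(__name__)


@dataclass
class GaiMatrix:
    """Genotype x trait matrix of geometric adaptability indices."""

    gai: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.gai.to_numpy(float) <= 0).any():
            raise ValueError("GAI values must be positive")


@dataclass
class RankReport:
    ranks: pd.DataFrame            # genotype x trait, average-tie ranks
    mean_rank: pd.Series           # MR
    rank_of_mean_rank: pd.Series   # R.MR
    occurrence_top10: pd.Series

    def as_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["MR"] = self.mean_rank
        out["R_MR"] = self.rank_of_mean_rank
        out["occurrence_top10"] = self.occurrence_top10
        return out


def geometric_adaptability_index(year_means: pd.DataFrame) -> pd.Series:
    """Row-wise geometric mean of a genotype x environment mean matrix."""
    vals = year_means.to_numpy(float)
    if (vals <= 0).any():
        bad = year_means.index[(vals <= 0).any(axis=1)].tolist()
        raise ValueError(
            f"geometric mean undefined for non-positive environment means: {bad}"
        )
    return pd.Series(
        np.exp(np.log(vals).mean(axis=1)), index=year_means.index
    )


def gai_from_table(table: TraitTable, traits=None) -> GaiMatrix:
    """GAI per genotype and trait from replicate-averaged environment means.

    Genotypes with a non-positive environment mean for any requested trait
    are excluded with a logged message rather than silently dropped.
    """
    traits = list(traits) if traits is not None else table.traits
    cols = {}
    excluded: set[str] = set()
    per_trait_means = {}
    for trait in traits:
        m = genotype_env_means(table, trait)[table.environments]
        per_trait_means[trait] = m
        excluded |= set(m.index[(m.to_numpy(float) <= 0).any(axis=1)])
    if excluded:
        log.warning("excluding %d genotype(s) with non-positive means: %s",
                    len(excluded), sorted(excluded))
    keep = [g for g in table.genotypes if g not in excluded]
    for trait in traits:
        cols[trait] = geometric_adaptability_index(per_trait_means[trait].loc[keep])
    return GaiMatrix(pd.DataFrame(cols).loc[keep])


def rank_by_gai(gai: GaiMatrix) -> pd.DataFrame:
    """Per-trait descending ranks: 1 = highest index, ties averaged."""
    ranks = gai.gai.apply(lambda col: rankdata(-col.to_numpy(float), method="average"))
    return pd.DataFrame(ranks, index=gai.gai.index, columns=gai.gai.columns)


def consolidate_ranks(ranks: pd.DataFrame, top: int = 10) -> RankReport:
    mr = ranks.mean(axis=1)
    r_mr = pd.Series(rankdata(mr.to_numpy(float), method="average"), index=mr.index)
    occ = (ranks <= top).sum(axis=1)
    return RankReport(
        ranks=ranks, mean_rank=mr, rank_of_mean_rank=r_mr, occurrence_top10=occ
    )


def select_superior(
    report: RankReport,
    min_occurrence: int = 5,
    *,
    extra_top_k_by: dict | None = None,
) -> pd.DataFrame:
    """Genotypes appearing at least ``min_occurrence`` times in the top ten.

    ``extra_top_k_by`` maps a trait (rank column) to k; genotypes in the
    top k of that column are admitted too, tagged with the reason.
    """
    reasons: dict[str, list[str]] = {}
    for g in report.occurrence_top10.index[
        report.occurrence_top10 >= min_occurrence
    ]:
        reasons.setdefault(g, []).append(f"occurrence>={min_occurrence}")
    for trait, k in (extra_top_k_by or {}).items():
        col = report.ranks[trait]
        for g in col.index[col <= k]:
            reasons.setdefault(g, []).append(f"top{k}:{trait}")
    order = [g for g in report.ranks.index if g in reasons]
    return pd.DataFrame(
        {
            "genotype": order,
            "occurrence_top10": [report.occurrence_top10[g] for g in order],
            "reason": ["; ".join(reasons[g]) for g in order],
        }
    )
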