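"""Bundled reference statistics from a published three-year turmeric trial.

A 53-genotype randomized-complete-block trial (2 replications) evaluated
twelve rhizome-yield traits over three seasons.  The plot-level data were
never deposited, but the published per-trait summaries are internally
consistent: every derived column (CVs, heritability, genetic advance, ...)
can be recomputed from the printed mean and variance components.  These
tables therefore serve three roles here:

* fixture inputs for :func:`metbiom.simulate.table1_like_config`,
* regression oracles for the genetic-parameter formulas,
* inputs for the rank-aggregation and ANOVA-partition checks.

All numbers are copied verbatim from the published report at its printed
precision (2 decimals).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TRAITS",
    "ENVIRONMENTS",
    "N_GENOTYPES",
    "N_REPLICATES",
    "genetic_parameter_table",
    "gai_rank_table",
    "GXY_SUM_SQUARES",
    "GXY_DF",
]

#: twelve trait codes, in published column order
TRAITS = ["PH", "NB", "NL", "NMR", "WMR", "NPF", "WPF", "NSF", "WSF", "LMR", "YPP", "FY"]

ENVIRONMENTS = ["2019-20", "2020-21", "2021-22"]
N_GENOTYPES = 53
N_REPLICATES = 2

_GP_COLUMNS = [
    "trait", "environment", "max", "min", "mean", "SE", "CV_percent", "CD5", "CD1",
    "sigma2_e", "sigma2_g", "sigma2_p", "ECV", "GCV", "PCV", "h2b", "GA", "GG",
]

# per-trait genetic-parameter rows: max, min, mean, SE, CV%, CD5%, CD1%,
# sigma2_e, sigma2_g, sigma2_p, ECV, GCV, PCV, h2b, GA, GG
_GP_ROWS = [
    # 2019-20
    ("PH", "2019-20", 140.36, 54.13, 86.94, 6.03, 9.81, 17.11, 22.79, 72.67, 275.09, 347.76, 9.81, 19.08, 21.45, 0.79, 30.39, 34.95),
    ("NB", "2019-20", 4.49, 1.34, 2.52, 0.17, 9.41, 0.48, 0.64, 0.06, 0.34, 0.39, 9.43, 23.03, 24.88, 0.86, 1.11, 43.90),
    ("NL", "2019-20", 31.24, 10.67, 18.62, 1.32, 9.99, 3.73, 4.97, 3.46, 22.93, 26.39, 9.99, 25.73, 27.60, 0.87, 9.20, 49.40),
    ("NMR", "2019-20", 2.75, 0.92, 1.61, 0.11, 9.66, 0.31, 0.42, 0.02, 0.20, 0.22, 9.66, 27.52, 29.17, 0.89, 0.86, 53.48),
    ("WMR", "2019-20", 188.38, 9.46, 58.91, 5.21, 12.52, 14.80, 19.72, 54.39, 1094.78, 1149.16, 12.52, 56.17, 57.55, 0.95, 66.53, 112.94),
    ("NPF", "2019-20", 10.76, 1.94, 5.67, 0.41, 10.15, 1.15, 1.54, 0.33, 3.58, 3.92, 10.15, 33.42, 34.93, 0.92, 3.73, 65.87),
    ("WPF", "2019-20", 173.80, 17.28, 64.27, 5.50, 12.11, 15.62, 20.81, 60.57, 1188.63, 1249.20, 12.11, 53.64, 54.99, 0.95, 69.28, 107.79),
    ("NSF", "2019-20", 16.78, 2.91, 8.38, 0.61, 10.28, 1.73, 2.30, 0.74, 9.67, 10.42, 10.28, 37.13, 38.52, 0.93, 6.18, 73.71),
    ("WSF", "2019-20", 118.80, 8.97, 38.00, 3.27, 12.15, 9.27, 12.35, 21.32, 583.57, 604.89, 12.15, 63.57, 64.72, 0.96, 48.88, 128.63),
    ("LMR", "2019-20", 10.07, 3.49, 6.04, 0.42, 9.74, 1.18, 1.57, 0.35, 1.30, 1.65, 9.74, 18.91, 21.27, 0.79, 2.09, 34.62),
    ("YPP", "2019-20", 1603.80, 47.53, 242.51, 27.40, 15.98, 77.75, 103.60, 1501.28, 47066.27, 48567.55, 15.98, 89.46, 90.88, 0.97, 439.95, 181.42),
    ("FY", "2019-20", 30.80, 1.46, 10.05, 0.99, 13.91, 2.80, 3.74, 1.95, 49.29, 51.24, 13.91, 69.88, 71.25, 0.96, 14.18, 141.17),
    # 2020-21
    ("PH", "2020-21", 118.98, 57.47, 100.24, 3.75, 5.29, 10.64, 14.18, 28.14, 39.15, 67.29, 5.29, 6.24, 8.18, 0.58, 9.83, 9.81),
    ("NB", "2020-21", 4.12, 2.05, 2.91, 0.11, 5.27, 0.31, 0.41, 0.02, 0.09, 0.11, 5.31, 10.28, 11.57, 0.79, 0.55, 18.82),
    ("NL", "2020-21", 34.86, 10.10, 25.72, 0.98, 5.39, 2.78, 3.71, 1.92, 12.61, 14.53, 5.39, 13.81, 14.82, 0.87, 6.81, 26.50),
    ("NMR", "2020-21", 3.09, 0.95, 1.51, 0.06, 5.66, 0.17, 0.23, 0.01, 0.22, 0.22, 5.65, 30.73, 31.25, 0.97, 0.94, 62.26),
    ("WMR", "2020-21", 314.18, 33.95, 127.40, 4.96, 5.50, 14.07, 18.75, 49.18, 3592.61, 3641.79, 5.50, 47.05, 47.37, 0.99, 122.64, 96.26),
    ("NPF", "2020-21", 9.19, 0.97, 2.15, 0.10, 6.74, 0.29, 0.39, 0.02, 1.07, 1.09, 6.71, 48.23, 48.70, 0.98, 2.11, 98.42),
    ("WPF", "2020-21", 247.16, 42.40, 97.92, 3.94, 5.69, 11.17, 14.89, 31.01, 1751.90, 1782.90, 5.69, 42.75, 43.12, 0.98, 85.47, 87.29),
    ("NSF", "2020-21", 22.31, 5.83, 11.69, 0.46, 5.61, 1.32, 1.76, 0.43, 9.36, 9.80, 5.62, 26.17, 26.77, 0.96, 6.16, 52.71),
    ("WSF", "2020-21", 529.20, 22.09, 205.88, 8.67, 5.96, 24.61, 32.79, 150.38, 7732.94, 7883.32, 5.96, 42.71, 43.13, 0.98, 179.41, 87.15),
    ("LMR", "2020-21", 12.76, 5.06, 8.98, 0.33, 5.27, 0.95, 1.26, 0.22, 1.47, 1.69, 5.27, 13.50, 14.49, 0.87, 2.33, 25.90),
    ("YPP", "2020-21", 1161.83, 146.60, 488.05, 20.04, 5.81, 56.88, 75.79, 803.48, 36257.85, 37061.33, 5.81, 39.02, 39.45, 0.98, 387.98, 79.50),
    ("FY", "2020-21", 36.55, 4.19, 20.96, 0.81, 5.47, 2.30, 3.06, 1.31, 57.99, 59.31, 5.46, 36.34, 36.75, 0.98, 15.51, 74.03),
    # 2021-22
    ("PH", "2021-22", 139.53, 77.19, 106.16, 5.40, 7.19, 15.31, 20.40, 58.23, 136.59, 194.82, 7.19, 11.01, 13.15, 0.70, 20.16, 18.99),
    ("NB", "2021-22", 11.56, 2.47, 5.62, 0.30, 7.65, 0.86, 1.15, 0.18, 2.48, 2.67, 7.65, 28.01, 29.04, 0.93, 3.13, 55.67),
    ("NL", "2021-22", 39.16, 13.02, 24.83, 1.29, 7.36, 3.66, 4.88, 3.33, 24.08, 27.41, 7.35, 19.77, 21.09, 0.88, 9.48, 38.16),
    ("NMR", "2021-22", 3.41, 0.93, 1.44, 0.07, 7.38, 0.21, 0.28, 0.01, 0.23, 0.25, 7.35, 33.67, 34.46, 0.95, 0.97, 67.76),
    ("WMR", "2021-22", 315.00, 23.04, 77.47, 4.39, 8.01, 12.45, 16.59, 38.51, 1977.05, 2015.56, 8.01, 57.40, 57.95, 0.98, 90.72, 117.10),
    ("NPF", "2021-22", 16.01, 1.19, 6.35, 0.32, 7.02, 0.90, 1.19, 0.20, 4.76, 4.96, 7.02, 34.35, 35.06, 0.96, 4.40, 69.33),
    ("WPF", "2021-22", 319.99, 40.61, 112.88, 6.50, 8.15, 18.45, 24.59, 84.55, 2741.62, 2826.17, 8.15, 46.39, 47.10, 0.97, 106.24, 94.12),
    ("NSF", "2021-22", 16.01, 3.49, 7.98, 0.42, 7.48, 1.20, 1.60, 0.36, 6.35, 6.71, 7.48, 31.59, 32.46, 0.95, 5.05, 63.32),
    ("WSF", "2021-22", 384.30, 27.89, 87.81, 5.39, 8.68, 15.29, 20.37, 58.07, 3076.71, 3134.78, 8.68, 63.17, 63.76, 0.98, 113.20, 128.92),
    ("LMR", "2021-22", 9.92, 5.19, 7.35, 0.38, 7.29, 1.08, 1.43, 0.29, 0.86, 1.15, 7.30, 12.63, 14.59, 0.75, 1.66, 22.54),
    ("YPP", "2021-22", 721.09, 97.27, 281.32, 15.71, 7.90, 44.57, 59.39, 493.43, 15418.26, 15911.70, 7.90, 44.14, 44.84, 0.97, 251.79, 89.51),
    ("FY", "2021-22", 47.70, 3.80, 19.54, 1.09, 7.89, 3.09, 4.12, 2.38, 90.37, 92.74, 7.89, 48.65, 49.29, 0.97, 19.33, 98.93),
]


def genetic_parameter_table() -> pd.DataFrame:
    """Published genetic-parameter summary, one row per trait x season."""
    return pd.DataFrame(_GP_ROWS, columns=_GP_COLUMNS)


# Published per-trait adaptability-index rank rows (12 trait ranks, mean
# rank MR, rank-of-MR, and number of ranks within the top ten).  Tied ranks
# carry the average of the tied positions (e.g. 9.5).
_RANK_COLUMNS = ["genotype", *TRAITS, "MR", "R_MR", "occurrence_top10"]

_RANK_ROWS = [
    ("BARI Holud-1", 40, 48, 41, 5, 47, 29, 20, 33, 3, 45, 24, 21, 29.67, 34, 2),
    ("BARI Holud-2", 43, 47, 31, 32, 39, 36, 42, 28, 26, 25, 47, 39, 36.25, 44, 0),
    ("BARI Holud-3", 28, 35, 34, 9.5, 21, 43, 27, 29, 28, 43, 33, 24, 29.54, 33, 1),
    ("BARI Holud-4", 11, 23.5, 25, 22, 13, 20, 11, 12, 13, 7, 20, 14, 15.96, 10, 1),
    ("BARI Holud-5", 16, 21, 14, 26, 42, 40, 35, 34, 43, 47, 38, 25, 31.75, 38, 0),
    ("T0008", 24, 43, 38, 43.5, 12, 18, 13, 13, 15, 19, 21, 35, 24.54, 22, 0),
    ("T0012", 41, 46, 43, 15, 34, 13, 12, 6, 27, 41, 27, 37, 28.50, 30, 1),
    ("T0013", 48, 29, 35, 36, 45, 25, 30, 10, 32, 23, 40, 48, 33.42, 40, 1),
    ("T0015", 17, 6, 20, 43.5, 19, 33, 28, 30, 33, 11, 29, 8, 23.13, 18, 2),
    ("T0016", 39, 44, 24, 8, 40, 31, 34, 7, 2, 48, 15, 29, 26.75, 26, 3),
    ("T0017", 20, 33, 8, 53, 37, 28, 37, 11, 17, 4, 42, 31, 26.75, 27, 2),
    ("T0019", 47, 3, 16, 25, 22, 1, 22, 8, 42, 44, 19, 11, 21.67, 16, 3),
    ("T0023", 30, 53, 23, 47, 33, 51, 41, 15, 8, 8, 9, 30, 29.00, 36, 3),
    ("T0052", 49, 51, 44, 18, 46, 52, 49, 53, 52, 51, 50, 51, 47.17, 51, 0),
    ("T0061", 13, 15, 29, 22, 5, 17, 8, 41, 38, 17, 14, 9, 19.00, 15, 3),
    ("T0063", 23, 7, 22, 49, 25, 30, 31, 40, 41, 16, 36, 32, 29.33, 32, 0),
    ("T0066", 27, 23.5, 32, 41, 17, 24, 15, 27, 20, 46, 11, 13, 24.71, 23, 1),
    ("T0077", 52, 40, 51, 3, 48, 37, 25, 50, 25, 53, 31, 49, 38.67, 45, 1),
    ("T0082", 7, 2, 10, 9.5, 2, 32, 7, 1, 11, 2, 3, 5, 7.63, 3, 10),
    ("T0083", 32, 10, 9, 30, 38, 41, 48, 35, 44, 39, 43, 40, 34.08, 42, 2),
    ("T0084", 14, 17, 19, 6, 31, 7, 16, 22, 19, 21, 28, 12, 17.67, 11, 2),
    ("T0085", 18, 13, 11, 19, 8, 9, 10, 17, 16, 14, 5, 10, 12.50, 7, 5),
    ("T0093", 35, 9, 2, 52, 32, 5, 18, 26, 40, 1, 12, 27, 21.58, 15, 4),
    ("T0094", 6, 12, 5, 2, 14, 3, 29, 32, 24, 31, 22, 3, 15.25, 9, 5),
    ("T0095", 36, 30, 18, 22, 50, 12, 47, 20, 31, 42, 44, 42, 32.83, 39, 0),
    ("T0095-1", 31, 25, 42, 40, 35, 46, 39, 48, 45, 40, 32, 43, 38.83, 46, 0),
    ("T0096", 12, 27, 53, 48, 16, 38, 40, 46, 30, 6, 39, 16, 30.92, 37, 1),
    ("T0097", 8, 34, 26, 14, 11, 16, 23, 18, 21, 26, 16, 22, 19.58, 14, 1),
    ("T0098", 21, 28, 30, 33, 29, 6, 21, 31, 35, 35, 30, 34, 27.75, 29, 1),
    ("T0102", 19, 4, 39, 31, 28, 19, 32, 25, 23, 29, 34, 15, 24.83, 24, 1),
    ("T0103", 3, 1, 1, 27, 23, 11, 1, 37, 22, 10, 8, 2, 12.17, 6, 7),
    ("T0104", 45, 41, 36, 42, 43, 48, 45, 44, 50, 13, 41, 50, 41.50, 48, 0),
    ("T0105", 33, 38, 28, 16, 20, 26, 33, 23, 9, 18, 17, 33, 24.50, 21, 1),
    ("T0106", 5, 5, 3, 7, 6, 14, 19, 16, 5, 27, 2, 6, 9.58, 4, 8),
    ("T0107", 26, 19, 12, 36, 26, 2, 24, 4, 48, 20, 49, 26, 24.33, 20, 2),
    ("T0108", 51, 42, 50, 38, 41, 8, 4, 47, 18, 22, 18, 19, 29.83, 36, 2),
    ("T0109", 42, 49, 48, 50, 51, 53, 53, 52, 51, 50, 53, 53, 50.42, 53, 0),
    ("T0116", 22, 8, 6, 29, 27, 42, 44, 38, 34, 33, 23, 20, 27.17, 28, 2),
    ("T0117", 1, 11, 17, 4, 4, 10, 6, 14, 10, 3, 10, 1, 7.58, 2, 9),
    ("T0118", 10, 18, 15, 46, 36, 47, 14, 36, 14, 38, 26, 17, 26.42, 25, 1),
    ("T0119", 9, 20, 27, 11.5, 18, 35, 26, 24, 36, 15, 35, 18, 22.88, 17, 1),
    ("T0121", 4, 26, 7, 1, 1, 4, 2, 5, 1, 30, 1, 7, 7.42, 1, 10),
    ("T0122", 50, 31, 37, 51, 53, 49, 50, 45, 46, 52, 37, 46, 45.58, 49, 0),
    ("T0123", 15, 50, 40, 20, 7, 23, 46, 39, 39, 24, 25, 28, 29.67, 35, 1),
    ("T0124", 29, 36, 47, 45, 24, 21, 38, 42, 37, 5, 46, 44, 34.50, 43, 1),
    ("T0126", 44, 37, 33, 34, 9, 44, 5, 2, 4, 28, 13, 36, 24.08, 19, 4),
    ("T0127", 53, 45, 52, 36, 52, 39, 52, 51, 53, 49, 52, 52, 48.83, 52, 0),
    ("T0128", 34, 32, 46, 28, 30, 27, 36, 19, 29, 34, 45, 45, 33.75, 41, 0),
    ("T0129", 2, 22, 13, 17, 15, 22, 9, 21, 7, 36, 7, 4, 14.58, 8, 5),
    ("T0130", 46, 52, 49, 24, 49, 50, 51, 49, 49, 37, 51, 47, 46.17, 50, 0),
    ("T0132", 25, 16, 4, 13, 3, 15, 3, 3, 6, 12, 4, 23, 10.58, 5, 6),
    ("T0133", 37, 39, 45, 39, 44, 34, 43, 43, 47, 32, 48, 38, 40.75, 47, 0),
    ("T0134", 38, 14, 21, 11.5, 10, 45, 17, 9, 12, 9, 6, 41, 19.46, 13, 4),
]


def gai_rank_table() -> pd.DataFrame:
    """Published per-trait adaptability ranks with mean-rank consolidation."""
    return pd.DataFrame(_RANK_ROWS, columns=_RANK_COLUMNS)


#: published combined genotype x year ANOVA sums of squares for fresh yield
GXY_SUM_SQUARES = {
    "Rep": 3.4,
    "Genotype": 11675.69,
    "Year": 7458.75,
    "Genotype x Year": 9171.76,
    "Residuals": 293.47,
}

#: published degrees of freedom for the same ANOVA (residual df 156 implies
#: replication nested within year, i.e. Y(R-1) = 3, not the printed Rep df 1)
GXY_DF = {"Genotype": 52, "Year": 2, "Genotype x Year": 104, "Residuals": 156}
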