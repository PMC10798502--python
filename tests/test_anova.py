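import numpy as np
import pandas as pd
import pytest

from metbiom.anova import (
    DesignError,
    combined_gxy_anova,
    fit_rcbd_anova,
    precision_stats,
    variance_components,
)
from metbiom.io import TraitTable
from metbiom.simulate import SimulationConfig, TraitSpec, simulate_met
from conftest import make_table


def _table_from_values(values):
    """values[g][r] single-trait single-environment layout."""
    rows = []
    for gi, reps in enumerate(values):
        for rk, v in enumerate(reps, start=1):
            rows.append((f"g{gi}", "e0", rk, "A", float(v)))
    return TraitTable(
        pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    )


def brute_force_rcbd(y):
    """Definitional sums for the two-way decomposition; independent oracle."""
    y = np.asarray(y, float)
    g, r = y.shape
    grand = y.mean()
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(g) for j in range(r))
    ss_gen = sum(r * (y[i, :].mean() - grand) ** 2 for i in range(g))
    ss_rep = sum(g * (y[:, j].mean() - grand) ** 2 for j in range(r))
    return ss_rep, ss_gen, ss_tot - ss_gen - ss_rep, ss_tot


def test_noiseless_contrast():
    table = _table_from_values([[1, 1], [3, 3]])
    res = fit_rcbd_anova(table, "A", "e0")
    assert res["Genotype"]["SS"] == pytest.approx(4.0)
    assert res["Error"]["SS"] == pytest.approx(0.0, abs=1e-12)
    assert res["Replication"]["SS"] == pytest.approx(0.0, abs=1e-12)


def test_constant_data_all_zero():
    table = _table_from_values([[5, 5], [5, 5], [5, 5]])
    res = fit_rcbd_anova(table, "A", "e0")
    assert res.total_SS == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rcbd_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(10, 3, size=(6, 3))
    table = _table_from_values(y)
    res = fit_rcbd_anova(table, "A", "e0")
    ss_rep, ss_gen, ss_err, ss_tot = brute_force_rcbd(y)
    assert res["Replication"]["SS"] == pytest.approx(ss_rep, rel=1e-8)
    assert res["Genotype"]["SS"] == pytest.approx(ss_gen, rel=1e-8)
    assert res["Error"]["SS"] == pytest.approx(ss_err, rel=1e-8)
    assert res.total_SS == pytest.approx(ss_tot, rel=1e-12)
    # df layout
    assert res["Genotype"]["df"] == 5
    assert res["Replication"]["df"] == 2
    assert res["Error"]["df"] == 10


def test_additivity_on_every_fit(small_table):
    for env in small_table.environments:
        res = fit_rcbd_anova(small_table, "A", env)
        assert res.sources["df"].sum() == res.total_df
        assert res.sources["SS"].sum() == pytest.approx(res.total_SS, rel=1e-12)
        ms = res.sources["SS"] / res.sources["df"]
        assert np.allclose(ms, res.sources["MS"])


def test_unbalanced_slice_is_design_error(small_table):
    broken = TraitTable(small_table.data.iloc[1:].reset_index(drop=True))
    with pytest.raises(DesignError):
        fit_rcbd_anova(broken, "A", small_table.environments[0])


def test_variance_components_inverse_arithmetic():
    # MS_gen = 622.85, MS_err = 72.67, r = 2 -> sigma2_g = 275.09
    sources = pd.DataFrame(
        {
            "source": ["Replication", "Genotype", "Error"],
            "df": [1, 52, 52],
            "SS": [0.0, 622.85 * 52, 72.67 * 52],
            "MS": [0.0, 622.85, 72.67],
            "F": [np.nan] * 3,
            "p": [np.nan] * 3,
        }
    )
    from metbiom.anova import AnovaTable

    anova = AnovaTable(sources, total_df=105, total_SS=622.85 * 52 + 72.67 * 52)
    vc = variance_components(anova, r=2, grand_mean=86.94)
    assert vc.sigma2_g == pytest.approx(275.09, abs=1e-9)
    assert vc.sigma2_e == pytest.approx(72.67)
    assert vc.sigma2_p == vc.sigma2_g + vc.sigma2_e


def test_negative_sigma2g_truncated():
    from metbiom.anova import AnovaTable

    sources = pd.DataFrame(
        {
            "source": ["Replication", "Genotype", "Error"],
            "df": [1, 5, 5],
            "SS": [0.0, 5.0, 50.0],
            "MS": [0.0, 1.0, 10.0],
            "F": [np.nan] * 3,
            "p": [np.nan] * 3,
        }
    )
    anova = AnovaTable(sources, total_df=11, total_SS=55.0)
    vc = variance_components(anova, r=2, grand_mean=1.0)
    assert vc.sigma2_g == 0.0
    assert vc.truncated


def test_equal_ms_gives_zero_sigma2g():
    from metbiom.anova import AnovaTable

    sources = pd.DataFrame(
        {
            "source": ["Replication", "Genotype", "Error"],
            "df": [1, 5, 5],
            "SS": [0.0, 50.0, 50.0],
            "MS": [0.0, 10.0, 10.0],
            "F": [np.nan] * 3,
            "p": [np.nan] * 3,
        }
    )
    vc = variance_components(AnovaTable(sources, 11, 100.0), r=2, grand_mean=1.0)
    assert vc.sigma2_g == 0.0


def test_precision_stats_zero_error():
    from metbiom.anova import VarianceComponents

    vc = VarianceComponents(sigma2_e=0.0, sigma2_g=1.0, r=2, df_error=10, grand_mean=5.0)
    out = precision_stats(vc)
    assert out["SE"] == 0.0
    assert out["CV_percent"] == 0.0
    assert out["CD"][0.05] == 0.0


def test_cd_ordering_strict():
    from metbiom.anova import VarianceComponents

    vc = VarianceComponents(sigma2_e=3.0, sigma2_g=1.0, r=2, df_error=20, grand_mean=5.0)
    out = precision_stats(vc)
    assert out["CD"][0.01] > out["CD"][0.05] > 0


def test_combined_brute_force_oracle():
    table = make_table(g=4, y=2, r=2, traits=("A",), seed=9)
    res = combined_gxy_anova(table, "A")
    df = table.data
    grand = df["value"].mean()
    ss_tot = ((df["value"] - grand) ** 2).sum()
    gm = df.groupby("genotype")["value"].mean()
    ym = df.groupby("environment")["value"].mean()
    gym = df.groupby(["genotype", "environment"])["value"].mean()
    repm = df.groupby(["environment", "replicate"])["value"].mean()
    ss_gen = 4 * ((gm - grand) ** 2).sum()
    ss_year = 8 * ((ym - grand) ** 2).sum()
    ss_gy = 2 * sum(
        (gym[g, e] - gm[g] - ym[e] + grand) ** 2
        for g in table.genotypes
        for e in table.environments
    )
    ss_rep = 4 * sum((repm[e, r] - ym[e]) ** 2 for e, r in repm.index)
    assert res["Genotype"]["SS"] == pytest.approx(ss_gen, rel=1e-8)
    assert res["Year"]["SS"] == pytest.approx(ss_year, rel=1e-8)
    assert res["Genotype x Year"]["SS"] == pytest.approx(ss_gy, rel=1e-8)
    assert res["Rep(Year)"]["SS"] == pytest.approx(ss_rep, rel=1e-8)
    assert res.sources["SS"].sum() == pytest.approx(ss_tot, rel=1e-10)


def test_combined_df_layout_matches_reference_design():
    # G=53, Y=3, R=2: residual df must be 156 with replication nested in year
    table = make_table(g=53, y=3, r=2, traits=("A",), seed=2)
    res = combined_gxy_anova(table, "A")
    assert res["Rep(Year)"]["df"] == 3
    assert res["Genotype"]["df"] == 52
    assert res["Year"]["df"] == 2
    assert res["Genotype x Year"]["df"] == 104
    assert res["Residual"]["df"] == 156


def test_combined_single_environment_rejected(single_env_table):
    with pytest.raises(DesignError):
        combined_gxy_anova(single_env_table, "A")


def test_null_year_and_gy_f_near_one():
    """With no year or interaction variance the F ratios average ~1."""
    fs_year, fs_gy = [], []
    for seed in range(40):
        cfg = SimulationConfig(
            n_genotypes=10, n_environments=3, n_replicates=2,
            traits=[TraitSpec("X", 10.0, 0.0, 4.0)], seed=seed,
        )
        table, _ = simulate_met(cfg)
        res = combined_gxy_anova(table, "X")
        fs_year.append(res["Year"]["F"])
        fs_gy.append(res["Genotype x Year"]["F"])
    # E[F] = df2/(df2-2) is slightly above 1; allow generous MC slack
    assert 0.7 < np.mean(fs_year) < 1.8
    assert 0.8 < np.mean(fs_gy) < 1.3


def test_sigma2g_recovery_monte_carlo():
    """Moment estimator recovers configured sigma2_g within 3 MC SEs."""
    true_g, true_e = 40.0, 10.0
    ests = []
    for seed in range(200):
        cfg = SimulationConfig(
            n_genotypes=100, n_environments=1, n_replicates=2,
            traits=[TraitSpec("X", 20.0, true_g, true_e)], seed=seed,
        )
        table, _ = simulate_met(cfg)
        anova = fit_rcbd_anova(table, "X", "E1")
        vc = variance_components(anova, 2, 20.0)
        ests.append(vc.sigma2_g)
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - true_g) < 3 * se
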