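import numpy as np
import pandas as pd
import pytest

from metbiom.clustering import (
    ClusterSolution,
    DistanceMatrix,
    cluster_genotypes,
    cluster_summary,
    dendrogram_newick,
    linkage_tree,
    mahalanobis_d2,
    pooled_within_covariance,
    standardized_euclidean_d2,
    tocher_cluster,
    trait_mean_matrix,
)
from conftest import make_table


def means_frame(arr, labels=None):
    arr = np.asarray(arr, float)
    labels = labels or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels,
                        columns=[f"t{j}" for j in range(arr.shape[1])])


def test_identical_means_zero_distance():
    m = means_frame([[1.0, 2.0], [1.0, 2.0]])
    cov = pd.DataFrame(np.eye(2), index=m.columns, columns=m.columns)
    dm = mahalanobis_d2(m, cov)
    assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_identity_cov_reduces_to_euclidean():
    rng = np.random.default_rng(0)
    m = means_frame(rng.normal(size=(5, 3)))
    cov = pd.DataFrame(np.eye(3), index=m.columns, columns=m.columns)
    dm = mahalanobis_d2(m, cov)
    x = m.to_numpy()
    for i in range(5):
        for j in range(5):
            assert dm.D[i, j] == pytest.approx(((x[i] - x[j]) ** 2).sum(), rel=1e-9)


def test_toy_brute_force_matrix_arithmetic():
    m = means_frame([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
    cov = pd.DataFrame([[2.0, 1.0], [1.0, 2.0]], index=m.columns, columns=m.columns)
    prec = np.linalg.inv(cov.to_numpy())
    dm = mahalanobis_d2(m, cov)
    x = m.to_numpy()
    for i in range(4):
        for j in range(4):
            d = x[i] - x[j]
            assert dm.D[i, j] == pytest.approx(d @ prec @ d, rel=1e-8)


def test_d2_invariant_under_linear_transform():
    rng = np.random.default_rng(1)
    m = means_frame(rng.normal(size=(6, 3)))
    resid = rng.normal(size=(40, 3))
    cov = pd.DataFrame(resid.T @ resid / 39, index=m.columns, columns=m.columns)
    dm = mahalanobis_d2(m, cov)
    a = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # nonsingular
    m2 = means_frame(m.to_numpy() @ a.T)
    cov2 = pd.DataFrame(a @ cov.to_numpy() @ a.T, index=m2.columns, columns=m2.columns)
    dm2 = mahalanobis_d2(m2, cov2)
    assert np.allclose(dm.D, dm2.D, rtol=1e-6)


def test_pooled_within_covariance_matches_brute_force():
    table = make_table(g=4, y=2, r=3, traits=("A", "B"), seed=8)
    cov = pooled_within_covariance(table)
    wide = table.data.pivot_table(index=["genotype", "environment", "replicate"],
                                  columns="trait", values="value")
    total = np.zeros((2, 2))
    df = 0
    for (_, _), cell in wide.groupby(level=["genotype", "environment"]):
        r = cell - cell.mean()
        total += r.T.to_numpy() @ r.to_numpy()
        df += len(cell) - 1
    assert np.allclose(cov.to_numpy(), total / df, rtol=1e-9)


def test_two_separated_blobs_recovered():
    rng = np.random.default_rng(2)
    blob1 = rng.normal(0.0, 0.5, size=(5, 2))
    blob2 = rng.normal(20.0, 0.5, size=(5, 2))
    m = means_frame(np.vstack([blob1, blob2]))
    cov = pd.DataFrame(0.25 * np.eye(2), index=m.columns, columns=m.columns)
    dm = mahalanobis_d2(m, cov)
    for method in ("ward", "average"):
        sol = cluster_genotypes(dm, method=method, k=2)
        labels = sol.assignments.to_numpy()
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
    # Tocher may split a tight blob (threshold = max nearest-neighbour
    # distance) but must never merge genotypes across the two blobs
    labels = cluster_genotypes(dm, method="tocher").assignments.to_numpy()
    assert set(labels[:5]).isdisjoint(set(labels[5:]))


def test_k_equals_n_all_singletons():
    rng = np.random.default_rng(3)
    m = means_frame(rng.normal(size=(6, 2)))
    dm = standardized_euclidean_d2(m)
    sol = cluster_genotypes(dm, method="ward", k=6)
    assert sol.n_clusters == 6
    summary = cluster_summary(sol, dm, m)
    assert np.allclose(np.diag(summary["distances"].to_numpy()), 0.0)


def test_k_one_single_cluster():
    rng = np.random.default_rng(4)
    m = means_frame(rng.normal(size=(5, 2)))
    dm = standardized_euclidean_d2(m)
    sol = cluster_genotypes(dm, method="average", k=1)
    assert sol.n_clusters == 1
    summary = cluster_summary(sol, dm, m)
    assert summary["distances"].shape == (1, 1)


def test_k_exceeding_n_rejected():
    m = means_frame(np.eye(3))
    dm = standardized_euclidean_d2(m)
    with pytest.raises(ValueError, match="exceeds"):
        cluster_genotypes(dm, method="ward", k=5)


def test_summary_brute_force_oracle():
    rng = np.random.default_rng(5)
    m = means_frame(rng.normal(size=(5, 2)))
    d2 = rng.uniform(1, 10, size=(5, 5))
    d2 = (d2 + d2.T) / 2
    np.fill_diagonal(d2, 0.0)
    dm = DistanceMatrix(list(m.index), d2, metric="mahalanobis_D2")
    sol = ClusterSolution(pd.Series([1, 1, 2, 2, 2], index=m.index), "manual")
    summary = cluster_summary(sol, dm, m, scale="sqrt")
    d = np.sqrt(d2)
    assert summary["distances"].loc[1, 1] == pytest.approx(d[0, 1])
    intra2 = np.mean([d[2, 3], d[2, 4], d[3, 4]])
    assert summary["distances"].loc[2, 2] == pytest.approx(intra2)
    inter = np.mean([d[i, j] for i in (0, 1) for j in (2, 3, 4)])
    assert summary["distances"].loc[1, 2] == pytest.approx(inter)
    assert summary["distances"].loc[2, 1] == pytest.approx(inter)
    # cluster means are unweighted member means
    assert np.allclose(summary["cluster_means"].loc[1], m.iloc[:2].mean())
    # membership percentages sum to 100
    assert summary["membership"]["percentage"].sum() == pytest.approx(100.0)
    assert summary["membership"]["percentage"].iloc[1] == pytest.approx(60.0)


def test_membership_percentage_example():
    assert 100 * 25 / 53 == pytest.approx(47.17, abs=0.005)


def test_tocher_deterministic_and_exhaustive():
    rng = np.random.default_rng(6)
    m = means_frame(rng.normal(size=(10, 3)))
    dm = standardized_euclidean_d2(m)
    sol1 = tocher_cluster(dm)
    sol2 = tocher_cluster(dm)
    pd.testing.assert_series_equal(sol1.assignments, sol2.assignments)
    assert set(sol1.assignments.index) == set(m.index)
    assert (sol1.assignments.value_counts().sum()) == 10


def test_singular_covariance_pseudo_inverse_warns(caplog):
    m = means_frame([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
    cov = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]], index=m.columns, columns=m.columns)
    import logging

    with caplog.at_level(logging.WARNING, logger="metbiom.clustering"):
        dm = mahalanobis_d2(m, cov)
    assert "pseudo-inverse" in caplog.text
    assert np.all(np.isfinite(dm.D))


def test_newick_export_parses():
    rng = np.random.default_rng(7)
    m = means_frame(rng.normal(size=(6, 2)), labels=[f"gen {i}" for i in range(6)])
    dm = standardized_euclidean_d2(m)
    z = linkage_tree(dm, "ward")
    nwk = dendrogram_newick(z, dm.labels)
    assert nwk.endswith(";")
    assert nwk.count("(") == nwk.count(")") == 5
    for lab in dm.labels:
        assert lab.replace(" ", "_") in nwk


def test_trait_mean_matrix_shape(small_table):
    m = trait_mean_matrix(small_table)
    assert m.shape == (6, 3)
    g, t = small_table.genotypes[0], small_table.traits[0]
    sub = small_table.data.query("genotype == @g and trait == @t")["value"]
    assert m.loc[g, t] == pytest.approx(sub.mean())
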