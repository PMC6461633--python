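import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from lipidshift.multivariate import (
    MultivariateError,
    cluster_heatmap,
    linkage_to_newick,
    pca_abundance,
    pca_log2fc,
    ward_linkage,
)


def _fixture_matrix(n=6, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.exp(rng.normal(2, 0.5, (n, p)))
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(n)],
        columns=["PC 34:1", "PC 36:2", "PE 38:4", "PI 38:5", "TG 52:3"][:p],
    )


def test_pca_matches_eigendecomposition_oracle():
    """Scores must match a brute-force eigendecomposition of the covariance
    of the preprocessed matrix (up to component sign)."""
    m = _fixture_matrix(5, 4)
    res = pca_abundance(m)
    X = np.log2(m.to_numpy())
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    C = X.T @ X / 1.0
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = res.scores.shape[1]
    oracle_scores = X @ evecs[:, :k]
    for j in range(k):
        col = res.scores.iloc[:, j].to_numpy()
        assert np.allclose(col, oracle_scores[:, j], atol=1e-8) or np.allclose(
            col, -oracle_scores[:, j], atol=1e-8
        )
    assert res.variance_explained.sum() == pytest.approx(100.0)


def test_pca_rank1_structure():
    profile_a = [1.0, 2.0, 4.0, 8.0]
    profile_b = [8.0, 4.0, 2.0, 1.0]
    m = pd.DataFrame(
        [profile_a] * 3 + [profile_b] * 3,
        index=[f"s{i}" for i in range(6)],
        columns=["PC 34:1", "PC 36:2", "PE 38:4", "PI 38:5"],
    )
    res = pca_abundance(m)
    assert res.variance_explained[0] == pytest.approx(100.0)
    assert res.variance_explained[1:] == pytest.approx(0.0, abs=1e-8)
    pc1 = res.scores["PC1"]
    assert pc1.iloc[:3].round(6).nunique() == 1
    assert np.sign(pc1.iloc[0]) != np.sign(pc1.iloc[-1])


def test_pca_constant_species_errors():
    m = _fixture_matrix()
    m["PC 34:1"] = 2.0
    with pytest.raises(MultivariateError, match="PC 34:1"):
        pca_abundance(m)


def test_pca_log2fc_sign_flip_flips_loading_only():
    rng = np.random.default_rng(1)
    fc = pd.DataFrame(
        rng.normal(0, 1, (6, 4)),
        index=[f"d{i}" for i in range(6)],
        columns=["PC 34:1", "PC 36:2", "PE 38:4", "PI 38:5"],
    )
    r0 = pca_log2fc(fc)
    flipped = fc.copy()
    flipped["PE 38:4"] *= -1.0
    r1 = pca_log2fc(flipped)
    # variance structure unchanged by a single column sign flip
    assert np.allclose(r0.variance_explained, r1.variance_explained)


def test_pca_degenerate_all_identical_rows():
    fc = pd.DataFrame(
        np.ones((4, 3)),
        columns=["PC 34:1", "PC 36:2", "PE 38:4"],
    )
    with pytest.raises(MultivariateError):
        pca_log2fc(fc)


def test_pca_scores_invariant_to_sample_order():
    m = _fixture_matrix(8, 5, seed=3)
    r0 = pca_abundance(m)
    perm = m.sample(frac=1.0, random_state=5)
    r1 = pca_abundance(perm)
    a = r0.scores.sort_index().to_numpy()
    b = r1.scores.sort_index().to_numpy()
    for j in range(a.shape[1]):
        assert np.allclose(a[:, j], b[:, j], atol=1e-8) or np.allclose(
            a[:, j], -b[:, j], atol=1e-8
        )


def naive_ward(D, variant="D2"):
    """O(n^3) agglomerative oracle via the Lance-Williams recurrence on
    dictionaries (independent of the array implementation)."""
    W = {}
    n = D.shape[0]
    clusters = {i: 1 for i in range(n)}
    val = (lambda d: d**2) if variant == "D2" else (lambda d: d)
    for i in range(n):
        for j in range(i + 1, n):
            W[(i, j)] = val(D[i, j])
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), w = min(W.items(), key=lambda kv: (kv[1], kv[0]))
        h = w**0.5 if variant == "D2" else w
        ni, nj = clusters[i], clusters[j]
        merges.append((i, j, h, ni + nj))
        for k in clusters:
            if k in (i, j):
                continue
            nk = clusters[k]
            wik = W[tuple(sorted((i, k)))]
            wjk = W[tuple(sorted((j, k)))]
            new = ((ni + nk) * wik + (nj + nk) * wjk - nk * w) / (ni + nj + nk)
            W[tuple(sorted((next_id, k)))] = new
        for key in list(W):
            if i in key or j in key:
                del W[key]
        del clusters[i], clusters[j]
        clusters[next_id] = ni + nj
        next_id += 1
    return merges


@pytest.mark.parametrize("variant", ["D", "D2"])
def test_ward_matches_naive_oracle(variant):
    rng = np.random.default_rng(4)
    for _ in range(5):
        X = rng.normal(size=(6, 4))
        D = squareform(pdist(X))
        Z = ward_linkage(D, variant)
        oracle = naive_ward(D, variant)
        for row, (i, j, h, size) in zip(Z, oracle):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(h)
            assert row[3] == size


def test_ward_d2_matches_scipy():
    rng = np.random.default_rng(5)
    for _ in range(10):
        X = rng.normal(size=(7, 4))
        D = squareform(pdist(X))
        Z1 = ward_linkage(D, "D2")
        Z2 = scipy_linkage(squareform(D), method="ward")
        assert np.allclose(np.sort(Z1[:, :2], axis=1), np.sort(Z2[:, :2], axis=1))
        assert np.allclose(Z1[:, 2], Z2[:, 2])


def test_cluster_heatmap_properties():
    m = _fixture_matrix(6, 5, seed=6)
    # duplicate one sample: its pair must merge first at height ~0
    m.loc["s1"] = m.loc["s0"].to_numpy()
    res = cluster_heatmap(m)
    Z = res.z_matrix.to_numpy()
    assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(Z.std(axis=1, ddof=1), 1, atol=1e-12)
    first = res.sample_linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == pytest.approx(0.0, abs=1e-6)
    # newick leaves are a permutation of inputs
    import re

    leaves = set(re.findall(r"[sA-Za-z0-9_]+(?=:)", res.sample_newick.replace("(", "")))
    assert set(m.index) <= leaves


def test_anticorrelated_species_distance_two():
    m = pd.DataFrame(
        {
            "PC 34:1": [1.0, 2.0, 4.0, 8.0],
            "PC 36:2": [8.0, 4.0, 2.0, 1.0],
            "PE 38:4": [1.0, 3.0, 2.0, 5.0],
        },
        index=[f"s{i}" for i in range(4)],
    )
    res = cluster_heatmap(m)
    # anticorrelated pair ends with maximal 1-r distance = 2 -> their merge
    # is the last and highest in the species dendrogram
    assert res.species_linkage[:, 2].max() > 1.0


def test_cluster_zero_variance_species_errors():
    m = _fixture_matrix()
    m["PE 38:4"] = 3.0
    with pytest.raises(MultivariateError, match="PE 38:4"):
        cluster_heatmap(m)


def test_pearson_distance_affine_invariance():
    """Scaling/shifting species rows with positive slope leaves sample
    distances (computed on z-scored rows) unchanged -> identical dendrograms."""
    m = _fixture_matrix(5, 4, seed=8)
    r0 = cluster_heatmap(m)
    scaled = m ** 2.0  # log2 -> affine per-column transform with slope 2
    r1 = cluster_heatmap(scaled)
    assert np.allclose(r0.sample_linkage, r1.sample_linkage)
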