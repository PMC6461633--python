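"""Descriptive multivariate views of the filtered lipidome.

Two PCAs are provided: one of log2-transformed, per-species centred and
unit-variance-scaled concentrations over all samples (treatment effects
appear as before/after separation), and one of per-subject log2 fold
changes (treatment- and sex-specific response signatures).  Hierarchical
clustering uses Pearson correlation distance (1 - r) with Ward
agglomeration on per-species autoscaled log2 values, the combination
typically used for dual-dendrogram abundance heatmaps.

The Ward recurrence is implemented directly (a small Lance-Williams
agglomerator) so both common variants are available: ``"D2"`` applies the
recurrence to squared dissimilarities and reports square-rooted heights,
``"D"`` applies it to the dissimilarities as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "ClusterResult",
    "pca_abundance",
    "pca_log2fc",
    "ward_linkage",
    "linkage_to_newick",
    "cluster_heatmap",
]


class MultivariateError(ValueError):
    pass


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # species x components
    variance_explained: np.ndarray  # per-component %, sums to 100
    preprocessing: dict = field(default_factory=dict)


def _preprocess(
    matrix: pd.DataFrame, log2: bool, center: bool, scale: bool
) -> np.ndarray:
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise MultivariateError("matrix contains missing or non-finite values")
    if log2:
        if (X <= 0).any():
            bad = matrix.columns[(X <= 0).any(axis=0)]
            raise MultivariateError(f"non-positive values, cannot log2: {list(bad[:5])}")
        X = np.log2(X)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = matrix.columns[sd == 0]
            raise MultivariateError(
                f"constant species column(s), scale undefined: {list(bad[:5])}"
            )
        X = X / sd
    return X


def _pca(X: np.ndarray, index, columns, preprocessing: dict) -> PCAResult:
    n, p = X.shape
    if n < 3:
        raise MultivariateError(f"PCA needs >= 3 samples, got {n}")
    total = (X ** 2).sum()
    if total == 0:
        raise MultivariateError("zero total variance: all rows identical after preprocessing")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, p)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic orientation: the largest-magnitude loading is positive
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var_pct = 100.0 * S ** 2 / (S ** 2).sum()
    comps = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=columns, columns=comps),
        variance_explained=var_pct,
        preprocessing=preprocessing,
    )


def pca_abundance(matrix: pd.DataFrame) -> PCAResult:
    """PCA of log2-transformed, centred, unit-variance species columns."""
    prep = {"log2": True, "centred": True, "scaled": True}
    X = _preprocess(matrix, log2=True, center=True, scale=True)
    return _pca(X, matrix.index, matrix.columns, prep)


def pca_log2fc(log2fc: pd.DataFrame) -> PCAResult:
    """PCA of per-subject log2 fold changes (centred and scaled, no log)."""
    prep = {"log2": False, "centred": True, "scaled": True}
    X = _preprocess(log2fc, log2=False, center=True, scale=True)
    return _pca(X, log2fc.index, log2fc.columns, prep)


def _pearson_distance(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; constant rows are rejected upstream."""
    r = np.corrcoef(rows)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def ward_linkage(dist: np.ndarray, variant: str = "D2") -> np.ndarray:
    """Agglomerate a square dissimilarity matrix with the Ward recurrence.

    Returns a linkage array in the conventional (n-1, 4) layout: merged
    cluster ids, merge height, merged size.  Ties are broken by the lowest
    pair of cluster ids, so the merge sequence is deterministic in input
    order.  ``variant="D2"`` squares the dissimilarities before applying
    the Lance-Williams update and reports sqrt heights; ``"D"`` uses them
    as given.
    """
    if variant not in ("D", "D2"):
        raise MultivariateError(f"unknown Ward variant {variant!r}")
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise MultivariateError("dist must be a square matrix of >= 2 items")
    W = D ** 2 if variant == "D2" else D.copy()
    np.fill_diagonal(W, np.inf)

    active = list(range(n))          # positions still in play
    ids = list(range(n))             # cluster ids at those positions
    sizes = np.ones(n)
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = W[np.ix_(active, active)]
        flat = np.argmin(sub)        # row-major: lowest i, then lowest j
        i_pos, j_pos = divmod(flat, sub.shape[0])
        if i_pos > j_pos:
            i_pos, j_pos = j_pos, i_pos
        ai, aj = active[i_pos], active[j_pos]
        w_ij = W[ai, aj]
        height = np.sqrt(w_ij) if variant == "D2" else w_ij
        ni, nj = sizes[ai], sizes[aj]
        Z[step] = [ids[i_pos] if ids[i_pos] < ids[j_pos] else ids[j_pos],
                   ids[j_pos] if ids[i_pos] < ids[j_pos] else ids[i_pos],
                   height, ni + nj]
        # Lance-Williams Ward update into position ai
        for ak in active:
            if ak in (ai, aj):
                continue
            nk = sizes[ak]
            W[ai, ak] = W[ak, ai] = (
                (ni + nk) * W[ak, ai] + (nj + nk) * W[ak, aj] - nk * w_ij
            ) / (ni + nj + nk)
        sizes[ai] = ni + nj
        ids[i_pos] = next_id
        next_id += 1
        del active[j_pos], ids[j_pos]
    return Z


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage array as a Newick string with height-difference
    branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: Dict[int, str] = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = heights[a]
        lb = heights[b]
        node_id = n + step
        nodes[node_id] = f"({nodes[a]}:{h - la:.6g},{nodes[b]}:{h - lb:.6g})"
        heights[node_id] = float(h)
    return nodes[n + len(Z) - 1] + ";"


@dataclass
class ClusterResult:
    z_matrix: pd.DataFrame       # species x samples, autoscaled log2 values
    species_linkage: np.ndarray
    sample_linkage: np.ndarray
    species_newick: str
    sample_newick: str
    distance: str = "pearson"
    ward_variant: str = "D2"


def cluster_heatmap(matrix: pd.DataFrame, ward_variant: str = "D2") -> ClusterResult:
    """Dual-dendrogram clustering of a concentration matrix.

    Rows (species) are autoscaled: log2 values z-scored per species.
    Pairwise distances are 1 - Pearson r — between species over samples,
    and between samples over the autoscaled species rows.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise MultivariateError("need >= 2 samples and >= 2 species")
    X = matrix.to_numpy(dtype=float)
    if (X <= 0).any() or not np.isfinite(X).all():
        raise MultivariateError("concentrations must be positive and finite")
    L = np.log2(X).T  # species x samples
    sd = L.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = matrix.columns[sd == 0]
        raise MultivariateError(f"zero-variance species row(s): {list(bad[:5])}")
    Zmat = (L - L.mean(axis=1, keepdims=True)) / sd[:, None]

    d_species = _pearson_distance(Zmat)
    d_samples = _pearson_distance(Zmat.T)
    link_species = ward_linkage(d_species, ward_variant)
    link_samples = ward_linkage(d_samples, ward_variant)
    zdf = pd.DataFrame(Zmat, index=matrix.columns, columns=matrix.index)
    return ClusterResult(
        z_matrix=zdf,
        species_linkage=link_species,
        sample_linkage=link_samples,
        species_newick=linkage_to_newick(link_species, list(matrix.columns)),
        sample_newick=linkage_to_newick(link_samples, list(matrix.index)),
        ward_variant=ward_variant,
    )
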