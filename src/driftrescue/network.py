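"""Signed-hybrid weighted co-expression network analysis, from similarity to
module-trait correlation.

The chain is: biweight midcorrelation -> signed-hybrid adjacency
(negatives clipped to zero, then raised to the soft-threshold power) ->
topological overlap -> average-linkage clustering of 1 - TOM -> dynamic
tree cut (height cut with recursive splitting at pronounced branch points)
-> module eigengenes (first principal component per module) -> optional
eigengene-based merging -> robust module-trait correlation with BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .drift import bh_fdr, bicor_matrix, bicor_with_p
from .preprocess import ExpressionMatrix

#: size-ranked module label vocabulary (cosmetic, mirrors common usage)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

GREY = "grey"


@dataclass
class NetworkParams:
    """Settings of the co-expression network build."""

    beta: float = 3.0
    network_type: str = "signed_hybrid"
    corr: str = "bicor"
    min_module_size: int = 30
    cut_height: float = 0.99
    core_height: float = 0.8  # branch cores: subtrees whose merges all lie below this
    merge_cut: float = 0.15
    split_gap: float = 0.1  # minimum branch-height gap that triggers a recursive split
    unassigned_label: str = GREY

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if not 0 < self.core_height <= 1:
            raise ValueError("core_height must be in (0, 1]")
        if not 0 <= self.merge_cut < 1:
            raise ValueError("merge_cut must be in [0, 1)")
        if self.network_type != "signed_hybrid":
            raise ValueError("only the signed_hybrid network type is supported")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


def adjacency_signed_hybrid(m: ExpressionMatrix, params: NetworkParams) -> np.ndarray:
    """A_ij = max(bicor_ij, 0)^beta with zero diagonal."""
    params.validate()
    if m.n_samples < 4:
        raise ValueError("network construction needs >= 4 samples")
    X = m.values.to_numpy(dtype=float)
    R = bicor_matrix(X)
    if np.isnan(R).all():
        raise ValueError("all genes are constant; no network can be built")
    R = np.nan_to_num(R, nan=0.0)  # constant genes: no defined co-expression
    A = np.clip(R, 0.0, None) ** params.beta
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """TOM omega_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij), omega_ii = 1."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(A)).max(initial=0) > 0:
        raise ValueError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max(initial=0) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    omega = (L + A) / denom
    np.fill_diagonal(omega, 1.0)
    return np.clip(omega, 0.0, 1.0)


def tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    return 1.0 - topological_overlap(A)


# ---------------------------------------------------------------------------
# dynamic tree cut (height cut + recursive branch splitting)
# ---------------------------------------------------------------------------


def _split_cluster(Z: np.ndarray, node, min_size: int, split_gap: float) -> list[np.ndarray]:
    """Recursively split a dendrogram branch at pronounced internal gaps.

    A node is split into its two children when both are at least
    ``min_size`` leaves and the merge-height gap between the node and its
    taller child exceeds ``split_gap`` (a "significant branch point").
    """
    if node.is_leaf():
        return [np.array([node.id])]
    left, right = node.get_left(), node.get_right()
    if left.count >= min_size and right.count >= min_size:
        gap = node.dist - max(left.dist, right.dist)
        if gap > split_gap:
            return _split_cluster(Z, left, min_size, split_gap) + _split_cluster(
                Z, right, min_size, split_gap
            )
    return [np.array(node.pre_order(lambda x: x.id))]


def detect_modules(
    dissim: np.ndarray,
    params: NetworkParams,
    gene_ids=None,
) -> pd.Series:
    """Average-linkage clustering of a dissimilarity plus dynamic tree cut.

    Returns a gene -> label Series; genes in clusters smaller than
    ``min_module_size`` get the unassigned (grey) label. Labels are
    size-ranked colour names, deterministic given the input.
    """
    params.validate()
    D = np.asarray(dissim, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("dissimilarity must be square")
    if params.min_module_size > n:
        raise ValueError("min_module_size exceeds the number of genes")
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    _, nodes = hierarchy.to_tree(Z, rd=True)

    # branch cores below core_height (genes merging above it are stragglers),
    # then recursive splitting of cores at pronounced branch points
    h = min(params.core_height, params.cut_height)
    roots = _cluster_roots(Z, n, h)
    clusters: list[np.ndarray] = []
    for node_id in roots:
        clusters.extend(
            _split_cluster(Z, nodes[node_id], params.min_module_size, params.split_gap)
        )

    clusters = [c for c in clusters if len(c) >= params.min_module_size]
    clusters.sort(key=lambda c: (-len(c), c.min()))
    labels = np.full(n, params.unassigned_label, dtype=object)
    for rank, members in enumerate(clusters):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        labels[members] = name
    return pd.Series(labels, index=gene_ids, name="module")


def _cluster_roots(Z: np.ndarray, n: int, cut_height: float) -> list[int]:
    """Node ids of the maximal subtrees whose merge heights are <= cut_height."""
    heights = np.concatenate([np.zeros(n), Z[:, 2]])
    parent = np.full(2 * n - 1, -1)
    for i in range(n - 1):
        parent[int(Z[i, 0])] = n + i
        parent[int(Z[i, 1])] = n + i
    below = heights <= cut_height
    roots = [
        int(i)
        for i in range(2 * n - 1)
        if below[i] and (parent[i] == -1 or not below[parent[i]])
    ]
    return roots


# ---------------------------------------------------------------------------
# eigengenes, merging, trait correlation
# ---------------------------------------------------------------------------


def module_eigengenes(
    m: ExpressionMatrix, labels: pd.Series, unassigned_label: str = GREY
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's gene-scaled submatrix.

    Eigengenes are unit-norm sample scores, sign-oriented so the average
    correlation with member genes is positive. Returns (eigengenes
    [modules x samples], variance_explained). A singleton module's
    eigengene is the scaled gene itself (variance explained 1).
    """
    labels = labels.reindex(m.gene_ids)
    if labels.isna().any():
        raise ValueError("labels do not cover all matrix genes")
    X = m.values.to_numpy(dtype=float)
    rows, var_exp = {}, {}
    modules = [l for l in labels.unique() if l != unassigned_label]
    for mod in sorted(modules):
        sub = X[(labels == mod).to_numpy()]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Zs = (sub - mu) / sd
        U, S, Vt = np.linalg.svd(Zs, full_matrices=False)
        eig = Vt[0]
        # orient: average correlation with members positive
        if np.corrcoef(np.vstack([eig, Zs]))[0, 1:].mean() < 0:
            eig = -eig
        rows[mod] = eig
        total = (S**2).sum()
        var_exp[mod] = float(S[0] ** 2 / total) if total > 0 else 0.0
    eigengenes = pd.DataFrame(rows, index=m.sample_ids).T
    return eigengenes, pd.Series(var_exp, name="variance_explained")


def merge_close_modules(
    m: ExpressionMatrix,
    labels: pd.Series,
    merge_cut: float = 0.15,
    unassigned_label: str = GREY,
) -> pd.Series:
    """Iteratively merge modules whose eigengene dissimilarity (1 - cor) is
    below ``merge_cut``, recomputing eigengenes until stable."""
    if not 0 <= merge_cut < 1:
        raise ValueError("merge_cut must be in [0, 1)")
    labels = labels.copy()
    if merge_cut == 0:
        return labels
    while True:
        modules = [l for l in labels.unique() if l != unassigned_label]
        if len(modules) < 2:
            return labels
        eig, _ = module_eigengenes(m, labels, unassigned_label)
        E = eig.to_numpy()
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_cut:
            return labels
        a, b = eig.index[i], eig.index[j]
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, max_p_outliers: float = 0.05
) -> pd.DataFrame:
    """Robust correlation of each eigengene with each trait, BH over the table.

    ``traits`` is samples x traits (indicators or continuous covariates such
    as hours of flow); its index must align with the eigengene columns.
    The outlier cap keeps the biweight from discarding a whole sample group
    of a bimodal eigengene (the recommended setting for group contrasts).
    """
    if not eigengenes.columns.equals(traits.index):
        if set(eigengenes.columns) != set(traits.index):
            raise ValueError("traits are not aligned with the eigengene samples")
        traits = traits.loc[eigengenes.columns]
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            r, p = bicor_with_p(e, traits[trait].to_numpy(dtype=float), max_p_outliers)
            rows.append({"module": mod, "trait": trait, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def reassign_by_kme(
    m: ExpressionMatrix,
    labels: pd.Series,
    kme_threshold: float = 0.5,
    unassigned_label: str = GREY,
) -> pd.Series:
    """Final membership pass by module membership (kME).

    Every gene is assigned to the module whose eigengene it follows most
    strongly, provided that correlation reaches ``kme_threshold``; genes
    below the bar become grey. This both expels weakly-connected genes that
    topological-overlap chaining pulled into a branch core (their kME is
    chance-level, ~N(0, 1/n_samples)) and reattaches true members lost as
    dendrogram stragglers.
    """
    labels = labels.copy()
    modules = [l for l in labels.unique() if l != unassigned_label]
    if not modules:
        return labels
    eig, _ = module_eigengenes(m, labels, unassigned_label)
    X = m.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.maximum(np.sqrt((Xc**2).sum(axis=1, keepdims=True)), 1e-12)
    E = eig.to_numpy()
    Ec = E - E.mean(axis=1, keepdims=True)
    Ec /= np.maximum(np.sqrt((Ec**2).sum(axis=1, keepdims=True)), 1e-12)
    kme = Xc @ Ec.T  # genes x modules
    best = kme.argmax(axis=1)
    accept = kme[np.arange(len(best)), best] >= kme_threshold
    out = np.where(accept, eig.index.to_numpy()[best], unassigned_label)
    return pd.Series(out, index=labels.index, name="module")


def build_network_modules(
    m: ExpressionMatrix,
    params: NetworkParams | None = None,
    merge: bool = True,
    kme_threshold: float = 0.5,
):
    """Full chain: adjacency -> TOM -> modules (-> merge) -> kME reattachment
    -> eigengenes.

    Returns (labels, eigengenes, variance_explained).
    """
    params = params or NetworkParams()
    A = adjacency_signed_hybrid(m, params)
    D = tom_dissimilarity(A)
    labels = detect_modules(D, params, gene_ids=m.gene_ids)
    if merge and params.merge_cut > 0:
        labels = merge_close_modules(m, labels, params.merge_cut, params.unassigned_label)
    if kme_threshold is not None and kme_threshold < 1:
        labels = reassign_by_kme(m, labels, kme_threshold, params.unassigned_label)
    eig, var_exp = module_eigengenes(m, labels, params.unassigned_label)
    return labels, eig, var_exp
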