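"""Parental population structure from metabolite profiles.

Squared Euclidean distance on the log2 matrix serves as a metabolic
"genetic distance"; average-linkage hierarchical clustering and Kaiser-rule
PCA (correlation matrix, components with eigenvalue > 1) recover the
subspecies grouping.  The distance also provides the classical
distance-vs-performance prediction baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

from .panel import DiallelCross
from .preprocess import MetaboliteMatrix

logger = logging.getLogger("hybridmet")


@dataclass
class DistanceMatrix:
    values: pd.DataFrame
    metric: str = "sqeuclidean"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (arr < 0).any():
            raise ValueError("distance matrix has negative entries")

    def between(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])


def squared_euclidean_distance(matrix: MetaboliteMatrix | pd.DataFrame) -> DistanceMatrix:
    """d(a, b) = sum_k (x_ak - x_bk)^2 over all analytes."""
    df = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    if df.isna().any().any():
        raise ValueError("missing cells in metabolite matrix")
    arr = df.to_numpy(dtype=float)
    d = cdist(arr, arr, metric="sqeuclidean")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=pd.DataFrame(d, index=df.index, columns=df.index))


def average_linkage_cluster(d: DistanceMatrix) -> pd.DataFrame:
    """Agglomerative clustering with unweighted average linkage (UPGMA).

    Naive O(n^3) agglomeration with an explicit deterministic tie rule:
    among minimum-distance cluster pairs, the lexicographically smallest
    (by each cluster's smallest leaf label) merges first.  Returns a merge
    table with columns (left, right, height, size); leaves are labelled by
    parent id, internal nodes "node<k>".
    """
    labels = list(d.values.index)
    n = len(labels)
    if n < 2:
        raise ValueError("clustering needs at least 2 items")
    # active clusters: id -> (leaf set, display label, min leaf label)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    names: dict[int, str] = {i: labels[i] for i in range(n)}
    dmat = d.values.to_numpy(dtype=float).copy()
    # average inter-cluster distance bookkeeping via leaf sums
    merges = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                la, lb = clusters[a], clusters[b]
                dist = dmat[np.ix_(la, lb)].mean()
                key_a = min(labels[x] for x in la)
                key_b = min(labels[x] for x in lb)
                tie_key = tuple(sorted((key_a, key_b)))
                if best is None or dist < best[0] - 1e-15 or (
                    abs(dist - best[0]) <= 1e-15 and tie_key < best[1]
                ):
                    best = (dist, tie_key, a, b)
        dist, _, a, b = best
        merges.append(
            {
                "left": names[a],
                "right": names[b],
                "height": dist,
                "size": len(clusters[a]) + len(clusters[b]),
            }
        )
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        names[next_id] = f"node{next_id - n + 1}"
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    logger.info("average-linkage clustering: %d leaves, %d merges", n, len(merges))
    return pd.DataFrame(merges)


def cut_two_groups(merge_table: pd.DataFrame, leaf_labels: list[str]) -> dict[str, int]:
    """Leaf membership of the two clusters below the final merge."""
    node_leaves: dict[str, list[str]] = {lab: [lab] for lab in leaf_labels}
    for k, row in enumerate(merge_table.itertuples(index=False), start=1):
        node_leaves[f"node{k}"] = node_leaves[row.left] + node_leaves[row.right]
    last = merge_table.iloc[-1]
    out = {}
    for lab in node_leaves[last["left"]]:
        out[lab] = 0
    for lab in node_leaves[last["right"]]:
        out[lab] = 1
    return out


def pca_grouping(
    matrix: MetaboliteMatrix | pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """PCA via eigendecomposition of the column correlation matrix.

    Components with eigenvalue > 1 (Kaiser rule) are retained; no rotation.
    Returns (scores for retained components, all eigenvalues descending,
    retained count).  Zero-variance columns are dropped with a warning.
    """
    df = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("PCA needs at least 2 non-constant columns")
    z = (arr[:, keep] - arr[:, keep].mean(axis=0)) / sd[keep]
    corr = (z.T @ z) / (arr.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    n_keep = max(int((eigval > 1.0).sum()), 1)
    scores = z @ eigvec[:, :n_keep]
    score_df = pd.DataFrame(
        scores, index=df.index, columns=[f"PC{i+1}" for i in range(n_keep)]
    )
    logger.info("PCA: %d of %d components retained (eigenvalue > 1)", n_keep, len(eigval))
    return score_df, eigval, n_keep


def distance_trait_correlation(
    d: DistanceMatrix,
    responses: pd.DataFrame,
    cross: DiallelCross,
) -> pd.DataFrame:
    """Pearson correlation of parental distance with each hybrid response.

    One row per response column: (response, r, p_value, n); a constant
    response yields NaN r with a note.
    """
    dist = np.array([d.between(f, m) for f, m in cross.hybrids])
    rows = []
    resp = responses.loc[cross.hybrid_ids]
    for col in resp.columns:
        y = resp[col].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(dist) == 0:
            rows.append({"response": col, "r": np.nan, "p_value": np.nan,
                         "n": len(y), "note": "undefined (constant input)"})
            continue
        r, p = stats.pearsonr(dist, y)
        rows.append({"response": col, "r": r, "p_value": p, "n": len(y), "note": ""})
    return pd.DataFrame(rows)
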