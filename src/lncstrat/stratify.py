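"""Unsupervised stratification: PCA, z-scoring, Spearman-distance
hierarchical clustering of lncRNA signatures, and validation of a
signature on an independent cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False):
    """PCA of samples in gene space via SVD of the centered matrix.

    ``matrix`` is features x samples. Returns ``(scores, var_explained)``:
    scores is samples x components, and the variance-explained fractions
    sum to 1.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    total = float((S ** 2).sum())
    var_explained = (S ** 2) / total if total > 0 else np.zeros_like(S)
    scores = pd.DataFrame(scores, index=matrix.columns,
                          columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    return scores, var_explained


def zscore_rows(matrix: pd.DataFrame):
    """Row-wise z-scoring (sample SD, ddof=1).

    Zero-variance rows become all-zero and are returned in the flag list.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, list(matrix.index[flat])


def hier_cluster(signature: pd.DataFrame, k: int = 3, method: str = "average"):
    """Hierarchical clustering of samples on 1 - Spearman rho distance.

    ``signature`` is (z-scored) genes x samples. Returns ``(Z, labels)``:
    the scipy linkage matrix and integer cluster labels (1..k) from
    cutting the tree into k clusters.
    """
    X = signature.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rho = spearmanr(X).statistic if X.shape[0] > 1 else np.ones((X.shape[1],) * 2)
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=signature.columns, name="cluster")


def _majority_map(labels: pd.Series, truth: pd.Series) -> dict:
    """Cluster -> label by majority vote; ties toward the smaller cluster
    index's earlier-seen label (deterministic)."""
    mapping = {}
    for cl in sorted(labels.unique()):
        members = truth[labels.index[labels == cl]]
        counts = members.value_counts()
        mapping[cl] = counts.index[0]
    return mapping


def validate_signature(
    signature_genes,
    external_expr: pd.DataFrame,
    true_labels: pd.Series,
    k: int,
    log_transform: bool = True,
):
    """Validate a DE signature on an independent cohort.

    The external matrix is subset to the signature genes present (error
    if < 50% are), log2(x+1)-transformed by default, z-scored per gene,
    clustered at k with Spearman-distance average linkage, and clusters
    mapped to subtype labels by majority vote. Returns a DataFrame with
    per-label sensitivity and specificity, plus the predicted labels.
    """
    signature_genes = list(signature_genes)
    present = [g for g in signature_genes if g in external_expr.index]
    if len(present) < 0.5 * len(signature_genes):
        raise ValueError(
            f"only {len(present)}/{len(signature_genes)} signature genes present "
            "in external matrix (< 50%)"
        )
    expr = external_expr.loc[present]
    if log_transform:
        expr = np.log2(expr + 1.0)
    z, _flat = zscore_rows(expr)
    _Z, clusters = hier_cluster(z, k=k)
    truth = true_labels.loc[clusters.index]
    mapping = _majority_map(clusters, truth)
    predicted = clusters.map(mapping)
    rows = []
    for label in sorted(truth.unique()):
        tp = int(((predicted == label) & (truth == label)).sum())
        fn = int(((predicted != label) & (truth == label)).sum())
        fp = int(((predicted == label) & (truth != label)).sum())
        tn = int(((predicted != label) & (truth != label)).sum())
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows.append({"label": label, "sensitivity": sens, "specificity": spec,
                     "n": tp + fn})
    return pd.DataFrame(rows).set_index("label"), predicted
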