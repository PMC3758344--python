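"""Hierarchical clustering of samples or peptides for heat-map analyses.

Agglomeration is delegated to scipy's linkage routines on a condensed
distance matrix.  Items are first sorted canonically by label, which makes
the result invariant to the order rows arrive in and gives ties a
deterministic resolution.  The default metric is correlation distance
(1 − Pearson r) with average linkage, the customary choice for array heat
maps; Euclidean distance and complete linkage are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .diffstats import SignatureSet
from .preprocess import InhibitionProfile, SignalMatrix

DISTANCES = ("one_minus_pearson", "euclidean")
LINKAGES = ("average", "complete")


@dataclass
class Dendrogram:
    """Result of agglomerative clustering over a set of labelled items."""

    labels: list[str]  # canonical (sorted) item order; leaves 0..n−1
    merges: np.ndarray  # scipy linkage matrix (n−1 × 4)
    leaf_order: list[str]  # dendrogram leaf sequence, left to right

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _item_matrix(mat, axis: str) -> pd.DataFrame:
    if isinstance(mat, SignalMatrix):
        df = mat.values
    elif isinstance(mat, InhibitionProfile):
        df = mat.lfc
    elif isinstance(mat, pd.DataFrame):
        df = mat
    else:
        df = pd.DataFrame(np.asarray(mat, dtype=float))
        df.index = [f"item{i}" for i in range(df.shape[0])]
    if axis == "peptides":
        df = df.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'peptides', got {axis!r}")
    return df


def hcluster(
    mat,
    axis: str = "samples",
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Cluster the rows (``axis='samples'``) or columns (``'peptides'``).

    Items are sorted by label before agglomeration so the dendrogram is a
    function of the data alone, not of input row order.

    Raises
    ------
    ValueError
        Fewer than 2 items, or a zero-variance item under correlation
        distance (named in the message).
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    df = _item_matrix(mat, axis)
    if df.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    df = df.loc[sorted(df.index, key=str)]
    X = df.to_numpy(dtype=float)

    if distance == "one_minus_pearson":
        sd = X.std(axis=1)
        flat = [str(lbl) for lbl, s in zip(df.index, sd) if s == 0]
        if flat:
            raise ValueError(
                f"zero-variance item(s) under correlation distance: {flat}"
            )
        d = pdist(X, metric="correlation")
    else:
        d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    labels = [str(lbl) for lbl in df.index]
    return Dendrogram(
        labels=labels,
        merges=Z,
        leaf_order=[labels[i] for i in leaves],
    )


def signature_heatmap_order(
    profile: InhibitionProfile | SignalMatrix | pd.DataFrame,
    signature: SignatureSet | list[str],
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> pd.DataFrame:
    """Restrict a matrix to signature peptides and order both axes by clustering.

    Returns the samples × signature-peptides matrix with rows in the sample
    dendrogram's leaf order and columns in the peptide dendrogram's leaf
    order — the layout of a clustered heat map.
    """
    df = _item_matrix(profile, "samples")
    peptides = (
        list(signature.peptide_ids)
        if isinstance(signature, SignatureSet)
        else list(signature)
    )
    if not peptides:
        raise ValueError("signature is empty")
    missing = set(peptides) - set(df.columns)
    if missing:
        raise ValueError(f"signature peptides not in matrix: {sorted(missing)}")
    sub = df[peptides]
    # correlation over a single-peptide profile is undefined; fall back to
    # euclidean row ordering for a 1-column restriction
    row_distance = distance if sub.shape[1] >= 2 else "euclidean"
    row_order = hcluster(sub, "samples", row_distance, linkage).leaf_order
    if sub.shape[1] >= 2:
        col_order = hcluster(sub, "peptides", distance, linkage).leaf_order
    else:
        col_order = peptides
    return sub.loc[row_order, col_order]


def top_split(dend: Dendrogram) -> tuple[list[str], list[str]]:
    """The two clusters produced by cutting the dendrogram below its root."""
    assignments = hierarchy.fcluster(dend.merges, t=2, criterion="maxclust")
    left = [l for l, a in zip(dend.labels, assignments) if a == 1]
    right = [l for l, a in zip(dend.labels, assignments) if a == 2]
    return left, right
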