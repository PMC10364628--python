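"""PCA + k-means grouping of significant-pathway change profiles.

Rows are pathways, columns are per-subject activity log-ratios (GDM subjects
first, then controls).  Profiles are centered (not scaled - activities share
units), projected onto principal axes with a deterministic sign convention,
optionally filtered by a strict |PC2| > bound outlier rule, and clustered by
best-of-n_init k-means on the first two PC scores (the plotted space).
Cluster ids are canonicalized by descending cluster size, ties broken by the
lexicographically smallest member id, so labels are platform-stable.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import AnalysisError
from .temporal import IntervalChangeMatrix


def pathway_feature_matrix(
    change: IntervalChangeMatrix,
    pathway_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pathways x subjects profile matrix, GDM subject columns first.

    ``change`` is the interval change matrix computed on pathway activities;
    ``pathway_ids`` restricts rows to the significant pathways.
    """
    df = change.to_dataframe()  # subjects x pathways
    if pathway_ids is not None:
        missing = [p for p in pathway_ids if p not in df.columns]
        if missing:
            raise ValueError(f"pathways absent from change matrix: {', '.join(missing)}")
        df = df[list(pathway_ids)]
    if df.isna().to_numpy().any():
        raise ValueError("missing subject values in change matrix; no silent imputation")
    gvec = change.group_vector
    order = [s for s, g in zip(change.subjects, gvec) if g] + [
        s for s, g in zip(change.subjects, gvec) if not g
    ]
    return df.T[order]  # pathways x subjects


def pca_scores(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: Optional[int] = None,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal-component scores of the row cloud, sign-stabilized.

    Each loading vector's largest-magnitude entry is made positive, which
    fixes the sign indeterminacy of the eigendecomposition.  Returns
    (scores, explained_variance_ratio, components).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise AnalysisError("PCA needs at least 2 rows")
    work = X.copy()
    if center:
        work = work - work.mean(axis=0, keepdims=True)
    if scale:
        sd = work.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        work = work / sd
    if not np.any(work.var(axis=0) > 0):
        raise AnalysisError("zero-variance matrix; PCA undefined")
    max_k = min(work.shape[0] - (1 if center else 0), work.shape[1])
    k = max(1, min(n_components or max_k, max_k))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(work)
    comps = pca.components_
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] *= -1.0
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), pca.explained_variance_ratio_, comps


def filter_pc2_outliers(pc_scores: pd.DataFrame, bound: float = 5.0) -> pd.Series:
    """Boolean outlier mask: PC2 strictly below -bound or strictly above bound.

    Values exactly at +-bound are not outliers (strict inequalities).  By
    convention this filter is applied to the Set2 pathway analysis only.
    """
    if "PC2" not in pc_scores.columns:
        raise AnalysisError("need at least 2 principal components for the PC2 filter")
    pc2 = pc_scores["PC2"]
    return (pc2 < -bound) | (pc2 > bound)


def _canonical_labels(raw_labels: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Relabel clusters by descending size, ties by smallest member id."""
    order = []
    for lab in np.unique(raw_labels):
        members = [ids[i] for i in np.nonzero(raw_labels == lab)[0]]
        order.append((-len(members), min(members), lab))
    mapping = {old: new for new, (_, _, old) in enumerate(sorted(order))}
    return np.array([mapping[l] for l in raw_labels])


def kmeans_assign(
    pc_scores: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> Tuple[pd.Series, float]:
    """Best-of-n_init k-means on the first two PC scores.

    Returns canonicalized labels (a Series indexed like ``pc_scores``) and
    the inertia of the best solution.
    """
    cols = [c for c in ("PC1", "PC2") if c in pc_scores.columns]
    X = pc_scores[cols].to_numpy(dtype=float)
    if X.shape[0] < k:
        raise AnalysisError(f"{X.shape[0]} rows < k={k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    labels = _canonical_labels(raw, list(pc_scores.index))
    return pd.Series(labels, index=pc_scores.index, name="cluster"), float(km.inertia_)


class PathwayClusterModel(BaseEstimator):
    """PCA -> optional PC2 outlier filter -> k-means, as one fitted model.

    Parameters
    ----------
    k : int
        Number of clusters (3 by default).
    pc2_bound : float
        Outlier bound on PC2 (strict inequalities at +-bound).
    filter_outliers : bool
        Apply the PC2 filter before clustering (used for the Set2 analysis).
    center, scale : bool
        Column preprocessing before PCA; centered, unscaled by default.
    n_init : int
        k-means restarts; the best (lowest-inertia) solution is kept.
    random_state : int
        Seed for k-means initialization.

    Attributes
    ----------
    pc_scores_ : DataFrame (pathways x components)
    explained_variance_ratio_ : ndarray
    outlier_mask_ : Series of bool per pathway
    labels_ : Series mapping non-outlier pathways to canonical cluster ids
    inertia_ : float
    """

    def __init__(
        self,
        k: int = 3,
        pc2_bound: float = 5.0,
        filter_outliers: bool = False,
        center: bool = True,
        scale: bool = False,
        n_init: int = 50,
        random_state: int = 0,
    ):
        self.k = k
        self.pc2_bound = pc2_bound
        self.filter_outliers = filter_outliers
        self.center = center
        self.scale = scale
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        scores, evr, comps = pca_scores(X, center=self.center, scale=self.scale)
        self.pc_scores_ = scores
        self.explained_variance_ratio_ = evr
        self.components_ = comps
        if self.filter_outliers and "PC2" in scores.columns:
            self.outlier_mask_ = filter_pc2_outliers(scores, self.pc2_bound)
        else:
            self.outlier_mask_ = pd.Series(False, index=scores.index)
        kept = scores.loc[~self.outlier_mask_]
        self.labels_, self.inertia_ = kmeans_assign(
            kept, k=self.k, seed=self.random_state, n_init=self.n_init
        )
        return self

    def assignment_table(self) -> pd.DataFrame:
        """Per-pathway PC1/PC2, outlier flag and cluster id (NA for outliers)."""
        df = pd.DataFrame(
            {
                "pathway_id": list(self.pc_scores_.index),
                "PC1": self.pc_scores_["PC1"].to_numpy(),
                "PC2": self.pc_scores_["PC2"].to_numpy()
                if "PC2" in self.pc_scores_.columns
                else np.nan,
                "outlier": self.outlier_mask_.to_numpy(),
            }
        )
        df["cluster"] = [
            int(self.labels_[p]) if p in self.labels_.index else pd.NA
            for p in self.pc_scores_.index
        ]
        return df
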