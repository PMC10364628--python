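"""Descriptive community layer: alpha diversity, top-MAD selection, LDA.

Alpha diversity is computed per sample on relative abundances with natural
logarithms: observed richness (features with count > 0), Shannon entropy
H = -sum p_i ln p_i, and Simpson index D = 1 - sum p_i^2.  No rarefaction is
applied; library depth is reported alongside the indices so users can judge
depth confounding themselves.

Feature selection for ordination ranks features by mean absolute deviation
about the mean (MAD) of relative abundance across all samples; MAD = 0
features are excluded.  Ordination is Fisher linear discriminant analysis
with ridge shrinkage on the within-class scatter, over the six
group x timepoint classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import shannon, simpson, sobs
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AnalysisError
from .io import OtuTable, SampleRecord


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Observed richness, Shannon (natural log) and Simpson (1 - sum p^2) per sample.

    Empty samples are excluded with a warning rather than an error.  Library
    depth is reported in the ``depth`` column.
    """
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        total = int(counts.sum())
        if total == 0:
            warnings.warn(f"sample {sid!r} is empty; excluded from alpha diversity")
            continue
        rows.append(
            {
                "sample_id": sid,
                "depth": total,
                "observed": int(sobs(counts)),
                "shannon": float(shannon(counts, base=np.e)),
                "simpson": float(simpson(counts)),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "depth", "observed", "shannon", "simpson"])


def alpha_group_test(
    records: pd.DataFrame,
    meta: Sequence[SampleRecord],
    timepoint: str,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum between arms at one timepoint, per index.

    Uses the exact null distribution when both groups have <= ``exact_max_n``
    samples and no ties, otherwise the tie- and continuity-corrected normal approximation.
    """
    group_of = {r.sample_id: r.group for r in meta if r.timepoint == timepoint}
    sub = records[records["sample_id"].isin(group_of)]
    g1 = sub[sub["sample_id"].map(group_of) == "GDM"]
    g2 = sub[sub["sample_id"].map(group_of) == "control"]
    if len(g1) == 0 or len(g2) == 0:
        raise AnalysisError(f"timepoint {timepoint}: both groups must be present")
    rows = []
    for index in ("observed", "shannon", "simpson"):
        x = g1[index].to_numpy(dtype=float)
        y = g2[index].to_numpy(dtype=float)
        stat, p = rank_sum_test(x, y, exact_max_n=exact_max_n)
        rows.append({"timepoint": timepoint, "index": index, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with the exact/asymptotic gate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    if max(len(x), len(y)) <= exact_max_n and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mean_absolute_deviation(x: np.ndarray) -> float:
    """MAD about the mean: mean(|x - mean(x)|)."""
    x = np.asarray(x, dtype=float)
    return float(np.abs(x - x.mean()).mean())


def top_mad_features(table: OtuTable, n_top: int = 100) -> List[str]:
    """Features ranked by mean absolute deviation of relative abundance.

    MAD(x) = mean(|x - mean(x)|) across all samples; MAD = 0 features are
    excluded (fewer than ``n_top`` may survive), ties broken lexicographically.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    counts = table.counts.astype(float)
    comp = counts / counts.sum(axis=1, keepdims=True)
    mad = np.abs(comp - comp.mean(axis=0, keepdims=True)).mean(axis=0)
    ranked = sorted(
        ((m, fid) for m, fid in zip(mad, table.feature_ids) if m > 0),
        key=lambda t: (-t[0], t[1]),
    )
    return [fid for _, fid in ranked[:n_top]]


class DiscriminantProjection(BaseEstimator, TransformerMixin):
    """Fisher LDA projection with ridge shrinkage on the within-class scatter.

    Solves the generalized eigenproblem S_b w = lambda S_w(s) w with the
    shrunk within-class covariance S_w(s) = (1 - s) S_w + s (tr S_w / p) I,
    and applies the same deterministic sign convention as the PCA scores:
    each discriminant's largest-magnitude loading entry is made positive.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        Ridge mixing of the within-class covariance toward an identity
        scaling; at 1.0 the within-scatter is replaced by (trace/p) * I and
        discriminants become eigenvectors of the between-class scatter.
    n_components : int
        Number of discriminants returned (2 by default).

    Attributes
    ----------
    scalings_ : ndarray (n_features, n_components_), discriminant loadings.
    eigenvalues_ : between/within variance ratios per discriminant.
    """

    def __init__(self, shrinkage: float = 0.1, n_components: int = 2):
        self.shrinkage = shrinkage
        self.n_components = n_components

    def fit(self, X, y):
        from scipy import linalg

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise AnalysisError("LDA needs at least 2 classes")
        if np.any(counts < 2):
            small = classes[counts < 2]
            raise AnalysisError(f"classes with < 2 samples: {list(small)}")
        n, p = X.shape
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for cls, n_c in zip(classes, counts):
            Xc = X[y == cls]
            mc = Xc.mean(axis=0)
            dev = Xc - mc
            Sw += dev.T @ dev
            dm = (mc - grand)[:, None]
            Sb += n_c * (dm @ dm.T)
        Sw /= n - len(classes)
        Sb /= n
        s = float(self.shrinkage)
        Sw_shrunk = (1.0 - s) * Sw + s * (np.trace(Sw) / p) * np.eye(p)
        try:
            evals, evecs = linalg.eigh(Sb, Sw_shrunk)
        except (np.linalg.LinAlgError, linalg.LinAlgError) as exc:
            raise AnalysisError(
                "singular within-class scatter; increase shrinkage (e.g. 0.1)"
            ) from exc
        order = np.argsort(evals)[::-1]
        k = min(self.n_components, len(classes) - 1, p)
        scalings = evecs[:, order[:k]].copy()
        for j in range(k):
            lead = np.argmax(np.abs(scalings[:, j]))
            if scalings[lead, j] < 0:
                scalings[:, j] *= -1.0
        self.scalings_ = scalings
        self.eigenvalues_ = evals[order[:k]]
        self.mean_ = grand
        self.classes_ = classes
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.scalings_


def lda_project(
    matrix: pd.DataFrame,
    classes: Sequence[str],
    shrinkage: float = 0.1,
) -> pd.DataFrame:
    """Project samples onto the first two Fisher discriminants.

    ``matrix`` is samples x features (e.g. the top-MAD features); ``classes``
    are group x timepoint labels, one per sample.
    """
    proj = DiscriminantProjection(shrinkage=shrinkage, n_components=2)
    scores = proj.fit(matrix.to_numpy(), np.asarray(classes)).transform(matrix.to_numpy())
    cols = [f"LD{j + 1}" for j in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=matrix.index, columns=cols)
    out.insert(0, "sample_id", list(matrix.index))
    out["class"] = list(classes)
    return out.reset_index(drop=True)
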