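"""Contribution-weighted pathway activity and its interval change testing.

Pathway activity for sample s and pathway p is the weighted sum

    activity[s, p] = sum_f contributions[p, f] * relabundance[s, f]

i.e. the PICRUSt2-style aggregation of taxon abundances through a pathway x
feature contribution matrix (the phylogenetic hidden-state prediction that
produces the contributions is upstream of this package and consumed as
data).  Activity changes per interval reuse the same per-subject log-ratio
and subject-label permutation machinery as the OTU analysis; pathways are
selected at raw p < alpha (no FDR gate at the pathway level).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AnalysisError
from .io import PathwayDb, SampleRecord
from .temporal import DEFAULT_EPSILON, interval_log_ratio, permutation_test

logger = logging.getLogger(__name__)


class PathwayActivityTransformer(BaseEstimator, TransformerMixin):
    """Map a samples x features composition to samples x pathways activity.

    The transform is linear and homogeneous in the composition: doubling a
    feature's relative abundance doubles its contribution term, and scaling
    all weights by c scales activities by c.

    Parameters
    ----------
    db : PathwayDb
        Contribution weights (pathways x features).

    Attributes
    ----------
    zero_pathways_ : list of str
        Pathways whose activity is all-zero on the fitted composition
        (no overlapping contributing features), flagged not dropped.
    """

    def __init__(self, db: PathwayDb):
        self.db = db

    def fit(self, X: pd.DataFrame, y=None):
        shared = [f for f in X.columns if f in set(self.db.feature_ids)]
        if not shared:
            raise AnalysisError("no overlap between composition features and pathway contributions")
        missing = [f for f in X.columns if f not in set(self.db.feature_ids)]
        if missing:
            logger.info("%d composition features absent from pathway DB contribute zero", len(missing))
        self.shared_features_ = shared
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "shared_features_"):
            self.fit(X)
        col_of = {f: j for j, f in enumerate(self.db.feature_ids)}
        W = self.db.contributions[:, [col_of[f] for f in self.shared_features_]]
        A = X[self.shared_features_].to_numpy() @ W.T
        activity = pd.DataFrame(A, index=X.index, columns=self.db.pathway_ids)
        self.zero_pathways_ = [p for p in self.db.pathway_ids if np.all(activity[p].to_numpy() == 0)]
        for p in self.zero_pathways_:
            logger.warning("pathway %s has all-zero activity (no contributing features observed)", p)
        return activity


def infer_activity(comp: pd.DataFrame, db: PathwayDb) -> pd.DataFrame:
    """Weighted-sum pathway activity table (samples x pathways)."""
    return PathwayActivityTransformer(db).fit(comp).transform(comp)


@dataclass
class PathwaySetResult:
    """Permutation results and the raw-p selection for one interval."""

    interval: str
    results: pd.DataFrame  # pathway_id, stat_obs, p_perm, q_bh
    alpha: float

    @property
    def selected(self) -> List[str]:
        mask = self.results["p_perm"].to_numpy() < self.alpha
        return self.results.loc[mask, "feature_id"].tolist()


def pathway_change_test(
    activity: pd.DataFrame,
    meta: Sequence[SampleRecord],
    interval: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    epsilon: float = DEFAULT_EPSILON,
) -> PathwaySetResult:
    """Interval log-ratio + permutation test on pathway activities.

    Same epsilon pseudocount policy as the OTU statistic; selection is on raw
    permutation p < alpha.
    """
    change = interval_log_ratio(activity, meta, interval, epsilon=epsilon)
    results = permutation_test(change, n_perm=n_perm, seed=seed)
    return PathwaySetResult(interval=interval, results=results, alpha=alpha)


def direction_fisher(
    selected_pathways: Sequence[str],
    change_gdm_mean: pd.Series,
    change_control_mean: pd.Series,
) -> Tuple[np.ndarray, float, float]:
    """Fisher exact test of change-direction (positive vs non-positive) by arm.

    Rows are the arms (GDM, control), columns the sign of each selected
    pathway's mean activity change.  A degenerate table (any zero margin)
    returns p = 1 with a warning rather than an error.
    """
    if len(selected_pathways) < 1:
        raise AnalysisError("direction test needs at least one selected pathway")
    g = change_gdm_mean.loc[list(selected_pathways)].to_numpy()
    c = change_control_mean.loc[list(selected_pathways)].to_numpy()
    table = np.array(
        [
            [int((g > 0).sum()), int((g <= 0).sum())],
            [int((c > 0).sum()), int((c <= 0).sum())],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 direction table (zero margin); p set to 1")
        row = table.sum(axis=1)
        odds = np.nan
        return table, odds, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)
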