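"""Self-controlled interval log-ratio statistics and permutation testing.

The change statistic for feature f in subject s over an interval
(earlier, later) is

    L[s, f] = ln( (a_f(s, later) + eps) / (a_f(s, earlier) + eps) )

on per-sample relative abundances ``a``, with a fixed pseudocount ``eps``
keeping L finite and exactly antisymmetric under timepoint exchange.
Because L is a within-subject difference of log-abundances, any per-subject
intercept on the log-composition cancels - the design is self-controlled.

Group differences of mean L are tested by permuting subject-level group
labels (the same permutation applied to all features in a round), with the
add-one two-sided p estimator, and gated into Set1 (t2 vs t1) and Set2
(t3 vs t2) by Benjamini-Hochberg FDR within each interval separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import OtuTable, SampleRecord

INTERVALS = {"t2_vs_t1": ("t1", "t2"), "t3_vs_t2": ("t2", "t3")}

DEFAULT_EPSILON = 1e-6
DEFAULT_N_PERM = 1000


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Close each sample's counts to relative abundances summing to one."""
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        bad = ", ".join(table.sample_ids[i] for i in zero)
        raise ValueError(f"zero-sum sample(s): {bad}")
    comp = counts / sums[:, None]
    return pd.DataFrame(comp, index=table.sample_ids, columns=table.feature_ids)


@dataclass
class IntervalChangeMatrix:
    """Subjects x features log-ratio matrix for one timepoint pair."""

    interval: str
    subjects: List[str]
    features: List[str]
    L: np.ndarray  # (n_subjects, n_features)
    epsilon: float
    group_of: Dict[str, str]
    excluded_subjects: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if not np.all(np.isfinite(self.L)):
            raise ValueError("non-finite interval log-ratios")

    @property
    def group_vector(self) -> np.ndarray:
        """Boolean vector, True where the subject is in the GDM arm."""
        return np.array([self.group_of[s] == "GDM" for s in self.subjects])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.L, index=self.subjects, columns=self.features)


def interval_log_ratio(
    comp: pd.DataFrame,
    meta: Sequence[SampleRecord],
    interval: str,
    epsilon: float = DEFAULT_EPSILON,
    min_per_group: int = 3,
) -> IntervalChangeMatrix:
    """Per-subject log-ratios of relative abundance between two timepoints.

    Subjects lacking either timepoint of the interval are excluded and listed
    in ``excluded_subjects``.  Raises :class:`AnalysisError` when fewer than
    ``min_per_group`` subjects per arm remain (a permutation test over fewer
    subjects is meaningless).
    """
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval {interval!r}; expected one of {sorted(INTERVALS)}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    earlier, later = INTERVALS[interval]
    sample_of: Dict[Tuple[str, str], str] = {}
    group_of: Dict[str, str] = {}
    for rec in meta:
        sample_of[(rec.subject_id, rec.timepoint)] = rec.sample_id
        group_of[rec.subject_id] = rec.group
    subjects, excluded = [], []
    for subj in dict.fromkeys(r.subject_id for r in meta):
        if (subj, earlier) in sample_of and (subj, later) in sample_of:
            # both samples must also be present in the composition matrix
            if sample_of[(subj, earlier)] in comp.index and sample_of[(subj, later)] in comp.index:
                subjects.append(subj)
                continue
        excluded.append(subj)
    n_gdm = sum(group_of[s] == "GDM" for s in subjects)
    n_ctl = len(subjects) - n_gdm
    if n_gdm < min_per_group or n_ctl < min_per_group:
        raise AnalysisError(
            f"interval {interval}: only {n_gdm} GDM and {n_ctl} control subjects have "
            f"both timepoints; need >= {min_per_group} per group"
        )
    a_early = comp.loc[[sample_of[(s, earlier)] for s in subjects]].to_numpy()
    a_late = comp.loc[[sample_of[(s, later)] for s in subjects]].to_numpy()
    L = np.log(a_late + epsilon) - np.log(a_early + epsilon)
    return IntervalChangeMatrix(
        interval=interval,
        subjects=subjects,
        features=list(comp.columns),
        L=L,
        epsilon=epsilon,
        group_of={s: group_of[s] for s in subjects},
        excluded_subjects=excluded,
    )


class GroupPermutationTest(BaseEstimator):
    """Per-feature two-group permutation test of mean interval change.

    The observed statistic is the difference of group means of per-subject
    log-ratios (GDM minus control).  The null is built by permuting
    subject-level group labels, the same permutation applied to every feature
    in a round, preserving within-subject pairing.  Two-sided p-values use
    the add-one estimator p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1),
    so p is never zero and never below 1/(n_perm + 1).

    Parameters
    ----------
    n_perm : int
        Number of permutation rounds (1000 by default).
    random_state : int
        Seed for the permutation stream.

    Attributes
    ----------
    stat_obs_ : ndarray of shape (n_features,)
        Observed group mean differences.
    p_values_ : ndarray of shape (n_features,)
        Two-sided permutation p-values.
    q_values_ : ndarray of shape (n_features,)
        Benjamini-Hochberg adjusted p-values within this feature family.
    """

    def __init__(self, n_perm: int = DEFAULT_N_PERM, random_state: int = 0):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        """Fit on a subjects x features matrix X and boolean group labels y."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X must be subjects x features with one label per subject")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n1 = int(y.sum())
        n0 = int((~y).sum())
        if n1 == 0 or n0 == 0:
            raise AnalysisError("permutation test needs both groups present")
        w = np.where(y, 1.0 / n1, -1.0 / n0)
        stat_obs = w @ X
        rng = np.random.default_rng(self.random_state)
        # permute rows of the weight vector: (n_perm x subjects) @ (subjects x features)
        perm_idx = np.argsort(rng.random((self.n_perm, w.size)), axis=1)
        W = w[perm_idx]
        stat_perm = W @ X
        # tolerance guards ties: a permutation logically identical to the
        # observed labeling must count as an exceedance despite float noise
        tol = 1e-12 * (1.0 + np.abs(stat_obs))
        exceed = (np.abs(stat_perm) >= (np.abs(stat_obs) - tol)[None, :]).sum(axis=0)
        self.stat_obs_ = stat_obs
        self.p_values_ = (1.0 + exceed) / (self.n_perm + 1.0)
        self.q_values_ = bh_adjust(self.p_values_)
        self.n_features_in_ = X.shape[1]
        return self


def permutation_test(
    change: IntervalChangeMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the subject-level permutation test on an interval change matrix.

    Returns a DataFrame with columns feature_id, interval, stat_obs, p_perm,
    q_bh, n_perm, in the change matrix's feature order.
    """
    groups = set(change.group_of.values())
    if len(groups) < 2:
        raise AnalysisError(f"single-group input (groups present: {sorted(groups)})")
    est = GroupPermutationTest(n_perm=n_perm, random_state=seed)
    est.fit(change.L, change.group_vector)
    return pd.DataFrame(
        {
            "feature_id": change.features,
            "interval": change.interval,
            "stat_obs": est.stat_obs_,
            "p_perm": est.p_values_,
            "q_bh": est.q_values_,
            "n_perm": n_perm,
        }
    )


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant_sets(
    results_by_interval: Mapping[str, pd.DataFrame],
    fdr_threshold: float = 0.1,
) -> Tuple[List[str], List[str]]:
    """Gate features into Set1 / Set2 by BH FDR within each interval.

    Set1 holds features with q_bh < threshold for t2 vs t1, Set2 the same for
    t3 vs t2; the two families are adjusted independently.
    """
    for key in INTERVALS:
        if key not in results_by_interval:
            raise ValueError(f"missing results for interval {key!r}")

    def _select(df: pd.DataFrame) -> List[str]:
        mask = df["q_bh"].to_numpy() < fdr_threshold
        return df.loc[mask, "feature_id"].tolist()

    return _select(results_by_interval["t2_vs_t1"]), _select(results_by_interval["t3_vs_t2"])


def label_trajectory(
    change: IntervalChangeMatrix,
    comp: pd.DataFrame,
    meta: Sequence[SampleRecord],
    tau_low: float = 1e-4,
    delta_stable: float = 0.1,
) -> pd.DataFrame:
    """Categorical abundance-dynamics labels per feature and group.

    Per group: ``low`` when the group's mean relative abundance over the two
    interval timepoints is below ``tau_low``; otherwise ``stable`` when
    |group mean L| <= ``delta_stable``; otherwise ``increasing`` /
    ``decreasing`` by the sign of the group mean L.
    """
    if tau_low <= 0 or delta_stable <= 0:
        raise ValueError("thresholds must be positive")
    earlier, later = INTERVALS[change.interval]
    sample_of = {(r.subject_id, r.timepoint): r.sample_id for r in meta}
    gvec = change.group_vector
    out = {"feature_id": list(change.features)}
    for gname, mask in (("gdm", gvec), ("control", ~gvec)):
        subj = [s for s, m in zip(change.subjects, mask) if m]
        samples = [sample_of[(s, t)] for s in subj for t in (earlier, later)]
        mean_ab = comp.loc[samples].to_numpy().mean(axis=0)
        mean_l = change.L[mask].mean(axis=0)
        labels = np.where(
            mean_ab < tau_low,
            "low",
            np.where(np.abs(mean_l) <= delta_stable, "stable", np.where(mean_l > 0, "increasing", "decreasing")),
        )
        out[f"label_{gname}"] = labels
        out[f"mean_abundance_{gname}"] = mean_ab
        out[f"mean_log_ratio_{gname}"] = mean_l
    return pd.DataFrame(out)
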