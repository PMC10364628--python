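"""Dirichlet-multinomial synthetic cohorts with planted ground truth.

The generator emulates the data structure the analysis assumes: two arms
(GDM, control) of ``n_per_group`` subjects each, sampled at three timepoints
(t1, t2, t3), with 16S-like overdispersed counts.

Model
-----
Per feature f, a log-normal baseline log-abundance ``beta_f``; per subject s,
a random intercept ``u[s, f]`` shared across timepoints (between-subject
microbiome variation - it cancels exactly in the within-subject interval
log-ratio).  The latent log-abundance is

    eta[s, t, f] = beta_f + u[s, f] + shift[s, t, f]

where the shift plants group-specific temporal effects on the interval
log-ratios: planted Set1 features diverge between the arms by
``effect_log_units`` over t1->t2 (GDM moves by +-effect/2, control by the
opposite half, as in real two-arm cohorts where taxa increase in one arm and
decrease in the other), planted Set2 features likewise over t2->t3.
Compositions are softmax(eta); counts are multinomial draws of a log-normal
library size from a Dirichlet-perturbed composition with concentration
``overdispersion * composition``.

Planting is compositionally neutral by construction: signs alternate within
each planted set, the up and down blocks' baseline shares are balanced
exactly, and the symmetric half-shifts make the (second-order) softmax
normalizer perturbation identical in both arms, so it cancels in the group
contrast and unplanted features remain true nulls.  Planted features are
drawn at moderate prevalence (narrow baseline spread) so their log-ratios
are estimable from counts without small-count bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import OtuTable, PathwayDb, SampleRecord

TIMEPOINTS = ("t1", "t2", "t3")

# Signature compounds used for planted recurrent metabolites, drawn from the
# butanoate / mevalonate focal families (see gutshift.recurrence).
_SIGNATURE_POOL = ["butanoate", "(R)-mevalonate", "DMAPP", "butanoyl-CoA", "crotonyl-CoA", "IPP"]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate a 27+27-subject, 3-timepoint cohort."""

    n_per_group: int = 27
    n_features: int = 300
    n_planted_set1: int = 20
    n_planted_set2: int = 20
    effect_log_units: float = 1.5  # group difference of mean interval log-ratio (natural log)
    sequencing_depth: int = 50_000  # mean library size
    overdispersion: float = 10000.0  # Dirichlet concentration scale
    dropout_low_fraction: float = 0.0  # features forced to near-zero baseline
    seed: int = 0
    baseline_sigma: float = 1.2  # sd of log-normal baseline across features
    subject_sigma: float = 0.8  # sd of per-subject random intercept
    planted_baseline_scale: float = 1.0  # down-weighting of planted features' baselines
    planted_sigma: float = 0.5  # baseline spread of planted (moderate-prevalence) features
    depth_cv: float = 0.3  # CV of log-normal library sizes

    def __post_init__(self) -> None:
        if self.n_planted_set1 + self.n_planted_set2 > self.n_features:
            raise ValueError("planted features exceed n_features")
        if self.effect_log_units < 0:
            raise ValueError("effect_log_units must be >= 0")
        if self.sequencing_depth <= 0 or self.overdispersion <= 0:
            raise ValueError("sequencing_depth and overdispersion must be positive")
        if not 0 <= self.dropout_low_fraction < 1:
            raise ValueError("dropout_low_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted-effect bookkeeping for parameter-recovery tests."""

    planted_set1: Set[str]
    planted_set2: Set[str]
    true_diff: Dict[str, float]  # feature -> signed group difference of interval log-ratio mean
    seed: int
    planted_recurrent_compounds: Set[str] = field(default_factory=set)
    pathway_cluster_of: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.planted_set1 & self.planted_set2:
            raise ValueError("planted sets must be disjoint")
        if set(self.true_diff) != self.planted_set1 | self.planted_set2:
            raise ValueError("truth must cover exactly the planted features")


def _feature_ids(n: int) -> List[str]:
    return [f"OTU{i:04d}" for i in range(n)]


def _subject_ids(n_per_group: int) -> Tuple[List[str], List[str]]:
    gdm = [f"GDM{i:02d}" for i in range(1, n_per_group + 1)]
    ctl = [f"CTL{i:02d}" for i in range(1, n_per_group + 1)]
    return gdm, ctl


def simulate_cohort(config: CohortConfig) -> Tuple[OtuTable, List[SampleRecord], SyntheticTruth]:
    """Generate one cohort: counts, metadata, and planted ground truth.

    Identical config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    nf = config.n_features
    features = _feature_ids(nf)
    gdm_subjects, ctl_subjects = _subject_ids(config.n_per_group)
    subjects = gdm_subjects + ctl_subjects
    is_gdm = np.array([True] * len(gdm_subjects) + [False] * len(ctl_subjects))

    beta = rng.normal(0.0, config.baseline_sigma, size=nf)
    n_drop = int(round(config.dropout_low_fraction * nf))
    drop_idx = rng.choice(nf, size=n_drop, replace=False) if n_drop else np.array([], dtype=int)
    beta[drop_idx] += np.log(1e-3)  # rare-taxon tail

    eligible = np.setdiff1d(np.arange(nf), drop_idx)
    n_planted = config.n_planted_set1 + config.n_planted_set2
    planted_idx = rng.choice(eligible, size=n_planted, replace=False)
    set1_idx = planted_idx[: config.n_planted_set1]
    set2_idx = planted_idx[config.n_planted_set1 :]

    # Planted (differentially regulated) taxa are moderate-prevalence features:
    # redraw their baselines with a narrower spread so their interval
    # log-ratios are estimable from counts.  Signs alternate within each set
    # and the up/down blocks' total baseline shares are equalized exactly;
    # combined with the symmetric half-shifts below this keeps the softmax
    # normalizer perturbation identical in both arms.
    signs = {}
    for idx_block in (set1_idx, set2_idx):
        for k, f in enumerate(idx_block):
            signs[int(f)] = 1.0 if k % 2 == 0 else -1.0
    scale = config.planted_baseline_scale
    for f in signs:
        beta[f] = rng.normal(0.0, config.planted_sigma) + np.log(scale)
    for idx_block in (set1_idx, set2_idx):
        up = [f for f in idx_block if signs[int(f)] > 0]
        down = [f for f in idx_block if signs[int(f)] < 0]
        if up and down:
            beta[down] += np.log(np.exp(beta[up]).sum() / np.exp(beta[down]).sum())

    u = rng.normal(0.0, config.subject_sigma, size=(len(subjects), nf))

    # Symmetric shift: GDM moves by +s*effect/2, control by -s*effect/2, so the
    # group contrast of the interval log-ratio is exactly effect_log_units while
    # the (second-order, even in the shift) normalizer perturbation is identical
    # in both arms and cancels in the contrast.
    shift = np.zeros((len(subjects), len(TIMEPOINTS), nf))
    half = config.effect_log_units / 2.0
    for f in set1_idx:
        s = signs[int(f)]
        for ti in (1, 2):  # persists at t3: t2->t3 ratio unaffected
            shift[is_gdm, ti, f] = s * half
            shift[~is_gdm, ti, f] = -s * half
    for f in set2_idx:
        s = signs[int(f)]
        shift[is_gdm, 2, f] = s * half
        shift[~is_gdm, 2, f] = -s * half

    eta = beta[None, None, :] + u[:, None, :] + shift
    eta2 = eta.reshape(-1, nf)
    comp = np.exp(eta2 - eta2.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)

    sigma_depth = np.sqrt(np.log1p(config.depth_cv**2))
    n_samples = comp.shape[0]
    depths = np.maximum(
        1,
        np.round(
            config.sequencing_depth
            * np.exp(rng.normal(-0.5 * sigma_depth**2, sigma_depth, size=n_samples))
        ).astype(np.int64),
    )
    alpha = config.overdispersion * comp
    gamma = rng.standard_gamma(alpha)
    probs = gamma / gamma.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depths, probs)

    records: List[SampleRecord] = []
    sample_ids: List[str] = []
    for si, subj in enumerate(subjects):
        for tp in TIMEPOINTS:
            sid = f"{subj}_{tp}"
            sample_ids.append(sid)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    subject_id=subj,
                    group="GDM" if is_gdm[si] else "control",
                    timepoint=tp,
                )
            )

    lineage = {fid: f"o__SimOrder{i % 12}; g__SimGenus{i % 40}" for i, fid in enumerate(features)}
    table = OtuTable(sample_ids=sample_ids, feature_ids=features, counts=counts, lineage=lineage)

    truth = SyntheticTruth(
        planted_set1={features[i] for i in set1_idx},
        planted_set2={features[i] for i in set2_idx},
        true_diff={features[i]: signs[int(i)] * config.effect_log_units for i in planted_idx},
        seed=config.seed,
    )
    if n_planted:
        expected = config.sequencing_depth * comp[:, planted_idx].mean(axis=0)
        if np.any(expected < 1):
            msg = (
                f"sequencing depth {config.sequencing_depth} yields expected count < 1 "
                f"for {int((expected < 1).sum())} planted feature(s)"
            )
            truth.warnings.append(msg)
            warnings.warn(msg)
    return table, records, truth


def simulate_pathway_db(
    n_pathways: int,
    n_clusters_true: int,
    config: CohortConfig,
    truth: SyntheticTruth,
    seed: Optional[int] = None,
) -> Tuple[PathwayDb, SyntheticTruth]:
    """Generate a pathway DB whose latent clusters track planted feature blocks.

    Pathways in the same latent cluster concentrate their contribution weight
    on a shared feature block (up-shifted Set1 features, down-shifted Set1
    features, unplanted features, ...) and share one signature compound, which
    becomes a planted recurrent metabolite; each pathway also carries 1-5
    private compounds.  Returns the DB and the updated truth.
    """
    if not n_pathways >= n_clusters_true >= 1:
        raise ValueError("need n_pathways >= n_clusters_true >= 1")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    features = _feature_ids(config.n_features)
    fidx = {f: i for i, f in enumerate(features)}

    set1 = sorted(truth.planted_set1)
    up1 = [f for f in set1 if truth.true_diff[f] > 0]
    down1 = [f for f in set1 if truth.true_diff[f] < 0]
    set2 = sorted(truth.planted_set2)
    up2 = [f for f in set2 if truth.true_diff[f] > 0]
    down2 = [f for f in set2 if truth.true_diff[f] < 0]
    unplanted = [f for f in features if f not in truth.true_diff]
    pools: List[List[str]] = [blk for blk in (up1, down1) if blk]
    null_chunks = max(1, n_clusters_true - len(pools) - sum(1 for b in (up2, down2) if b))
    chunk = max(3, len(unplanted) // (null_chunks + 1))
    pools.append(unplanted[:chunk])
    for blk in (up2, down2):
        if blk:
            pools.append(blk)
    for j in range(1, null_chunks):
        pools.append(unplanted[(j) * chunk : (j + 1) * chunk])
    blocks = [pools[j % len(pools)] for j in range(n_clusters_true)]

    signatures = []
    for j in range(n_clusters_true):
        if j < len(_SIGNATURE_POOL):
            signatures.append(_SIGNATURE_POOL[j])
        else:
            signatures.append(f"CPD-RECUR-{j}")

    pathway_ids = [f"PWY-{1000 + i}" for i in range(n_pathways)]
    cluster_of = {pid: i % n_clusters_true for i, pid in enumerate(pathway_ids)}
    contributions = np.zeros((n_pathways, len(features)))
    compounds: Dict[str, Set[str]] = {}
    for i, pid in enumerate(pathway_ids):
        block = blocks[cluster_of[pid]]
        w_block = rng.dirichlet(np.ones(len(block)))
        for f, w in zip(block, w_block):
            contributions[i, fidx[f]] += 0.9 * w
        bg = rng.choice(len(features), size=5, replace=False)
        contributions[i, bg] += 0.1 * rng.dirichlet(np.ones(5))
        n_private = int(rng.integers(1, 6))
        private = {f"CPD-{pid}-{k}" for k in range(n_private)}
        compounds[pid] = {signatures[cluster_of[pid]]} | private

    hormone = {s for s in signatures if not s.startswith("CPD-RECUR-")} | {"butanoate", "(R)-mevalonate"}
    db = PathwayDb(
        pathway_ids=pathway_ids,
        feature_ids=features,
        contributions=contributions,
        compounds=compounds,
        hormone_compounds=hormone,
    )
    # Clusters of size 1 cannot make their signature compound recurrent (n > 1).
    sizes = {j: sum(1 for p in cluster_of.values() if p == j) for j in range(n_clusters_true)}
    recurrent = {signatures[j] for j, size in sizes.items() if size > 1}
    updated = replace(
        truth,
        planted_recurrent_compounds=set(truth.planted_recurrent_compounds) | recurrent,
        pathway_cluster_of={**truth.pathway_cluster_of, **cluster_of},
    )
    return db, updated


def simulate_clinical(
    n_per_group: int,
    effects: Dict[str, float],
    seed: int = 0,
    skewed: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-subject clinical values with stated standardized mean differences.

    Values are standard normal (unit SD) plus ``effect`` in the GDM arm;
    features flagged in ``skewed`` are exponentiated (log-normal), with the
    effect applied on the log scale.  Layout: one row per subject with
    ``subject_id``, ``group``, then one column per clinical feature.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed)
    gdm, ctl = _subject_ids(n_per_group)
    groups = ["GDM"] * n_per_group + ["control"] * n_per_group
    out = {"subject_id": gdm + ctl, "group": groups}
    is_gdm = np.array([g == "GDM" for g in groups], dtype=float)
    skewed = set(skewed)
    for feat, eff in effects.items():
        x = rng.normal(0.0, 1.0, size=2 * n_per_group) + eff * is_gdm
        out[feat] = np.exp(x) if feat in skewed else x
    return pd.DataFrame(out)
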