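"""End-to-end orchestration: simulate/load -> temporal tests -> pathways ->
clustering -> recurrence -> clinical -> reports.

Every stochastic stage consumes a sub-seed derived by stable hashing of
(master seed, stage name), so results are reproducible and adding a stage
never perturbs the randomness of earlier ones.  Any stage failure aborts
with the stage name; tables already produced are still written.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .clinical import run_clinical_table
from .clustering import PathwayClusterModel, pathway_feature_matrix
from .diversity import alpha_diversity, alpha_group_test, lda_project, top_mad_features
from .errors import AnalysisError
from .io import (
    OtuTable,
    PathwayDb,
    read_feature_table,
    read_metadata,
    read_pathway_db,
    write_results,
)
from .pathways import direction_fisher, infer_activity, pathway_change_test
from .recurrence import FOCAL_FAMILIES, compound_recurrence, hormone_overlap, representative_pathways
from .simulate import CohortConfig, simulate_clinical, simulate_cohort, simulate_pathway_db
from .temporal import (
    INTERVALS,
    interval_log_ratio,
    label_trajectory,
    permutation_test,
    select_significant_sets,
    to_relative_abundance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    Thresholds default to the analysis design: 1000 permutation rounds,
    OTU FDR gate 0.1, pathway raw-p gate 0.05, PC2 outlier bound 5, three
    pathway clusters, recurrence at n > 1, top-100 MAD features, pseudocount
    1e-6.
    """

    n_perm: int = 1000
    fdr_otu: float = 0.1
    alpha_pathway: float = 0.05
    pc2_bound: float = 5.0
    k_clusters: int = 3
    recurrence_min: int = 2
    top_mad: int = 100
    epsilon: float = 1e-6
    tau_low: float = 1e-4
    delta_stable: float = 0.1
    seed: int = 0
    # input paths; when None, inputs are simulated on the fly
    feature_table: Optional[str] = None
    metadata: Optional[str] = None
    pathway_contrib: Optional[str] = None
    pathway_compounds: Optional[str] = None
    hormone_compounds: Optional[str] = None
    clinical: Optional[str] = None
    out_dir: str = "gutshift_out"
    figures: bool = False
    # synthetic fallback settings
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_pathways: int = 40
    n_clusters_true: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.fdr_otu <= 1 and 0 <= self.alpha_pathway <= 1):
            raise ValueError("thresholds out of range")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.k_clusters < 1 or self.top_mad < 1 or self.recurrence_min < 1:
            raise ValueError("k_clusters, top_mad and recurrence_min must be >= 1")
        if self.epsilon <= 0 or self.tau_low <= 0 or self.delta_stable <= 0:
            raise ValueError("epsilon, tau_low and delta_stable must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**raw)
        if cohort_raw:
            cfg = replace(cfg, cohort=CohortConfig(**cohort_raw))
        return cfg

    def flat_dict(self) -> Dict[str, object]:
        d = asdict(self)
        cohort = d.pop("cohort")
        for k, v in cohort.items():
            d[f"cohort.{k}"] = v
        return d


def _sub_seeds(config: PipelineConfig) -> Dict[str, int]:
    stages = [
        "simulate_cohort",
        "simulate_pathway_db",
        "simulate_clinical",
        "perm_otu_t2_vs_t1",
        "perm_otu_t3_vs_t2",
        "perm_pwy_t2_vs_t1",
        "perm_pwy_t3_vs_t2",
        "cluster_set1",
        "cluster_set2",
    ]
    return {s: derive_seed(config.seed, s) for s in stages}


def run_pipeline(config: PipelineConfig) -> Tuple[Dict[str, object], Dict[str, pd.DataFrame]]:
    """Execute all stages; returns (manifest, result tables) and writes both."""
    tables: Dict[str, pd.DataFrame] = {}
    notes: Dict[str, object] = {}
    seeds = _sub_seeds(config)
    stage = "inputs"
    try:
        # ---- stage: inputs -------------------------------------------------
        if config.feature_table and config.metadata:
            table = read_feature_table(config.feature_table)
            meta = read_metadata(config.metadata)
            truth = None
            notes["inputs"] = "files"
        else:
            cohort_cfg = replace(config.cohort, seed=seeds["simulate_cohort"])
            table, meta, truth = simulate_cohort(cohort_cfg)
            notes["inputs"] = "simulated"
        if config.pathway_contrib and config.pathway_compounds:
            db = read_pathway_db(
                config.pathway_contrib, config.pathway_compounds, config.hormone_compounds
            )
        elif truth is not None:
            db, truth = simulate_pathway_db(
                config.n_pathways,
                config.n_clusters_true,
                replace(config.cohort, seed=seeds["simulate_cohort"]),
                truth,
                seed=seeds["simulate_pathway_db"],
            )
        else:
            db = None

        # ---- stage: diversity ---------------------------------------------
        stage = "diversity"
        alpha = alpha_diversity(table)
        tables["alpha_diversity"] = alpha
        tests = [alpha_group_test(alpha, meta, tp) for tp in ("t1", "t2", "t3")]
        tables["alpha_tests"] = pd.concat(tests, ignore_index=True)
        comp = to_relative_abundance(table)
        top = top_mad_features(table, n_top=config.top_mad)
        class_of = {r.sample_id: f"{r.group}_{r.timepoint}" for r in meta}
        sub = comp.loc[[s for s in comp.index if s in class_of], top]
        tables["lda_scores"] = lda_project(sub, [class_of[s] for s in sub.index])

        # ---- stage: temporal ----------------------------------------------
        stage = "temporal"
        otu_results = {}
        changes = {}
        for interval in INTERVALS:
            change = interval_log_ratio(comp, meta, interval, epsilon=config.epsilon)
            changes[interval] = change
            res = permutation_test(change, n_perm=config.n_perm, seed=seeds[f"perm_otu_{interval}"])
            labels = label_trajectory(
                change, comp, meta, tau_low=config.tau_low, delta_stable=config.delta_stable
            )
            otu_results[interval] = res.merge(
                labels[["feature_id", "label_gdm", "label_control"]], on="feature_id"
            )
            otu_results[interval]["lineage"] = [
                table.lineage.get(f, "") for f in otu_results[interval]["feature_id"]
            ]
            notes[f"excluded_subjects.{interval}"] = ",".join(change.excluded_subjects)
        set1_otus, set2_otus = select_significant_sets(otu_results, fdr_threshold=config.fdr_otu)
        tables["otu_results"] = pd.concat(otu_results.values(), ignore_index=True)
        notes["n_set1_otus"] = len(set1_otus)
        notes["n_set2_otus"] = len(set2_otus)
        if truth is not None:
            notes["recovered_set1"] = len(set(set1_otus) & truth.planted_set1)
            notes["recovered_set2"] = len(set(set2_otus) & truth.planted_set2)

        # ---- stage: pathways ----------------------------------------------
        pathway_sets = {}
        if db is not None:
            stage = "pathways"
            activity = infer_activity(comp, db)
            pw_rows = []
            for interval in INTERVALS:
                res = pathway_change_test(
                    activity,
                    meta,
                    interval,
                    n_perm=config.n_perm,
                    seed=seeds[f"perm_pwy_{interval}"],
                    alpha=config.alpha_pathway,
                    epsilon=config.epsilon,
                )
                pathway_sets[interval] = res
                df = res.results.rename(columns={"feature_id": "pathway_id"})
                df["selected"] = df["p_perm"] < config.alpha_pathway
                pw_rows.append(df)
            tables["pathway_results"] = pd.concat(pw_rows, ignore_index=True)
            notes["n_set1_pathways"] = len(pathway_sets["t2_vs_t1"].selected)
            notes["n_set2_pathways"] = len(pathway_sets["t3_vs_t2"].selected)
            sel1 = pathway_sets["t2_vs_t1"].selected
            if sel1:
                act_change = interval_log_ratio(activity, meta, "t2_vs_t1", epsilon=config.epsilon)
                adf = act_change.to_dataframe()
                gvec = act_change.group_vector
                gmean = adf.loc[np.array(act_change.subjects)[gvec]].mean()
                cmean = adf.loc[np.array(act_change.subjects)[~gvec]].mean()
                tab2x2, odds, fisher_p = direction_fisher(sel1, gmean, cmean)
                notes["set1_direction_fisher_p"] = fisher_p
                notes["set1_direction_table"] = tab2x2.tolist()

            # ---- stage: clustering ----------------------------------------
            stage = "clustering"
            cluster_rows = []
            labels_by_set: Dict[str, Dict[str, int]] = {}
            for set_name, interval, filt in (
                ("set1", "t2_vs_t1", False),
                ("set2", "t3_vs_t2", True),
            ):
                selected = pathway_sets[interval].selected
                if len(selected) < config.k_clusters:
                    notes[f"clustering.{set_name}"] = (
                        f"skipped: {len(selected)} selected pathways < k={config.k_clusters}"
                    )
                    continue
                act_change = interval_log_ratio(activity, meta, interval, epsilon=config.epsilon)
                profile = pathway_feature_matrix(act_change, selected)
                model = PathwayClusterModel(
                    k=config.k_clusters,
                    pc2_bound=config.pc2_bound,
                    filter_outliers=filt,
                    n_init=50,
                    random_state=seeds[f"cluster_{set_name}"],
                ).fit(profile)
                at = model.assignment_table()
                at.insert(0, "set", set_name)
                cluster_rows.append(at)
                labels_by_set[set_name] = {
                    p: int(model.labels_[p]) for p in model.labels_.index
                }
                if config.figures:
                    _plot_clusters(model, set_name, Path(config.out_dir))
            if cluster_rows:
                tables["pathway_clusters"] = pd.concat(cluster_rows, ignore_index=True)

            # ---- stage: recurrence ----------------------------------------
            stage = "recurrence"
            rec_rows, rep_rows = [], []
            focal = set().union(*FOCAL_FAMILIES.values())
            for set_name, interval in (("set1", "t2_vs_t1"), ("set2", "t3_vs_t2")):
                labels = labels_by_set.get(set_name)
                if not labels:
                    continue
                rec = compound_recurrence(labels, db, recurrence_min=config.recurrence_min)
                rdf = rec.to_dataframe()
                rdf.insert(0, "set", set_name)
                rec_rows.append(rdf)
                overlap = hormone_overlap(rec, db)
                notes[f"hormone_recurrent.{set_name}"] = {
                    k: ",".join(v) for k, v in overlap.items() if v
                }
                pvals = dict(
                    zip(
                        pathway_sets[interval].results["feature_id"],
                        pathway_sets[interval].results["p_perm"],
                    )
                )
                rep = representative_pathways(rec, db, focal, labels, p_values=pvals)
                rep.insert(0, "set", set_name)
                rep_rows.append(rep)
            if rec_rows:
                tables["recurrence"] = pd.concat(rec_rows, ignore_index=True)
            if rep_rows:
                tables["representative_pathways"] = pd.concat(rep_rows, ignore_index=True)

        # ---- stage: clinical ----------------------------------------------
        stage = "clinical"
        if config.clinical:
            clin = pd.read_csv(config.clinical, sep="\t")
        else:
            clin = simulate_clinical(
                n_per_group=config.cohort.n_per_group,
                effects={"hba1c": 1.0, "weight_gain": -0.7, "age": 0.0, "alt": 0.0},
                seed=seeds["simulate_clinical"],
                skewed=("alt",),
            )
        tables["clinical_results"] = run_clinical_table(clin)

    except Exception as exc:
        # preserve partial outputs before propagating, tagged with the stage
        manifest = _write(config, tables, notes, seeds, error=f"{stage}: {exc}")
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "report"
    manifest = _write(config, tables, notes, seeds)
    return manifest, tables


def _write(config, tables, notes, seeds, error: Optional[str] = None):
    meta = config.flat_dict()
    meta.update({f"subseed.{k}": v for k, v in seeds.items()})
    for k, v in notes.items():
        meta[f"note.{k}"] = v
    meta["statistic"] = "difference of group means of per-subject log-ratios, subject-label permutation"
    meta["pathway_selection"] = "raw permutation p < alpha_pathway"
    meta["simpson_definition"] = "1 - sum(p^2)"
    meta["clustering_space"] = "first two PC scores of centered change profiles"
    if error:
        meta["error"] = error
    return write_results(tables, config.out_dir, config=meta, seed=config.seed)


def _plot_clusters(model: PathwayClusterModel, set_name: str, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    at = model.assignment_table()
    kept = at[~at["outlier"]]
    sc = ax.scatter(kept["PC1"], kept["PC2"], c=kept["cluster"].astype(int), cmap="tab10", s=30)
    out = at[at["outlier"]]
    if len(out):
        ax.scatter(out["PC1"], out["PC2"], marker="x", c="grey", s=30)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"{set_name} pathway clusters")
    fig.tight_layout()
    fig.savefig(out_dir / f"clusters_{set_name}.png", dpi=120)
    plt.close(fig)
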