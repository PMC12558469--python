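"""End-to-end orchestration of the repertoire analysis on an in-memory cohort.

Order of operations (baseline samples only):

1. productive filtering + CDR3-level aggregation;
2. per-sample clonality (Gini, raw and at common downsampled depth), group
   comparisons, age-adjusted OLS;
3. pooled Hamming-1 + MCL clustering and the sample × cluster matrix;
4. fixed stratified 70/30 split (healthy vs diseased);
5. differential cluster prevalence (Fisher, BH-FDR, nominal α) on the training
   split only, plus permutation-calibrated group exclusivity;
6. physicochemical profiles of the selected clusters and their
   direction-stratified comparisons;
7. two-stage classification (repeated 80/20 internal holdout; external test on
   the 30% split), DeLong comparisons and variable importance;
8. optional ground-truth evaluation when the cohort is synthetic.

The test split's presence values never reach the selection stage: prevalence
tables are computed on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, cluster, da, diversity, properties
from .io import (
    Repertoire,
    SampleMetadata,
    DISEASE_GROUPS,
    aggregate_by_cdr3aa,
    filter_productive,
)
from .simulate import GroundTruth

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    alpha: float = 0.001
    n_permutations: int = 1000
    split_fraction: float = 0.70
    repeats: int = 5
    inner_fraction: float = 0.8
    mcl: cluster.MCLParams = field(default_factory=cluster.MCLParams)
    model_families: tuple[str, ...] = classify.FAMILIES
    downsample_target: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 0 < self.inner_fraction < 1:
            raise ValueError("inner_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class AnalysisResult:
    diversity: pd.DataFrame
    group_comparisons: pd.DataFrame
    age_model: diversity.GroupAgeModel
    cluster_set: cluster.ClusterSet
    matrix: cluster.ClusterMatrix
    cluster_gini: pd.Series
    gini_spearman: float
    split: classify.SplitPlan
    da_results: list[da.DAResult]
    selected: list[int]
    exclusivity: list[da.ExclusivityResult]
    property_means: pd.DataFrame
    property_z: pd.DataFrame
    property_comparisons: pd.DataFrame
    internal_metrics: dict[str, classify.MetricSet]
    external_metrics: dict[str, dict[str, float]]
    external_scores: dict[str, np.ndarray]
    delong: pd.DataFrame
    importance: dict[str, pd.DataFrame]
    ground_truth_eval: dict | None = None


def binary_labels(metadata: list[SampleMetadata]) -> pd.Series:
    """sample_id → 'healthy' / 'diseased' (MGUS + SMM + MM pooled)."""
    return pd.Series(
        {
            m.sample_id: ("diseased" if m.group in DISEASE_GROUPS else "healthy")
            for m in metadata
        }
    )


def analyze_cohort(
    repertoires: list[Repertoire],
    metadata: list[SampleMetadata],
    config: AnalysisConfig | None = None,
    ground_truth: GroundTruth | None = None,
) -> AnalysisResult:
    config = config or AnalysisConfig()
    config.validate()
    seed = int(config.seed)

    meta_by_id = {m.sample_id: m for m in metadata}
    baseline = [
        r
        for r in repertoires
        if meta_by_id.get(r.sample_id) is not None
        and meta_by_id[r.sample_id].timepoint == "baseline"
    ]
    if not baseline:
        raise ValueError("no baseline samples to analyze")
    clean = [aggregate_by_cdr3aa(filter_productive(r)) for r in baseline]
    groups = pd.Series({m.sample_id: m.group for m in metadata}).reindex(
        [r.sample_id for r in clean]
    )
    ages = pd.Series({m.sample_id: m.age for m in metadata}).reindex(groups.index)

    # --- diversity -----------------------------------------------------
    div = diversity.diversity_table(
        clean, target=config.downsample_target, seed=seed + 10
    )
    comparisons = diversity.group_comparisons(div, groups)
    age_model = diversity.fit_group_age_model(
        div.loc[groups.index, "gini_downsampled"], ages, groups
    )

    # --- clustering ----------------------------------------------------
    cluster_set = cluster.cluster_pooled(clean, params=config.mcl)
    matrix = cluster.build_cluster_matrix(cluster_set, clean)
    cgini = cluster.cluster_gini_per_sample(matrix)
    joint = pd.concat([div["gini_downsampled"], cgini], axis=1).dropna()
    gini_rho = (
        diversity.spearman(joint["gini_downsampled"], joint["cluster_gini"])
        if len(joint) >= 3
        else float("nan")
    )

    # --- split + differential abundance (training only) ----------------
    labels = binary_labels(metadata).reindex(groups.index)
    split = classify.stratified_split(labels, fraction=config.split_fraction, seed=seed + 20)
    train_ids = list(split.train_ids)
    test_ids = list(split.test_ids)
    train_matrix = cluster.ClusterMatrix(abundance=matrix.abundance.loc[train_ids])
    da_results = da.differential_abundance(
        train_matrix, labels.loc[train_ids], alpha=config.alpha
    )
    selected = da.select_candidates(da_results)

    excl = da.permutation_exclusivity_test(
        matrix.presence, groups, n_permutations=config.n_permutations, seed=seed + 30
    )

    # --- physicochemical profiles of selected clusters ------------------
    directions = pd.Series(
        {r.cluster_id: r.direction for r in da_results if r.selected}
    )
    sel_clusters = cluster.ClusterSet(
        clusters=[c for c in cluster_set.clusters if c.cluster_id in set(selected)]
    )
    if sel_clusters.clusters:
        prop_means, prop_z = properties.cluster_property_summary(sel_clusters)
        prop_cmp = properties.compare_property_distributions(prop_means, directions)
    else:
        cols = list(properties.PROPERTY_NAMES)
        prop_means = pd.DataFrame(columns=cols)
        prop_z = pd.DataFrame(columns=cols)
        prop_cmp = pd.DataFrame(columns=["statistic", "p"])

    # --- classification -------------------------------------------------
    specs = classify.default_model_specs(config.model_families)
    X_train = classify.build_features(matrix.abundance.loc[train_ids], selected)
    X_test = classify.build_features(matrix.abundance.loc[test_ids], selected)
    internal = classify.repeated_holdout_eval(
        X_train,
        labels.loc[train_ids],
        specs,
        repeats=config.repeats,
        inner_fraction=config.inner_fraction,
        seed=seed + 40,
    )
    external, ext_scores, models = classify.final_fit_and_external_test(
        X_train, labels.loc[train_ids], X_test, labels.loc[test_ids], specs, seed=seed + 41
    )
    y_test = (labels.loc[test_ids] == classify.POSITIVE_CLASS).astype(int).to_numpy()
    dl = classify.delong_matrix(ext_scores, y_test)
    importance = {
        fam: classify.variable_importance(models[fam], fam, X_test, y_test, seed=seed + 42)
        for fam in models
    }

    gt_eval = (
        evaluate_ground_truth(ground_truth, cluster_set, da_results)
        if ground_truth is not None and ground_truth.spiked_motifs
        else None
    )

    return AnalysisResult(
        diversity=div,
        group_comparisons=comparisons,
        age_model=age_model,
        cluster_set=cluster_set,
        matrix=matrix,
        cluster_gini=cgini,
        gini_spearman=gini_rho,
        split=split,
        da_results=da_results,
        selected=selected,
        exclusivity=excl,
        property_means=prop_means,
        property_z=prop_z,
        property_comparisons=prop_cmp,
        internal_metrics=internal,
        external_metrics=external,
        external_scores=ext_scores,
        delong=dl,
        importance=importance,
        ground_truth_eval=gt_eval,
    )


def evaluate_ground_truth(
    ground_truth: GroundTruth,
    cluster_set: cluster.ClusterSet,
    da_results: list[da.DAResult],
) -> dict:
    """Recovery of planted clusters: recall, purity and selection rate.

    A spiked motif counts as *recovered* when all of its pooled member
    sequences sit in a single inferred cluster (at least two present); purity
    is the share of that cluster's members belonging to the motif; the motif is
    *selected* when its host cluster passed the nominal Fisher threshold.
    """
    lookup = cluster_set.member_to_cluster()
    sizes = {c.cluster_id: len(c.members) for c in cluster_set.clusters}
    selected = {r.cluster_id for r in da_results if r.selected}
    n = len(ground_truth.spiked_motifs)
    recovered = 0
    purities: list[float] = []
    n_selected = 0
    for motif in ground_truth.spiked_motifs:
        assignments = [lookup.get(m) for m in motif["members"] if lookup.get(m) is not None]
        if len(assignments) < 2:
            continue
        hosts = set(assignments)
        if len(hosts) == 1:
            recovered += 1
            host = hosts.pop()
            purities.append(len(assignments) / sizes[host])
            if host in selected:
                n_selected += 1
        else:
            # credit selection if the majority host cluster was selected
            host = max(hosts, key=lambda h: assignments.count(h))
            if host in selected:
                n_selected += 1
    return {
        "n_spiked": n,
        "recall": recovered / n if n else float("nan"),
        "mean_purity": float(np.mean(purities)) if purities else float("nan"),
        "selection_rate": n_selected / n if n else float("nan"),
    }
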