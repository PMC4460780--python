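"""End-to-end wiring: cohort -> connectivity -> both feature arms -> evaluation.

The pathway arm infers one activity feature per catalog instance via the
exhaustive subset search; the region arm computes RFCS for every region and
keeps the top-K by Welch t, with K equal to the pathway feature count so both
arms feed the classifiers the same number of inputs.

Feature construction in :func:`build_features` is *label-aware*: subset
selection and region ranking see the full cohort's labels before
cross-validation, replicating the original study design.
:func:`nested_cv_scores` instead re-runs the selection inside each training
fold and scores honest held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .activity import ActivityFeatureTable, exhaustive_search, infer_all_pathways
from .baseline import RegionFeatureSelection, rfcs_table, select_top_regions
from .catalog import PathwayInstance
from .connectivity import (
    ConnectivityMatrix,
    RegionTimeSeries,
    build_f_matrix,
    pearson_connectivity,
)
from .evaluate import CLASSIFIERS, EvaluationReport, cross_validate

__all__ = ["FeatureArms", "compute_connectivity", "build_features", "evaluate_arms",
           "nested_cv_scores"]


@dataclass
class FeatureArms:
    """Matched feature tables for the pathway-based and region-based arms."""

    pathway: ActivityFeatureTable
    region_selection: RegionFeatureSelection
    region_features: pd.DataFrame
    group_labels: np.ndarray


def compute_connectivity(cohort: Sequence[RegionTimeSeries]) -> list[ConnectivityMatrix]:
    return [pearson_connectivity(ts) for ts in cohort]


def build_features(
    connectivity: Sequence[ConnectivityMatrix],
    instances: Sequence[PathwayInstance],
    group_labels: Sequence,
    cap: int = 20,
) -> FeatureArms:
    """Both feature arms from per-subject connectivity, with matched widths."""
    group_labels = np.asarray(group_labels)
    pathway = infer_all_pathways(connectivity, instances, group_labels, cap=cap)
    strengths = rfcs_table(connectivity, group_labels)
    K = min(len(instances), strengths.table.shape[1])
    selection = select_top_regions(strengths, K=K)
    return FeatureArms(
        pathway=pathway,
        region_selection=selection,
        region_features=selection.feature_table(strengths),
        group_labels=group_labels,
    )


def evaluate_arms(
    arms: FeatureArms,
    classifiers: Sequence[str] = CLASSIFIERS,
    folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict[str, EvaluationReport]:
    """Cross-validate both arms with identical fold assignments (same seed)."""
    return {
        "pathway": cross_validate(
            arms.pathway.table, arms.group_labels, classifiers, folds, seed, **kwargs
        ),
        "region": cross_validate(
            arms.region_features, arms.group_labels, classifiers, folds, seed, **kwargs
        ),
    }


def nested_cv_scores(
    connectivity: Sequence[ConnectivityMatrix],
    instances: Sequence[PathwayInstance],
    group_labels: Sequence,
    folds: int = 10,
    seed: int = 0,
    cap: int = 20,
) -> pd.DataFrame:
    """Leakage-free pathway features: re-select subsets inside each training fold.

    For every fold, the discriminative connectivity set of each pathway is
    chosen on the training subjects only and then applied to the held-out
    subjects.  Returns a samples × pathways activity table whose entries were
    all computed out-of-fold, suitable for honest downstream evaluation.
    """
    group_labels = np.asarray(group_labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = len(connectivity)
    out = pd.DataFrame(
        np.full((n, len(instances)), np.nan),
        index=[c.subject_id for c in connectivity],
        columns=[inst.id for inst in instances],
    )
    dummy = np.zeros(n)
    for train, test in skf.split(dummy, group_labels):
        train_conn = [connectivity[i] for i in train]
        for inst in instances:
            F_train = build_f_matrix(train_conn, inst, group_labels[train])
            res = exhaustive_search(F_train, cap=cap)
            F_all = build_f_matrix(connectivity, inst, group_labels)
            out.iloc[test, out.columns.get_loc(inst.id)] = F_all.z[
                np.ix_(test, res.selected.edge_indices)
            ].mean(axis=1)
    return out
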