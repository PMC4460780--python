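"""Pathway activity inference by exhaustive search over connectivity subsets.

For a pathway with n edges and its samples × edges Fisher-z matrix F, every
nonempty edge subset ``B_k`` defines a per-sample *activity score*

    a_pk(i) = (1/k) * sum_{s in B_k} R_is

— the mean z over the chosen edges.  Each subset's activity vector is scored
by the two-group Welch t statistic ``T(B_pk)``; the *discriminative
connectivity set* is the subset maximizing |T| over all 2^n - 1 candidates,
and its activity vector becomes the pathway's per-subject feature.  Ties are
broken toward smaller subsets, then lexicographically smaller index sets, so
the search is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ParcellationLabels, PathwayInstance
from .connectivity import ConnectivityMatrix, PathwayConnectivityMatrix, build_f_matrix

__all__ = [
    "ActivityFeatureTable",
    "ConnectivitySubset",
    "PathwayActivityResult",
    "SUBSET_CAP",
    "activity_diagnostics",
    "activity_score",
    "exhaustive_search",
    "infer_all_pathways",
    "subset_t_score",
    "write_activity_table",
]

#: default upper bound on edges per pathway (2^20 - 1 ~ 1e6 subsets)
SUBSET_CAP = 20

_CHUNK = 1 << 15


@dataclass(frozen=True)
class ConnectivitySubset:
    """A nonempty set of 0-based edge positions within a pathway's F matrix."""

    edge_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(set(self.edge_indices)))
        if not idx:
            raise ValueError("connectivity subset may not be empty")
        if idx[0] < 0:
            raise ValueError("negative edge index")
        object.__setattr__(self, "edge_indices", idx)

    @property
    def k(self) -> int:
        return len(self.edge_indices)


@dataclass
class PathwayActivityResult:
    """Winning subset, per-sample activity vector and its t-score for one pathway."""

    pathway_id: str
    selected: ConnectivitySubset
    selected_edges: tuple[str, ...]
    activity: np.ndarray
    t_score: float
    p_value: float
    diagnostics: dict = field(default_factory=dict)
    n_subsets_evaluated: int = 0


@dataclass
class ActivityFeatureTable:
    """Samples × pathways activity features, columns ordered by significance."""

    table: pd.DataFrame
    results: dict[str, PathwayActivityResult]
    group_labels: np.ndarray

    @property
    def ranking(self) -> list[str]:
        return list(self.table.columns)


def activity_score(z_row: np.ndarray, subset: ConnectivitySubset) -> float:
    """Mean of the subset's z values for one sample (the activity a_pk)."""
    z_row = np.asarray(z_row, dtype=float)
    idx = np.array(subset.edge_indices)
    if idx.max() >= z_row.shape[-1]:
        raise IndexError("subset index outside the pathway's edge range")
    return float(z_row[idx].mean())


def _split_groups(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    return values[labels == groups[0]], values[labels == groups[1]]


def subset_t_score(activity: np.ndarray, labels: Sequence) -> tuple[float, float]:
    """Welch (unequal-variance) two-tailed t statistic for a two-group activity vector.

    Sign convention: positive t means the first group (smaller label) has the
    larger mean.  Groups need >= 2 samples each and nonzero within-group
    variance.
    """
    activity = np.asarray(activity, dtype=float)
    a, b = _split_groups(activity, np.asarray(labels))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero within-group variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _welch_t_columns(
    A: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> np.ndarray:
    """Welch t per column of a samples × subsets activity block."""
    a, b = A[mask1], A[mask2]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / a.shape[0] + v2 / b.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / denom


def exhaustive_search(
    F: PathwayConnectivityMatrix, cap: int = SUBSET_CAP
) -> PathwayActivityResult:
    """Scan all nonempty edge subsets of a pathway for the maximal |t| activity.

    Evaluates every one of the 2^n - 1 subsets (n = edge count, capped at
    ``cap``), computing each subset's mean-z activity vector and its Welch t
    between the two groups.  Returns the winner with its activity vector,
    two-sided p-value and normality/variance diagnostics.
    """
    n = F.n_edges
    if n == 0:
        raise ValueError(f"{F.pathway_id}: pathway has no edges")
    if n > cap:
        raise ValueError(
            f"{F.pathway_id}: {n} edges exceeds the exhaustive-search cap of {cap}; "
            "shorten the catalog entry or raise the cap explicitly"
        )
    labels = F.group_labels
    groups = np.unique(labels)
    mask1, mask2 = labels == groups[0], labels == groups[1]
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError(f"{F.pathway_id}: each group needs at least 2 samples")

    Z = F.z
    bits = np.arange(n)
    best_t = -np.inf
    best_key: tuple[int, tuple[int, ...]] | None = None
    best_mask = 0
    total = (1 << n) - 1
    for start in range(1, total + 1, _CHUNK):
        masks = np.arange(start, min(start + _CHUNK, total + 1), dtype=np.int64)
        B = ((masks[:, None] >> bits) & 1).astype(float)  # subsets × edges
        k = B.sum(axis=1)
        A = Z @ B.T / k  # samples × subsets
        t = _welch_t_columns(A, mask1, mask2)
        abs_t = np.abs(t)
        abs_t[~np.isfinite(abs_t)] = -np.inf
        # candidates that could beat or tie the incumbent
        for j in np.flatnonzero(abs_t >= best_t):
            if abs_t[j] < best_t:  # incumbent improved earlier in this chunk
                continue
            idx = tuple(int(i) for i in np.flatnonzero((masks[j] >> bits) & 1))
            key = (len(idx), idx)
            if abs_t[j] > best_t or best_key is None or key < best_key:
                best_t = float(abs_t[j])
                best_key = key
                best_mask = int(masks[j])
    if not np.isfinite(best_t):
        raise ValueError(f"{F.pathway_id}: no subset has nonzero within-group variance")

    subset = ConnectivitySubset(
        tuple(int(i) for i in np.flatnonzero((best_mask >> bits) & 1))
    )
    activity = Z[:, subset.edge_indices].mean(axis=1)
    t, p = subset_t_score(activity, labels)
    return PathwayActivityResult(
        pathway_id=F.pathway_id,
        selected=subset,
        selected_edges=tuple(F.edge_names[i] for i in subset.edge_indices),
        activity=activity,
        t_score=t,
        p_value=p,
        diagnostics=activity_diagnostics(activity, labels),
        n_subsets_evaluated=total,
    )


def activity_diagnostics(activity: np.ndarray, labels: Sequence) -> dict:
    """Normality and variance-equality checks on an activity vector.

    Per group, a one-sample Kolmogorov-Smirnov test against a normal with the
    group's own moments; across groups, Levene's test for equal variances.
    These are reported for inspection and never gate subset selection.
    """
    activity = np.asarray(activity, dtype=float)
    a, b = _split_groups(activity, np.asarray(labels))
    out: dict = {}
    for name, grp in (("group1", a), ("group2", b)):
        sd = grp.std(ddof=1) if len(grp) > 1 else 0.0
        if sd == 0:
            out[f"ks_p_{name}"] = float("nan")
        else:
            out[f"ks_p_{name}"] = float(
                stats.kstest(grp, "norm", args=(grp.mean(), sd)).pvalue
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lev = stats.levene(a, b)
    out["levene_p"] = float(lev.pvalue) if np.isfinite(lev.pvalue) else 1.0
    return out


def infer_all_pathways(
    cohort: Sequence[ConnectivityMatrix],
    instances: Sequence[PathwayInstance],
    group_labels: Sequence,
    cap: int = SUBSET_CAP,
) -> ActivityFeatureTable:
    """Run the exhaustive search for every pathway instance in a catalog.

    Returns one activity column per instance, ordered by ascending p-value of
    the winning t-score (most significant first); per-pathway results stay
    retrievable by id.
    """
    group_labels = np.asarray(group_labels)
    results: dict[str, PathwayActivityResult] = {}
    for inst in instances:
        try:
            F = build_f_matrix(cohort, inst, group_labels)
            results[inst.id] = exhaustive_search(F, cap=cap)
        except Exception as err:
            raise RuntimeError(f"pathway {inst.id!r}: {err}") from err
    order = sorted(results, key=lambda pid: (results[pid].p_value, pid))
    table = pd.DataFrame(
        {pid: results[pid].activity for pid in order},
        index=[c.subject_id for c in cohort],
    )
    return ActivityFeatureTable(table=table, results=results, group_labels=group_labels)


def write_activity_table(features: ActivityFeatureTable, path: str | Path) -> None:
    """Write the activity table (TSV) plus a JSON sidecar of per-pathway selections."""
    path = Path(path)
    features.table.to_csv(path, sep="\t", float_format="%.6f")
    sidecar = {
        pid: {
            "selected_edges": list(res.selected_edges),
            "edge_indices": list(res.selected.edge_indices),
            "t_score": res.t_score,
            "p_value": res.p_value,
            "diagnostics": res.diagnostics,
            "n_subsets_evaluated": res.n_subsets_evaluated,
        }
        for pid, res in features.results.items()
    }
    path.with_suffix(path.suffix + ".report.json").write_text(
        json.dumps(sidecar, indent=2)
    )
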