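"""Region-based baseline: regional functional correlation strength (RFCS).

RFCS is a degree-like node statistic: for region a,

    CS(a) = (1/(N-1)) * sum_{b != a} |r_ab|

the mean absolute Pearson correlation of a region to every other region.
The samples × regions CS table is the region-based feature set; feature
selection ranks regions by a two-group Welch t-test on their CS values and
keeps the top K (K chosen to match the pathway arm's feature count, so the
two arms see the same number of inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix

__all__ = [
    "RegionFeatureSelection",
    "RegionStrengthTable",
    "rfcs",
    "rfcs_table",
    "select_top_regions",
    "write_rfcs_table",
]


@dataclass
class RegionStrengthTable:
    """Samples × regions table of CS values in [0, 1], with group labels."""

    table: pd.DataFrame
    group_labels: np.ndarray


@dataclass
class RegionFeatureSelection:
    """Welch-t ranking of regions with the selected top-K subset."""

    ranking: pd.DataFrame  # region, t, p — most discriminative first
    selected: tuple[str, ...]
    K: int

    def feature_table(self, strengths: RegionStrengthTable) -> pd.DataFrame:
        return strengths.table[list(self.selected)]


def rfcs(conn: ConnectivityMatrix) -> np.ndarray:
    """Per-region correlation strength CS(a) = mean_{b != a} |r_ab|."""
    n = conn.r.shape[0]
    if n < 2:
        raise ValueError("RFCS needs at least 2 regions")
    abs_r = np.abs(conn.r)
    return (abs_r.sum(axis=1) - np.diag(abs_r)) / (n - 1)


def rfcs_table(
    cohort: Sequence[ConnectivityMatrix], group_labels: Sequence
) -> RegionStrengthTable:
    """CS values for every subject and region, rows in cohort order."""
    if not cohort:
        raise ValueError("empty cohort")
    table = pd.DataFrame(
        np.stack([rfcs(conn) for conn in cohort]),
        index=[c.subject_id for c in cohort],
        columns=list(cohort[0].labels.names),
    )
    return RegionStrengthTable(table=table, group_labels=np.asarray(group_labels))


def select_top_regions(
    strengths: RegionStrengthTable, K: int, order: str = "p"
) -> RegionFeatureSelection:
    """Rank regions by a two-group Welch t on CS and keep the top K.

    ``order`` controls the ranking key: ``"p"`` (default) ranks by ascending
    p-value, ``"abs_t"`` by descending |t| (equivalent up to degrees of
    freedom), ``"t"`` by ascending raw t.  Ties break on region index, so the
    ranking is total and deterministic.
    """
    n_regions = strengths.table.shape[1]
    if not 1 <= K <= n_regions:
        raise ValueError(f"K must be in [1, {n_regions}], got {K}")
    labels = strengths.group_labels
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = strengths.table.to_numpy()[labels == groups[0]]
    b = strengths.table.to_numpy()[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    ranking = pd.DataFrame(
        {"region": strengths.table.columns, "t": t, "p": p, "index": range(n_regions)}
    )
    if order == "p":
        ranking = ranking.sort_values(["p", "index"], kind="stable")
    elif order == "abs_t":
        ranking = ranking.assign(abs_t=np.abs(t)).sort_values(
            ["abs_t", "index"], ascending=[False, True], kind="stable"
        ).drop(columns="abs_t")
    elif order == "t":
        ranking = ranking.sort_values(["t", "index"], kind="stable")
    else:
        raise ValueError(f"unknown ranking order {order!r}")
    ranking = ranking.drop(columns="index").reset_index(drop=True)
    return RegionFeatureSelection(
        ranking=ranking,
        selected=tuple(ranking["region"].head(K)),
        K=K,
    )


def write_rfcs_table(
    selection: RegionFeatureSelection, strengths: RegionStrengthTable, path: str | Path
) -> None:
    """Write the selected-region CS table (TSV) plus a ranking sidecar."""
    path = Path(path)
    selection.feature_table(strengths).to_csv(path, sep="\t", float_format="%.6f")
    selection.ranking.to_csv(
        path.with_suffix(path.suffix + ".ranking.tsv"), sep="\t", index=False
    )
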