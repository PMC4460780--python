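"""Exhaustive subset search, activity scoring, and Welch t machinery."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from brainpath.activity import (
    ConnectivitySubset,
    activity_diagnostics,
    activity_score,
    exhaustive_search,
    infer_all_pathways,
    subset_t_score,
)
from brainpath.catalog import ParcellationLabels
from brainpath.connectivity import PathwayConnectivityMatrix
from brainpath.simulate import simulate_f_matrix
from conftest import chain_instance, make_connectivity


def brute_force_search(F: PathwayConnectivityMatrix):
    """Independent full-enumeration oracle: scipy t-test on every subset."""
    groups = np.unique(F.group_labels)
    g1, g2 = F.group_labels == groups[0], F.group_labels == groups[1]
    best = (-np.inf, None)
    for k in range(1, F.n_edges + 1):
        for c in combinations(range(F.n_edges), k):
            a = F.z[:, c].mean(axis=1)
            t = stats.ttest_ind(a[g1], a[g2], equal_var=False).statistic
            if abs(t) > best[0]:
                best = (abs(t), c)
    return best[1], best[0]


def make_f(z, labels, pid="toy"):
    z = np.asarray(z, dtype=float)
    return PathwayConnectivityMatrix(
        pathway_id=pid,
        z=z,
        sample_ids=tuple(f"s{i}" for i in range(z.shape[0])),
        group_labels=np.asarray(labels),
        edge_names=tuple(f"e{j}" for j in range(z.shape[1])),
    )


class TestActivityScore:
    def test_mean_of_subset(self):
        assert activity_score(np.array([0.2, 0.4]), ConnectivitySubset((0, 1))) == pytest.approx(0.3)
        assert activity_score(np.array([0.1, -0.1]), ConnectivitySubset((0, 1))) == pytest.approx(0.0)

    def test_singleton_is_identity(self):
        assert activity_score(np.array([0.7, -0.2, 0.5]), ConnectivitySubset((2,))) == pytest.approx(0.5)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ConnectivitySubset(())


class TestSubsetTScore:
    def test_hand_computed_welch(self):
        # groups {1,2,3} vs {4,5,6}: means 2 vs 5, variances 1 -> |t| = 3/sqrt(2/3)
        t, p = subset_t_score(np.array([1, 2, 3, 4, 5, 6.0]), [0, 0, 0, 1, 1, 1])
        assert abs(t) == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-6)
        assert abs(t) == pytest.approx(3.674, abs=1e-3)

    def test_identical_groups_give_zero(self):
        t, _ = subset_t_score(np.array([1, 2, 3, 1, 2, 3.0]), [0, 0, 0, 1, 1, 1])
        assert t == pytest.approx(0.0)

    def test_label_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        act = rng.normal(size=20)
        labels = np.array([0] * 10 + [1] * 10)
        t1, p1 = subset_t_score(act, labels)
        t2, p2 = subset_t_score(act, 1 - labels)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    @pytest.mark.parametrize(
        "activity, labels",
        [
            ([1.0, 2.0, 3.0], [0, 1, 1]),  # group with < 2 samples
            ([1.0, 1.0, 2.0, 2.0], [0, 0, 1, 1]),  # zero variance in both groups
        ],
    )
    def test_degenerate_groups_rejected(self, activity, labels):
        with pytest.raises(ValueError):
            subset_t_score(np.array(activity), labels)


class TestExhaustiveSearch:
    def test_counts_all_nonempty_subsets(self):
        F = simulate_f_matrix((5, 5), 2, seed=0)
        assert exhaustive_search(F).n_subsets_evaluated == 3
        F = simulate_f_matrix((5, 5), 6, seed=0)
        assert exhaustive_search(F).n_subsets_evaluated == 63

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_edges = int(rng.integers(2, 9))
        F = simulate_f_matrix(
            (20, 20), n_edges, planted=[0], delta=1.5, seed=seed + 1000
        )
        res = exhaustive_search(F)
        oracle_subset, oracle_t = brute_force_search(F)
        assert res.selected.edge_indices == oracle_subset
        assert abs(res.t_score) == pytest.approx(oracle_t, rel=1e-9)

    def test_winner_beats_singletons_and_full_set(self):
        F = simulate_f_matrix((15, 15), 5, planted=[1, 3], delta=0.8, seed=42)
        res = exhaustive_search(F)
        g1 = F.group_labels == 0
        for c in [(i,) for i in range(5)] + [tuple(range(5))]:
            a = F.z[:, c].mean(axis=1)
            t = stats.ttest_ind(a[g1], a[~g1], equal_var=False).statistic
            assert abs(res.t_score) >= abs(t) - 1e-12

    def test_tied_singletons_resolve_to_lower_index(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=12)
        col[6:] += 2.0
        z = np.column_stack([col, col])  # duplicated edge -> exact |t| tie
        F = make_f(z, [0] * 6 + [1] * 6)
        res = exhaustive_search(F)
        assert res.selected.edge_indices == (0,)

    def test_appending_edge_never_decreases_winning_t(self):
        rng = np.random.default_rng(11)
        for seed in range(8):
            F = simulate_f_matrix((12, 12), 4, planted=[2], delta=1.0, seed=seed)
            extra = rng.normal(size=(24, 1))
            F_wide = make_f(np.hstack([F.z, extra]), F.group_labels)
            t_small = abs(exhaustive_search(F).t_score)
            t_wide = abs(exhaustive_search(F_wide).t_score)
            assert t_wide >= t_small - 1e-12

    def test_edge_count_cap_enforced(self):
        F = simulate_f_matrix((5, 5), 6, seed=0)
        with pytest.raises(ValueError, match="cap"):
            exhaustive_search(F, cap=5)

    def test_winning_t_invariant_under_group_relabeling(self):
        F = simulate_f_matrix((14, 18), 5, planted=[0], delta=0.7, seed=5)
        res1 = exhaustive_search(F)
        F_swapped = make_f(F.z, 1 - F.group_labels)
        res2 = exhaustive_search(F_swapped)
        assert res1.selected == res2.selected
        assert abs(res1.t_score) == pytest.approx(abs(res2.t_score), rel=1e-12)


class TestDiagnostics:
    def test_normal_samples_pass_ks(self):
        rng = np.random.default_rng(123)
        act = rng.normal(size=400)
        d = activity_diagnostics(act, [0] * 200 + [1] * 200)
        assert d["ks_p_group1"] > 0.05
        assert d["ks_p_group2"] > 0.05

    def test_heavy_tails_fail_ks(self):
        rng = np.random.default_rng(124)
        act = rng.standard_cauchy(size=400)
        d = activity_diagnostics(act, [0] * 200 + [1] * 200)
        assert min(d["ks_p_group1"], d["ks_p_group2"]) < 0.05

    def test_identical_groups_levene_boundary(self):
        act = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        d = activity_diagnostics(act, [0, 0, 0, 1, 1, 1])
        assert d["levene_p"] == pytest.approx(1.0)


class TestInferAllPathways:
    def _toy_cohort(self, n_subjects=12, n_regions=5, seed=0):
        labels = ParcellationLabels(tuple(f"R{i:03d}" for i in range(n_regions)))
        rng = np.random.default_rng(seed)
        cohort = []
        for i in range(n_subjects):
            r = rng.uniform(-0.7, 0.7, size=(n_regions, n_regions))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            cohort.append(make_connectivity(r, labels, subject_id=f"s{i}"))
        return cohort, np.array([0] * (n_subjects // 2) + [1] * (n_subjects // 2))

    def test_single_instance_single_column(self):
        cohort, groups = self._toy_cohort()
        inst = chain_instance(["R000", "R001", "R002"], pid="p1")
        features = infer_all_pathways(cohort, [inst], groups)
        assert features.table.shape == (12, 1)
        assert np.allclose(
            features.table["p1"].to_numpy(), features.results["p1"].activity
        )

    def test_columns_ordered_by_ascending_p(self):
        cohort, groups = self._toy_cohort(seed=3)
        instances = [
            chain_instance(["R000", "R001"], pid="a"),
            chain_instance(["R002", "R003", "R004"], pid="b"),
            chain_instance(["R001", "R003"], pid="c"),
        ]
        features = infer_all_pathways(cohort, instances, groups)
        ps = [features.results[pid].p_value for pid in features.table.columns]
        assert ps == sorted(ps)

    def test_errors_carry_pathway_id(self):
        cohort, groups = self._toy_cohort()
        bad = chain_instance(["R000", "MISSING"], pid="broken")
        with pytest.raises(RuntimeError, match="broken"):
            infer_all_pathways(cohort, [bad], groups)


def test_null_permutation_p_values_are_calibrated():
    """Under exchangeable labels the search's max-|t| has uniform permutation p.

    The selection-inflated null is quantified by a label-permutation oracle:
    each replicate's observed max-|t| is ranked within its own permutation
    distribution, and the resulting p-values must be approximately uniform.
    """
    rng = np.random.default_rng(2024)
    n1 = n2 = 15
    n_perm, n_rep = 199, 60
    pvals = []
    for rep in range(n_rep):
        F = simulate_f_matrix((n1, n2), 4, delta=0.0, seed=int(rng.integers(2**31)))
        obs = abs(exhaustive_search(F).t_score)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(F.group_labels)
            stat = abs(exhaustive_search(make_f(F.z, perm)).t_score)
            if stat >= obs:
                exceed += 1
        pvals.append((1 + exceed) / (1 + n_perm))
    pvals = np.array(pvals)
    # mean of Uniform(0,1) over 60 draws: 0.5 +/- 3 * 0.289/sqrt(60) ~ 0.11
    assert abs(pvals.mean() - 0.5) < 0.12
    assert (pvals < 0.05).mean() < 0.20
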