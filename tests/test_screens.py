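from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from igaseq import (
    Cohort,
    CountTable,
    SimulationConfig,
    TaxonomyTable,
    bh_fdr,
    differential_abundance,
    differential_targeting,
    group_mean_relabund_screen,
    permutation_group_test,
    simulate_cohort,
    simulate_feature_table,
    volcano_screen,
)
from igaseq import scenarios
from igaseq.errors import InsufficientDataError, ParameterError, \
    SelectionError
from tests.conftest import make_metadata


def perm_test_oracle(values, labels):
    """Brute-force exhaustive two-group |mean difference| p-value."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    idx_b = [i for i, l in enumerate(labels) if l == uniq[1]]
    n, k = len(labels), len(idx_b)
    obs = abs(values[idx_b].mean()
              - values[[i for i in range(n) if i not in idx_b]].mean())
    count = total = 0
    for combo in combinations(range(n), k):
        rest = [i for i in range(n) if i not in combo]
        stat = abs(values[list(combo)].mean() - values[rest].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def bh_oracle(p):
    """Direct step-up: q_(i) = min_{j>=i} p_(j) * m / j, clipped to 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestPermutationTest:
    def test_separated_pairs_exhaustive(self):
        # (10, 11) vs (0, 1): only the true split and its mirror reach
        # |mean difference| = 10, so p = 2/6
        values = np.array([10.0, 11.0, 0.0, 1.0])
        labels = np.array(["a", "a", "b", "b"])
        p = permutation_group_test(values, labels)
        assert p == pytest.approx(2 / 6)
        assert p == pytest.approx(perm_test_oracle(values, labels))

    def test_identical_groups_p_one(self):
        values = np.array([3.0, 3.0, 3.0, 3.0])
        labels = np.array(["a", "a", "b", "b"])
        assert permutation_group_test(values, labels) == pytest.approx(1.0)

    def test_sampled_mode_is_seeded(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=24)
        labels = np.array(["a"] * 12 + ["b"] * 12)
        p1 = permutation_group_test(values, labels, n_perm=199, seed=5,
                                    exhaustive_if_feasible=False)
        p2 = permutation_group_test(values, labels, n_perm=199, seed=5,
                                    exhaustive_if_feasible=False)
        assert p1 == p2
        # sampled p uses the +1/(B+1) convention: never exactly zero
        assert p1 >= 1 / 200

    def test_group_below_two_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            permutation_group_test(np.arange(4.0),
                                   np.array(["a", "b", "b", "b"]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=10),
           st.integers(0, 10_000))
    def test_exhaustive_matches_brute_force_oracle(self, values, seed):
        values = np.asarray(values)
        rng = np.random.default_rng(seed)
        n = len(values)
        n_b = int(rng.integers(2, n - 1))
        labels = np.array(["a"] * (n - n_b) + ["b"] * n_b)
        rng.shuffle(labels)
        if min(n_b, n - n_b) < 2:
            return
        p = permutation_group_test(values, labels)
        assert p == pytest.approx(perm_test_oracle(values, labels))

    def test_label_swap_leaves_p_unchanged_exhaustive(self, rng):
        values = rng.normal(size=(5, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        swapped = np.where(labels == "a", "b", "a")
        p1 = permutation_group_test(values, labels)
        p2 = permutation_group_test(values, swapped)
        np.testing.assert_allclose(p1, p2)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_case(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_tied_p_values_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_step_up_property(self, p):
        q = bh_fdr(p)
        p, q = np.asarray(p), np.asarray(q)
        assert (q <= 1 + 1e-15).all() and (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDifferentialAbundance:
    def test_planted_enrichment_has_positive_log2fc(self):
        cfg = SimulationConfig(
            n_taxa=30, seed=2, mean_depth=20000,
            effect_taxa={0: 1.0}, subject_concentration=1e6,
            group_sizes={2.5: {"control": 8, "celiac": 8}})
        cohort, truth = simulate_cohort(cfg)
        res = differential_abundance(cohort, "presort", 2.5, seed=0)
        assert res.table["log2fc"].iloc[0] > 0

    def test_significance_is_conjunctive(self, small_cohort):
        cohort, _ = small_cohort
        res = differential_abundance(cohort, "presort", 2.5, seed=0)
        t = res.table
        assert (t.loc[t["significant"], "q"] < res.q_max).all()
        assert (t.loc[t["significant"], "p"] < res.p_max).all()

    def test_missing_fraction_is_selection_error(self):
        counts = CountTable(pd.DataFrame(
            {"A_presort": [5, 5], "B_presort": [5, 5]},
            index=["t1", "t2"]))
        cohort = Cohort(counts, make_metadata(
            [("A", "control"), ("B", "celiac")], sorted_pairs=False))
        with pytest.raises(SelectionError):
            differential_abundance(cohort, "igapos", 2.5)

    def test_label_swap_negates_log2fc(self, small_cohort):
        cohort, _ = small_cohort
        res = differential_abundance(cohort, "presort", 2.5, seed=0)
        flipped_meta = cohort.metadata.table.copy()
        flipped_meta["group"] = flipped_meta["group"].map(
            {"control": "celiac", "celiac": "control"})
        from igaseq import SampleMetadata
        flipped = Cohort(cohort.counts, SampleMetadata(flipped_meta))
        res2 = differential_abundance(flipped, "presort", 2.5, seed=0)
        np.testing.assert_allclose(res2.table["log2fc"],
                                   -res.table["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res2.table["p"], res.table["p"])


class TestDifferentialTargeting:
    def test_presort_effect_without_coating_effect_not_called(self):
        # a strong presort difference with group-identical coating must
        # not be called differentially targeted
        theta = np.full(30, 0.2)
        cfg = SimulationConfig(
            n_taxa=30, seed=4, mean_depth=30471,
            effect_taxa={0: 3.0},
            coating_prob={"control": theta, "celiac": theta},
            group_sizes={2.5: {"control": 10, "celiac": 10}})
        cohort, truth = simulate_cohort(cfg)
        call = differential_targeting(cohort, 2.5, seed=0)
        taxon = truth.base_composition.index[0]
        assert not call.table.loc[taxon, "differentially_targeted"]

    def test_planted_coating_effect_is_called(self):
        cohort, truth, planted = scenarios.targeting_recovery(seed=0)
        call = differential_targeting(cohort, 2.5, seed=0)
        called = call.table.loc[planted, "differentially_targeted"]
        assert called.sum() >= len(planted) - 1

    def test_composite_implies_both_flags(self):
        cohort, _, _ = scenarios.targeting_recovery(seed=1)
        call = differential_targeting(cohort, 2.5, seed=1)
        t = call.table
        assert (t["differentially_targeted"]
                <= (t["presort_comparable"] & t["coating_differential"])).all()

    def test_ici_route_also_calls_planted_taxa(self):
        cohort, truth, planted = scenarios.targeting_recovery(seed=2)
        call = differential_targeting(cohort, 2.5, coating_on="ici", seed=2)
        called = call.table.loc[planted, "differentially_targeted"]
        assert called.sum() >= len(planted) - 1


class TestVolcanoScreen:
    def _screen(self, log2fc, p_target_low=True, seed=0):
        features, groups, _ = simulate_feature_table(
            5, n_per_group=(9, 7), effect_features={0: log2fc},
            noise_sd=0.2, seed=seed)
        return volcano_screen(features, groups)

    def test_strong_fold_change_and_p_is_significant(self):
        res = self._screen(1.5)
        row = res.table.iloc[0]
        assert abs(row["log2fc"]) > 1.2 and row["p"] < 0.05
        assert row["volcano_significant"] and row["volcano_class"] == "up"

    def test_fc_gate_blocks_small_fold_changes(self):
        features, groups, _ = simulate_feature_table(3, seed=1)
        res = volcano_screen(features, groups)
        t = res.table
        blocked = t[np.abs(t["log2fc"]) <= 1.2]
        assert not blocked["volcano_significant"].any()

    def test_constant_feature_flagged_with_p_one(self):
        from igaseq import FeatureTable
        values = pd.DataFrame(
            [[2.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["flat", "varies"],
            columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["control"] * 3 + ["celiac"] * 3,
                           index=values.columns)
        res = volcano_screen(FeatureTable(values), groups)
        assert res.table.loc["flat", "p"] == 1.0
        assert bool(res.table.loc["flat", "constant_flag"])

    def test_planted_fold_change_recovered(self):
        # one true effect at FC = 1.92, 9 vs 7 samples: the mean estimate
        # across seeds stays within the simulation CI of 1.92
        fcs = []
        for seed in range(100):
            features, groups, _ = simulate_feature_table(
                20, n_per_group=(9, 7),
                effect_features={0: np.log2(1.92)}, noise_sd=0.3, seed=seed)
            res = volcano_screen(features, groups)
            fcs.append(2 ** res.table["log2fc"].iloc[0])
        mean, se = np.mean(fcs), np.std(fcs, ddof=1) / 10.0
        assert abs(mean - 1.92) < 4 * se + 0.05


class TestRankLevelScreen:
    def _rank_cohort(self):
        # genus A ~4%, genus B ~0.9%, genus C the remainder
        rng = np.random.default_rng(10)
        p = np.array([0.04, 0.009, 0.951])
        cols = {}
        subjects = []
        for i in range(4):
            for grp, tag in (("control", "c"), ("celiac", "d")):
                subj = f"{tag}{i}"
                subjects.append((subj, grp))
                cols[f"{subj}_presort"] = rng.multinomial(20000, p)
        counts = CountTable(pd.DataFrame(
            cols, index=["asvA", "asvB", "asvC"]))
        meta = make_metadata(subjects, sorted_pairs=False)
        tax = TaxonomyTable(pd.DataFrame(
            {"genus": ["A", "B", "C"]}, index=["asvA", "asvB", "asvC"]))
        return Cohort(counts, meta), tax

    def test_sub_percent_taxa_excluded(self):
        cohort, tax = self._rank_cohort()
        res = group_mean_relabund_screen(cohort, tax, "genus", age=2.5)
        assert "B" not in res.table.index
        assert {"A", "C"} <= set(res.table.index)

    def test_exactly_one_percent_excluded(self):
        # strict > filter: a taxon at exactly the threshold is dropped
        counts = CountTable(pd.DataFrame(
            {f"{s}_presort": [10, 990] for s in "abcd"},
            index=["asvA", "asvB"]))
        meta = make_metadata([("a", "control"), ("b", "control"),
                              ("c", "celiac"), ("d", "celiac")],
                             sorted_pairs=False)
        tax = TaxonomyTable(pd.DataFrame({"genus": ["A", "B"]},
                                         index=["asvA", "asvB"]))
        res = group_mean_relabund_screen(Cohort(counts, meta), tax, "genus",
                                         age=2.5)
        assert "A" not in res.table.index

    def test_no_taxa_passing_gives_empty_notice(self):
        counts = CountTable(pd.DataFrame(
            {f"{s}_presort": [50, 50] for s in "abcd"},
            index=["asvA", "asvB"]))
        meta = make_metadata([("a", "control"), ("b", "control"),
                              ("c", "celiac"), ("d", "celiac")],
                             sorted_pairs=False)
        tax = TaxonomyTable(pd.DataFrame({"genus": ["A", "B"]},
                                         index=["asvA", "asvB"]))
        res = group_mean_relabund_screen(Cohort(counts, meta), tax, "genus",
                                         age=2.5, min_mean_abundance=0.99)
        assert res.table.empty
        assert "notice" in res.notes
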