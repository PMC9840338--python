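import numpy as np
import pandas as pd
import pytest

from igaseq import (
    Cohort,
    CountTable,
    SimulationConfig,
    expected_sorted_compositions,
    group_ici,
    high_coaters,
    ici_per_taxon,
    normalize_rows,
    relative_abundance,
    retention_filter,
    simulate_cohort,
)
from igaseq.errors import DegenerateSampleError, ParameterError
from tests.conftest import make_metadata


def closed_form_ici(p, theta):
    """Independent oracle: ICI_t = [th/(1-th)] * [sum p(1-th) / sum p th]."""
    p, theta = np.asarray(p, float), np.asarray(theta, float)
    return (theta / (1 - theta)) * (np.dot(p, 1 - theta) / np.dot(p, theta))


class TestRelativeAbundance:
    def test_direct_normalization(self):
        table = CountTable(pd.DataFrame({"S": [10, 30, 60]},
                                        index=["a", "b", "c"]))
        rel = relative_abundance(table, pseudocount=0)
        np.testing.assert_allclose(rel.proportions["S"], [0.1, 0.3, 0.6])

    def test_pseudocount_arithmetic(self):
        table = CountTable(pd.DataFrame({"S": [0, 9]}, index=["a", "b"]))
        rel = relative_abundance(table, pseudocount=1)
        np.testing.assert_allclose(rel.proportions["S"], [1 / 11, 10 / 11])

    def test_all_zero_sample_rejected_without_pseudocount(self):
        table = CountTable(pd.DataFrame({"S": [0, 0]}, index=["a", "b"]))
        with pytest.raises(DegenerateSampleError):
            relative_abundance(table, pseudocount=0)


class TestIciPerTaxon:
    def test_equal_abundance_gives_unity(self):
        ici = ici_per_taxon([0.3, 0.7], [0.3, 0.7])
        np.testing.assert_allclose(ici, 1.0)

    def test_simple_ratio(self):
        assert ici_per_taxon([0.2], [0.1]).iloc[0] == pytest.approx(2.0)

    def test_matches_closed_form_on_expected_compositions(self):
        p, theta = np.array([0.5, 0.5]), np.array([0.8, 0.2])
        q_pos, q_neg = expected_sorted_compositions(p, theta, 0.0)
        ici = ici_per_taxon(q_pos, q_neg)
        np.testing.assert_allclose(ici, [4.0, 0.25], atol=1e-12)
        np.testing.assert_allclose(ici, closed_form_ici(p, theta), atol=1e-12)

    def test_zero_denominator_directs_to_pseudocount(self):
        with pytest.raises(ParameterError, match="pseudocount"):
            ici_per_taxon([0.5, 0.5], [0.0, 1.0])


def _cohort_from_compositions(comps):
    """Build a cohort whose counts exactly encode given compositions.

    comps: {subject: {fraction: integer count vector}} (single group).
    """
    cols, subjects = {}, []
    for subj, fracs in comps.items():
        subjects.append((subj, "control"))
        for frac, vec in fracs.items():
            cols[f"{subj}_{frac}"] = vec
    taxa = [f"t{i}" for i in range(len(next(iter(comps.values()))["presort"]))]
    counts = CountTable(pd.DataFrame(cols, index=taxa))
    return Cohort(counts, make_metadata(subjects))


class TestGroupIci:
    def test_single_subject_reduces_to_per_taxon_ici(self):
        cohort = _cohort_from_compositions({
            "A": {"presort": [50, 50], "igapos": [80, 20],
                  "iganeg": [20, 80]}})
        for agg in ("mean", "median"):
            gi = group_ici(cohort, "control", 2.5, aggregation=agg,
                           pseudocount=0)
            np.testing.assert_allclose(gi, [4.0, 0.25])

    def test_identical_subjects_equal_single_subject(self):
        fracs = {"presort": [50, 50], "igapos": [80, 20], "iganeg": [20, 80]}
        cohort = _cohort_from_compositions({"A": fracs, "B": fracs})
        gi = group_ici(cohort, "control", 2.5, pseudocount=0)
        np.testing.assert_allclose(gi, [4.0, 0.25])

    def test_strongly_coated_taxon_exceeds_high_coater_bar(self):
        # theta 0.9 against a 0.1 background: group ICI > 10 in >= 95% of
        # seeded cohorts at study depth
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            theta = np.full(40, 0.1)
            theta[0] = 0.9
            cfg = SimulationConfig(
                n_taxa=40, seed=seed, mean_depth=30471,
                coating_prob={"control": theta, "celiac": theta},
                group_sizes={2.5: {"control": 16, "celiac": 15}})
            cohort, _ = simulate_cohort(cfg)
            gi = group_ici(cohort, "control", 2.5)
            hits += gi.iloc[0] > 10
        assert hits >= int(0.95 * n_rep)


class TestRetentionRule:
    def test_all_branches_of_the_rule(self):
        # both<1 (drop), both>1 (keep), both discordant directions (keep),
        # boundary cases at exactly 1
        ici_c = pd.Series([0.5, 2.0, 0.5, 2.0, 1.0, 1.0, 0.3, 15.0],
                          index=list("abcdefgh"))
        ici_e = pd.Series([0.8, 3.0, 2.0, 0.5, 1.0, 0.5, 1.0, 0.2],
                          index=list("abcdefgh"))
        retained, discordant = retention_filter(ici_c, ici_e)
        assert set(retained.index[retained]) == {"b", "c", "d", "e", "h"}
        assert set(discordant.index[discordant]) == {"c", "d", "h"}

    def test_boundary_one_is_not_lower_than_one(self):
        retained, _ = retention_filter(pd.Series([1.0]), pd.Series([1.0]))
        assert bool(retained.iloc[0])


class TestNormalizeRows:
    def test_two_point_z_score(self):
        z = normalize_rows(pd.DataFrame([[2.0, 8.0]]))
        np.testing.assert_allclose(z.to_numpy()[0],
                                   [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_row_maps_to_zeros(self):
        z = normalize_rows(pd.DataFrame([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(z.to_numpy(), 0.0)

    def test_rows_standardized(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 6)))
        z = normalize_rows(mat)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestHighCoaters:
    def test_strict_threshold(self):
        table = pd.DataFrame({"ici_control": [12.0, 10.0],
                              "ici_celiac": [1.0, 30.0]},
                             index=["a", "b"])
        sets = high_coaters(table)
        assert sets["control"] == {"a"}
        assert sets["celiac"] == {"b"}

    def test_empty_table_gives_empty_sets(self):
        table = pd.DataFrame(columns=["ici_control", "ici_celiac"])
        sets = high_coaters(table)
        assert sets == {"control": set(), "celiac": set()}

    def test_closed_form_enumeration_recovered_at_high_depth(self):
        # the taxa whose closed-form ICI exceeds 10 at infinite depth are
        # exactly the taxa flagged at depth 1e6
        rng = np.random.default_rng(77)
        theta = rng.uniform(0.02, 0.98, 30)
        cfg = SimulationConfig(
            n_taxa=30, seed=123, mean_depth=1e6, impurity=0.0,
            coating_prob={"control": theta, "celiac": theta},
            coating_kappa=1e7, subject_concentration=1e7,
            group_sizes={2.5: {"control": 16, "celiac": 15}})
        cohort, truth = simulate_cohort(cfg)
        base = truth.base_composition["control"].to_numpy()
        expected_hits = set(
            truth.base_composition.index[closed_form_ici(base, theta) > 10])
        gi = group_ici(cohort, "control", 2.5)
        assert 0 < len(expected_hits) < 30
        assert set(gi.index[gi > 10]) == expected_hits


class TestIciInvariants:
    def test_scale_invariance_exact_without_pseudocount(self):
        cohort = _cohort_from_compositions({
            "A": {"presort": [50, 50, 10], "igapos": [80, 20, 5],
                  "iganeg": [20, 80, 30]}})
        scaled = cohort.counts.counts.copy()
        scaled["A_igapos"] *= 7
        cohort2 = Cohort(CountTable(scaled), cohort.metadata)
        gi1 = group_ici(cohort, "control", 2.5, pseudocount=0)
        gi2 = group_ici(cohort2, "control", 2.5, pseudocount=0)
        np.testing.assert_array_equal(gi1.to_numpy(), gi2.to_numpy())

    def test_scale_invariance_approximate_with_pseudocount(self, rng):
        # with pseudocount 1 the per-taxon bias under integer scaling is
        # bounded by ~(1/p_t - S)/N, so for a balanced community at depth
        # 1e5 the ICI moves by well under 1e-3
        p = rng.dirichlet(np.full(20, 100.0))  # balanced: p in ~[0.03, 0.08]
        deep = rng.multinomial(100_000, p, size=3)
        cols = {"A_presort": deep[0], "A_igapos": deep[1],
                "A_iganeg": deep[2]}
        counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(20)])
        cohort = Cohort(CountTable(counts), make_metadata([("A", "control")]))
        scaled = counts.copy()
        scaled["A_igapos"] *= 3
        cohort2 = Cohort(CountTable(scaled), cohort.metadata)
        gi1 = group_ici(cohort, "control", 2.5, pseudocount=1)
        gi2 = group_ici(cohort2, "control", 2.5, pseudocount=1)
        np.testing.assert_allclose(gi1, gi2, rtol=1e-3)

    def test_ici_strictly_increases_with_theta(self):
        # holding the community fixed, a larger coating probability gives
        # a larger expected ICI
        p = np.array([0.2, 0.3, 0.5])
        icis = []
        for th0 in [0.05, 0.2, 0.5, 0.8, 0.95]:
            theta = np.array([th0, 0.3, 0.4])
            q_pos, q_neg = expected_sorted_compositions(p, theta, 0.0)
            icis.append(ici_per_taxon(q_pos, q_neg).iloc[0])
        assert all(a < b for a, b in zip(icis, icis[1:]))
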