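"""Genotype completeness filter, allele-sharing distance, clustering, ID rules."""

import numpy as np
import pandas as pd
import pytest

import orcadiet as od
from orcadiet.errors import EmptyResultError, UndefinedDistanceError
from orcadiet.genotype_id import match_reference

from conftest import identity_accuracy


def matrix_of(rows: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"locus_{j}" for j in range(n)]).T.astype(np.int8)


class TestFilter:
    def test_85_percent_boundary_on_68_loci(self):
        calls_58 = [0] * 58 + [-1] * 10   # 58/68 = 85.3% -> retained
        calls_57 = [0] * 57 + [-1] * 11   # 57/68 = 83.8% -> dropped
        m = matrix_of({"pass": calls_58, "fail": calls_57})
        out = od.filter_genotypes(m, 0.85)
        assert list(out.index) == ["pass"]

    def test_zero_min_fraction_rejected(self):
        m = matrix_of({"s": [0, 1]})
        with pytest.raises(ValueError):
            od.filter_genotypes(m, 0.0)

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(20, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.3] = -1
        m = pd.DataFrame(calls, index=[f"s{i:02d}" for i in range(20)])
        kept_strict = set(od.filter_genotypes(m, 0.8).index)
        kept_loose = set(od.filter_genotypes(m, 0.6).index)
        assert kept_strict <= kept_loose

    def test_empty_result_error(self):
        m = matrix_of({"s": [-1, -1, 0, -1]})
        with pytest.raises(EmptyResultError):
            od.filter_genotypes(m, 0.9)


class TestDistance:
    def test_identical_is_zero(self):
        a = np.array([0, 1, 2, 1])
        assert od.genotype_distance(a, a) == 0.0

    def test_opposite_homozygotes_is_one(self):
        a = np.zeros(10, dtype=int)
        b = np.full(10, 2)
        assert od.genotype_distance(a, b) == 1.0

    def test_one_het_mismatch_over_ten_loci(self):
        # AA vs AB at one locus, identical elsewhere: 1 - 19/20 = 0.05
        a = np.array([0] + [1] * 9)
        b = np.array([1] + [1] * 9)
        assert od.genotype_distance(a, b) == pytest.approx(0.05)

    def test_missing_loci_ignored(self):
        a = np.array([0, -1, 2])
        b = np.array([0, 2, -1])
        assert od.genotype_distance(a, b) == 0.0

    def test_no_overlap_raises(self):
        with pytest.raises(UndefinedDistanceError):
            od.genotype_distance(np.array([-1, 0]), np.array([1, -1]))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        assert od.genotype_distance(a, b) == od.genotype_distance(b, a)


class TestCluster:
    def test_zero_noise_recovers_individuals_exactly(self):
        cfg = od.SimConfig(
            genotype=od.GenotypeConfig(missing_rate=0.0, error_rate=0.0), seed=5
        )
        matrix, _, truth = od.sim_genotypes(cfg)
        clusters = od.cluster_genotypes(matrix, 0.05)
        # partition identity: same cluster <=> same individual
        df = pd.DataFrame({"cluster": clusters, "truth": truth})
        assert (df.groupby("cluster")["truth"].nunique() == 1).all()
        assert (df.groupby("truth")["cluster"].nunique() == 1).all()

    def test_two_distant_samples_stay_separate(self):
        # distance 0.2 > cut 0.05 -> two singleton clusters
        m = matrix_of({"s1": [0] * 10, "s2": [0] * 6 + [2] * 4})
        assert od.genotype_distance(m.loc["s1"], m.loc["s2"]) == pytest.approx(0.4)
        clusters = od.cluster_genotypes(m, 0.05)
        assert clusters.nunique() == 2

    def test_noisy_recovery_matches_truth(self):
        cfg = od.SimConfig(
            genotype=od.GenotypeConfig(
                n_individuals=20, missing_rate=0.10, error_rate=0.01,
                samples_per_individual=5,
            ),
            seed=42,
        )
        matrix, _, truth = od.sim_genotypes(cfg)
        retained = od.filter_genotypes(matrix, 0.85)
        clusters = od.cluster_genotypes(retained, 0.05)
        df = pd.DataFrame({"cluster": clusters, "truth": truth.loc[retained.index]})
        # adjusted agreement: fraction of samples in cluster-majority classes
        agree = (
            df.groupby("cluster")["truth"]
            .apply(lambda s: (s == s.value_counts().idxmax()).sum())
            .sum()
        )
        assert agree / len(df) >= 0.95


class TestAssign:
    @pytest.fixture
    def reference_db(self):
        return matrix_of({"REF_A": [0, 1, 2, 1, 0], "REF_B": [2, 2, 2, 2, 2]})

    def test_single_known_sample_rule_one(self, reference_db):
        m = matrix_of({"s1": [0, 1, 2, 1, 0]})
        clusters = pd.Series({"s1": 1})
        asg = od.assign_identity(clusters, m, reference_db)
        row = asg.table.loc["s1"]
        assert row["individual"] == "REF_A"
        assert row["rule"] == 1
        assert row["representative"] == "s1"

    def test_known_with_highest_fraction_wins(self, reference_db):
        # both match REF_A; fractions 0.95-like vs 0.90-like (one missing call)
        m = matrix_of({"s_full": [0, 1, 2, 1, 0], "s_miss": [0, 1, 2, 1, -1]})
        clusters = pd.Series({"s_full": 1, "s_miss": 1})
        asg = od.assign_identity(clusters, m, reference_db)
        assert (asg.table["representative"] == "s_full").all()
        assert asg.table.loc["s_full", "rule"] == 2

    def test_tie_among_known_goes_to_first_id(self, reference_db):
        m = matrix_of({"s_b": [0, 1, 2, 1, 0], "s_a": [0, 1, 2, 1, 0]})
        clusters = pd.Series({"s_b": 1, "s_a": 1})
        asg = od.assign_identity(clusters, m, reference_db)
        assert (asg.table["representative"] == "s_a").all()
        assert asg.table.loc["s_a", "rule"] == 3

    def test_no_known_equal_fractions_first_id(self):
        m = matrix_of({"s_z": [0, 0, 0, 0, 0], "s_a": [0, 0, 0, 0, 1]})
        clusters = pd.Series({"s_z": 1, "s_a": 1})
        asg = od.assign_identity(clusters, m, reference_db=None)
        assert (asg.table["representative"] == "s_a").all()
        assert asg.table.loc["s_a", "rule"] == 5
        assert asg.table["individual"].str.startswith("UNK_").all()

    def test_no_known_highest_fraction_rule_four(self):
        m = matrix_of({"s_z": [0, 0, 0, 0, 0], "s_a": [0, 0, 0, 0, -1]})
        clusters = pd.Series({"s_z": 1, "s_a": 1})
        asg = od.assign_identity(clusters, m, reference_db=None)
        assert (asg.table["representative"] == "s_z").all()
        assert asg.table.loc["s_z", "rule"] == 4

    def test_decision_tree_order_invariant(self, reference_db):
        m = matrix_of(
            {
                "s3": [0, 1, 2, 1, 0],
                "s1": [0, 1, 2, 1, -1],
                "s2": [2, 2, 2, 2, 2],
            }
        )
        clusters = pd.Series({"s3": 1, "s1": 1, "s2": 2})
        asg1 = od.assign_identity(clusters, m, reference_db)
        shuffled = clusters.loc[["s2", "s3", "s1"]]
        asg2 = od.assign_identity(shuffled, m.loc[["s2", "s3", "s1"]], reference_db)
        merged = asg1.table.join(asg2.table, rsuffix="_2")
        assert (merged["individual"] == merged["individual_2"]).all()
        assert (merged["representative"] == merged["representative_2"]).all()

    def test_mismatch_threshold(self, reference_db):
        near = pd.Series([0, 1, 2, 1, 2], index=reference_db.columns)  # 1 mismatch
        far = pd.Series([0, 1, 0, 0, 2], index=reference_db.columns)   # 3 mismatches
        assert match_reference(near, reference_db, 2) == "REF_A"
        assert match_reference(far, reference_db, 2) is None

    def test_end_to_end_identity_accuracy(self):
        cfg = od.SimConfig(
            genotype=od.GenotypeConfig(
                n_individuals=20, missing_rate=0.10, error_rate=0.01,
                samples_per_individual=5, known_fraction=0.8,
            ),
            seed=42,
        )
        matrix, reference_db, truth = od.sim_genotypes(cfg)
        retained = od.filter_genotypes(matrix, 0.85)
        clusters = od.cluster_genotypes(retained, 0.05)
        asg = od.assign_identity(clusters, retained, reference_db)
        known = truth.loc[retained.index].isin(reference_db.index)
        exact = (
            asg.table.loc[known.values, "individual"]
            == truth.loc[retained.index][known.values]
        ).mean()
        assert exact >= 0.95
        assert identity_accuracy(asg.table["individual"], truth) >= 0.95
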