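import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliscope.evaluate import (
    AbundanceProfile,
    ConfusionCounts,
    chao1,
    chao1_error_percent,
    confusion_at_rank,
    diversity_indices,
    drop_singleton_taxa,
    evaluate_pipeline,
    f_measure,
    merge_otus,
    partition_agreement,
    partition_labels,
    profile_from_assignments,
)
from ampliscope.exceptions import DataError, InputError
from ampliscope.taxonomy import normalize_assignments

from conftest import (
    all_unclassified,
    mutual_info_oracle,
    nmi_oracle,
    oracle_assignment,
    partition_to_labels,
    set_partitions,
)


def make_truth(taxids):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(taxids))],
            "genome_id": "g",
            "taxid": taxids,
            "start": 0, "end": 10, "strand": "+",
            "n_del": 0, "n_ins": 0, "n_sub": 0,
        }
    )


def make_pred(read_ids, statuses, taxids):
    return pd.DataFrame({"read_id": read_ids, "status": statuses, "taxid": taxids})


class TestConfusion:
    def test_perfect_pipeline(self, toy_tree):
        truth = make_truth([40] * 10)
        pred = oracle_assignment(truth)
        cc = confusion_at_rank(truth, pred, toy_tree, "family")
        assert (cc.tp, cc.fp, cc.fn) == (10, 0, 0)

    def test_wrong_family_is_fp(self, toy_tree):
        truth = make_truth([40])
        pred = make_pred(["r0"], ["classified"], [41])  # SpY1a -> FamY, truth FamX
        cc = confusion_at_rank(truth, pred, toy_tree, "family")
        assert (cc.tp, cc.fp, cc.fn) == (0, 1, 0)

    def test_discarded_and_unclassified_are_fn(self, toy_tree):
        truth = make_truth([40, 40, 40])
        pred = make_pred(["r0", "r1", "r2"],
                         ["classified", "discarded", "unclassified"],
                         [40, pd.NA, pd.NA])
        cc = confusion_at_rank(truth, pred, toy_tree, "family")
        assert (cc.tp, cc.fp, cc.fn) == (1, 0, 2)

    def test_coarser_than_rank_call_is_fn(self, toy_tree):
        truth = make_truth([40])
        pred = make_pred(["r0"], ["classified"], [10])  # order-level call
        cc = confusion_at_rank(truth, pred, toy_tree, "family")
        assert (cc.tp, cc.fp, cc.fn) == (0, 0, 1)

    def test_missing_reads_injected_as_discarded(self, toy_tree):
        truth = make_truth([40, 40])
        pred = make_pred(["r0"], ["classified"], [40])
        cc = confusion_at_rank(truth, pred, toy_tree, "family")
        assert (cc.tp, cc.fn) == (1, 1)

    def test_unknown_read_id_rejected(self, toy_tree):
        truth = make_truth([40])
        pred = make_pred(["rX"], ["classified"], [40])
        with pytest.raises(InputError):
            confusion_at_rank(truth, pred, toy_tree, "family")

    def test_singleton_rule_hand_example(self, toy_tree):
        """9 reads correct to family X plus 1 single-read family Y: the
        singleton taxon is removed and its read recounted as FN."""
        truth = make_truth([40] * 9 + [41])
        pred = oracle_assignment(truth)  # all correct, FamY has one read
        cc = confusion_at_rank(truth, pred, toy_tree, "family", drop_singletons=True)
        assert (cc.tp, cc.fp, cc.fn) == (9, 0, 1)
        cc2 = confusion_at_rank(truth, pred, toy_tree, "family", drop_singletons=False)
        assert (cc2.tp, cc2.fp, cc2.fn) == (10, 0, 0)

    def test_truth_that_cannot_project_is_data_error(self, toy_tree):
        truth = make_truth([10])  # an order: no family on its root path
        with pytest.raises(DataError):
            confusion_at_rank(truth, oracle_assignment(truth), toy_tree, "family")

    @given(st.lists(st.sampled_from([40, 41, 42]), min_size=1, max_size=30),
           st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_conservation_tp_fp_fn(self, taxids, drop):
        from ampliscope.taxonomy import TaxonomyTree
        from conftest import TOY_NODES

        toy_tree = TaxonomyTree(dict(TOY_NODES))
        truth = make_truth(taxids)
        rng = np.random.default_rng(len(taxids))
        statuses = rng.choice(["classified", "unclassified", "discarded"], len(taxids))
        pred = make_pred(truth["read_id"], statuses,
                         [40 if s == "classified" else pd.NA for s in statuses])
        for rank in ("family", "genus"):
            cc = confusion_at_rank(truth, pred, toy_tree, rank, drop_singletons=drop)
            assert cc.tp + cc.fp + cc.fn == len(taxids)


class TestFMeasure:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (10, 0, 0, (1.0, 1.0, 1.0)),
            (0, 5, 5, (0.0, 0.0, 0.0)),
            (80, 20, 0, (0.8, 1.0, 2 * 0.8 / 1.8)),
        ],
    )
    def test_worked_examples(self, tp, fp, fn, expected):
        assert f_measure(ConfusionCounts(tp, fp, fn, "family")) == pytest.approx(expected)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_harmonic_identity(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        p, r, f = f_measure(ConfusionCounts(tp, fp, fn, "family"))
        assert 0 <= f <= 1
        assert f <= min(2 * p, 2 * r) + 1e-12
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
        if p == r:
            assert f == pytest.approx(p)


class TestMergeOtus:
    def test_single_taxon_merge(self, toy_tree):
        otus = pd.DataFrame({"otu_id": ["o1", "o2", "o3"], "size": [5, 3, 2],
                             "taxid": [40, 40, 40]})
        profile = merge_otus(otus, toy_tree, "family")
        assert profile.counts == {20: 10}

    def test_species_under_two_genera(self, toy_tree):
        otus = pd.DataFrame({"otu_id": ["o1", "o2", "o3"], "size": [4, 2, 1],
                             "taxid": [40, 41, 42]})
        profile = merge_otus(otus, toy_tree, "genus")
        assert profile.counts == {30: 4, 31: 3}

    def test_unclassified_pooling(self, toy_tree):
        otus = pd.DataFrame({"otu_id": ["o1", "o2"], "size": [4, 6],
                             "taxid": [pd.NA, 40]})
        profile = merge_otus(otus, toy_tree, "family")
        assert profile.counts == {"unclassified": 4, 20: 6}

    def test_richness_bounded_by_otu_count(self, toy_tree):
        otus = pd.DataFrame({"otu_id": [f"o{i}" for i in range(6)],
                             "size": [1] * 6, "taxid": [40, 41, 42, 40, 41, 43]})
        profile = merge_otus(otus, toy_tree, "family")
        assert profile.observed_richness <= 6


class TestRichnessDiversity:
    def test_chao1_no_singletons_equals_observed(self):
        assert chao1(AbundanceProfile({"A": 5, "B": 4, "C": 3})) == 3.0

    def test_chao1_bias_corrected_formula(self):
        # S=3, f1=2, f2=1 -> 3 + 2*1/(2*2) = 3.5
        assert chao1(AbundanceProfile({"A": 1, "B": 1, "C": 2})) == 3.5

    def test_chao1_single_singleton(self):
        assert chao1(AbundanceProfile({"A": 1})) == 1.0

    def test_chao1_classic_variant(self):
        # classic: S + f1^2/(2 f2) = 3 + 4/2 = 5
        assert chao1(AbundanceProfile({"A": 1, "B": 1, "C": 2}), bias_corrected=False) == 5.0

    def test_chao1_excludes_unclassified_and_floors_at_observed(self):
        profile = AbundanceProfile({"A": 1, "B": 2, "unclassified": 50})
        assert chao1(profile) >= profile.observed_richness == 2

    def test_chao1_empty_profile(self):
        with pytest.raises(InputError):
            chao1(AbundanceProfile({"unclassified": 5}))

    @pytest.mark.parametrize("est,truth,expected", [(50, 50, 0.0), (54, 50, 8.0), (45, 50, -10.0)])
    def test_chao1_error_percent(self, est, truth, expected):
        assert chao1_error_percent(est, truth) == pytest.approx(expected)

    def test_shannon_two_equal_taxa(self):
        sh, _ = diversity_indices(AbundanceProfile({"A": 50, "B": 50}))
        assert sh == pytest.approx(math.log(2))

    def test_inverse_simpson_closed_forms(self):
        _, inv = diversity_indices(AbundanceProfile({c: 10 for c in "ABCDE"}))
        assert inv == pytest.approx(5.0)
        _, inv = diversity_indices(AbundanceProfile({"A": 75, "B": 25}))
        assert inv == pytest.approx(1.6)

    def test_inverse_simpson_bounds(self):
        profile = AbundanceProfile({"A": 7, "B": 2, "C": 1})
        _, inv = diversity_indices(profile)
        assert 1.0 <= inv <= profile.observed_richness
        _, single = diversity_indices(AbundanceProfile({"A": 9}))
        assert single == pytest.approx(1.0)


class TestPartitionAgreement:
    def test_identical_partitions(self):
        assert partition_agreement("aabb", "xxyy") == (1.0, 1.0, 1.0)

    def test_orthogonal_two_by_two(self):
        # U = {a,b | c,d}, V = {a,c | b,d}: zero mutual information
        nmi, ami, nid = partition_agreement([0, 0, 1, 1], [0, 1, 0, 1])
        assert nmi == 0.0 and ami == 0.0 and nid == 0.0

    def test_degenerate_conventions(self):
        assert partition_agreement([1, 1, 1], [2, 2, 2]) == (1.0, 1.0, 1.0)
        assert partition_agreement([1, 1, 1], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            partition_agreement([1, 2], [1, 2, 3])

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = rng.integers(0, 3, 10)
            v = rng.integers(0, 3, 10)
            a = partition_agreement(u, v)
            b = partition_agreement(v, u)
            assert a[0] == pytest.approx(b[0])
            assert a[2] == pytest.approx(b[2])

    def test_nmi_matches_entropy_oracle_exhaustively_n4(self):
        """All pairs of set partitions of 4 items against an independent
        contingency/entropy computation."""
        parts = list(set_partitions(range(4)))
        for pu, pv in itertools.product(parts, parts):
            u = partition_to_labels(pu, 4)
            v = partition_to_labels(pv, 4)
            nmi, _, nid = partition_agreement(u, v)
            assert nmi == pytest.approx(nmi_oracle(u, v), abs=1e-9)
            assert nid == pytest.approx(nmi, abs=1e-12)

    def test_ami_matches_permutation_model_oracle(self):
        """AMI = (I - E[I]) / (max(H) - E[I]) where E[I] is the exact
        average of I over all relabelings (permutations) of one side."""
        cases = [([0, 0, 1, 1, 2, 2], [0, 1, 1, 0, 2, 2]),
                 ([0, 0, 0, 1, 1, 1], [0, 1, 0, 1, 0, 1]),
                 ([0, 1, 2, 0, 1, 2], [0, 0, 1, 1, 2, 2])]
        for u, v in cases:
            i_obs = mutual_info_oracle(u, v)
            perms = list(itertools.permutations(range(len(v))))
            e_i = np.mean([mutual_info_oracle(u, [v[p] for p in perm]) for perm in perms])
            h_max = max(
                -sum(p * math.log(p) for p in np.bincount(u) / len(u) if p > 0),
                -sum(p * math.log(p) for p in np.bincount(v) / len(v) if p > 0),
            )
            expected = max(0.0, (i_obs - e_i) / (h_max - e_i))
            _, ami, _ = partition_agreement(u, v)
            assert ami == pytest.approx(expected, abs=1e-6)

    def test_random_labelings_have_near_zero_ami_but_positive_nmi(self):
        """Chance correction: over random 2-cluster labelings of 6 items the
        uncorrected NMI stays well above zero while the chance-corrected
        agreement averages ~0 (before clamping)."""
        from sklearn.metrics import adjusted_mutual_info_score

        rng = np.random.default_rng(4)
        raw_amis, nmis = [], []
        for _ in range(400):
            u = rng.integers(0, 2, 6)
            v = rng.integers(0, 2, 6)
            if len(set(u)) < 2 or len(set(v)) < 2:
                continue
            nmi, ami, _ = partition_agreement(u, v)
            assert ami >= 0.0  # public API clamps
            raw_amis.append(adjusted_mutual_info_score(u, v, average_method="max"))
            nmis.append(nmi)
        assert abs(np.mean(raw_amis)) < 0.05
        assert np.mean(nmis) > 0.1


class TestEvaluatePipeline:
    def test_oracle_scores_perfectly(self, error_free_dataset, fixture_collection):
        truth = error_free_dataset.truth
        report = evaluate_pipeline(truth, oracle_assignment(truth),
                                   fixture_collection.taxonomy,
                                   dataset="d", pipeline="oracle")
        wide = report.pivot_table(index="rank", columns="metric", values="value")
        for rank in ("family", "genus"):
            assert wide.loc[rank, "f_measure"] == 1.0
            assert wide.loc[rank, "chao1_error_percent"] == 0.0
            assert wide.loc[rank, "one_minus_nid"] == 1.0

    def test_all_unclassified_has_zero_recall(self, error_free_dataset, fixture_collection):
        truth = error_free_dataset.truth
        report = evaluate_pipeline(truth, all_unclassified(truth),
                                   fixture_collection.taxonomy)
        wide = report.pivot_table(index="rank", columns="metric", values="value")
        assert (wide["recall"] == 0.0).all()
        assert (wide["precision"] == 0.0).all()

    def test_truth_copy_recovers_designed_family_count(self, error_free_dataset, fixture_collection):
        """Parameter recovery: on an error-free uniform community the merged
        oracle profile has exactly the designed number of families."""
        truth = error_free_dataset.truth
        tree = fixture_collection.taxonomy
        norm = normalize_assignments(tree, oracle_assignment(truth), "family")
        profile = profile_from_assignments(norm, "family")
        n_families = (tree.to_table()["rank"] == "family").sum()
        assert profile.observed_richness == n_families == 3

    def test_report_shape(self, error_free_dataset, fixture_collection):
        truth = error_free_dataset.truth
        report = evaluate_pipeline(truth, oracle_assignment(truth),
                                   fixture_collection.taxonomy)
        assert list(report.columns) == ["dataset", "pipeline", "rank", "metric", "value"]
        assert len(report) == 2 * 10  # ranks x metrics

    def test_unclassified_reads_penalize_partition_agreement(self, toy_tree):
        truth = make_truth([40] * 5 + [41] * 5)
        # unclassified reads drawn from BOTH families: the pooled
        # unclassified cluster cannot mirror the truth partition
        statuses = ["classified"] * 3 + ["unclassified"] * 2
        half = make_pred(truth["read_id"], statuses * 2,
                         [40] * 3 + [pd.NA] * 2 + [41] * 3 + [pd.NA] * 2)
        norm = normalize_assignments(toy_tree, half, "family")
        u, v = partition_labels(truth, norm, toy_tree, "family")
        assert len(u) == 10  # unclassified kept, as a dedicated cluster
        nmi, _, _ = partition_agreement(u, v)
        assert nmi < 1.0


class TestSingletonDrop:
    def test_drop_shifts_to_unclassified(self):
        pred = make_pred(["r0", "r1", "r2"], ["classified"] * 3, [20, 20, 21])
        out = drop_singleton_taxa(pred)
        assert list(out["status"]) == ["classified", "classified", "unclassified"]
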