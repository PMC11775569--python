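"""Metrics against brute-force oracles; baselines; perturbations; ablation."""

import numpy as np
import pandas as pd
import pytest

from preciseadr.cohort import build_vocabulary, split_cohort
from preciseadr.estimators import DrugOnlyMLP, FrequencyBaseline
from preciseadr.evaluate import (ablation_harness, frequency_baseline,
                                 hit_at_k, labels_matrix, macro_auc,
                                 micro_auc, mlp_baseline,
                                 perturb_demographics, recall_at_k,
                                 run_experiment, training_size_spearman)
from preciseadr.simulate import generate_cohort
from .conftest import make_report, null_spec

RNG = np.random.default_rng(3)


def auc_bruteforce(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMacroAUC:
    def test_patient_constant_scores_give_exactly_half(self):
        labels = (RNG.random((40, 6)) < 0.3).astype(float)
        labels[0] = 1  # ensure evaluable
        labels[1] = 0
        scores = np.tile(RNG.random(6), (40, 1))
        assert macro_auc(scores, labels) == 0.5

    def test_perfect_scores_give_one(self):
        labels = (RNG.random((30, 4)) < 0.4).astype(float)
        labels[0], labels[1] = 1, 0
        assert macro_auc(labels.copy(), labels) == 1.0

    def test_matches_pair_counting_oracle(self):
        for _ in range(10):
            labels = (RNG.random((15, 3)) < 0.4).astype(float)
            labels[0], labels[1] = 1, 0
            scores = np.round(RNG.random((15, 3)), 1)  # force ties
            expect = np.mean([auc_bruteforce(scores[:, j], labels[:, j])
                              for j in range(3)])
            assert macro_auc(scores, labels) == pytest.approx(expect, abs=1e-12)

    def test_four_patient_single_adr_example(self):
        scores = np.array([[0.9], [0.4], [0.6], [0.1]])
        labels = np.array([[1.0], [0.0], [1.0], [0.0]])
        # positives 0.9, 0.6 vs negatives 0.4, 0.1: all 4 pairs won
        assert macro_auc(scores, labels) == 1.0
        assert macro_auc(scores, labels) == auc_bruteforce(
            scores[:, 0], labels[:, 0])

    def test_no_evaluable_adr_raises(self):
        with pytest.raises(ValueError):
            macro_auc(np.zeros((3, 2)), np.ones((3, 2)))


class TestHitAtK:
    def test_top_scored_true_adr_counts(self):
        scores = np.array([[0.9, 0.1, 0.2]])
        labels = np.array([[1.0, 0.0, 0.0]])
        assert hit_at_k(scores, labels, k=1) == 1.0

    def test_saturates_at_full_vocabulary(self):
        labels = (RNG.random((20, 8)) < 0.3).astype(float)
        labels[:, 0] = 1
        scores = RNG.random((20, 8))
        assert hit_at_k(scores, labels, k=8) == 1.0

    def test_monotone_in_k(self):
        labels = (RNG.random((30, 12)) < 0.2).astype(float)
        labels[:, 0] = labels[:, 0] + (labels.sum(axis=1) == 0)
        scores = RNG.random((30, 12))
        vals = [hit_at_k(scores, labels, k) for k in range(1, 13)]
        assert vals == sorted(vals)

    def test_uniform_scores_match_analytic_rate(self):
        """One true ADR among S, k of S chosen at random: hit rate k/S."""
        s, k, n = 60, 6, 4000
        labels = np.zeros((n, s))
        labels[np.arange(n), RNG.integers(0, s, n)] = 1.0
        scores = RNG.random((n, s))
        rate = hit_at_k(scores, labels, k)
        expect = k / s
        assert abs(rate - expect) < 3 * np.sqrt(expect * (1 - expect) / n)

    def test_ties_break_by_adr_index(self):
        scores = np.array([[0.5, 0.5, 0.5]])
        assert hit_at_k(scores, np.array([[1.0, 0, 0]]), k=1) == 1.0
        assert hit_at_k(scores, np.array([[0.0, 1, 0]]), k=1) == 0.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            hit_at_k(np.zeros((2, 3)), np.ones((2, 3)), k=0)
        with pytest.raises(ValueError):
            hit_at_k(np.zeros((2, 3)), np.ones((2, 3)), k=4)

    def test_recall_at_k_counts_fractions(self):
        scores = np.array([[0.9, 0.8, 0.1, 0.0]])
        labels = np.array([[1.0, 0.0, 1.0, 0.0]])
        assert recall_at_k(scores, labels, k=2) == 0.5


class TestFrequencyBaselines:
    def test_marginal_macro_auc_is_exactly_half(self, small_cohort):
        train, _, test = split_cohort(small_cohort, (0.7, 0.1, 0.2), 1)
        vocab = build_vocabulary(train)
        scores = frequency_baseline(train, test, vocab, "marginal")
        labels = labels_matrix(test, vocab)
        assert macro_auc(scores, labels) == 0.5

    def test_perfectly_cooccurring_drug_ranks_first(self):
        train = [make_report(f"t{i}", drugs=("MX",), adrs=("SX", "S_other"))
                 for i in range(10)]
        train += [make_report(f"u{i}", drugs=("MY",), adrs=("S_other",))
                  for i in range(10)]
        vocab = build_vocabulary(train)
        test = [make_report("q", drugs=("MX",), adrs=("SX",))]
        scores = frequency_baseline(train, test, vocab, "given_drugs")
        assert np.argmax(scores[0]) == vocab.adr_index["SX"]

    def test_given_both_matches_hand_computed_conditionals(self):
        r1 = make_report("a", ("D1",), ("M1",), adrs=("S1",))
        r2 = make_report("b", ("D1",), ("M2",), adrs=("S2",))
        r3 = make_report("c", ("D2",), ("M1",), adrs=("S1", "S2"))
        train = [r1, r2, r3]
        vocab = build_vocabulary(train)
        test = [make_report("q", ("D1",), ("M1",))]
        scores = frequency_baseline(train, test, vocab, "given_both")
        # P(S1|D1) = (1+1)/(2+2) = 0.5 ; P(S1|M1) = (2+1)/(2+2) = 0.75
        s1 = vocab.adr_index["S1"]
        assert scores[0, s1] == pytest.approx(0.5 * (0.5 + 0.75))
        # P(S2|D1) = (1+1)/(2+2) = 0.5 ; P(S2|M1) = (1+1)/(2+2) = 0.5
        s2 = vocab.adr_index["S2"]
        assert scores[0, s2] == pytest.approx(0.5)

    def test_patient_without_known_entities_falls_back_to_marginal(
            self, small_cohort):
        train = small_cohort[:80]
        vocab = build_vocabulary(train)
        stranger = make_report("s", ("Z1",), ("Z2",))
        scores = frequency_baseline(train, [stranger], vocab, "given_drugs")
        marg = frequency_baseline(train, [stranger], vocab, "marginal")
        assert np.array_equal(scores, marg)

    def test_random_variant_deterministic_per_seed(self, small_cohort):
        train, _, test = split_cohort(small_cohort, (0.7, 0.1, 0.2), 1)
        vocab = build_vocabulary(train)
        a = frequency_baseline(train, test, vocab, "random", seed=5)
        b = frequency_baseline(train, test, vocab, "random", seed=5)
        assert np.array_equal(a, b)


class TestPerturbations:
    def test_gender_flip_on_all_male_cohort(self):
        reports = [make_report(f"m{i}", sex=1) for i in range(5)]
        flipped = perturb_demographics(reports, "gender")
        assert all(r.sex == 2 for r in flipped)

    def test_gender_flip_is_an_involution(self, small_cohort):
        twice = perturb_demographics(
            perturb_demographics(small_cohort, "gender"), "gender")
        assert twice == list(small_cohort)

    def test_age_permutation_preserves_multiset(self, small_cohort):
        shuffled = perturb_demographics(small_cohort, "age", seed=3)
        assert sorted(r.age for r in shuffled) == \
            sorted(r.age for r in small_cohort)
        assert [r.drugs for r in shuffled] == [r.drugs for r in small_cohort]

    def test_both_applies_both(self, small_cohort):
        both = perturb_demographics(small_cohort, "both", seed=3)
        assert all(b.sex == 3 - r.sex for b, r in zip(both, small_cohort))
        assert sorted(r.age for r in both) == sorted(r.age for r in small_cohort)


class TestMLPBaseline:
    def test_learns_drug_driven_signal(self):
        spec = null_spec(n_patients=800, n_adrs=8, n_drugs=10, n_diseases=10,
                         base_logit=-2.5, seed=31)
        spec.drug_effect[:, :] = 0.0
        rng = np.random.default_rng(0)
        for s in range(8):
            for m in rng.choice(10, size=2, replace=False):
                spec.drug_effect[m, s] = 2.0
        reports, _ = generate_cohort(spec)
        train, _, test = split_cohort(reports, (0.8, 0.1, 0.1), 0)
        vocab = build_vocabulary(train)
        res = mlp_baseline(train, test, vocab, epochs=120, seed=0)
        marg = macro_auc(frequency_baseline(train, test, vocab, "marginal"),
                         labels_matrix(test, vocab))
        assert res.macro_auc > marg + 0.05

    def test_blind_to_demographic_signal(self):
        spec = null_spec(n_patients=800, n_adrs=8, base_logit=-2.0, seed=33)
        spec.gender_effect[:] = np.log(6.0)
        spec.age_effect[:, 2] = np.log(6.0)
        reports, _ = generate_cohort(spec)
        train, _, test = split_cohort(reports, (0.8, 0.1, 0.1), 0)
        vocab = build_vocabulary(train)
        res = mlp_baseline(train, test, vocab, epochs=80, seed=0)
        assert abs(res.macro_auc - 0.5) < 0.05

    def test_deterministic_for_fixed_seed(self, small_cohort):
        train, _, test = split_cohort(small_cohort, (0.7, 0.1, 0.2), 1)
        vocab = build_vocabulary(train)
        a = mlp_baseline(train, test, vocab, epochs=10, seed=4)
        b = mlp_baseline(train, test, vocab, epochs=10, seed=4)
        assert a.macro_auc == b.macro_auc


class TestHarness:
    def _factory(self, alpha, seed):
        return DrugOnlyMLP(hidden=8, epochs=15, random_state=seed)

    def test_grid_produces_one_row_per_setting_and_seed(self, small_cohort):
        table = ablation_harness(small_cohort, self._factory,
                                 fractions_grid=(0.5, 1.0),
                                 alpha_grid=(0.1,), seeds=(0, 1))
        assert len(table) == 4
        assert set(table.columns) >= {"train_fraction", "alpha", "seed",
                                      "macro_auc"}

    def test_identical_grid_reproduces_table(self, small_cohort):
        kw = dict(fractions_grid=(0.5, 1.0), alpha_grid=(0.1,), seeds=(0,))
        a = ablation_harness(small_cohort, self._factory, **kw)
        b = ablation_harness(small_cohort, self._factory, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_spearman_statistic_computed(self):
        table = pd.DataFrame({"train_fraction": [0.25, 0.5, 1.0],
                              "macro_auc": [0.6, 0.7, 0.8]})
        assert training_size_spearman(table) == pytest.approx(1.0)

    def test_run_experiment_reports_model_and_baselines(self, small_cohort):
        results = run_experiment(small_cohort,
                                 DrugOnlyMLP(hidden=8, epochs=10),
                                 seed=0, baselines=("marginal",))
        assert set(results) == {"mlp_drug_only", "marginal"}
        assert results["marginal"].macro_auc == 0.5
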