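"""Per-type logistic models, ROC/AUC, cutoffs and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ppitype import model as mdl
from ppitype import synthetic as syn


def brute_force_auc(scores, y):
    """Concordant-pair counting oracle (ties count 1/2)."""
    pos = [s for s, lab in zip(scores, y) if lab == 1]
    neg = [s for s, lab in zip(scores, y) if lab == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def neg_log_likelihood(beta, X, y):
    z = X @ beta[1:] + beta[0]
    return np.sum(np.logaddexp(0, z) - y * z)


class TestFitLogistic:
    def test_matches_independent_numerical_optimization(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(60, 2)).astype(float)
        logits = -0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(60) < 1 / (1 + np.exp(-logits))).astype(int)
        m = mdl.fit_logistic(pd.DataFrame(X, columns=["f1", "f2"]), y)
        assert not m.stabilized_
        oracle = minimize(neg_log_likelihood, np.zeros(3), args=(X, y),
                          method="BFGS", options={"gtol": 1e-10})
        got = np.concatenate([m.intercept_, m.coef_[0]])
        assert np.allclose(got, oracle.x, atol=1e-4)

    def test_loglik_at_fit_beats_random_probes(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(30, 2)).astype(float)
        y = (rng.random(30) < 0.4).astype(int)
        m = mdl.fit_logistic(pd.DataFrame(X), y)
        beta_hat = np.concatenate([m.intercept_, m.coef_[0]])
        best = neg_log_likelihood(beta_hat, X, y)
        probes = rng.normal(0, 2, size=(1000, 3))
        assert all(neg_log_likelihood(b, X, y) >= best - 1e-8 for b in probes)

    def test_separable_data_uses_stabilized_fit(self):
        X = pd.DataFrame({"f": [1.0] * 10 + [0.0] * 10})
        y = np.array([1] * 10 + [0] * 10)
        m = mdl.fit_logistic(X, y)
        assert m.stabilized_
        p = m.predict_proba(X)[:, 1]
        assert (p[:10] >= 0.99).all() and (p[10:] <= 0.01).all()

    def test_allzero_feature_gets_near_zero_weight(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "live": rng.integers(0, 2, 40).astype(float),
            "dead": np.zeros(40),
        })
        y = rng.integers(0, 2, 40)
        m = mdl.fit_logistic(X, y)
        assert abs(m.weights_["dead"]) < 1e-6

    def test_one_class_input_errors(self):
        with pytest.raises(ValueError):
            mdl.fit_logistic(pd.DataFrame({"f": [0.0, 1.0]}), np.array([1, 1]))


class TestRocAuc:
    def test_perfect_and_inverted_ranking(self):
        assert mdl.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0
        assert mdl.roc_auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]).auc == 0.0

    def test_three_of_four_concordant(self):
        roc = mdl.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert roc.auc == 0.75

    def test_sensitivity_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        roc = mdl.roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(roc.sensitivity) <= 1e-12).all()

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            mdl.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_exhaustively_short_vectors(self):
        # all score/label vectors of length <= 8 over a tiny score alphabet
        for n in (2, 4, 6, 8):
            for scores in itertools.product((0.2, 0.5, 0.8), repeat=min(n, 4)):
                full = (list(scores) * 2)[:n]
                for labels in itertools.product((0, 1), repeat=n):
                    if 0 < sum(labels) < n:
                        got = mdl.roc_auc(full, list(labels)).auc
                        want = brute_force_auc(full, labels)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_brute_force_random_long_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            y = rng.integers(0, 2, n)
            if 0 < y.sum() < n:
                assert mdl.roc_auc(scores, y).auc == pytest.approx(
                    brute_force_auc(scores, y), abs=1e-12
                )


class TestYoudenCutoff:
    def test_separable_scores_give_midgap_threshold(self):
        roc = mdl.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert mdl.youden_cutoff(roc) == pytest.approx(0.5)

    def test_identical_scores_degenerate_without_error(self):
        roc = mdl.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        cut = mdl.youden_cutoff(roc)
        j = roc.sensitivity + roc.specificity
        assert j.max() == pytest.approx(1.0)
        assert np.isfinite(cut)

    def test_equals_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)
            y = rng.integers(0, 2, n)
            if not 0 < y.sum() < n:
                continue
            roc = mdl.roc_auc(scores, y)
            cut = mdl.youden_cutoff(roc)

            def j_at(t):
                sens = (scores[y == 1] >= t).mean()
                spec = (scores[y == 0] < t).mean()
                return sens + spec

            best = max(j_at(t) for t in roc.thresholds)
            assert j_at(cut) == pytest.approx(best, abs=1e-12)


class TestTrainingSets:
    def test_negative_set_sizes_follow_max_rule(self, standard_fixture,
                                                standard_matrix,
                                                type_ontology):
        _, inter, _ = standard_fixture
        specific = (type_ontology.subtree(syn.ENZYMATIC_REACTION)
                    | type_ontology.subtree(syn.COVALENT_BINDING))
        rng = np.random.default_rng(0)
        for type_id in syn.DEFAULT_TYPES:
            ts = mdl.assemble_training_set(
                inter, type_id, standard_matrix, rng, specific
            )
            assert len(ts.negative_ids) == max(len(ts.positive_ids), 100)
            assert not set(ts.positive_ids) & set(ts.negative_ids)

    def test_small_positive_set_gets_100_negatives(self, standard_matrix,
                                                   standard_fixture,
                                                   type_ontology):
        # emulate |pos|=34 -> |neg|=100 and |pos|=153 -> |neg|=153
        _, inter, _ = standard_fixture
        specific = type_ontology.subtree(syn.ENZYMATIC_REACTION)
        rng = np.random.default_rng(1)
        by_type = {}
        for u in inter:
            for t in u.types_closed & set(syn.DEFAULT_TYPES):
                by_type.setdefault(t, []).append(u)
        # truncate positives of one type to 34 by relabeling the rest
        t34 = syn.DEFAULT_TYPES[0]
        keep = {u.pair_id for u in by_type[t34][:34]}
        trimmed = []
        for u in inter:
            if t34 in u.types_closed and u.pair_id not in keep:
                continue
            trimmed.append(u)
        ts = mdl.assemble_training_set(trimmed, t34, standard_matrix, rng,
                                       specific)
        assert len(ts.positive_ids) == 34
        assert len(ts.negative_ids) == 100

    def test_other_type_positives_never_serve_as_negatives(
        self, standard_fixture, standard_matrix, type_ontology
    ):
        _, inter, _ = standard_fixture
        specific = (type_ontology.subtree(syn.ENZYMATIC_REACTION)
                    | type_ontology.subtree(syn.COVALENT_BINDING))
        rng = np.random.default_rng(2)
        type_id = syn.DEFAULT_TYPES[1]
        ts = mdl.assemble_training_set(inter, type_id, standard_matrix, rng,
                                       specific)
        typed = {u.pair_id for u in inter if type_id in u.types_closed}
        assert not typed & set(ts.negative_ids)

    def test_empty_positive_set_errors(self, standard_fixture,
                                       standard_matrix):
        _, inter, _ = standard_fixture
        with pytest.raises(ValueError, match="no positive"):
            mdl.assemble_training_set(inter, "MI:9999", standard_matrix,
                                      np.random.default_rng(0), set())


class TestEligibleTypes:
    def test_threshold_and_exclusions(self, type_ontology):
        from ppitype.interactions import UniqueInteraction

        def mk(i, types):
            u = UniqueInteraction(pair=(f"a{i}", f"b{i}"))
            u.types_closed = type_ontology.closure(types)
            return u

        inter = [mk(i, {syn.PHOSPHORYLATION}) for i in range(20)]
        inter += [mk(100 + i, {syn.CLEAVAGE}) for i in range(19)]
        got = mdl.eligible_types(
            inter, type_ontology, syn.SPECIFIC_TYPE_ROOTS,
            min_positives=20, excluded=[syn.ENZYMATIC_REACTION],
        )
        assert syn.PHOSPHORYLATION in got
        assert syn.CLEAVAGE not in got          # 19 < 20
        assert syn.ENZYMATIC_REACTION not in got  # excluded though abundant


class TestCrossValidate:
    def test_seeded_runs_are_bit_reproducible(self, standard_fixture,
                                              standard_matrix, type_ontology):
        _, inter, _ = standard_fixture
        specific = type_ontology.subtree(syn.ENZYMATIC_REACTION)
        kwargs = dict(k=5, repeats=3)
        a = mdl.cross_validate(inter, syn.PHOSPHORYLATION, standard_matrix,
                               specific, rng=np.random.default_rng(7),
                               **kwargs)
        b = mdl.cross_validate(inter, syn.PHOSPHORYLATION, standard_matrix,
                               specific, rng=np.random.default_rng(7),
                               **kwargs)
        assert a.aucs == b.aucs
        assert np.array_equal(a.pooled_scores, b.pooled_scores)

    def test_different_seed_same_signal(self, standard_fixture,
                                        standard_matrix, type_ontology):
        _, inter, _ = standard_fixture
        specific = type_ontology.subtree(syn.ENZYMATIC_REACTION)
        a = mdl.cross_validate(inter, syn.PHOSPHORYLATION, standard_matrix,
                               specific, k=5, repeats=3,
                               rng=np.random.default_rng(1))
        b = mdl.cross_validate(inter, syn.PHOSPHORYLATION, standard_matrix,
                               specific, k=5, repeats=3,
                               rng=np.random.default_rng(2))
        assert a.aucs != b.aucs
        assert abs(a.mean_auc - b.mean_auc) < 0.05


class TestPredictAll:
    def test_allzero_features_score_sigmoid_intercept(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.integers(0, 2, size=(40, 3)).astype(float),
                         columns=list("abc"))
        y = rng.integers(0, 2, 40)
        m = mdl.fit_logistic(X, y)
        m.set_cutoff(0.5)
        zero_row = pd.DataFrame(np.zeros((1, 3)), columns=list("abc"))
        scores, _ = mdl.predict_all({"t": m}, zero_row)
        expected = 1 / (1 + np.exp(-m.intercept_[0]))
        assert scores.iloc[0, 0] == pytest.approx(expected)

    def test_feature_mismatch_errors(self):
        X = pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"])
        y = np.array([0, 1, 0, 1])
        m = mdl.fit_logistic(X + np.eye(4, 2), y)
        with pytest.raises(ValueError, match="mismatch"):
            mdl.predict_all({"t": m},
                            pd.DataFrame(np.zeros((2, 2)),
                                         columns=["a", "zzz"]))

    def test_mixed_fixture_coverage_strictly_between_0_and_1(
        self, standard_fixture, standard_matrix, type_ontology
    ):
        _, inter, _ = standard_fixture
        specific = (type_ontology.subtree(syn.ENZYMATIC_REACTION)
                    | type_ontology.subtree(syn.COVALENT_BINDING))
        rng = np.random.default_rng(0)
        predictors = {}
        for t in syn.DEFAULT_TYPES[:2]:
            model, _ = mdl.train_predictor(inter, t, standard_matrix,
                                           specific, k=5, repeats=2, rng=rng)
            predictors[t] = model
        _, calls = mdl.predict_all(predictors, standard_matrix)
        frac = calls.any(axis=1).mean()
        assert 0.0 < frac < 1.0
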