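"""Cascade training loop, pool management, selection rules, serialization."""

import dataclasses

import numpy as np
import pytest

import cascadet as cd
from cascadet.boosting import DecisionStump, StageClassifier
from cascadet.cascade import (
    CascadeModel,
    ModelFormatError,
    NegativePool,
    TrainConfig,
    cascade_classify,
    evaluate_rates,
    filter_pool,
    load_model,
    save_model,
    select_informative,
    select_random,
    train_cascade,
    train_soft_cascade,
)


def make_stage(feature, thr, pol=1, alpha=1.0, stage_threshold=0.0):
    return StageClassifier(stumps=[DecisionStump(feature, thr, pol, alpha)],
                           stage_threshold=stage_threshold)


@pytest.fixture()
def toy_model():
    """3-stage cascade on 3 independent features: accept iff x_i > 0."""
    return CascadeModel(stages=[make_stage(i, 0.0) for i in range(3)])


class TestClassify:
    def test_permissive_stage_accepts_everything(self):
        m = CascadeModel(stages=[make_stage(0, 0.0, stage_threshold=-np.inf)])
        label, passed, _ = cascade_classify(m, np.array([-5.0]))
        assert label == 1 and passed == 1

    def test_short_circuit_skips_later_stages(self, toy_model, monkeypatch):
        calls = []
        orig = StageClassifier.confidence

        def counting(self, X):
            calls.append(self)
            return orig(self, X)

        monkeypatch.setattr(StageClassifier, "confidence", counting)
        x = np.array([1.0, -1.0, 1.0])  # rejected at stage 1
        label, passed, margin = cascade_classify(toy_model, x)
        assert label == -1 and passed == 1 and margin < 0
        assert calls == toy_model.stages[:2]

    def test_label_is_conjunction_of_stages(self, toy_model):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        acc, _, _ = toy_model.classify_batch(X)
        per_stage = np.column_stack([s.decide(X) for s in toy_model.stages])
        assert np.array_equal(acc, per_stage.all(axis=1))

    def test_batch_matches_single(self, toy_model):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        acc, passed, margin = toy_model.classify_batch(X)
        for i in range(20):
            l1, p1, m1 = cascade_classify(toy_model, X[i])
            assert (l1 == 1) == acc[i] and p1 == passed[i]
            assert m1 == pytest.approx(margin[i])


class TestRates:
    def test_permissive_and_rejecting(self):
        rng = np.random.default_rng(2)
        P, N = rng.normal(size=(10, 1)), rng.normal(size=(10, 1))
        permissive = CascadeModel(stages=[make_stage(0, 0, stage_threshold=-np.inf)])
        assert evaluate_rates(permissive, P, N) == (1.0, 1.0)
        rejecting = CascadeModel(stages=[make_stage(0, 0, stage_threshold=np.inf)])
        assert evaluate_rates(rejecting, P, N) == (0.0, 0.0)

    def test_rates_equal_direct_counting(self, toy_model):
        rng = np.random.default_rng(3)
        P, N = rng.normal(0.5, 1, (40, 3)), rng.normal(-0.5, 1, (40, 3))
        F, D = evaluate_rates(toy_model, P, N)
        acc_p = np.array([cascade_classify(toy_model, x)[0] == 1 for x in P])
        acc_n = np.array([cascade_classify(toy_model, x)[0] == 1 for x in N])
        assert D == acc_p.mean() and F == acc_n.mean()

    def test_empty_set_rejected(self, toy_model):
        with pytest.raises(ValueError):
            evaluate_rates(toy_model, np.empty((0, 3)), np.ones((2, 3)))


class TestPool:
    def test_filter_keeps_exactly_false_positives(self, toy_model):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3))
        pool = NegativePool(X)
        filter_pool(toy_model, pool)
        expect = {i for i in range(100) if cascade_classify(toy_model, X[i])[0] == 1}
        assert set(pool.alive_indices()) == expect

    def test_permissive_keeps_all_rejecting_empties(self):
        X = np.random.default_rng(5).normal(size=(20, 1))
        pool = NegativePool(X)
        filter_pool(CascadeModel(stages=[make_stage(0, 0, stage_threshold=-np.inf)]), pool)
        assert pool.n_alive == 20
        filter_pool(CascadeModel(stages=[make_stage(0, 0, stage_threshold=np.inf)]), pool)
        assert pool.n_alive == 0

    def test_deleted_never_reappear(self, toy_model):
        X = np.random.default_rng(6).normal(size=(50, 3))
        pool = NegativePool(X)
        pool.delete(np.arange(0, 50, 2))
        dead = set(range(0, 50, 2))
        filter_pool(toy_model, pool)
        assert dead.isdisjoint(pool.alive_indices())
        _, idx, _ = select_informative(pool, toy_model, 5)
        assert dead.isdisjoint(idx)


class TestSelection:
    def test_smallest_confidences_selected(self):
        # two stumps on features 0/1 give pool margins 0.9, 0.1, 0.5
        stage = StageClassifier(
            stumps=[DecisionStump(0, 0.0, 1, 1.0)], stage_threshold=0.0
        )
        m = CascadeModel(stages=[stage])
        pool = NegativePool(np.array([[0.9], [0.1], [0.5]]))
        conf = {i: float(stage.confidence(pool.X[i : i + 1])[0]) for i in range(3)}
        assert conf == {0: 1.0, 1: 1.0, 2: 1.0}  # stump outputs are +/-1: tie
        _, idx, short = select_informative(pool, m, 2)
        assert list(idx) == [0, 1] and not short  # stable pool order on ties

    def test_smallest_margin_values_chosen(self):
        # identity-like stage whose margin differs per sample
        stage = StageClassifier(
            stumps=[DecisionStump(j, 0.5, 1, 2.0 ** -j) for j in range(3)]
        )
        m = CascadeModel(stages=[stage])
        X = np.array([  # margins: distinct weighted votes
            [1.0, 1.0, 1.0],
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
        ])
        pool = NegativePool(X)
        conf = stage.confidence(X)
        _, idx, _ = select_informative(pool, m, 2)
        assert list(idx) == list(np.argsort(conf, kind="stable")[:2])

    def test_selection_equals_sort_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 4))
        stage = cd.adaboost_train(rng.normal(1, 1, (30, 4)), rng.normal(-1, 1, (30, 4)), 5)
        m = CascadeModel(stages=[stage])
        pool = NegativePool(X)
        sel, idx, _ = select_informative(pool, m, 50)
        conf = stage.confidence(X)
        oracle = np.argsort(conf, kind="stable")[:50]
        assert np.array_equal(np.sort(idx), np.sort(oracle))
        assert np.allclose(sel, X[idx])

    def test_k_larger_than_pool_returns_all_with_flag(self, toy_model):
        pool = NegativePool(np.random.default_rng(8).normal(size=(5, 3)))
        sel, idx, short = select_informative(pool, toy_model, 10)
        assert len(sel) == 5 and short

    def test_random_selection_reproducible(self):
        pool = NegativePool(np.random.default_rng(9).normal(size=(30, 2)))
        s1, i1, _ = select_random(pool, 10, 123)
        s2, i2, _ = select_random(pool, 10, 123)
        assert np.array_equal(i1, i2)

    def test_random_selection_uniform_chi2(self):
        from scipy.stats import chisquare

        pool = NegativePool(np.zeros((20, 1)))
        counts = np.zeros(20)
        rng = np.random.default_rng(10)
        n_draws, k = 10_000, 5
        for _ in range(n_draws):
            _, idx, _ = select_random(pool, k, rng)
            counts[idx] += 1
        stat, p = chisquare(counts, f_exp=np.full(20, n_draws * k / 20))
        assert p > 0.01

    def test_empty_pool(self, toy_model):
        pool = NegativePool(np.zeros((3, 3)))
        pool.delete([0, 1, 2])
        sel, idx, short = select_informative(pool, toy_model, 2)
        assert len(sel) == 0 and short


class TestTrainCascade:
    def test_separable_reaches_target(self, easy_features):
        X_pos, X_neg, _ = easy_features
        cfg = TrainConfig(F=0.05, f=0.5, d=1.0, seed=0)
        m = train_cascade(X_pos, NegativePool(X_neg), cfg)
        meta = m.training_meta
        assert meta["final_F"] <= 0.05
        assert meta["final_D"] == 1.0
        _, D = evaluate_rates(m, X_pos, X_neg[:10])
        assert D == 1.0  # every training positive survives the cascade

    def test_stage_bookkeeping_and_balance(self, trained_cascade, easy_features):
        X_pos, _, _ = easy_features
        meta = trained_cascade.training_meta
        prev_F = 1.0
        for s in meta["stages"]:
            assert s["F_i"] <= 0.5 * prev_F + 1e-12
            assert s["n_neg"] == len(X_pos) or "pool_shortage" in meta["flags"]
            prev_F = s["F_i"]
        assert meta["stages"][0]["selection"] == "random"
        for s in meta["stages"][1:]:
            assert s["selection"] == "confidence"
        # pool occupancy never grows
        occ = [s["pool_alive_before"] for s in meta["stages"]]
        assert occ == sorted(occ, reverse=True)

    def test_single_stage_equals_adaboost_plus_decrement(self, easy_features):
        X_pos, X_neg, _ = easy_features
        cfg = TrainConfig(F=0.05, max_stages=1, seed=3)
        pool = NegativePool(X_neg)
        m = train_cascade(X_pos, pool, cfg)
        assert m.n_stages == 1
        n_i = m.training_meta["stages"][0]["n_i"]
        # replay: same random first-stage negatives, same number of rounds
        rng = np.random.default_rng(3)
        X_sel, _, _ = select_random(NegativePool(X_neg), len(X_pos), rng)
        stage = cd.adaboost_train(X_pos, X_sel, n_i)
        cd.decrement_threshold(stage, X_pos, 1.0)
        assert stage.stumps == m.stages[0].stumps
        assert stage.stage_threshold == pytest.approx(m.stages[0].stage_threshold)

    def test_random_mode_uses_same_machinery(self, easy_features):
        X_pos, X_neg, _ = easy_features
        cfg = TrainConfig(F=0.1, selection_mode="random", seed=1)
        m = train_cascade(X_pos, NegativePool(X_neg), cfg)
        assert all(s["selection"] == "random" for s in m.training_meta["stages"])
        assert m.training_meta["final_F"] <= 0.1

    def test_determinism(self, easy_features):
        X_pos, X_neg, _ = easy_features
        cfg = TrainConfig(F=0.1, seed=5)
        m1 = train_cascade(X_pos, NegativePool(X_neg), cfg)
        m2 = train_cascade(X_pos, NegativePool(X_neg), cfg)
        assert [s.stumps for s in m1.stages] == [s.stumps for s in m2.stages]

    def test_pool_too_small_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_cascade(X, NegativePool(X[:5]), TrainConfig())


class TestSoftCascade:
    def test_quantile_zero_keeps_all_positives(self, gauss_2d):
        X_pos, X_neg = gauss_2d
        m = train_soft_cascade(X_pos, X_neg, T=8, rejection_quantile=0.0)
        acc, _, _ = m.classify_batch(X_pos)
        assert acc.all()

    def test_single_stump_equivalence(self, gauss_2d):
        X_pos, X_neg = gauss_2d
        m = train_soft_cascade(X_pos, X_neg, T=1, rejection_quantile=0.0)
        assert len(m.stages[0].stumps) == 1
        stump = m.stages[0].stumps[0]
        X = np.vstack([X_pos, X_neg])
        acc, _, _ = m.classify_batch(X)
        manual = stump.alpha * stump.predict(X) >= m.soft_thresholds[0]
        assert np.array_equal(acc, manual)

    def test_early_exit_preserves_full_ensemble_accepts(self):
        rng = np.random.default_rng(11)
        X_pos = rng.normal(0.8, 1, (40, 3))
        X_neg = rng.normal(-0.8, 1, (40, 3))
        m = train_soft_cascade(X_pos, X_neg, T=10, rejection_quantile=0.0)
        stage = m.stages[0]
        full_scores = stage.score(X_pos)
        full_accept = full_scores >= m.soft_thresholds[-1]
        early_accept, _, _ = m.classify_batch(X_pos)
        # anything the full ensemble accepts must survive the early exits
        assert np.all(early_accept[full_accept])


class TestSerialization:
    def test_roundtrip_identical_scores(self, trained_cascade, tmp_path):
        rng = np.random.default_rng(12)
        nfeat = max(s.n_features_min for s in trained_cascade.stages)
        X = rng.normal(size=(100, nfeat))
        p = tmp_path / "model.yaml"
        save_model(trained_cascade, p)
        back = load_model(p)
        a1, p1, m1 = trained_cascade.classify_batch(X)
        a2, p2, m2 = back.classify_batch(X)
        assert np.array_equal(a1, a2) and np.array_equal(p1, p2)
        assert np.array_equal(m1, m2)  # bit-exact float round-trip
        assert back.feature_config == trained_cascade.feature_config

    def test_truncated_file_raises(self, trained_cascade, tmp_path):
        p = tmp_path / "model.yaml"
        save_model(trained_cascade, p)
        text = p.read_text()
        p.write_text(text[: len(text) // 2].rsplit("\n", 1)[0] + "\n  - broken: [")
        with pytest.raises(ModelFormatError):
            load_model(p)

    def test_version_mismatch_raises(self, trained_cascade, tmp_path):
        p = tmp_path / "model.yaml"
        save_model(trained_cascade, p)
        p.write_text(p.read_text().replace("format_version: 1", "format_version: 99"))
        with pytest.raises(ModelFormatError, match="format_version"):
            load_model(p)

    def test_missing_field_raises(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text("format_version: 1\nkind: hard\n")
        with pytest.raises(ModelFormatError):
            load_model(p)
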