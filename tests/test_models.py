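import numpy as np
import pytest
from scipy import stats

from sortbind import (HyperParams, TrainedModel, evaluate, hyperparam_search,
                      learning_curve, one_hot, split_dataset,
                      structure_ablation_test, train_whole_library_model,
                      train_wt_model)
from sortbind.encoding import encode_dataset
from sortbind.models import WHOLE_LIBRARY_SPACE, WT_SPACE, draw_hyperparams, pearson


def random_fixed_length_dataset(n, L, rng, rule):
    seqs = ["".join("ACGU"[b] for b in rng.integers(4, size=L)) for _ in range(n)]
    y = np.array([rule(s) for s in seqs])
    return np.stack([one_hot(s) for s in seqs]), y


def random_padded_dataset(n, rng, rule):
    rows = []
    for _ in range(n):
        L = int(rng.integers(19, 26))
        s = "".join("ACGU"[b] for b in rng.integers(4, size=L))
        rows.append((s, "C", "." * L, rule(s)))
    return encode_dataset(rows)


def structure_planted_dataset(n, seed):
    """Labels depend on the assigned loop length; sequences are random, so
    only the structural-context rows carry the signal directly."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        b = int(rng.integers(0, 3))
        us = int(rng.integers(2, 5))
        loop = int(rng.integers(3, 9))
        db = "(" * 4 + "." * b + "(" * us + "." * loop + ")" * us + ")" * 4
        s = "".join("ACGU"[k] for k in rng.integers(4, size=len(db)))
        rows.append((s, "C", db, 2.0 * (loop - 5.5) + rng.normal(0, 0.3)))
    return encode_dataset(rows)


class TestSplit:
    def test_exact_80_20_partition(self):
        tr, te = split_dataset(100, seed=0)
        assert len(tr) == 80 and len(te) == 20

    def test_seed_reproducibility(self):
        assert all(np.array_equal(a, b) for a, b
                   in zip(split_dataset(57, seed=3), split_dataset(57, seed=3)))

    def test_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        for n in rng.integers(10, 200, size=10):
            tr, te = split_dataset(int(n), seed=int(n))
            assert len(set(tr) & set(te)) == 0
            assert sorted(np.concatenate([tr, te])) == list(range(n))


class TestHyperparamSearch:
    def test_draws_stay_inside_the_search_spaces(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            hp = draw_hyperparams(WT_SPACE, rng)
            assert all(5 <= h <= 50 for h in hp.hidden)
            assert 1 <= len(hp.hidden) <= 3
            assert hp.activation in ("identity", "tanh", "relu")
            assert hp.epochs in range(20, 101, 10)
            hp = draw_hyperparams(WHOLE_LIBRARY_SPACE, rng)
            assert 4 <= hp.kernel_len <= 10
            assert 4 <= hp.kernel_num <= 35
            assert hp.epochs in range(10, 101, 10)

    def test_single_point_space_is_returned(self):
        rng = np.random.default_rng(2)
        X, y = random_fixed_length_dataset(60, 10, rng, lambda s: float(s[2] == "A"))
        space = {"nodes": [8], "layers": [1], "activation": ["relu"], "epochs": [20]}
        hp, log = hyperparam_search(X, y, space, "wt", n_draws=3, seed=0)
        assert hp.hidden == (8,) and hp.epochs == 20
        assert len(log) == 3

    def test_deterministic_under_a_seed_and_argmax_selection(self):
        rng = np.random.default_rng(3)
        X, y = random_fixed_length_dataset(90, 8, rng,
                                           lambda s: 5.0 if s[4] == "C" else -5.0)
        space = {"nodes": [4, 16], "layers": [1], "activation": ["relu", "identity"],
                 "epochs": [10, 30]}
        hp1, log1 = hyperparam_search(X, y, space, "wt", n_draws=5, seed=9)
        hp2, log2 = hyperparam_search(X, y, space, "wt", n_draws=5, seed=9)
        assert hp1 == hp2
        assert log1["cv_pearson"].max() >= log1["cv_pearson"].median()
        assert log1.loc[log1["cv_pearson"].idxmax()]["draw"] == \
            log1[log1.cv_pearson == log1.cv_pearson.max()]["draw"].min()


class TestWtModel:
    def test_constant_labels_predict_the_constant(self):
        rng = np.random.default_rng(4)
        X, _ = random_fixed_length_dataset(120, 10, rng, lambda s: 0.0)
        y = np.full(120, 0.5)
        m = train_wt_model(X, y, HyperParams(hidden=(10,), epochs=40), seed=0)
        pred = m.predict(X)
        assert abs(pred.mean() - 0.5) < 0.1
        assert pred.std() < 0.2

    def test_planted_single_position_rule(self):
        rng = np.random.default_rng(5)
        X, y = random_fixed_length_dataset(2000, 19, rng,
                                           lambda s: 5.0 if s[7] == "A" else -5.0)
        tr, te = split_dataset(2000, seed=0)
        m = train_wt_model(X[tr], y[tr],
                           HyperParams(hidden=(20,), epochs=20), seed=0)
        assert evaluate(m, X[te], y[te])["pearson"] >= 0.9

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X, y = random_fixed_length_dataset(50, 8, rng, lambda s: float(len(s)))
        m = train_wt_model(X, y, HyperParams(hidden=(6,), epochs=5), seed=1)
        m.save(tmp_path / "m.json")
        loaded = TrainedModel.load(tmp_path / "m.json")
        assert np.array_equal(loaded.predict(X), m.predict(X))
        assert loaded.hp == m.hp


class TestWholeLibraryModel:
    def test_planted_motif_rule_learned(self):
        rng = np.random.default_rng(7)
        X, y = random_padded_dataset(2000, rng,
                                     lambda s: 5.0 if "ACAU" in s else -5.0)
        tr, te = split_dataset(2000, seed=1)
        hp = HyperParams(hidden=(24,), epochs=20, kernel_len=5, kernel_num=24)
        m = train_whole_library_model(X[tr], y[tr], hp, seed=0)
        assert evaluate(m, X[te], y[te])["pearson"] >= 0.8

    def test_prediction_depends_only_on_the_encoding(self, wildtypes):
        # re-encoding the same site yields the same matrix, hence the same
        # prediction (idempotent padding)
        rng = np.random.default_rng(8)
        X, y = random_padded_dataset(60, rng, lambda s: 1.0)
        hp = HyperParams(hidden=(8,), epochs=2, kernel_len=4, kernel_num=4)
        m = train_whole_library_model(X, y, hp, seed=0)
        wt = wildtypes[1]
        a = m.predict_site(wt.sequence, wt.dotbracket)
        b = m.predict_site(wt.sequence, wt.dotbracket)
        assert a == b

    def test_malformed_encoding_rejected(self):
        hp = HyperParams(hidden=(8,), epochs=1, kernel_len=4, kernel_num=4)
        with pytest.raises(ValueError):
            train_whole_library_model(np.zeros((10, 4, 50)), np.zeros(10), hp)


class TestEvaluation:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([0.0, 1.0, 2.0, 5.0, 6.0])

        class Echo:
            def predict(self, X):
                return np.asarray(X, dtype=float).ravel()

        m = TrainedModel(Echo(), "wt", HyperParams(hidden=(1,), epochs=1), 0)
        assert evaluate(m, y, y)["pearson"] == pytest.approx(1.0)
        assert evaluate(m, y, y)["auc"] == 1.0
        assert evaluate(m, -y, y)["pearson"] == pytest.approx(-1.0)

    def test_auc_matches_pairwise_concordance_count(self):
        rng = np.random.default_rng(9)
        y = rng.normal(3.5, 2.0, size=30)
        pred = rng.normal(0, 1, size=30)

        class Echo:
            def predict(self, X):
                return np.asarray(X, dtype=float).ravel()

        m = TrainedModel(Echo(), "wt", HyperParams(hidden=(1,), epochs=1), 0)
        auc = evaluate(m, pred, y)["auc"]
        pos = pred[y > 3.5]
        neg = pred[y <= 3.5]
        conc = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert auc == pytest.approx(conc)

    def test_zero_variance_prediction_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert pearson(np.ones(5), np.arange(5.0)) == 0.0


class TestStructureAblation:
    HP = HyperParams(hidden=(16,), epochs=8, kernel_len=5, kernel_num=8)

    def test_identical_pairs_give_pvalue_one(self):
        X, y = structure_planted_dataset(80, seed=10)
        X[:, 4:, :] = 0.0       # no structural information at all
        res = structure_ablation_test(X, y, self.HP, n_rep=4, seed=0)
        assert np.allclose(res["pairs"]["with_structure"],
                           res["pairs"]["without_structure"])
        assert res["pvalue"] == 1.0

    def test_structure_signal_detected(self):
        X, y = structure_planted_dataset(600, seed=11)
        res = structure_ablation_test(X, y, self.HP, n_rep=8, seed=1)
        assert res["n_improved"] >= 7
        assert res["pvalue"] < 0.05

    def test_wilcoxon_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.6, 0.05, 30)
        b = a - np.abs(rng.normal(0.05, 0.02, 30))
        ours = stats.wilcoxon(a, b, alternative="greater")
        # hand-computed signed-rank statistic
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        assert ours.statistic == pytest.approx(w_plus)


class TestLearningCurve:
    def test_monotone_trend_and_determinism(self):
        rng = np.random.default_rng(13)
        X, y = random_fixed_length_dataset(600, 10, rng,
                                           lambda s: 5.0 if s[3] == "G" else -5.0)
        hp = HyperParams(hidden=(10,), epochs=10)
        sizes = [40, 160, 400]
        lc1 = learning_curve(X, y, sizes, hp, kind="wt", n_rep=3, seed=0)
        lc2 = learning_curve(X, y, sizes, hp, kind="wt", n_rep=3, seed=0)
        assert lc1.equals(lc2)
        means, stds = lc1["mean_pearson"].to_numpy(), lc1["std_pearson"].to_numpy()
        assert all(means[i + 1] >= means[i] - stds[i] for i in range(len(sizes) - 1))

    def test_oversized_training_request_rejected(self):
        rng = np.random.default_rng(14)
        X, y = random_fixed_length_dataset(50, 6, rng, lambda s: 1.0)
        with pytest.raises(ValueError):
            learning_curve(X, y, [49], HyperParams(hidden=(4,), epochs=2),
                           kind="wt", n_rep=1, seed=0)
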