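import numpy as np
import pytest

from fuzzybnn import cohort as C, linear, mlp
from tests.conftest import toy_cohort


def tiny_params(n_in=3, n_hidden=2, n_out=2, seed=0):
    return mlp.init_params(n_in, n_hidden, n_out, seed=seed)


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = mlp.MLPParams(a=np.zeros(2), U=np.zeros((3, 2)),
                          b=np.zeros(2), V=np.zeros((2, 2)))
        assert np.allclose(mlp.forward(np.ones(3), p), 0.0)

    def test_tanh_saturation_single_unit(self):
        p = mlp.MLPParams(a=np.zeros(1), U=np.ones((1, 1)),
                          b=np.zeros(1), V=np.ones((1, 1)))
        assert mlp.forward(np.array([0.0]), p)[0] == 0.0
        assert mlp.forward(np.array([50.0]), p)[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_evaluation_on_toy(self):
        p = tiny_params(seed=3)
        x = np.array([0.4, -1.2, 0.7])
        # explicit loops over the defining equations
        expected = np.zeros(2)
        for k in range(2):
            s = p.b[k]
            for j in range(2):
                h = np.tanh(p.a[j] + sum(p.U[i, j] * x[i] for i in range(3)))
                s += p.V[j, k] * h
            expected[k] = s
        np.testing.assert_allclose(mlp.forward(x, p), expected, rtol=1e-12)

    def test_hidden_activations_bounded(self, small_cohort):
        params, _ = mlp.train(small_cohort, mlp.TrainConfig(epochs=20, seed=0))
        H = mlp.hidden_activations(small_cohort.X, params)
        assert (np.abs(H) < 1.0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inputs"):
            mlp.forward(np.ones(4), tiny_params())


class TestSplit:
    @pytest.mark.parametrize("n,frac,n_train,n_test", [
        (3551, 0.6, 2131, 1420),
        (10, 0.5, 5, 5),
        (5, 0.5, 3, 2),   # round-half-up
    ])
    def test_split_sizes(self, n, frac, n_train, n_test):
        tr, te = mlp.split_train_test(n, frac, seed=0)
        assert (tr.size, te.size) == (n_train, n_test)

    def test_partition_disjoint_exhaustive_deterministic(self):
        tr1, te1 = mlp.split_train_test(101, 0.6, seed=9)
        tr2, te2 = mlp.split_train_test(101, 0.6, seed=9)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert len(np.intersect1d(tr1, te1)) == 0
        assert len(np.union1d(tr1, te1)) == 101

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            mlp.split_train_test(1, 0.6)


class TestTrain:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(5)
        p = tiny_params(seed=5)
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 2))
        _, (ga, gU, gb, gV) = mlp.loss_and_grad(p, X, Y)
        grads = {"a": ga, "U": gU, "b": gb, "V": gV}
        eps = 1e-6
        for field, g in grads.items():
            arr = getattr(p, field)
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = mlp.loss_and_grad(p, X, Y)
                arr[idx] = orig - eps
                lm, _ = mlp.loss_and_grad(p, X, Y)
                arr[idx] = orig
                fd[idx] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-8, err_msg=field)

    def test_zero_learning_rate_leaves_params_at_init(self, small_cohort):
        cfg = mlp.TrainConfig(learning_rate=0.0, epochs=5, seed=1)
        params, _ = mlp.train(small_cohort, cfg)
        ref = mlp.init_params(30, cfg.n_hidden, 5, seed=1)
        np.testing.assert_array_equal(params.a, ref.a)
        np.testing.assert_array_equal(params.U, ref.U)

    def test_loss_non_increasing_for_small_learning_rate(self, small_cohort):
        _, hist = mlp.train(small_cohort, mlp.TrainConfig(learning_rate=0.01,
                                                          epochs=150, seed=2))
        assert (np.diff(hist) <= 1e-12).all()

    def test_separable_two_class_toy_reaches_full_accuracy(self):
        rng = np.random.default_rng(7)
        n = 60
        x = np.concatenate([rng.normal(-3, 0.3, n), rng.normal(3, 0.3, n)])
        gos = np.array([1] * n + [2] * n)
        coh = toy_cohort(x[:, None], y_latent=gos.astype(float), gos=gos)
        params, _ = mlp.train(coh, mlp.TrainConfig(learning_rate=0.3,
                                                   epochs=800, n_hidden=3, seed=3))
        pred = np.argmax(mlp.forward(coh.X, params), axis=1) + 1
        assert (pred == gos).mean() == 1.0

    def test_divergent_learning_rate_raises(self, small_cohort):
        with pytest.raises(FloatingPointError, match="learning_rate"):
            mlp.train(small_cohort, mlp.TrainConfig(learning_rate=1e4,
                                                    epochs=200, seed=0))


class TestImportance:
    def test_single_active_input_takes_all(self):
        p = mlp.MLPParams(a=np.zeros(2), U=np.zeros((4, 2)),
                          b=np.zeros(3), V=np.ones((2, 3)))
        p.U[0, :] = 1.5
        imp = mlp.normalized_importance(p)
        np.testing.assert_allclose(imp, [1.0, 0, 0, 0])

    def test_sums_to_one(self, small_cohort):
        params, _ = mlp.train(small_cohort, mlp.TrainConfig(epochs=30, seed=4))
        imp = mlp.normalized_importance(params)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_mirror_symmetry_gives_equal_importance(self):
        p = mlp.MLPParams(a=np.zeros(1), U=np.array([[0.8], [-0.8]]),
                          b=np.zeros(1), V=np.array([[1.2]]))
        imp = mlp.normalized_importance(p)
        assert imp[0] == pytest.approx(imp[1])

    def test_permutation_equivariance(self):
        p = tiny_params(n_in=4, seed=8)
        imp = mlp.normalized_importance(p)
        perm = [2, 0, 3, 1]
        p2 = p.copy()
        p2.U = p.U[perm]
        np.testing.assert_allclose(mlp.normalized_importance(p2), imp[perm])

    def test_all_zero_weights_rejected(self):
        p = mlp.MLPParams(a=np.zeros(2), U=np.zeros((3, 2)),
                          b=np.zeros(2), V=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            mlp.normalized_importance(p)


class TestAuc:
    def test_perfect_separation(self):
        assert mlp.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.4
        assert mlp.auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self):
        scores = np.array([0.2, 0.7, 0.4, 0.4, 0.9, 0.1])
        labels = np.array([0, 1, 0, 1, 1, 0])
        wins = ties = 0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / (labels.sum() * (1 - labels).sum())
        assert mlp.auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            mlp.auc([0.1, 0.2], [1, 1])


class TestLinearDataLimit:
    def test_mlp_not_much_worse_than_ols_on_linear_data(self):
        spec = C.default_spec("table1", n=1200)
        coh = C.generate(spec, seed=12)
        tr, te = mlp.split_train_test(coh.n, 0.6, seed=12)
        params, _ = mlp.train(coh, mlp.TrainConfig(learning_rate=0.05,
                                                   epochs=600, seed=12),
                              indices=tr)
        pred = mlp.predict_severity(coh.X[te], params)
        mlp_rmse = np.sqrt(np.mean((pred - coh.gos[te]) ** 2))
        ols = linear.fit_ols(coh, outcome="gos")
        X1 = np.column_stack([np.ones(coh.n), coh.X])
        ols_pred = X1[te] @ np.concatenate([[ols.intercept], ols.table["beta"]])
        ols_rmse = np.sqrt(np.mean((ols_pred - coh.gos[te]) ** 2))
        assert mlp_rmse <= ols_rmse + 0.15
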