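"""Prediction networks, weighted voting, combined loss, and inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swarmlda as sw
from swarmlda.ensemble import _NetBank


class TestProportionalProbs:
    def test_symmetry_and_hand_value(self):
        np.testing.assert_allclose(sw.proportional_probs([3.0, 3.0]), [0.5, 0.5])
        np.testing.assert_allclose(
            sw.proportional_probs([0.0, np.log(3.0)]), [0.25, 0.75], rtol=1e-12
        )

    @given(
        deltas=st.lists(st.floats(-30, 30), min_size=2, max_size=6),
        c=st.floats(-100, 100),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_shift_invariance(self, deltas, c):
        d = np.array(deltas)
        np.testing.assert_allclose(
            sw.proportional_probs(d), sw.proportional_probs(d + c), rtol=1e-9, atol=1e-12
        )


class TestPrelimNet:
    def _net(self, K=3, H=8, seed=0):
        rng = np.random.default_rng(seed)
        return sw.PrelimNet(
            W1=rng.normal(size=(K, H)),
            b1=np.zeros(H),
            W2=rng.normal(size=(H, K)),
            b2=np.zeros(K),
            in_mean=np.zeros(K),
            in_sd=np.ones(K),
        )

    def test_outputs_on_simplex_and_deterministic(self):
        net = self._net()
        scores = np.random.default_rng(1).normal(size=(10, 3))
        p = sw.prelim_forward(net, scores)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)
        np.testing.assert_array_equal(p, sw.prelim_forward(net, scores))
        np.testing.assert_array_equal(p[0], sw.prelim_forward(net, scores[[0, 0]])[0])

    def test_nonfinite_scores_fatal(self):
        net = self._net()
        with pytest.raises(ValueError, match="non-finite"):
            sw.prelim_forward(net, np.array([[0.0, np.nan, 1.0]]))


class TestAggregateVote:
    def test_equal_weights_average(self):
        prelim = np.array([[[0.2, 0.8]], [[0.6, 0.4]]])
        voting = sw.VotingWeights(np.zeros((2, 2)))
        np.testing.assert_allclose(sw.aggregate_vote(prelim, voting), [[0.4, 0.6]])

    def test_degenerate_weights_select_one_model(self):
        prelim = np.array([[[0.2, 0.8]], [[0.6, 0.4]]])
        voting = sw.VotingWeights(np.array([[50.0, 50.0], [-50.0, -50.0]]))
        np.testing.assert_allclose(
            sw.aggregate_vote(prelim, voting), [[0.2, 0.8]], atol=1e-12
        )

    def test_identical_models_are_a_fixed_point(self):
        rng = np.random.default_rng(2)
        row = rng.dirichlet(np.ones(3), size=4)
        prelim = np.stack([row] * 5)
        voting = sw.VotingWeights(rng.normal(size=(5, 3)))
        np.testing.assert_allclose(sw.aggregate_vote(prelim, voting), row, rtol=1e-12)

    def test_weights_sum_to_one_per_class(self):
        voting = sw.VotingWeights(np.random.default_rng(3).normal(size=(7, 4)))
        np.testing.assert_allclose(voting.weights.sum(axis=0), np.ones(4), atol=1e-12)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        prelim = rng.dirichlet(np.ones(3), size=(5, 6))
        voting = sw.VotingWeights(rng.normal(size=(5, 3)))
        perm = [2, 0, 1]
        out = sw.aggregate_vote(prelim, voting)
        out_p = sw.aggregate_vote(
            prelim[:, :, perm], sw.VotingWeights(voting.logits[:, perm])
        )
        np.testing.assert_allclose(out[:, perm], out_p, rtol=1e-12)

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            sw.aggregate_vote(np.zeros((2, 3, 4)), sw.VotingWeights(np.zeros((3, 4))))


class TestEnsembleLoss:
    def test_alpha_endpoints_match_independent_cross_entropies(self):
        rng = np.random.default_rng(5)
        n, K, M = 20, 3, 4
        final = rng.dirichlet(np.ones(K), size=n)
        prelim = rng.dirichlet(np.ones(K), size=(M, n))
        y = rng.integers(0, K, size=n)
        ce_final = -np.mean(np.log(final[np.arange(n), y]))
        ce_models = sum(-np.mean(np.log(prelim[m, np.arange(n), y])) for m in range(M))
        assert sw.ensemble_loss(final, prelim, y, 1.0) == pytest.approx(ce_final, abs=1e-8)
        assert sw.ensemble_loss(final, prelim, y, 0.0) == pytest.approx(ce_models, abs=1e-8)

    def test_uniform_prediction_hand_value(self):
        final = np.array([[0.5, 0.5]])
        prelim = np.array([[[0.5, 0.5]]])
        for alpha in (0.0, 0.3, 1.0):
            assert sw.ensemble_loss(final, prelim, [0], alpha) == pytest.approx(
                np.log(2.0), rel=1e-12
            )

    def test_invalid_alpha_fatal(self):
        with pytest.raises(ValueError):
            sw.ensemble_loss(np.ones((1, 2)), np.ones((1, 1, 2)), [0], 1.5)


class TestNetBankGradients:
    def test_backward_matches_finite_differences(self):
        """The hand-derived gradient of the combined loss is verified numerically."""
        rng = np.random.default_rng(6)
        M, B, K, H = 3, 7, 3, 5
        bank = _NetBank(M, K, H, shared_voter=False, rng=rng)
        for p in ("W1", "b1", "W2", "b2", "logits"):
            getattr(bank, p)[...] += rng.normal(0, 0.3, size=getattr(bank, p).shape)
        Zb = rng.normal(size=(M, B, K))
        y = rng.integers(0, K, size=B)
        alpha = 0.6

        def loss_value():
            _, _, _, logP, _, Q, R = bank.forward(Zb)
            return bank.loss_from_forward(logP, Q, R, y, alpha)

        A1, H1, P, logP, w, Q, R = bank.forward(Zb)
        grads = bank.backward(Zb, A1, H1, P, w, Q, R, y, alpha)
        eps = 1e-6
        for pname in ("W1", "b1", "W2", "b2", "logits"):
            arr = getattr(bank, pname)
            it = np.ndindex(*arr.shape)
            for _ in range(5):  # spot-check a few coordinates per parameter
                idx = next(it)
                old = arr[idx]
                arr[idx] = old + eps
                up = loss_value()
                arr[idx] = old - eps
                dn = loss_value()
                arr[idx] = old
                num = (up - dn) / (2 * eps)
                assert grads[pname][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_separable_two_class_scores_learned(self):
        """A single-member ensemble learns linearly separable scores (alpha=0
        trains the prelim net alone)."""
        rng = np.random.default_rng(7)
        n = 200
        # counts with a strong class difference in two marker genes
        cfg = sw.SimConfig(
            n_cells=n, n_genes=60, n_types=2, class_props=(0.5, 0.5),
            n_marker_genes_per_class=5, log_fold_change=2.0, seed=7,
        )
        matrix, labels, _ = sw.simulate_counts(cfg)
        norm = sw.log_normalize(matrix)
        plan = sw.draw_swarm(n=n, p=norm.n_genes, M=1, cell_frac=1.0, master_seed=7)
        config = sw.TrainingConfig(alpha=0.0, max_epochs=100, seed=7)
        model = sw.train_ensemble(norm, labels, plan, config)
        assert model.fit_report["train_accuracy"] >= 0.95

    def test_single_member_alpha_one_equals_its_net(self, counts_fixture):
        matrix, labels = counts_fixture["matrix"], counts_fixture["labels"]
        norm = sw.log_normalize(matrix)
        plan = sw.draw_swarm(n=norm.n_cells, p=norm.n_genes, M=1, master_seed=1)
        config = sw.TrainingConfig(alpha=1.0, max_epochs=5, seed=1)
        model = sw.train_ensemble(norm, labels, plan, config)
        res = sw.predict(model, norm, return_per_model=True)
        np.testing.assert_allclose(res.probs, res.per_model_probs[0], rtol=1e-10)

    def test_shared_voter_constrains_columns_equal(self, counts_fixture):
        matrix, labels = counts_fixture["matrix"], counts_fixture["labels"]
        norm = sw.log_normalize(matrix)
        plan = sw.draw_swarm(n=norm.n_cells, p=norm.n_genes, M=3, master_seed=2)
        config = sw.TrainingConfig(shared_voter=True, max_epochs=10, seed=2)
        model = sw.train_ensemble(norm, labels, plan, config)
        w = model.voting.weights
        for k in range(1, w.shape[1]):
            np.testing.assert_array_equal(w[:, 0], w[:, k])


class TestPredict:
    def test_probability_rows_sum_to_one(self, trained_fixture):
        res = sw.predict(trained_fixture["model"], trained_fixture["query_norm"])
        np.testing.assert_allclose(res.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((res.probs >= 0) & (res.probs <= 1))
        assert set(res.labels) <= set(trained_fixture["model"].label_order)

    def test_inference_is_deterministic(self, trained_fixture):
        model, q = trained_fixture["model"], trained_fixture["query_norm"]
        a = sw.predict(model, q)
        b = sw.predict(model, q)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_gene_order_irrelevant(self, trained_fixture):
        model, q = trained_fixture["model"], trained_fixture["query_norm"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(q.n_genes)
        q_perm = q.subset(gene_idx=perm)
        np.testing.assert_array_equal(
            sw.predict(model, q).probs, sw.predict(model, q_perm).probs
        )

    def test_missing_genes_degrade_gracefully(self, trained_fixture):
        model, q = trained_fixture["model"], trained_fixture["query_norm"]
        rng = np.random.default_rng(1)
        keep = np.sort(
            rng.choice(q.n_genes, size=int(0.9 * q.n_genes), replace=False)
        )
        res = sw.predict(model, q.subset(gene_idx=keep))
        acc = sw.evaluate(res, trained_fixture["query_lab"]).overall_accuracy
        assert acc >= 0.90

    def test_too_few_genes_fatal_with_overlap_report(self, trained_fixture):
        model, q = trained_fixture["model"], trained_fixture["query_norm"]
        keep = np.arange(int(0.2 * q.n_genes))
        with pytest.raises(ValueError, match="/"):
            sw.predict(model, q.subset(gene_idx=keep))

    def test_ensemble_beats_mean_member_on_holdout(self, trained_fixture):
        model = trained_fixture["model"]
        res = sw.predict(model, trained_fixture["query_norm"], return_per_model=True)
        y = trained_fixture["query_lab"].codes
        ens = np.mean(np.argmax(res.probs, axis=1) == y)
        member = np.mean(
            [
                np.mean(np.argmax(res.per_model_probs[m], axis=1) == y)
                for m in range(model.n_models)
            ]
        )
        assert ens >= member
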