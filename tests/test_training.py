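"""Loss, scale optimisation, schedules, batching and the training loop."""

import numpy as np
import pytest

from hyperplace.encoder import EncoderSpec, encoder_init
from hyperplace.geometry import pairwise_unit_distances
from hyperplace.simulate import SimulationConfig, random_binary_tree, simulate_jc_alignment
from hyperplace.trees import TreeDistances, leaf_distance_matrix
from hyperplace.training import (
    TrainingConfig,
    add_terminal_pseudocounts,
    loss_and_tangent_grad,
    lr_schedule,
    make_batches,
    normalize_tree_distances,
    optimal_scale,
    scale_step,
    train,
    weighted_cost,
)


class TestNormalize:
    def test_divides_by_max_and_stores_factor(self):
        D = TreeDistances(["a", "b"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        N = normalize_tree_distances(D)
        assert N.matrix[0, 1] == 1.0
        assert N.normalization_factor == 4.0
        assert np.allclose(N.matrix * N.normalization_factor, D.matrix)

    def test_already_normalized_unchanged(self):
        D = TreeDistances(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        N = normalize_tree_distances(D)
        assert N.normalization_factor == 1.0
        assert np.array_equal(N.matrix, D.matrix)

    def test_all_zero_rejected(self):
        D = TreeDistances(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            normalize_tree_distances(D)


class TestPseudocounts:
    def test_zero_is_identity(self, small_tree):
        out = add_terminal_pseudocounts(small_tree, 0.0)
        assert np.allclose(
            leaf_distance_matrix(out).matrix, leaf_distance_matrix(small_tree).matrix
        )

    @pytest.mark.parametrize("eps", [1e-3, 1e-4])
    def test_every_pair_grows_by_two_eps(self, small_tree, eps):
        before = leaf_distance_matrix(small_tree)
        after = leaf_distance_matrix(add_terminal_pseudocounts(small_tree, eps))
        n = len(before.labels)
        expected = before.matrix + 2 * eps * (1 - np.eye(n))
        assert np.allclose(after.matrix, expected, atol=1e-12)


class TestWeightedCost:
    def make_inputs(self, ratios):
        # one embedded pair per ratio on a line in euclidean mode
        t = np.ones(len(ratios))
        d = np.array(ratios)
        return d, t

    def test_exact_fit_is_zero(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        D = pairwise_unit_distances(V, "euclidean")
        Dt = TreeDistances(["a", "b", "c"], D)
        pairs = np.array([[0, 1], [0, 2], [1, 2]])
        assert weighted_cost(V, 1.0, Dt, pairs, mode="euclidean") == 0.0

    def test_double_distance_gives_one(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0]])
        D = pairwise_unit_distances(V, "euclidean")
        Dt = TreeDistances(["a", "b"], D)
        assert weighted_cost(V, 2.0, Dt, np.array([[0, 1]]), "euclidean") == 1.0

    def test_mixed_ratios(self):
        # ratios 0.5 and 1.5 -> mean of (0.5-1)^2 and (1.5-1)^2 = 0.25
        V = np.array([[0.0], [1.0], [3.0]])  # sq distances: ab=1, bc=4
        t_ab, t_bc = 2.0, 4.0 / 1.5
        Dt = TreeDistances(
            ["a", "b", "c"],
            np.array([[0, t_ab, 5.0], [t_ab, 0, t_bc], [5.0, t_bc, 0]]),
        )
        got = weighted_cost(V, 1.0, Dt, np.array([[0, 1], [1, 2]]), "euclidean")
        assert got == pytest.approx(0.25, abs=1e-12)

    def test_zero_tree_distance_rejected(self):
        V = np.array([[0.0], [1.0]])
        Dt = TreeDistances(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="pseudo"):
            weighted_cost(V, 1.0, Dt, np.array([[0, 1]]), "euclidean")


class TestOptimalScale:
    def test_perfect_ratios_give_one(self):
        t = np.array([1.0, 2.0, 3.0])
        assert optimal_scale(t, t) == pytest.approx(1.0)

    def test_double_distances_give_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert optimal_scale(2 * t, t) == pytest.approx(0.5)

    def test_beats_grid_search(self, rng):
        d = rng.uniform(0.1, 3.0, size=60)
        t = rng.uniform(0.1, 3.0, size=60)
        s_star = optimal_scale(d, t)
        cost = lambda s: np.mean((s * d / t - 1) ** 2)
        grid = np.linspace(1e-3, 10, 10_000)
        assert cost(s_star) <= min(cost(s) for s in grid) + 1e-12

    def test_collapsed_embedding_rejected(self):
        with pytest.raises(ValueError, match="collapsed"):
            optimal_scale(np.zeros(3), np.ones(3))


class TestScaleStepAndSchedule:
    @pytest.mark.parametrize(
        "s, star, alpha, expected", [(1.0, 3.0, 1.0, 3.0), (1.0, 3.0, 0.5, 2.0)]
    )
    def test_scale_step(self, s, star, alpha, expected):
        assert scale_step(s, star, alpha) == expected

    def test_scale_step_alpha_zero_invalid(self):
        with pytest.raises(ValueError):
            scale_step(1.0, 2.0, 0.0)

    @pytest.mark.parametrize(
        "k, alpha0, expected",
        [(0, 1.0, 1.0), (9, 1.0, 1.0), (10, 1.0, 0.95), (25, 0.1, 0.1 * 0.95**2)],
    )
    def test_lr_values(self, k, alpha0, expected):
        assert lr_schedule(k, alpha0) == pytest.approx(expected, rel=1e-12)

    def test_lr_non_increasing(self):
        vals = [lr_schedule(k, 1e-3) for k in range(100)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestMakeBatches:
    def test_single_batch_when_b_equals_n(self):
        ids = [f"s{i}" for i in range(10)]
        batches = make_batches(ids, 10, seed=1, epoch=0)
        assert len(batches) == 1
        assert sorted(batches[0]) == sorted(ids)

    def test_partition_sizes_and_coverage(self):
        ids = [f"s{i}" for i in range(10)]
        batches = make_batches(ids, 3, seed=1, epoch=2)
        assert [len(b) for b in batches] == [3, 3, 3, 1]
        assert sorted(x for b in batches for x in b) == sorted(ids)

    def test_fresh_partition_each_epoch(self):
        ids = [f"s{i}" for i in range(20)]
        assert make_batches(ids, 5, 0, 0) != make_batches(ids, 5, 0, 1)
        assert make_batches(ids, 5, 0, 3) == make_batches(ids, 5, 0, 3)

    def test_cobatch_rate_matches_closed_form(self):
        # Monte-Carlo co-occurrence of a fixed pair vs the B/N approximation
        ids = [f"s{i}" for i in range(40)]
        B, epochs = 8, 2000
        together = 0
        for e in range(epochs):
            for batch in make_batches(ids, B, seed=3, epoch=e):
                if "s0" in batch and "s1" in batch:
                    together += 1
        rate = together / epochs
        approx = B / len(ids)
        # exact per-epoch probability is (B-1)/(N-1); the B/N approximation
        # is close for these sizes
        se = np.sqrt(approx * (1 - approx) / epochs)
        assert abs(rate - approx) < 4 * se + 0.02


@pytest.fixture(scope="module")
def tiny_problem():
    tree = random_binary_tree(SimulationConfig(n_leaves=8, seed=21))
    aln = simulate_jc_alignment(tree, 80, seed=22)
    return tree, aln


class TestTrainLoop:
    def make_model(self, aln, mode="loid"):
        spec = EncoderSpec(input_length=aln.length, embed_dim=2, channels=(4, 6, 6), seed=0)
        return encoder_init(spec, mode=mode)

    def test_zero_epochs_returns_model_unchanged(self, tiny_problem):
        tree, aln = tiny_problem
        model = self.make_model(aln)
        out, log = train(model, aln, tree, TrainingConfig(epochs=0))
        assert log == []
        for k in model.params:
            assert np.array_equal(out.params[k], model.params[k])

    def test_loss_decreases(self, tiny_problem):
        tree, aln = tiny_problem
        model = self.make_model(aln)
        _, log = train(model, aln, tree, TrainingConfig(epochs=60, seed=4))
        assert log[-1]["loss"] < log[0]["loss"]
        assert all(rec["s"] > 0 for rec in log)

    def test_determinism(self, tiny_problem):
        tree, aln = tiny_problem
        cfg = TrainingConfig(epochs=12, seed=9)
        _, log1 = train(self.make_model(aln), aln, tree, cfg)
        _, log2 = train(self.make_model(aln), aln, tree, cfg)
        assert log1 == log2

    def test_label_mismatch_reported(self, tiny_problem):
        tree, aln = tiny_problem
        bad = aln.subset(aln.ids[:-1])
        with pytest.raises(ValueError, match="differ"):
            train(self.make_model(bad), bad, tree, TrainingConfig(epochs=1))

    def test_duplicate_sequences_rejected(self, tiny_problem):
        tree, _ = tiny_problem
        from hyperplace.alignio import Alignment
        from hyperplace.trees import leaf_labels

        ids = leaf_labels(tree)
        rows = ["ACGT" * 5] * len(ids)
        dup = Alignment(ids, rows)
        model = self.make_model(dup)
        with pytest.raises(ValueError, match="duplicate"):
            train(model, dup, tree, TrainingConfig(epochs=1))

    def test_scale_per_epoch_variant_runs(self, tiny_problem):
        tree, aln = tiny_problem
        _, log = train(
            self.make_model(aln), aln, tree,
            TrainingConfig(epochs=5, scale_per="epoch", seed=1),
        )
        assert len(log) == 5


class TestTangentGradient:
    @pytest.mark.parametrize("mode", ["loid", "poincare", "euclidean"])
    def test_matches_finite_differences(self, mode, rng):
        n, d = 6, 3
        V = rng.normal(size=(n, d))
        T = np.abs(rng.normal(size=(n, n))) + 0.3
        T = (T + T.T) / 2
        np.fill_diagonal(T, 0)
        s = 1.2
        _, dV, _ = loss_and_tangent_grad(V, T, s, mode)
        eps = 1e-6
        for i in range(n):
            for j in range(d):
                Vp, Vm = V.copy(), V.copy()
                Vp[i, j] += eps
                Vm[i, j] -= eps
                lp, _, _ = loss_and_tangent_grad(Vp, T, s, mode)
                lm, _, _ = loss_and_tangent_grad(Vm, T, s, mode)
                assert dV[i, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-8)

    def test_closed_form_scale_minimises_cost(self, rng):
        # optimal_scale minimises the weighted cost for a fixed embedding
        V = rng.normal(size=(8, 2))
        D = pairwise_unit_distances(V, "loid")
        iu, ju = np.triu_indices(8, k=1)
        t = np.abs(rng.normal(size=iu.size)) + 0.2
        s_star = optimal_scale(D[iu, ju], t)
        cost = lambda s: float(np.mean((s * D[iu, ju] / t - 1) ** 2))
        for s in np.linspace(0.01, 5, 500):
            assert cost(s_star) <= cost(s) + 1e-12
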