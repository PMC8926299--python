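"""Network assembly, neuron labeling, fused inference and evaluation."""

import numpy as np
import pytest

from resom.hebbian import LateralMatrix
from resom.model import (
    LabelingCoefficients,
    MapSpec,
    ReSOM,
    ResomModel,
    build_resom,
)
from resom.som import ActivationParams, SomGrid, activations, find_bmu
from resom.synthetic import MultimodalDataset


def toy_model(rng, k=2, side=2, dim=3, n_classes=3, labeled=True):
    """Random small network with random nonnegative laterals and labels."""
    n = side * side
    maps = [SomGrid(side, side, rng.uniform(size=(n, dim))) for _ in range(k)]
    laterals = {
        (x, y): LateralMatrix(x, y, rng.uniform(size=(n, n)) *
                              (rng.uniform(size=(n, n)) > 0.3))
        for x in range(k) for y in range(x + 1, k)
    }
    model = ResomModel(maps=maps,
                       act_params=[ActivationParams(0.5)] * k,
                       laterals=laterals)
    if labeled:
        data = MultimodalDataset(
            [rng.uniform(size=(3 * n_classes, dim)) for _ in range(k)],
            np.repeat(np.arange(n_classes), 3),
        )
        model.label_neurons(data, n_classes=n_classes)
    return model


class TestBuildResom:
    @pytest.mark.parametrize("k,n_lat", [(7, 21), (1, 0), (4, 6)])
    def test_lateral_matrix_count(self, k, n_lat):
        model = build_resom([MapSpec(3, 3, 5)] * k)
        assert len(model.laterals) == n_lat

    def test_lateral_shapes_match_maps(self):
        specs = [MapSpec(2, 2, 4), MapSpec(3, 2, 4), MapSpec(4, 1, 4), MapSpec(2, 3, 4)]
        model = build_resom(specs)
        for (x, y), lat in model.laterals.items():
            assert lat.W.shape == (model.maps[x].n_neurons, model.maps[y].n_neurons)
            assert not lat.W.any()

    def test_default_alpha_is_input_dim(self):
        model = build_resom([MapSpec(2, 2, 7)])
        assert model.act_params[0].alpha == 7


class TestLateralActivity:
    def test_zero_weight_gives_zero(self, rng):
        model = toy_model(rng, labeled=False)
        model.laterals[(0, 1)].W[:] = 0
        assert model.lateral_activity(1.0, 0, 1, 0, 0) == 0.0

    def test_identity_scaling(self, rng):
        model = toy_model(rng, labeled=False)
        model.laterals[(0, 1)].W[2, 3] = 0.25
        assert model.lateral_activity(1.0, 0, 1, 2, 3) == 0.25

    def test_scalar_product_both_orientations(self, rng):
        model = toy_model(rng, labeled=False)
        W = model.laterals[(0, 1)].W
        assert model.lateral_activity(0.6, 0, 1, 1, 2) == pytest.approx(0.6 * W[1, 2])
        assert model.lateral_activity(0.6, 1, 0, 2, 1) == pytest.approx(0.6 * W[1, 2])

    def test_index_error(self, rng):
        model = toy_model(rng, labeled=False)
        with pytest.raises(IndexError):
            model.lateral_activity(1.0, 0, 1, 99, 0)


class TestLabelingActivation:
    def test_unimodal_is_scaled_afferent(self, rng):
        model = toy_model(rng, labeled=False)
        sample = [rng.uniform(size=3) for _ in range(2)]
        coeffs = LabelingCoefficients.unimodal(2)
        a, _ = activations(model.maps[0], sample[0], model.act_params[0])
        for s in range(4):
            assert model.labeling_activation(sample, 0, s, coeffs) == pytest.approx(a[s])

    def test_divergence_is_pure_lateral(self, rng):
        model = toy_model(rng, labeled=False)
        sample = [rng.uniform(size=3) for _ in range(2)]
        coeffs = LabelingCoefficients.divergence(2)
        bmu1 = find_bmu(model.maps[1], sample[1])
        _, a1 = activations(model.maps[1], sample[1], model.act_params[1])
        W = model.laterals[(0, 1)].W
        for s in range(4):
            expected = a1 * W[s, bmu1]   # source 1 -> target 0 is the transpose
            assert model.labeling_activation(sample, 0, s, coeffs) == pytest.approx(expected)

    def test_hand_worked_mixed_case(self):
        # two 2x1 maps in 1-D with hand-set prototypes and lateral weights
        maps = [SomGrid(2, 1, np.array([[0.0], [1.0]])),
                SomGrid(2, 1, np.array([[0.0], [1.0]]))]
        W = np.array([[0.5, 0.1], [0.2, 0.8]])
        model = ResomModel(
            maps=maps, act_params=[ActivationParams(1.0)] * 2,
            laterals={(0, 1): LateralMatrix(0, 1, W)},
        )
        coeffs = LabelingCoefficients.mixed([0.5, 0.5], np.array([[0, 1.0], [1.0, 0]]))
        sample = [np.array([0.0]), np.array([1.0])]
        # afferent on map 0: a = [1, e^-1]; map 1 BMU = 1 with a = 1
        got = model.labeling_activation(sample, 0, 0, coeffs)
        assert got == pytest.approx(0.5 * 1.0 + 1.0 * 1.0 * W[0, 1])
        got = model.labeling_activation(sample, 0, 1, coeffs)
        assert got == pytest.approx(0.5 * np.exp(-1.0) + 1.0 * 1.0 * W[1, 1])


class TestLabelNeurons:
    def test_single_class_dominates(self, rng):
        model = toy_model(rng, labeled=False)
        data = MultimodalDataset([rng.uniform(size=(6, 3)) for _ in range(2)],
                                 np.full(6, 2), )
        with pytest.warns(UserWarning, match="covers"):
            table = model.label_neurons(data, n_classes=4)
        for j in range(2):
            assert np.all(table.assigned[j] == 2)
            np.testing.assert_allclose(table.probs[j][:, 2], 1.0)

    def test_probability_rows_sum_to_one(self, rng):
        model = toy_model(rng, n_classes=4)
        for p in model.label_table.probs:
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(p >= 0)

    def test_matches_scalar_oracle(self, rng):
        model = toy_model(rng, labeled=False)
        n_cls = 3
        data = MultimodalDataset([rng.uniform(size=(9, 3)) for _ in range(2)],
                                 np.repeat(np.arange(n_cls), 3))
        coeffs = LabelingCoefficients.unimodal(2)
        table = model.label_neurons(data, coeffs, n_classes=n_cls)
        for j in range(2):
            for s in range(4):
                sums = np.zeros(n_cls)
                for i in range(9):
                    sample = [X[i] for X in data.modalities]
                    sums[data.labels[i]] += model.labeling_activation(sample, j, s, coeffs)
                np.testing.assert_allclose(table.probs[j][s], sums / sums.sum(),
                                           atol=1e-12)

    def test_empty_subset_rejected(self, rng):
        model = toy_model(rng, labeled=False)
        empty = MultimodalDataset([np.empty((0, 3))] * 2, np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            model.label_neurons(empty)

    def test_warns_on_missing_classes(self, rng):
        model = toy_model(rng, labeled=False)
        data = MultimodalDataset([rng.uniform(size=(4, 3))] * 2, np.array([0, 0, 1, 1]))
        with pytest.warns(UserWarning, match="covers"):
            model.label_neurons(data, n_classes=5)


class TestResomActivation:
    def test_single_map_reduces_to_afferent(self, rng):
        model = toy_model(rng, k=1, labeled=False)
        v = rng.uniform(size=3)
        fused = model.resom_activation([v])
        a, _ = activations(model.maps[0], v, model.act_params[0])
        assert np.array_equal(fused[0], a)

    def test_zero_lateral_annihilates(self, rng):
        model = toy_model(rng, labeled=False)
        model.laterals[(0, 1)].W[:] = 0
        fused = model.resom_activation([rng.uniform(size=3)] * 2)
        assert not fused[0].any() and not fused[1].any()

    def test_hand_worked_two_map_case(self):
        maps = [SomGrid(2, 1, np.array([[0.0], [1.0]])),
                SomGrid(2, 1, np.array([[0.25], [0.75]]))]
        W = np.array([[0.5, 0.1], [0.2, 0.8]])
        model = ResomModel(maps=maps, act_params=[ActivationParams(1.0)] * 2,
                           laterals={(0, 1): LateralMatrix(0, 1, W)})
        sample = [np.array([0.1]), np.array([0.9])]
        # map0 afferent: exp(-0.1), exp(-0.9); BMU 0, a0 = exp(-0.1)
        # map1 afferent: exp(-0.65), exp(-0.15); BMU 1, a1 = exp(-0.15)
        fused = model.resom_activation(sample)
        a0 = np.exp([-0.1, -0.9])
        a1 = np.exp([-0.65, -0.15])
        np.testing.assert_allclose(fused[0], a0 * (a1[1] * W[:, 1]), atol=1e-14)
        np.testing.assert_allclose(fused[1], a1 * (a0[0] * W[0, :]), atol=1e-14)

    def test_missing_modality_rejected(self, rng):
        model = toy_model(rng, labeled=False)
        with pytest.raises(ValueError):
            model.resom_activation([rng.uniform(size=3)])


class TestPredict:
    def test_matches_bruteforce_argmax_on_random_models(self, rng):
        for _ in range(100):
            model = toy_model(rng, k=rng.integers(1, 4))
            sample = [rng.uniform(size=3) for _ in range(model.k)]
            cls, j_max, s_max = model.predict(sample)
            fused = model.resom_activation(sample)
            flat = np.concatenate(fused)
            if flat.any():
                best = int(flat.argmax())
            else:
                best = int(np.concatenate(
                    [activations(g, v, p)[0] for g, v, p in
                     zip(model.maps, sample, model.act_params)]).argmax())
            exp_j, exp_s = 0, best
            while exp_s >= model.maps[exp_j].n_neurons:
                exp_s -= model.maps[exp_j].n_neurons
                exp_j += 1
            assert (j_max, s_max) == (exp_j, exp_s)
            assert cls == model.label_table.assigned[exp_j][exp_s]

    def test_all_zero_fused_falls_back_to_afferent(self, rng):
        model = toy_model(rng)
        for lat in model.laterals.values():
            lat.W[:] = 0
        sample = [rng.uniform(size=3) for _ in range(2)]
        cls, j_max, s_max = model.predict(sample)
        affs = [activations(g, v, p)[0] for g, v, p in
                zip(model.maps, sample, model.act_params)]
        best = int(np.concatenate(affs).argmax())
        assert (j_max, s_max) == (best // 4, best % 4)
        assert cls == model.label_table.assigned[j_max][s_max]

    def test_unlabeled_model_rejected(self, rng):
        model = toy_model(rng, labeled=False)
        with pytest.raises(RuntimeError):
            model.predict([rng.uniform(size=3)] * 2)

    def test_batch_agrees_with_scalar_path(self, rng):
        model = toy_model(rng, k=2)
        data = MultimodalDataset([rng.uniform(size=(25, 3))] * 2,
                                 rng.integers(0, 3, 25))
        batch = model.predict_batch(data)
        single = [model.predict([X[i] for X in data.modalities])[0]
                  for i in range(25)]
        assert np.array_equal(batch, np.array(single))


class TestEvaluate:
    def test_perfect_predictor_diagonal_confusion(self, rng):
        model = toy_model(rng, k=1, n_classes=2)
        # relabel every neuron to class 0 and test on all-zero labels
        model.label_table.assigned[0][:] = 0
        data = MultimodalDataset([rng.uniform(size=(10, 3))], np.zeros(10, dtype=int))
        rep = model.evaluate(data)
        assert rep.accuracy == 1.0
        assert rep.confusion[0, 0] == 10 and rep.confusion.sum() == 10

    def test_confusion_tally_matches_manual_count(self, rng):
        model = toy_model(rng, k=2, n_classes=3)
        data = MultimodalDataset([rng.uniform(size=(30, 3))] * 2,
                                 rng.integers(0, 3, 30))
        rep = model.evaluate(data)
        pred = model.predict_batch(data)
        manual = np.zeros((3, 3), dtype=int)
        for t, p in zip(data.labels, pred):
            manual[t, p] += 1
        assert np.array_equal(rep.confusion, manual)
        assert rep.confusion.sum() == 30
        assert rep.accuracy == pytest.approx(np.trace(manual) / 30)

    def test_empty_test_set_rejected(self, rng):
        model = toy_model(rng, k=1)
        empty = MultimodalDataset([np.empty((0, 3))], np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            model.evaluate(empty)


class TestEstimator:
    def test_fit_is_deterministic(self, small_benchmark):
        spec, train, label, test, res = small_benchmark
        res2 = ReSOM(train, [(6, 6), (6, 6)], epochs=3).fit(
            label_data=label, n_classes=spec.n_classes, seed=7)
        for g1, g2 in zip(res.model.maps, res2.model.maps):
            assert np.array_equal(g1.weights, g2.weights)
        assert np.array_equal(res.model.laterals[(0, 1)].W,
                              res2.model.laterals[(0, 1)].W)

    def test_results_accuracy_reasonable(self, small_benchmark):
        spec, train, label, test, res = small_benchmark
        rep = res.evaluate(test)
        assert 0.5 < rep.accuracy <= 1.0

    def test_summary_mentions_structure(self, small_benchmark):
        *_, res = small_benchmark
        text = res.summary()
        assert "modalities:        2" in text
        assert "lateral (0,1)" in text
        assert "label table" in text

    def test_prune_keep_one_is_identity(self, small_benchmark):
        *_, res = small_benchmark
        pruned = res.prune(1.0)
        assert np.array_equal(pruned.model.laterals[(0, 1)].W,
                              res.model.laterals[(0, 1)].W)

    def test_auto_alpha_equals_quantization_error(self, small_benchmark):
        *_, res = small_benchmark
        assert res.alphas == pytest.approx(res.quantization_errors)


class TestLabelingCoefficients:
    def test_mode_detection(self):
        assert LabelingCoefficients.unimodal(3).mode == "unimodal"
        assert LabelingCoefficients.divergence(3).mode == "divergence"
        mixed = LabelingCoefficients.mixed([1, 1], np.array([[0, 0.5], [0.5, 0]]))
        assert mixed.mode == "mixed"

    def test_range_validation(self):
        with pytest.raises(ValueError):
            LabelingCoefficients(np.array([1.5]), np.zeros((1, 1)))
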