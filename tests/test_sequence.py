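"""Sequence fusion: losses against scalar oracles, shuffle, stitch, LSTM wiring."""

import numpy as np
import pytest

from pyrascreen import nn
from pyrascreen.backbone import BackboneConfig, build_deconvnet
from pyrascreen.search import LocationCode
from pyrascreen.sequence import (LossWeights, SequenceDensityCounter,
                                 dimension_shuffle, encode_sequence,
                                 integrated_count, loss_lstm, loss_tissue,
                                 lstm_residual, stitch_density, total_loss)


class TestLossOracles:
    """The closed-form losses agree with direct scalar-loop evaluation."""

    def test_tissue_loss_hand_value(self):
        # N=1, single-pixel maps: (1/2) * (3-1)^2 = 2
        assert loss_tissue([np.array([[3.0]])], [np.array([[1.0]])]) == 2.0

    def test_lstm_loss_hand_value(self):
        # N=2, errors (1, -1): (1/4) * 2 = 0.5
        assert loss_lstm([1.0, 2.0], [0.0, 3.0]) == 0.5

    def test_perfect_prediction_zero(self, rng):
        maps = [rng.random((6, 6)) for _ in range(3)]
        assert loss_tissue(maps, maps) == 0.0
        assert loss_lstm([4.0, 5.0], [4.0, 5.0]) == 0.0

    def test_duplication_invariance(self, rng):
        pred = [rng.random((5, 5)) for _ in range(2)]
        gt = [rng.random((5, 5)) for _ in range(2)]
        assert loss_tissue(pred * 2, gt * 2) == pytest.approx(
            loss_tissue(pred, gt), rel=1e-12)

    def test_quadratic_scaling(self):
        base = loss_lstm([1.0, -2.0], [0.0, 0.0])
        assert loss_lstm([3.0, -6.0], [0.0, 0.0]) == pytest.approx(9 * base)

    def test_random_inputs_match_scalar_loops(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 5))
            h, w = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            pred = [rng.standard_normal((h, w)) for _ in range(n)]
            gt = [rng.standard_normal((h, w)) for _ in range(n)]
            T = rng.standard_normal(n)
            T0 = rng.standard_normal(n)
            alpha = float(rng.uniform(0, 2))
            # brute-force scalar loops
            lt = sum((pred[i][r, c] - gt[i][r, c]) ** 2
                     for i in range(n) for r in range(h) for c in range(w)) / (2 * n)
            ll = sum((T[i] - T0[i]) ** 2 for i in range(n)) / (2 * n)
            assert loss_tissue(pred, gt) == pytest.approx(lt, abs=1e-9)
            assert loss_lstm(T, T0) == pytest.approx(ll, abs=1e-9)
            assert total_loss(lt, ll, LossWeights(alpha)) == pytest.approx(
                lt + alpha * ll, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_tissue([np.zeros((2, 2))], [np.zeros((3, 3))])
        with pytest.raises(ValueError):
            loss_lstm([1.0], [1.0, 2.0])

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)
        assert total_loss(2.0, 0.5, LossWeights(0.1)) == pytest.approx(2.05)
        assert total_loss(2.0, 123.0, LossWeights(0.0)) == 2.0


class TestDimensionShuffle:
    def test_descriptor_sum_equals_integral(self, rng):
        maps = rng.random((5, 64, 64))
        desc = dimension_shuffle(maps)
        np.testing.assert_allclose(desc.sum(axis=1), maps.sum(axis=(1, 2)),
                                   rtol=1e-12)

    def test_order_and_length_preserved(self, rng):
        maps = rng.random((7, 32, 32))
        desc = dimension_shuffle(maps)
        assert desc.shape == (7, 16)
        np.testing.assert_allclose(desc[3], dimension_shuffle(maps[3:4])[0])

    def test_identical_maps_identical_descriptors(self):
        maps = np.ones((4, 16, 16))
        desc = dimension_shuffle(maps)
        assert np.all(desc == desc[0])

    def test_uneven_dims_partition(self, rng):
        maps = rng.random((2, 10, 13))
        desc = dimension_shuffle(maps, grid=(3, 4))
        np.testing.assert_allclose(desc.sum(axis=1), maps.sum(axis=(1, 2)))


class TestEncodeSequence:
    def test_single_element_matches_predict_density(self, rng):
        from pyrascreen.backbone import predict_density

        model = build_deconvnet(BackboneConfig(base_filters=4), seed=0)
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        np.testing.assert_allclose(encode_sequence(model, img[None])[0],
                                   predict_density(model, img), atol=1e-6)

    def test_permutation_equivariance(self, rng):
        model = build_deconvnet(BackboneConfig(base_filters=4), seed=0)
        imgs = rng.integers(0, 256, (4, 32, 32, 3), dtype=np.uint8)
        F = encode_sequence(model, imgs)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(encode_sequence(model, imgs[perm]), F[perm],
                                   atol=1e-6)

    def test_mixed_sizes_rejected(self, rng):
        model = build_deconvnet(BackboneConfig(base_filters=4), seed=0)
        with pytest.raises(ValueError, match="mixed"):
            encode_sequence(model, [np.zeros((32, 32, 3)), np.zeros((64, 64, 3))])


class TestLstmResidual:
    def test_zero_readout_zero_residual(self, rng):
        lstm = nn.LSTM(16, 10, rng)
        readout = nn.Dense(10, 1, rng)
        readout.w[...] = 0
        readout.b[...] = 0
        R = lstm_residual(rng.random((5, 16)), lstm, readout)
        np.testing.assert_allclose(R, 0.0)

    def test_deterministic(self, rng):
        lstm = nn.LSTM(16, 10, rng)
        readout = nn.Dense(10, 1, rng)
        d = rng.random((5, 16))
        np.testing.assert_array_equal(lstm_residual(d, lstm, readout),
                                      lstm_residual(d, lstm, readout))


def test_integrated_count_arithmetic():
    assert integrated_count(np.full((5, 5), 0.5), 0.0) == pytest.approx(12.5)
    assert integrated_count(np.full((2, 5), 1.0), -2.0) == pytest.approx(8.0)
    assert integrated_count(np.zeros((4, 4)), 3.25) == pytest.approx(3.25)


class TestStitchDensity:
    def test_single_patch_identity(self, rng):
        m = rng.random((32, 32))
        lci = LocationCode("", start_level=2, root=(0, 0))
        out = stitch_density([m], [lci], (32, 32), patch_size=32)
        np.testing.assert_array_equal(out, m)

    def test_integral_additive_and_roundtrip(self, rng):
        maps = [rng.random((16, 16)) for _ in range(4)]
        lcis = [LocationCode(q, start_level=3, root=(0, 0)) for q in "0123"]
        out = stitch_density(maps, lcis, (32, 32), patch_size=16)
        assert out.sum() == pytest.approx(sum(m.sum() for m in maps))
        # re-tiling recovers each map at its decoded location
        np.testing.assert_array_equal(out[:16, :16], maps[0])
        np.testing.assert_array_equal(out[:16, 16:], maps[1])
        np.testing.assert_array_equal(out[16:, :16], maps[2])
        np.testing.assert_array_equal(out[16:, 16:], maps[3])

    def test_overlap_rejected(self, rng):
        m = rng.random((16, 16)) + 0.5
        lci = LocationCode("0", start_level=3, root=(0, 0))
        with pytest.raises(ValueError, match="overlap"):
            stitch_density([m, m], [lci, lci], (32, 32), patch_size=16)


def test_joint_training_recovers_tumor_masses():
    """Jointly trained channel-FCN + LSTM recovers per-patch tumor masses on
    held-out 4-patch 64x64 sequences to within 20% of the mean true mass."""
    from pyrascreen.bench import lstm_recovery_benchmark

    out = lstm_recovery_benchmark(seed=0)
    assert out["relative_count_error"] <= 0.2


def test_alpha_zero_keeps_lstm_readout_gradients_zero(rng):
    """With alpha = 0 the composite loss carries no gradient into the LSTM
    readout (exact zero, not merely small)."""
    from pyrascreen.synthetic import generate_sequence_dataset

    seqs = generate_sequence_dataset(2, seq_len=3, size=32, seed=0)
    model = SequenceDensityCounter(base_filters=4, alpha=0.0, epochs=1,
                                   random_state=0)
    model._build((32, 32))
    params = (model.cfcn_.parameters("density") + model.lstm_.params()
              + model.readout_.params())
    opt = nn.Adam(params, lr=1e-3)
    opt.zero_grad()
    model._step(seqs, opt, lr=0.0)
    for _, g in model.lstm_.params() + model.readout_.params():
        np.testing.assert_array_equal(g, 0.0)
    # ...while the CFCN does receive gradient from L_t
    assert any(np.abs(g).max() > 0 for _, g in model.cfcn_.parameters("density"))
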