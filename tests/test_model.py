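"""Model: shape laws, attention normalization, spatial reduction, feature
fusion, the differentiable orthogonal layer, and checkpoint round-trips."""

import numpy as np
import pytest

import vhsnet.autodiff as ad
from vhsnet.autodiff import Parameter, Tensor
from vhsnet.errors import ConfigError, FormatError, ShapeError
from vhsnet.geometry import flatten, orthogonalize, unflatten
from vhsnet.model import (ModelConfig, RVTModel, SpatialReduction, SRAttention,
                          load_checkpoint, orthogonal_layer, save_checkpoint,
                          scaled_dot_attention, upsample_bilinear, vhs_from_flat)


@pytest.fixture(scope="module")
def desk_model():
    return RVTModel(ModelConfig.desk(), seed=0)


@pytest.fixture(scope="module")
def images(request):
    rng = np.random.default_rng(5)
    return rng.random((4, 96, 96, 3)).astype(np.float32)


class TestConfig:
    def test_full_preset_strides(self):
        cfg = ModelConfig.full()
        assert cfg.grid_sizes() == [128, 64, 32, 16]   # /4, /8, /16, /32

    @pytest.mark.parametrize("kwargs", [
        dict(dims=(32, 65)),                       # not divisible by heads=2
        dict(input_size=100),                      # not divisible by patches
        dict(patch_sizes=(6,)),                    # wrong arity
        dict(head_mode="nope"),
        dict(low_stage=2, high_stage=2),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig.desk(**kwargs)

    def test_round_trip_dict(self):
        cfg = ModelConfig.full(use_rel_bias=False)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestSpatialReduction:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        sr = SpatialReduction(rng, dim=16, R=2)
        x = Tensor(rng.normal(size=(3, 64, 16)).astype(np.float32))
        out = sr(x, 8, 8)
        assert out.shape == (3, 16, 16)

    def test_r1_keeps_spatial_size(self):
        rng = np.random.default_rng(0)
        sr = SpatialReduction(rng, dim=8, R=1)
        x = Tensor(rng.normal(size=(2, 36, 8)).astype(np.float32))
        assert sr(x, 6, 6).shape == (2, 36, 8)

    def test_zero_input_zero_projection(self):
        rng = np.random.default_rng(0)
        sr = SpatialReduction(rng, dim=8, R=2)
        x = Tensor(np.zeros((1, 16, 8), dtype=np.float32))
        pre_norm = sr.proj((x.reshape(1, 2, 2, 2, 2, 8)
                            .transpose((0, 1, 3, 2, 4, 5)).reshape(1, 4, 32)))
        np.testing.assert_allclose(pre_norm.data, 0.0)

    def test_indivisible_size_names_dimensions(self):
        rng = np.random.default_rng(0)
        sr = SpatialReduction(rng, dim=8, R=3)
        x = Tensor(np.zeros((1, 64, 8), dtype=np.float32))
        with pytest.raises(ShapeError, match="R=3"):
            sr(x, 8, 8)


class TestAttention:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        attn = SRAttention(rng, dim=16, heads=2, R=2, H=4, W=4, use_rel_bias=True)
        x = Tensor(rng.normal(size=(3, 16, 16)).astype(np.float32))
        _, weights = attn(x, return_weights=True)
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_output_shape_matches_input(self):
        rng = np.random.default_rng(1)
        for heads, R in [(1, 1), (2, 2), (4, 4)]:
            attn = SRAttention(rng, dim=16, heads=heads, R=R, H=8, W=8, use_rel_bias=False)
            x = Tensor(rng.normal(size=(2, 64, 16)).astype(np.float32))
            assert attn(x).shape == x.shape

    def test_single_query_is_softmax_weighted_mean(self):
        """One query over 3 keys with identity values: output equals the
        hand-computed softmax mixture of the value rows."""
        q = Tensor(np.array([[[1.0, 0.0]]]))
        k = Tensor(np.array([[[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]]))
        v = Tensor(np.eye(3)[None].astype(float))
        d = 2
        out, w = scaled_dot_attention(q, k, v, d)
        scores = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        expected = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(w.data[0, 0], expected, atol=1e-12)
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-12)


class TestEncoderAndFusion:
    def test_pyramid_shrinks_and_batch_preserved(self, desk_model, images):
        feats = desk_model.encode(Tensor(images))
        grids = [g for _, g in feats]
        assert grids == desk_model.cfg.grid_sizes()
        assert all(t.shape[0] == 4 for t, _ in feats)
        assert grids[0] > grids[1]

    def test_fused_map_concatenates_channels(self, desk_model, images):
        fused = desk_model.fuse(desk_model.encode(Tensor(images)))
        g = desk_model.cfg.grid_sizes()[0]
        assert fused.shape == (4, g, g, 2 * desk_model.cfg.fusion_channels)

    def test_fusion_example_shapes(self):
        """Low 24x24x64 + high 12x12x128 projected to 64 each -> 24x24x128."""
        rng = np.random.default_rng(3)
        from vhsnet.model import ConvUnit
        low = Tensor(rng.normal(size=(2, 24, 24, 64)).astype(np.float32))
        high = Tensor(rng.normal(size=(2, 12, 12, 128)).astype(np.float32))
        a = ConvUnit(rng, 64, 64)(low)
        b = upsample_bilinear(ConvUnit(rng, 128, 64)(high), 24, 24)
        fused = ad.concat([a, b], axis=-1)
        assert fused.shape == (2, 24, 24, 128)

    def test_no_fusion_uses_high_stage_alone(self, images):
        model = RVTModel(ModelConfig.desk(use_feature_fusion=False), seed=0)
        fused = model.fuse(model.encode(Tensor(images)))
        g_hi = model.cfg.grid_sizes()[1]
        assert fused.shape == (4, g_hi, g_hi, model.cfg.dims[1])

    def test_upsample_constant_preserved(self):
        x = Tensor(np.full((1, 4, 4, 2), 3.5, dtype=np.float32))
        y = upsample_bilinear(x, 8, 8)
        np.testing.assert_allclose(y.data, 3.5, atol=1e-6)

    def test_wrong_input_size_rejected(self, desk_model):
        with pytest.raises(ShapeError):
            desk_model.encode(Tensor(np.zeros((1, 64, 64, 3), dtype=np.float32)))


class TestHeads:
    def test_forward_outputs_in_range(self, desk_model, images):
        coords, logits = desk_model.forward(images)
        assert coords.shape == (4, 12) and logits.shape == (4, 3)
        assert (coords.data > -5).all() and (coords.data < 6).all()
        # non-D slots come straight from the sigmoid
        non_d = np.concatenate([coords.data[:, :6], coords.data[:, 8:]], axis=1)
        assert (non_d > 0).all() and (non_d < 1).all()

    def test_orthogonality_of_predictions(self, desk_model, images):
        coords, _ = desk_model.forward(images)
        for row in coords.data:
            k = unflatten(row.astype(float))
            ab = np.array([k.B.x - k.A.x, k.B.y - k.A.y])
            cd = np.array([k.D.x - k.C.x, k.D.y - k.C.y])
            assert abs(ab @ cd) <= 1e-6 * np.linalg.norm(ab) * np.linalg.norm(cd)

    def test_predict_bundle_invariants(self, desk_model, images):
        preds = desk_model.predict(images, orig_sizes=[(200, 100)] * 4)
        for p in preds:
            assert p.class_probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert p.class_label in (0, 1, 2)
            assert p.vhs > 0
            np.testing.assert_allclose(flatten(p.keypoints_px),
                                       p.keypoints_norm * np.tile([200, 100], 6),
                                       rtol=1e-6)

    def test_soft_vhs_mode_ranks_by_distance(self, images):
        model = RVTModel(ModelConfig.desk(head_mode="soft_vhs"), seed=0)
        coords, logits = model.forward(images)
        vhs = vhs_from_flat(coords.data)
        mids = np.asarray(model.cfg.soft_vhs_mids)
        for v, row in zip(vhs, logits.data):
            assert np.argmax(row) == np.argmin(np.abs(mids - v))

    def test_ablation_variants_run_as_configuration(self, images):
        """P, P+F, P+O and P+F+O are pure configuration switches."""
        for fusion in (False, True):
            for orth in (False, True):
                m = RVTModel(ModelConfig.desk(use_feature_fusion=fusion,
                                              use_orthogonal_layer=orth), seed=0)
                coords, logits = m.forward(images[:2])
                assert coords.shape == (2, 12) and logits.shape == (2, 3)


class TestOrthogonalLayer:
    def test_matches_pure_geometry_on_random_vectors(self, rng):
        """Oracle equivalence with the scalar geometry implementation."""
        vecs = rng.uniform(0, 1, size=(1000, 12))
        out = orthogonal_layer(vecs)
        for vin, vout in zip(vecs, out):
            expected = flatten(orthogonalize(unflatten(vin)))
            np.testing.assert_allclose(vout, expected, rtol=1e-9, atol=1e-12)

    def test_gradient_of_y4_wrt_x4_equals_slope(self):
        """d y4_hat / d x4 = s, checked against central finite differences."""
        base = np.array([0.2, 0.3, 0.7, 0.8, 0.4, 0.6, 0.55, 0.1, 0.3, 0.2, 0.8, 0.25])
        s = -(base[0] - base[2]) / (base[1] - base[3])
        t = Parameter(base.copy())
        out = orthogonal_layer(t)
        out[7].backward()
        assert t.grad[6] == pytest.approx(s, rel=1e-9)
        h = 1e-7
        plus, minus = base.copy(), base.copy()
        plus[6] += h
        minus[6] -= h
        fd = (orthogonal_layer(plus)[7] - orthogonal_layer(minus)[7]) / (2 * h)
        assert t.grad[6] == pytest.approx(fd, rel=1e-5)

    def test_perpendicular_input_is_fixed_point(self):
        vec = np.array([0.5, 0.2, 0.5, 0.8, 0.3, 0.5, 0.7, 0.5, 0.1, 0.1, 0.9, 0.1])
        np.testing.assert_allclose(orthogonal_layer(vec), vec)

    def test_degenerate_branch_changes_x4(self):
        vec = np.array([0.2, 0.5, 0.8, 0.5, 0.4, 0.3, 0.6, 0.7, 0.1, 0.1, 0.9, 0.1])
        out = orthogonal_layer(vec)
        assert out[6] == vec[4] and out[7] == vec[7]

    def test_wrong_width_rejected(self):
        with pytest.raises(FormatError):
            orthogonal_layer(np.zeros(11))


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, desk_model, images, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(desk_model, path)
        clone = load_checkpoint(path)
        a, _ = desk_model.forward(images)
        b, _ = clone.forward(images)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_mismatch_detected(self, desk_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(desk_model, path)
        other = RVTModel(ModelConfig.desk(fusion_channels=16), seed=0)
        state = desk_model.state_dict()
        with pytest.raises(FormatError):
            other.load_state_dict(state)


def test_desk_forward_is_fast_enough(desk_model):
    """Single-image forward completes well under a second on one core."""
    import time
    x = np.zeros((1, 96, 96, 3), dtype=np.float32)
    desk_model.predict(x)  # warm-up
    t0 = time.perf_counter()
    desk_model.predict(x)
    assert time.perf_counter() - t0 < 1.0
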