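import numpy as np
import pytest

from orchard_vqa.autograd import Tensor
from orchard_vqa.errors import InvalidInputError
from orchard_vqa.fusion import (
    BaselineFusion, ClassifierHead, FusionOutput, LowRankCore, TuckerFusion,
    baseline_fuse, build_lowrank_core, classifier_head, full_bilinear_oracle,
    squared_tucker_fuse, tucker_fuse,
)


def small_params(seed=0, R=2, **kw):
    kwargs = dict(d_q=3, d_v=4, n_answers=5, t_q=2, t_v=2, t_o=2, R=R)
    kwargs.update(kw)
    return TuckerFusion(rng=np.random.default_rng(seed), **kwargs)


class TestTuckerFuse:
    def test_zero_question_gives_bias(self, rng):
        params = small_params()
        params.b_f.data = rng.normal(size=5)
        out = tucker_fuse(np.zeros(3), rng.normal(size=4), params)
        np.testing.assert_array_equal(out, params.b_f.data)

    @pytest.mark.parametrize("R", [None, 1, 2])
    def test_matches_oracle(self, R):
        for seed in range(30):
            g = np.random.default_rng(seed)
            params = small_params(seed=seed, R=R)
            q, v = g.normal(size=3), g.normal(size=4)
            np.testing.assert_allclose(
                tucker_fuse(q, v, params),
                full_bilinear_oracle(q, v, params), atol=1e-8)

    def test_linearity_in_question(self, rng):
        params = small_params()
        q, v = rng.normal(size=3), rng.normal(size=4)
        b = params.b_f.data
        f1 = tucker_fuse(q, v, params) - b
        f2 = tucker_fuse(2.5 * q, v, params) - b
        np.testing.assert_allclose(f2, 2.5 * f1, atol=1e-10)

    def test_linearity_in_image(self, rng):
        params = small_params()
        q, v = rng.normal(size=3), rng.normal(size=4)
        b = params.b_f.data
        f1 = tucker_fuse(q, v, params) - b
        f2 = tucker_fuse(q, -3.0 * v, params) - b
        np.testing.assert_allclose(f2, -3.0 * f1, atol=1e-10)

    def test_batched_matches_single(self, rng):
        params = small_params()
        q = rng.normal(size=(6, 3))
        v = rng.normal(size=(6, 4))
        batched = params(q, v).data
        for i in range(6):
            np.testing.assert_allclose(batched[i], params(q[i], v[i]).data,
                                       atol=1e-12)

    def test_dim_mismatch_rejected(self, rng):
        params = small_params()
        with pytest.raises(InvalidInputError):
            tucker_fuse(rng.normal(size=7), rng.normal(size=4), params)

    def test_decomposed_parameter_count_below_full(self):
        params = TuckerFusion(d_q=64, d_v=64, n_answers=50,
                              t_q=16, t_v=16, t_o=16, R=4)
        counts = params.parameter_counts()
        assert counts["decomposed"] < counts["full_tensor"]


class TestSquaredTuckerFuse:
    def test_projected_ones_equals_plain(self, rng):
        params = small_params()
        # choose v so its projection is the all-ones vector
        w = params.W_v_glimpses[0].data          # (4, 2)
        v = np.linalg.lstsq(w.T, np.ones(2), rcond=None)[0]
        q = rng.normal(size=3)
        np.testing.assert_allclose(squared_tucker_fuse(q, v, params),
                                   tucker_fuse(q, v, params), atol=1e-8)

    def test_even_in_image_vector(self, rng):
        params = small_params()
        q, v = rng.normal(size=3), rng.normal(size=4)
        np.testing.assert_allclose(squared_tucker_fuse(q, v, params),
                                   squared_tucker_fuse(q, -v, params),
                                   atol=1e-12)

    @pytest.mark.parametrize("R", [None, 2])
    def test_matches_modified_oracle(self, R):
        for seed in range(30):
            g = np.random.default_rng(seed + 100)
            params = small_params(seed=seed, R=R)
            q, v = g.normal(size=3), g.normal(size=4)
            np.testing.assert_allclose(
                squared_tucker_fuse(q, v, params),
                full_bilinear_oracle(q, v, params, squared=True), atol=1e-8)

    def test_quadratic_in_projected_image(self, rng):
        params = small_params()
        q, v = rng.normal(size=3), rng.normal(size=4)
        b = params.b_f.data
        f1 = squared_tucker_fuse(q, v, params) - b
        f2 = squared_tucker_fuse(q, 2.0 * v, params) - b
        np.testing.assert_allclose(f2, 4.0 * f1, atol=1e-9)


class TestLowRankCore:
    def test_rank_one_slices(self):
        core = build_lowrank_core(2, 2, 1, R=1, seed=0)
        dense = core.dense()
        assert np.linalg.matrix_rank(dense[:, :, 0]) == 1

    def test_full_rank_represents_any_matrix(self, rng):
        t_q = t_v = 4
        core = build_lowrank_core(t_q, t_v, 1, R=min(t_q, t_v), seed=0)
        target = rng.normal(size=(t_q, t_v))
        u, s, vt = np.linalg.svd(target)
        core.A.data = (u[:, :4] * s).T[None, :, :]       # (t_o=1, R, t_q)
        core.B.data = vt[:4][None, :, :]                 # (t_o=1, R, t_v)
        np.testing.assert_allclose(core.dense()[:, :, 0], target, atol=1e-6)

    def test_parameter_count_formula(self):
        t_q, t_v, t_o, R = 3, 5, 7, 2
        core = build_lowrank_core(t_q, t_v, t_o, R, seed=1)
        assert core.num_parameters() == t_o * R * (t_q + t_v)

    def test_contract_consistent_with_dense(self, rng):
        core = build_lowrank_core(3, 4, 5, R=2, seed=2)
        qp = rng.normal(size=(2, 3))
        vp = rng.normal(size=(2, 4))
        got = core.contract(Tensor(qp), Tensor(vp)).data
        want = np.einsum("abo,na,nb->no", core.dense(), qp, vp)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_invalid_rank(self):
        with pytest.raises(InvalidInputError):
            build_lowrank_core(2, 2, 2, R=0)


class TestOracle:
    def test_single_core_entry_identity_factors(self):
        params = small_params(d_q=2, d_v=2, n_answers=2, t_q=2, t_v=2, t_o=2,
                              R=None)
        params.W_q.data = np.eye(2)
        params.W_v_glimpses[0].data = np.eye(2)
        params.W_o.data = np.eye(2)
        params.b_f.data = np.zeros(2)
        params.core.core.data = np.zeros((2, 2, 2))
        params.core.core.data[1, 0, 1] = 1.0     # (i=1, j=0, k=1)
        q, v = np.array([2.0, 3.0]), np.array([5.0, 7.0])
        out = full_bilinear_oracle(q, v, params)
        np.testing.assert_allclose(out, [0.0, 3.0 * 5.0], atol=1e-12)

    def test_zero_core_gives_bias(self, rng):
        params = small_params(R=None)
        params.core.core.data[...] = 0.0
        params.b_f.data = rng.normal(size=5)
        out = full_bilinear_oracle(rng.normal(size=3), rng.normal(size=4), params)
        np.testing.assert_allclose(out, params.b_f.data, atol=1e-12)

    def test_size_guard(self, rng):
        params = TuckerFusion(d_q=200, d_v=200, n_answers=100,
                              t_q=2, t_v=2, t_o=2, R=1)
        with pytest.raises(InvalidInputError):
            full_bilinear_oracle(rng.normal(size=200), rng.normal(size=200),
                                 params)


class TestBaselines:
    def test_concat_preprojection_length(self, rng):
        fusion = BaselineFusion("concat", d_q=3, d_v=4, out_dim=6, rng=rng)
        assert fusion.proj.weight.shape == (7, 6)

    def test_mlb_zero_input_gives_zero(self, rng):
        fusion = BaselineFusion("mlb", d_q=3, d_v=4, out_dim=6, rng=rng)
        out = baseline_fuse(np.zeros(3), rng.normal(size=4), fusion)
        np.testing.assert_array_equal(out, np.zeros(6))

    def test_mutan_is_tucker_code_path(self, rng):
        fusion = BaselineFusion("mutan", d_q=3, d_v=4, out_dim=5,
                                rng=np.random.default_rng(3),
                                t_q=2, t_v=2, t_o=2, R=2)
        q, v = rng.normal(size=3), rng.normal(size=4)
        np.testing.assert_array_equal(baseline_fuse(q, v, fusion),
                                      tucker_fuse(q, v, fusion.tucker))

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            BaselineFusion("outer", 3, 4, 5)


class TestClassifierHead:
    def test_probabilities_valid(self, rng):
        head = ClassifierHead(d=6, n_answers=4, d_z=8, rng=rng)
        out = classifier_head(rng.normal(size=6), rng.normal(size=6), head)
        assert np.all(out.probabilities > 0)
        np.testing.assert_allclose(out.probabilities.sum(), 1.0, atol=1e-12)
        assert out.prediction == int(np.argmax(out.logits))

    def test_uniform_logits_uniform_probabilities(self):
        out = FusionOutput.from_logits(np.full(5, 1.7))
        np.testing.assert_allclose(out.probabilities, 0.2, atol=1e-12)

    def test_layernorm_pre_affine_moments(self, rng):
        head = ClassifierHead(d=6, n_answers=4, d_z=32, rng=rng)
        x, y = rng.normal(size=6), rng.normal(size=6)
        z = head.ln.normalized(
            Tensor(x) @ head.W_x + Tensor(y) @ head.W_y).data
        assert abs(z.mean()) < 1e-6
        np.testing.assert_allclose(z.var(), 1.0, atol=1e-6)

    def test_dim_mismatch_rejected(self, rng):
        head = ClassifierHead(d=6, n_answers=4, d_z=8, rng=rng)
        with pytest.raises(InvalidInputError):
            head.fused(rng.normal(size=5), rng.normal(size=6))


class TestGradients:
    @pytest.mark.parametrize("squared", [False, True])
    def test_fusion_gradients_match_finite_differences(self, squared):
        params = small_params(seed=7)
        g = np.random.default_rng(8)
        q = Tensor(g.normal(size=3), requires_grad=True)
        v = Tensor(g.normal(size=4), requires_grad=True)
        weights = g.normal(size=5)

        def loss_value():
            return float((params(q, v, squared=squared).data * weights).sum())

        out = (params(q, v, squared=squared) * weights).sum()
        out.backward()
        eps = 1e-6
        for t in [q, v, params.W_q, params.W_v_glimpses[0],
                  params.core.A, params.core.B, params.W_o, params.b_f]:
            flat = t.data.reshape(-1)
            num = np.zeros_like(flat)
            for i in range(flat.size):
                old = flat[i]
                flat[i] = old + eps
                hi = loss_value()
                flat[i] = old - eps
                lo = loss_value()
                flat[i] = old
                num[i] = (hi - lo) / (2 * eps)
            np.testing.assert_allclose(t.grad.reshape(-1), num, atol=1e-4,
                                       rtol=1e-4)


class TestGlimpses:
    def test_multi_glimpse_changes_core_width(self):
        params = small_params(G=3)
        assert params.core.t_v == 6
        assert len(params.W_v_glimpses) == 3

    def test_multi_glimpse_matches_oracle(self, rng):
        params = small_params(seed=4, G=2)
        q, v = rng.normal(size=3), rng.normal(size=4)
        np.testing.assert_allclose(tucker_fuse(q, v, params),
                                   full_bilinear_oracle(q, v, params),
                                   atol=1e-8)
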