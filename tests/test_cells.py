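"""Unit and property tests for the BRC/nBRC/GRU update rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bistablernn.cells import (DimensionError, brc_gates, brc_step, gru_step,
                               init_weights, load_weights, nbrc_gates,
                               nbrc_step, save_weights, step, unroll)
from bistablernn.bptt import backward_layer, forward_layer

from conftest import scalar_brc, zero_cell, zero_gru

ATANH_HALF = np.arctanh(0.5)  # pre-activation giving tanh = 0.5


class TestGates:
    def test_zero_weights_give_neutral_gates(self, rng):
        for kind, fn in (("brc", brc_gates), ("nbrc", nbrc_gates)):
            w = zero_cell(kind, 3, 4)
            g = fn(rng.standard_normal(3), rng.standard_normal(4), w)
            np.testing.assert_array_equal(g.a, np.ones(4))
            np.testing.assert_array_equal(g.c, 0.5 * np.ones(4))

    def test_feedback_gate_saturates_to_interval_endpoints(self):
        w = zero_cell("brc", 1, 1)
        w.U_a[:] = 1.0
        lo = brc_gates(np.array([-40.0]), np.zeros(1), w).a[0]
        hi = brc_gates(np.array([40.0]), np.zeros(1), w).a[0]
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi == pytest.approx(2.0, abs=1e-12)

    def test_half_saturation_preactivation_gives_a_1_5(self):
        # 1 + tanh(atanh(0.5)) = 1.5
        w = scalar_brc(a_pre=ATANH_HALF)
        g = brc_gates(np.zeros(1), np.zeros(1), w)
        assert g.a[0] == pytest.approx(1.5, abs=1e-12)

    def test_identity_kernel_with_zero_state_is_neutral(self):
        w = zero_cell("nbrc", 2, 3)
        w.W_a[:] = np.eye(3)
        g = nbrc_gates(np.zeros(2), np.zeros(3), w)
        np.testing.assert_array_equal(g.a, np.ones(3))

    def test_diagonal_kernels_reduce_nbrc_gates_to_brc(self, rng):
        wb = init_weights("brc", 3, 5, seed=7)
        wn = zero_cell("nbrc", 3, 5)
        for name in ("U", "U_a", "U_c", "b", "b_a", "b_c"):
            setattr(wn, name, getattr(wb, name).copy())
        wn.W_a = np.diag(wb.w_a)
        wn.W_c = np.diag(wb.w_c)
        x = rng.standard_normal((8, 3))
        h = rng.uniform(-1, 1, (8, 5))
        gb, gn = brc_gates(x, h, wb), nbrc_gates(x, h, wn)
        np.testing.assert_allclose(gn.a, gb.a, atol=1e-12)
        np.testing.assert_allclose(gn.c, gb.c, atol=1e-12)
        np.testing.assert_allclose(nbrc_step(x, h, wn), brc_step(x, h, wb),
                                   atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_gate_ranges_hold_for_random_weights_and_inputs(self, seed):
        rng = np.random.default_rng(seed)
        for kind, fn in (("brc", brc_gates), ("nbrc", nbrc_gates)):
            w = init_weights(kind, 4, 6, rng)
            for arr in w.param_list():
                arr += rng.standard_normal(arr.shape) * 0.5
            x = rng.standard_normal((50, 4))
            h = rng.uniform(-1, 1, (50, 6))
            g = fn(x, h, w)
            assert np.all(g.a > 0) and np.all(g.a < 2)
            assert np.all(g.c > 0) and np.all(g.c < 1)

    def test_shape_mismatch_raises(self, rng):
        w = zero_cell("brc", 3, 4)
        with pytest.raises(DimensionError):
            brc_gates(rng.standard_normal(2), rng.standard_normal(4), w)
        with pytest.raises(DimensionError):
            brc_step(rng.standard_normal(3), rng.standard_normal(5), w)


class TestSteps:
    def test_origin_is_a_fixed_point_of_every_cell(self):
        for kind in ("brc", "nbrc"):
            h = step(kind, np.zeros(3), np.zeros(4), zero_cell(kind, 3, 4))
            np.testing.assert_array_equal(h, np.zeros(4))
        h = gru_step(np.zeros(3), np.zeros(4), zero_gru(3, 4))
        np.testing.assert_array_equal(h, np.zeros(4))

    def test_scalar_update_matches_direct_formula(self):
        # a = 1.5, c = 0.5, no input drive, h = 0.5
        w = scalar_brc(a_pre=ATANH_HALF, c_pre=0.0)
        h = brc_step(np.zeros(1), np.array([0.5]), w)
        expected = 0.5 * 0.5 + 0.5 * np.tanh(1.5 * 0.5)
        assert h[0] == pytest.approx(expected, abs=1e-14)

    def test_bistable_cell_converges_to_two_signed_attractors(self):
        w = scalar_brc(a_pre=ATANH_HALF)  # a = 1.5 > 1: bistable regime
        limits = []
        for h0 in (0.5, -0.5):
            h = np.array([h0])
            for _ in range(500):
                h = brc_step(np.zeros(1), h, w)
            limits.append(h[0])
        assert limits[0] > 0.5 and limits[1] < -0.5
        assert limits[0] == pytest.approx(-limits[1], abs=1e-9)

    @pytest.mark.parametrize("kind", ["brc", "nbrc"])
    def test_state_stays_in_unit_box(self, kind, rng):
        # h_t is a convex combination of h_{t-1} and a tanh value
        w = init_weights(kind, 3, 6, seed=3)
        for arr in w.param_list():
            arr += rng.standard_normal(arr.shape)
        h = rng.uniform(-1, 1, (20, 6))
        for _ in range(50):
            h = step(kind, rng.standard_normal((20, 3)) * 5, h, w)
            assert np.all(np.abs(h) <= 1.0)

    def test_brc_state_jacobian_is_diagonal(self, rng):
        w = init_weights("brc", 3, 5, seed=11)
        for arr in w.param_list():
            arr += rng.standard_normal(arr.shape) * 0.5
        x = rng.standard_normal(3)
        h = rng.uniform(-0.8, 0.8, 5)
        eps = 1e-6
        jac = np.empty((5, 5))
        for j in range(5):
            hp, hm = h.copy(), h.copy()
            hp[j] += eps
            hm[j] -= eps
            jac[:, j] = (brc_step(x, hp, w) - brc_step(x, hm, w)) / (2 * eps)
        off = jac - np.diag(np.diag(jac))
        assert np.max(np.abs(off)) < 1e-6

    def test_gru_gate_limits(self, rng):
        w = zero_gru(2, 3)
        x, h = rng.standard_normal(2), rng.uniform(-1, 1, 3)
        w.b_z[:] = 40.0  # z -> 1: state frozen
        np.testing.assert_allclose(gru_step(x, h, w), h, atol=1e-12)
        w.b_z[:] = -40.0  # z -> 0
        w.b_r[:] = 40.0   # r -> 1
        w.U_h[:] = np.ones((2, 3))
        w.W_h[:] = np.eye(3)
        expected = np.tanh(x @ w.U_h + h @ w.W_h)
        np.testing.assert_allclose(gru_step(x, h, w), expected, atol=1e-12)


class TestUnroll:
    def test_zero_weight_stack_stays_at_zero(self, rng):
        layers = [zero_cell("brc", 2, 3), zero_cell("brc", 3, 4)]
        finals, trajs, trace = unroll("brc", rng.standard_normal((6, 2)), layers)
        assert [t.shape for t in trajs] == [(6, 3), (6, 4)]
        for t in trajs:
            np.testing.assert_array_equal(t, 0)
        assert trace is None

    def test_pulse_latches_when_bistable_and_decays_when_monostable(self):
        pulse = np.zeros((40, 1))
        pulse[:3] = 2.0
        w_bi = scalar_brc(a_pre=ATANH_HALF)       # a = 1.5
        w_mono = scalar_brc(a_pre=np.arctanh(-0.5))  # a = 0.5
        w_bi.U[:] = 1.0   # couple the input into the candidate
        w_mono.U[:] = 1.0
        _, (traj_bi,), _ = unroll("brc", pulse, [w_bi])
        _, (traj_mono,), _ = unroll("brc", pulse, [w_mono])
        assert abs(traj_bi[-1, 0]) > 0.5       # latched on a nonzero branch
        assert abs(traj_mono[-1, 0]) < 1e-3    # relaxed to the origin

    def test_unroll_is_deterministic(self, rng):
        layers = [init_weights("nbrc", 2, 4, seed=5)]
        xs = rng.standard_normal((7, 3, 2))
        out1 = unroll("nbrc", xs, layers, record_gates=True)
        out2 = unroll("nbrc", xs, layers, record_gates=True)
        np.testing.assert_array_equal(out1[1][0], out2[1][0])
        np.testing.assert_array_equal(out1[2].a[0], out2[2].a[0])

    def test_rejects_empty_sequence_and_dim_mismatch(self):
        with pytest.raises(ValueError):
            unroll("brc", np.zeros((0, 1, 2)), [zero_cell("brc", 2, 3)])
        with pytest.raises(DimensionError):
            unroll("brc", np.zeros((4, 2)), [zero_cell("brc", 3, 3)])


class TestInitAndSerialization:
    def test_same_seed_reproduces_weights_different_seed_does_not(self):
        for kind in ("brc", "nbrc", "gru"):
            w1 = init_weights(kind, 3, 4, seed=42)
            w2 = init_weights(kind, 3, 4, seed=42)
            w3 = init_weights(kind, 3, 4, seed=43)
            for a, b in zip(w1.param_list(), w2.param_list()):
                np.testing.assert_array_equal(a, b)
            assert any(not np.array_equal(a, b)
                       for a, b in zip(w1.param_list(), w3.param_list()))

    def test_gates_at_init_are_in_range_for_random_inputs(self, rng):
        w = init_weights("nbrc", 5, 8, seed=0)
        g = nbrc_gates(rng.standard_normal((100, 5)),
                       rng.uniform(-1, 1, (100, 8)), w)
        assert np.all((g.a > 0) & (g.a < 2)) and np.all((g.c > 0) & (g.c < 1))

    def test_weights_round_trip_through_npz(self, tmp_path, rng):
        layers = [init_weights("nbrc", 2, 3, seed=1),
                  init_weights("nbrc", 3, 3, seed=2)]
        path = tmp_path / "w.npz"
        save_weights(path, layers)
        loaded = load_weights(path)
        for a, b in zip(layers, loaded):
            for n in a.param_names():
                np.testing.assert_array_equal(getattr(a, n), getattr(b, n))


class TestGradients:
    @pytest.mark.parametrize("kind", ["brc", "nbrc", "gru"])
    def test_bptt_gradients_match_finite_differences(self, kind, rng):
        """Analytic BPTT gradient vs central differences on a 2-neuron,
        5-step, 2-layer stack (relative error < 1e-4)."""
        layers = [init_weights(kind, 3, 2, seed=1), init_weights(kind, 2, 2, seed=2)]
        for w in layers:
            for arr in w.param_list():
                arr += rng.standard_normal(arr.shape) * 0.3
        xs = rng.standard_normal((5, 4, 3))

        def loss():
            inp = xs
            for w in layers:
                inp = forward_layer(w, inp).hs[1:]
            return float((inp[-1] ** 2).sum())

        caches, inp = [], xs
        for w in layers:
            c = forward_layer(w, inp)
            caches.append(c)
            inp = c.hs[1:]
        ghs = np.zeros_like(caches[-1].hs[1:])
        ghs[-1] = 2 * caches[-1].hs[-1]
        analytic = []
        for w, c in zip(reversed(layers), reversed(caches)):
            grads, ghs = backward_layer(w, c, ghs)
            analytic.append((w, grads))
        eps = 1e-6
        for w, grads in analytic:
            for name in w.param_names():
                arr = getattr(w, name)
                flat = arr.reshape(-1)
                for i in range(flat.size):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = loss()
                    flat[i] = old - eps
                    lm = loss()
                    flat[i] = old
                    fd = (lp - lm) / (2 * eps)
                    an = grads[name].reshape(-1)[i]
                    assert abs(an - fd) <= 1e-4 * max(1.0, abs(fd), abs(an))
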