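"""Cascade core: raised-cosine kernels, synapse aggregation, static and
dynamic subunits, tree evaluation, and soft/hard assignment."""

import numpy as np
import pytest

from neurocascade.cascade import (ArchitectureSpec, CascadeModel,
                                  DynamicSubunitParams, StaticSubunitParams,
                                  aggregate_synapses, filter_spikes,
                                  gru_step, hard_assignment, soft_assignment,
                                  static_forward)
from neurocascade.kernels import KernelBank, eval_kernel


class TestKernels:
    def test_zero_coefficients_give_zero_kernel(self, bank):
        assert np.allclose(eval_kernel(bank, np.zeros(30)), 0.0)

    def test_one_hot_peak_location_and_value(self, bank):
        """Bump k peaks with value 1 at tau* = scale*(exp(phi_k/a) - c)."""
        for k in (0, 7, 29):
            alpha = np.zeros(30)
            alpha[k] = 1.0
            kern = eval_kernel(bank, alpha)
            tau_star = bank.peak_lag_ms(k)
            i = int(round(tau_star / bank.dt_ms))
            assert kern.max() <= 1.0 + 1e-12
            assert kern[i] == pytest.approx(kern.max(), rel=1e-3)
            assert kern.max() == pytest.approx(1.0, abs=0.02)

    def test_linearity_in_coefficients(self, bank, rng):
        a1 = rng.standard_normal(30)
        a2 = rng.standard_normal(30)
        assert np.allclose(eval_kernel(bank, a1 + a2),
                           eval_kernel(bank, a1) + eval_kernel(bank, a2))

    def test_support_ends_at_span(self, bank):
        kern = eval_kernel(bank, np.ones(30))
        assert kern[-1] == pytest.approx(0.0, abs=1e-10)

    def test_wrong_length_rejected(self, bank):
        with pytest.raises(ValueError):
            eval_kernel(bank, np.zeros(7))


class TestFilterAggregate:
    def test_no_spikes_gives_zero(self):
        assert np.allclose(filter_spikes(np.zeros(50), np.ones(5)), 0.0)

    def test_single_spike_reproduces_kernel(self):
        drive = np.zeros(60)
        drive[10] = 1.0
        kern = np.array([3.0, 2.0, 1.0])
        out = filter_spikes(drive, kern)
        assert np.allclose(out[10:13], kern)
        assert np.allclose(out[:10], 0.0)

    def test_matches_brute_force_double_loop(self, rng):
        drive = rng.poisson(0.3, 100).astype(float)
        kern = rng.standard_normal(12)
        out = filter_spikes(drive, kern)
        brute = np.zeros(100)
        for t in range(100):
            for tau in range(12):
                if t - tau >= 0:
                    brute[t] += kern[tau] * drive[t - tau]
        assert np.allclose(out, brute, atol=1e-10)

    def test_aggregation_equals_matrix_product_oracle(self, rng):
        C = rng.dirichlet(np.ones(3), size=10).T       # (3, 10), cols sum to 1
        w = rng.uniform(0, 2, 10)
        S = rng.poisson(0.5, (10, 40)).astype(float)
        out = aggregate_synapses(C, w, S)
        brute = np.zeros((3, 40))
        for n in range(3):
            for l in range(10):
                brute[n] += C[n, l] * w[l] * S[l]
        assert np.allclose(out, brute, atol=1e-12)

    def test_binary_assignment_counts_spikes(self, rng):
        C = np.zeros((2, 6))
        C[0, :3] = 1.0
        C[1, 3:] = 1.0
        S = rng.poisson(1.0, (6, 20)).astype(float)
        out = aggregate_synapses(C, np.ones(6), S)
        assert np.allclose(out[0], S[:3].sum(axis=0))
        assert np.allclose(out[1], S[3:].sum(axis=0))


class TestStaticSubunit:
    def test_zero_drive_gives_constant(self, bank):
        p = StaticSubunitParams(w=np.array([0.5, -0.2]), b=np.array([0.3, 1.0]),
                                alpha_e=np.zeros((2, 30)),
                                alpha_i=np.zeros((2, 30)))
        y = static_forward(p, np.zeros(50), np.zeros(50), 0.0, bank)
        want = 0.5 * np.tanh(0.3) - 0.2 * np.tanh(1.0)
        assert np.allclose(y, want)

    def test_output_bounded_by_weight_sum(self, bank, rng):
        p = StaticSubunitParams(w=rng.standard_normal(2),
                                b=rng.standard_normal(2),
                                alpha_e=rng.standard_normal((2, 30)),
                                alpha_i=rng.standard_normal((2, 30)))
        drive = rng.poisson(2.0, 200).astype(float)
        y = static_forward(p, drive, drive, 0.0, bank)
        assert np.all(np.abs(y) <= np.abs(p.w).sum() + 1e-12)

    def test_extra_channel_with_zero_weight_reduces_to_one_channel(self, bank, rng):
        a_e = rng.standard_normal((2, 30)) * 0.1
        a_i = rng.standard_normal((2, 30)) * 0.1
        p2 = StaticSubunitParams(w=np.array([0.7, 0.0]),
                                 b=np.array([0.2, -0.4]),
                                 alpha_e=a_e, alpha_i=a_i)
        p1 = StaticSubunitParams(w=np.array([0.7]), b=np.array([0.2]),
                                 alpha_e=a_e[:1], alpha_i=a_i[:1])
        drive = rng.poisson(0.5, 100).astype(float)
        y2 = static_forward(p2, drive, drive * 0.5, 0.0, bank)
        y1 = static_forward(p1, drive, drive * 0.5, 0.0, bank)
        assert np.allclose(y1, y2)


class TestGRU:
    def test_zero_parameters_hand_evaluation(self):
        """All parameters zero, h_prev = 1: z = r = 1/2, k = 0, h = 1/2."""
        G = 4
        p = DynamicSubunitParams(
            wr=np.zeros(G), wz=np.zeros(G), wk=np.zeros(G),
            Whr=np.zeros((G, G)), Whz=np.zeros((G, G)), Whk=np.zeros((G, G)),
            br=np.zeros(G), bz=np.zeros(G), bk=np.zeros(G),
            w_out=np.zeros(G), b_out=0.0)
        h = gru_step(p, 0.0, np.ones(G))
        assert np.allclose(h, 0.5)

    def test_update_gate_saturation_freezes_state(self, rng):
        """b_z -> +inf forces z = 1, so h_t = h_prev."""
        G = 3
        p = DynamicSubunitParams(
            wr=rng.standard_normal(G), wz=np.zeros(G),
            wk=rng.standard_normal(G),
            Whr=rng.standard_normal((G, G)), Whz=np.zeros((G, G)),
            Whk=rng.standard_normal((G, G)),
            br=rng.standard_normal(G), bz=np.full(G, 50.0),
            bk=rng.standard_normal(G), w_out=np.zeros(G), b_out=0.0)
        h0 = rng.standard_normal(G)
        h1 = gru_step(p, 1.3, h0)
        assert np.allclose(h1, h0, atol=1e-12)

    def test_step_matches_scalar_reimplementation(self, rng):
        G = 3
        p = DynamicSubunitParams(
            wr=rng.standard_normal(G), wz=rng.standard_normal(G),
            wk=rng.standard_normal(G),
            Whr=rng.standard_normal((G, G)), Whz=rng.standard_normal((G, G)),
            Whk=rng.standard_normal((G, G)),
            br=rng.standard_normal(G), bz=rng.standard_normal(G),
            bk=rng.standard_normal(G), w_out=np.zeros(G), b_out=0.0)
        x, h0 = 0.7, rng.standard_normal(G)
        got = gru_step(p, x, h0)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for g in range(G):
            r = np.array([sig(p.wr[i] * x + sum(p.Whr[i, j] * h0[j]
                                                for j in range(G)) + p.br[i])
                          for i in range(G)])
            z_g = sig(p.wz[g] * x + sum(p.Whz[g, j] * h0[j]
                                        for j in range(G)) + p.bz[g])
            k_g = np.tanh(p.wk[g] * x + p.bk[g]
                          + sum(p.Whk[g, j] * r[j] * h0[j] for j in range(G)))
            want = (1 - z_g) * k_g + z_g * h0[g]
            assert got[g] == pytest.approx(want, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        G = 3
        p = DynamicSubunitParams(
            wr=np.zeros(G), wz=np.zeros(G), wk=np.zeros(G),
            Whr=np.zeros((G, G)), Whz=np.zeros((G, G)), Whk=np.zeros((G, G)),
            br=np.zeros(G), bz=np.zeros(G), bk=np.zeros(G),
            w_out=np.zeros(G), b_out=0.0)
        with pytest.raises(ValueError):
            gru_step(p, 0.0, np.zeros(G + 1))


def _toy_model(kinds, rng, n_exc=6, n_inh=2, bank=None, C=None, G=3):
    N = len(kinds)
    if C is None:
        C = np.zeros((N + 1, N + 1))
        C[0, 1:] = 1.0
    Ce = rng.dirichlet(np.ones(N), size=n_exc).T
    Ci = rng.dirichlet(np.ones(N), size=n_inh).T
    arch = ArchitectureSpec(C, list(kinds), n_ch=1, G=G, C_syn_e=Ce,
                            C_syn_i=Ci, w_syn_e=rng.uniform(0, 1, n_exc),
                            w_syn_i=rng.uniform(0, 1, n_inh))
    params = []
    for kind in kinds:
        if kind == "static":
            params.append(StaticSubunitParams(
                w=rng.standard_normal(1), b=rng.standard_normal(1),
                alpha_e=rng.standard_normal((1, 30)) * 0.1,
                alpha_i=rng.standard_normal((1, 30)) * 0.1))
        else:
            params.append(DynamicSubunitParams(
                wr=rng.standard_normal(G), wz=rng.standard_normal(G),
                wk=rng.standard_normal(G), Whr=rng.standard_normal((G, G)),
                Whz=rng.standard_normal((G, G)),
                Whk=rng.standard_normal((G, G)), br=rng.standard_normal(G),
                bz=rng.standard_normal(G), bk=rng.standard_normal(G),
                w_out=rng.standard_normal(G), b_out=0.1))
    return CascadeModel(arch, params, bank or KernelBank())


class TestCascadeForward:
    def test_single_subunit_root_is_identity(self, bank, rng):
        m = _toy_model(["static"], rng, bank=bank)
        Se = rng.poisson(0.4, (6, 80)).astype(float)
        Si = rng.poisson(0.4, (2, 80)).astype(float)
        v = m.forward(Se, Si)
        de = aggregate_synapses(m.arch.C_syn_e, m.arch.w_syn_e, Se)[0]
        di = aggregate_synapses(m.arch.C_syn_i, m.arch.w_syn_i, Si)[0]
        y = static_forward(m.params[0], de, di, 0.0, bank)
        assert np.allclose(v, y)

    def test_subunit_relabeling_invariance(self, bank, rng):
        m = _toy_model(["static", "dynamic", "static"], rng, bank=bank)
        Se = rng.poisson(0.4, (6, 60)).astype(float)
        Si = rng.poisson(0.4, (2, 60)).astype(float)
        v1 = m.forward(Se, Si)
        # permute subunits 1 and 3 consistently
        perm = [0, 3, 2, 1]
        C2 = m.arch.C[np.ix_(perm, perm)]
        order = [2, 1, 0]
        arch2 = ArchitectureSpec(C2, [m.arch.kinds[i] for i in order], 1,
                                 m.arch.G, m.arch.C_syn_e[order],
                                 m.arch.C_syn_i[order], m.arch.w_syn_e,
                                 m.arch.w_syn_i)
        m2 = CascadeModel(arch2, [m.params[i] for i in order], bank)
        assert np.allclose(m2.forward(Se, Si), v1)

    def test_root_linearity_under_output_scaling(self, bank, rng):
        m = _toy_model(["static", "static"], rng, bank=bank)
        Se = rng.poisson(0.4, (6, 60)).astype(float)
        Si = rng.poisson(0.4, (2, 60)).astype(float)
        v1 = m.forward(Se, Si)
        for p in m.params:
            p.w = 3.0 * p.w
        assert np.allclose(m.forward(Se, Si), 3.0 * v1)

    def test_three_layer_identity_middle_matches_two_layer(self, bank, rng):
        """A chain root <- middle GRU <- leaf, with the middle GRU forced to
        integrate-and-pass (z=0 freeze-free readout of its input), behaves
        like the two-layer model up to the middle unit's affine readout."""
        G = 2
        leaf = _toy_model(["static"], rng, bank=bank)
        # 3-layer: node 1 = middle (dynamic), node 2 = leaf (static)
        C = np.zeros((3, 3))
        C[0, 1] = 1.0
        C[1, 2] = 1.0
        # middle GRU with b_z -> +inf: h stays at 0, output = b_out
        frozen = DynamicSubunitParams(
            wr=np.zeros(G), wz=np.zeros(G), wk=np.zeros(G),
            Whr=np.zeros((G, G)), Whz=np.zeros((G, G)), Whk=np.zeros((G, G)),
            br=np.zeros(G), bz=np.full(G, 60.0), bk=np.zeros(G),
            w_out=rng.standard_normal(G), b_out=0.77)
        arch3 = ArchitectureSpec(C, ["dynamic", "static"], 1, G,
                                 np.vstack([np.zeros(6), np.ones(6)]),
                                 np.vstack([np.zeros(2), np.ones(2)]),
                                 leaf.arch.w_syn_e, leaf.arch.w_syn_i)
        m3 = CascadeModel(arch3, [frozen, leaf.params[0]], bank)
        Se = rng.poisson(0.4, (6, 50)).astype(float)
        Si = rng.poisson(0.4, (2, 50)).astype(float)
        v3 = m3.forward(Se, Si)
        assert np.allclose(v3, 0.77)  # frozen GRU passes only its bias

    def test_cyclic_connectivity_rejected(self, rng):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 2] = C[2, 1] = 1.0
        arch = ArchitectureSpec(C, ["static", "static"], 1, 3,
                                np.ones((2, 1)) / 2, np.ones((2, 1)) / 2,
                                np.ones(1), np.ones(1))
        with pytest.raises(ValueError):
            arch.validate()

    def test_kernel_causality_by_trace_diffing(self, bank, rng):
        m = _toy_model(["static", "dynamic"], rng, bank=bank)
        Se = rng.poisson(0.4, (6, 100)).astype(float)
        Si = rng.poisson(0.4, (2, 100)).astype(float)
        v1 = m.forward(Se, Si)
        Se2 = Se.copy()
        Se2[:, 60:] += 3
        v2 = m.forward(Se2, Si)
        assert np.allclose(v1[:60], v2[:60])
        assert not np.allclose(v1[60:], v2[60:])


class TestAssignment:
    def test_soft_columns_sum_to_one_and_shift_invariance(self, rng):
        om = rng.standard_normal((5, 12))
        C = soft_assignment(om, 2.0)
        assert np.allclose(C.sum(axis=0), 1.0)
        om2 = om.copy()
        om2[:, 3] += 10.0
        assert np.allclose(soft_assignment(om2, 2.0)[:, 3], C[:, 3])

    def test_equal_omegas_give_uniform(self):
        C = soft_assignment(np.zeros((4, 6)), 5.0)
        assert np.allclose(C, 0.25)

    def test_hard_assignment_argmax_and_tie_rule(self):
        om = np.array([[0.1, 0.9, 0.5],
                       [0.9, 0.1, 0.5]])
        C = hard_assignment(om)
        assert np.array_equal(C, [[0, 1, 1], [1, 0, 0]])  # tie -> lower index

    def test_soft_limit_matches_hard(self, rng):
        om = rng.standard_normal((4, 20))
        hard = hard_assignment(om)
        soft = soft_assignment(om, 1e4)
        assert np.allclose(soft, hard, atol=1e-6)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            soft_assignment(np.zeros((2, 2)), 0.0)
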