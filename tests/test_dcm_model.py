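"""Forward model: model space structure, drift equations, simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from perceptdcm import dcm
from perceptdcm.dcm import (DCMParams, NeuronalState, StimulusFunctions,
                            bold_observation, build_model_space,
                            hemodynamic_drift, neuronal_drift, simulate_bold,
                            simulate_neuronal)

INPUT_NAMES = (*dcm.DRIVING_INPUTS, *dcm.MODULATORY_INPUTS)


def default_params(C=None, B=None, A=None, **kw):
    n = 4
    return DCMParams(A=-0.5 * np.eye(n) if A is None else A,
                     B=np.zeros((2, n, n)) if B is None else B,
                     C=np.zeros((n, 2)) if C is None else C, **kw)


def stimuli(U):
    return StimulusFunctions(dt=0.125, names=INPUT_NAMES, U=U)


class TestModelSpace:
    def test_four_models_with_shared_A_and_C(self, model_space):
        assert [s.name for s in model_space] == [f"model{i}" for i in (1, 2, 3, 4)]
        for s in model_space[1:]:
            assert np.array_equal(s.A_mask, model_space[0].A_mask)
            assert np.array_equal(s.C_mask, model_space[0].C_mask)

    def test_A_mask_has_14_entries_without_mtg_iof(self, model1):
        # 4 self + 12 directed pairs - the absent MTG<->IOF reciprocal pair
        assert model1.A_mask.sum() == 14
        mtg, iof = model1.region_index("MTG"), model1.region_index("IOF")
        assert not model1.A_mask[mtg, iof] and not model1.A_mask[iof, mtg]

    def test_model1_block1_modulations_are_bottom_up(self, model1):
        b1 = model1.B_masks[0]
        assert b1.sum() == 4
        for i, j in zip(*np.nonzero(b1)):
            assert model1.region_names[j] in ("LIN", "PRE")
            assert model1.region_names[i] in ("MTG", "IOF")

    def test_model1_block3_modulations_are_top_down(self, model1):
        b3 = model1.B_masks[1]
        assert b3.sum() == 4
        for i, j in zip(*np.nonzero(b3)):
            assert model1.region_names[j] in ("MTG", "IOF")
            assert model1.region_names[i] in ("LIN", "PRE")

    def test_model2_is_union_of_models_3_and_4(self, model_space):
        m2, m3, m4 = model_space[1], model_space[2], model_space[3]
        for m in range(2):
            assert np.array_equal(m2.B_masks[m], m3.B_masks[m] | m4.B_masks[m])

    def test_optional_block2_driving_input(self):
        space = build_model_space(include_block2_input=True)
        for s in space:
            assert s.driving_names[-1] == "nonamb_block2"
            assert s.C_mask.shape == (4, 3)

    def test_b_masks_respect_A_and_exclude_diagonal(self, model_space):
        for s in model_space:
            for Bm in s.B_masks:
                assert not Bm[~s.A_mask].any()
                assert not Bm.diagonal().any()


class TestNeuronalDrift:
    def test_driving_input_at_rest(self):
        C = np.zeros((4, 2))
        C[0, 0] = 1.0
        p = default_params(C=C)
        dz = neuronal_drift(NeuronalState.rest(), np.array([1, 0, 0, 0.0]), p)
        assert np.allclose(dz, [1, 0, 0, 0])

    def test_self_decay_only(self):
        p = default_params()
        st = NeuronalState.rest()
        st.z = np.array([1.0, 0, 0, 0])
        dz = neuronal_drift(st, np.zeros(4), p)
        assert np.allclose(dz, [-0.5, 0, 0, 0])

    def test_matches_elementwise_loop_oracle(self, rng):
        A = -0.6 * np.eye(4) + 0.1 * rng.standard_normal((4, 4))
        B = 0.2 * rng.standard_normal((2, 4, 4))
        C = rng.standard_normal((4, 2))
        p = default_params(A=A, B=B, C=C)
        st = NeuronalState.rest()
        st.z = rng.standard_normal(4)
        u = rng.random(4)
        expected = np.zeros(4)
        for i in range(4):
            for j in range(4):
                a = A[i, j] + sum(u[2 + m] * B[m, i, j] for m in range(2))
                expected[i] += a * st.z[j]
            for d in range(2):
                expected[i] += C[i, d] * u[d]
        assert np.allclose(neuronal_drift(st, u, p), expected, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            neuronal_drift(NeuronalState.rest(), np.zeros(3), default_params())


class TestHemodynamics:
    def test_rest_is_exact_fixed_point(self):
        p = default_params()
        ds, df, dv, dq = hemodynamic_drift(NeuronalState.rest(), p)
        assert max(np.abs(x).max() for x in (ds, df, dv, dq)) < 1e-10
        assert np.abs(bold_observation(NeuronalState.rest(), p)).max() == 0.0

    def test_activity_drives_vasodilatory_signal_only(self):
        st = NeuronalState.rest()
        st.z = np.array([0.3, 0, 0, 0])
        ds, df, dv, dq = hemodynamic_drift(st, default_params())
        assert ds[0] == pytest.approx(0.3)
        assert np.allclose(df, 0) and np.allclose(dv, 0) and np.allclose(dq, 0)

    def test_nonpositive_state_raises(self):
        st = NeuronalState.rest()
        st.f = np.array([0.0, 1, 1, 1])
        with pytest.raises(FloatingPointError):
            hemodynamic_drift(st, default_params())

    def test_decreased_deoxyhemoglobin_raises_bold(self):
        st = NeuronalState.rest()
        st.q = np.full(4, 0.9)
        assert (bold_observation(st, default_params()) > 0).all()

    def test_perturbation_decays_to_rest_against_reference(self):
        """Single-region cascade returns to rest; checked against RK45."""
        p = default_params()

        def odes(_t, x):
            st = NeuronalState(z=np.zeros(4), s=x[0::4].copy(),
                               f=x[1::4].copy(), v=x[2::4].copy(),
                               q=x[3::4].copy())
            ds, df, dv, dq = hemodynamic_drift(st, p)
            out = np.empty(16)
            out[0::4], out[1::4], out[2::4], out[3::4] = ds, df, dv, dq
            return out

        x0 = np.array([0.1, 1.2, 1.1, 0.95] * 4)
        sol = solve_ivp(odes, (0, 40), x0, rtol=1e-10, atol=1e-12,
                        dense_output=True)
        assert np.abs(sol.y[:, -1] - np.array([0, 1, 1, 1] * 4)).max() < 1e-3
        # our explicit Euler at a fine step tracks the reference mid-course
        dt = 1e-3
        x = x0.copy()
        for _ in range(int(10 / dt)):
            x = x + dt * odes(0, x)
        assert np.abs(x - sol.sol(10.0)).max() < 1e-3


class TestSimulation:
    def test_rest_is_invariant_without_input_or_noise(self, model1):
        p = default_params()
        U = np.zeros((16 * 20, 4))
        ts = simulate_bold(model1, p, stimuli(U), duration=40, tr=2.0, seed=0)
        # constant zero up to float round-off of the resting extraction term
        assert np.abs(ts.Y).max() < 1e-12

    def test_same_seed_reproduces_different_seed_differs(self, model1):
        C = np.full((4, 2), 0.1)
        p = default_params(C=C, innovation_sd=0.01, obs_noise_sd=0.001)
        U = np.zeros((16 * 20, 4))
        U[:80, 0] = 1
        a = simulate_bold(model1, p, stimuli(U), 40, 2.0, seed=3)
        b = simulate_bold(model1, p, stimuli(U), 40, 2.0, seed=3)
        c = simulate_bold(model1, p, stimuli(U), 40, 2.0, seed=4)
        assert np.array_equal(a.Y, b.Y)
        assert not np.array_equal(a.Y, c.Y)

    def test_kernel_matches_python_step_oracle(self, model1, rng):
        """Full BOLD simulation equals a direct Python loop of the same
        Euler scheme (log-space hemodynamic states)."""
        p = default_params(C=0.1 * rng.standard_normal((4, 2)))
        p.A += 0.1 * rng.standard_normal((4, 4)) * model1.A_mask * \
            ~np.eye(4, dtype=bool)
        B = np.zeros((2, 4, 4))
        B[0][model1.B_masks[0]] = 0.2
        B[1][model1.B_masks[1]] = 0.15
        p.B = B
        S = 16 * 15
        U = (rng.random((S, 4)) < 0.3).astype(float)
        ts = simulate_bold(model1, p, stimuli(U), duration=30, tr=2.0, seed=0)
        z = np.zeros(4)
        s = np.zeros(4)
        lf = np.zeros(4)
        lv = np.zeros(4)
        lq = np.zeros(4)
        dt = 0.125
        ys = []
        for t in range(S):
            um, ud = U[t, 2:], U[t, :2]
            dz = (p.A + np.tensordot(um, p.B, axes=1)) @ z + p.C @ ud
            f, v, q = np.exp(lf), np.exp(lv), np.exp(lq)
            fv = v ** (1 / p.alpha)
            E = 1 - (1 - p.rho) ** (1 / f)
            ds = z - p.kappa * s - p.gamma * (f - 1)
            dlf = s / f
            dlv = (f - fv) / (p.tau * v)
            dlq = (f * E / p.rho - fv * q / v) / (p.tau * q)
            z = z + dt * dz
            s = s + dt * ds
            lf = lf + dt * dlf
            lv = lv + dt * dlv
            lq = lq + dt * dlq
            if (t + 1) % 16 == 0:
                v, q = np.exp(lv), np.exp(lq)
                k1, k2, k3 = 7 * p.rho, 2.0, 2 * p.rho - 0.2
                ys.append(p.V0 * (k1 * (1 - q) + k2 * (1 - q / v)
                                  + k3 * (1 - v)))
        assert np.allclose(ts.Y, np.array(ys), atol=1e-12)

    def test_masked_out_parameters_never_influence_output(self, model1):
        C = np.full((4, 2), 0.1)
        B = np.zeros((2, 4, 4))
        B[0][model1.B_masks[0]] = 0.25
        p = default_params(C=C, B=B)
        S = 16 * 30
        U = np.zeros((S, 4))
        U[:480, 0] = 1
        U[100:116, 2] = 1
        ref = simulate_bold(model1, p, stimuli(U), 60, 2.0, seed=1)
        q = p.copy()
        q.A[2, 3] = 0.7       # masked out (MTG<->IOF absent)
        q.B[1][0, 1] = -0.9   # outside model-1 block-3 mask
        with pytest.raises(ValueError):
            simulate_bold(model1, q, stimuli(U), 60, 2.0, seed=1)
        # zeroing them back restores bit-identical output
        q.A[2, 3] = 0.0
        q.B[1][0, 1] = 0.0
        again = simulate_bold(model1, q, stimuli(U), 60, 2.0, seed=1)
        assert np.array_equal(ref.Y, again.Y)

    def test_impulse_response_peak_latency_3_to_7_s(self, model1):
        C = np.zeros((4, 2))
        C[:, 0] = 1.0
        p = default_params(C=C)
        U = np.zeros((16 * 30, 4))
        U[:4, 0] = 1.0  # 0.5-s impulse
        ts = simulate_bold(model1, p, stimuli(U), 60, 2.0, seed=0)
        latency = (np.argmax(ts.Y[:, 0]) + 1) * 2.0
        assert 3.0 <= latency <= 7.0

    def test_linear_regime_matches_matrix_exponential(self, rng):
        """With B = 0 and a small constant input, the neuronal trajectory
        follows the linear closed form z(t) = (e^{At} - I) A^{-1} C u."""
        A = -0.5 * np.eye(4)
        A[1, 0], A[2, 1] = 0.2, 0.15
        C = np.zeros((4, 2))
        C[:, 0] = 0.01
        p = default_params(A=A, C=C)
        S = 16 * 20
        U = np.zeros((S, 4))
        U[:, 0] = 1.0
        z = simulate_neuronal(p, stimuli(U))
        u = np.array([1.0, 0.0])
        for t_idx in (79, 159, S - 1):
            t = (t_idx + 1) * 0.125
            closed = np.linalg.solve(A, (expm(A * t)
                                         - np.eye(4)) @ (C @ u))
            assert np.abs(z[t_idx] - closed).max() < 1e-4

    def test_models_1_and_4_differ_only_through_block1_windows(self, model_space):
        """With shared top-down block-3 gating, model-1 and model-4
        realizations diverge only once the block-1 pre-switch input acts."""
        m1, m4 = model_space[0], model_space[3]
        Bshared = np.zeros((2, 4, 4))
        Bshared[1][m1.B_masks[1]] = 0.3
        B1 = Bshared.copy()
        B1[0][m1.B_masks[0]] = 0.3
        B4 = Bshared.copy()
        B4[0][m4.B_masks[0]] = 0.3
        C = np.full((4, 2), 0.1)
        S = 16 * 40
        U = np.zeros((S, 4))
        U[:, 0] = 1.0
        p1 = default_params(C=C, B=B1)
        p4 = default_params(C=C, B=B4)
        # block-1 modulator silent: identical
        a = simulate_bold(m1, p1, stimuli(U), 80, 2.0, seed=0)
        b = simulate_bold(m4, p4, stimuli(U), 80, 2.0, seed=0)
        assert np.array_equal(a.Y, b.Y)
        # switch the block-1 modulator on: they must diverge
        U2 = U.copy()
        U2[160:176, 2] = 1.0
        a2 = simulate_bold(m1, p1, stimuli(U2), 80, 2.0, seed=0)
        b2 = simulate_bold(m4, p4, stimuli(U2), 80, 2.0, seed=0)
        assert np.array_equal(a2.Y[:9], b2.Y[:9])  # before the window
        assert not np.array_equal(a2.Y, b2.Y)


class TestParamValidation:
    def test_unstable_diagonal_rejected(self):
        with pytest.raises(ValueError):
            default_params(A=0.1 * np.eye(4))

    def test_domain_bounds(self):
        with pytest.raises(ValueError):
            default_params(alpha=np.full(4, 1.5))
        with pytest.raises(ValueError):
            default_params(tau=np.zeros(4))
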