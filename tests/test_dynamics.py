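import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from rt2des import (PropagationConfig, StabilityError, average_density,
                    build_hamiltonian, make_fixture, polarization,
                    propagate_sse, propagate_tdse)
from rt2des.dynamics import (coherence_decay_rate, dephasing_channels,
                             dephasing_gamma, draw_jump_plan, propagate_batch,
                             substream, total_jump_rate)
from rt2des.fields import Pulse, PulseSequence, field_at, sequence_for_scan
from rt2des.units import fs_to_au


def _free_seq(space, amp=0.0):
    p = Pulse(center=fs_to_au(10.0), omega=space.energies[1] or 0.1,
              phase=0.0, amplitude=np.array([0.0, 0.0, amp]),
              width=fs_to_au(2.0))
    return PulseSequence((p,), polarization=np.array([0.0, 0.0, 1.0]))


class TestHamiltonian:
    def test_zero_field_is_diagonal(self, benzene):
        H = build_hamiltonian(benzene, np.zeros(3))
        np.testing.assert_array_equal(H, np.diag(benzene.energies))

    def test_two_state_off_diagonal(self, benzene):
        f = 3e-4
        H = build_hamiltonian(benzene, np.array([0.0, 0.0, f]))
        assert np.isclose(H[0, 1], -f * benzene.dipoles[0, 1, 2])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_symmetric_for_any_field(self, seed):
        space = make_fixture("dimer_like")
        f = np.random.default_rng(seed).normal(size=3)
        H = build_hamiltonian(space, f)
        np.testing.assert_allclose(H, H.T)

    def test_bad_field_shape(self, benzene):
        with pytest.raises(ValueError):
            build_hamiltonian(benzene, np.zeros(2))


class TestTdse:
    def test_ground_state_is_stationary(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=40.0)
        tr = propagate_tdse(benzene, _free_seq(benzene), cfg,
                            np.array([1, 0], complex))
        assert np.abs(np.abs(tr.coeffs[:, 0]) - 1).max() < 1e-12

    def test_field_free_moduli_constant(self, dimer):
        cfg = PropagationConfig.from_lab(t_final_fs=40.0)
        rng = np.random.default_rng(5)
        C0 = rng.normal(size=6) + 1j * rng.normal(size=6)
        C0 /= np.linalg.norm(C0)
        tr = propagate_tdse(dimer, _free_seq(dimer), cfg, C0)
        assert np.abs(np.abs(tr.coeffs) - np.abs(C0)).max() < 2e-5

    def test_rabi_against_rotating_wave_solution(self, benzene):
        # resonant cw-limit drive; P0(t) = cos^2(Omega_R t / 2)
        F = 1e-3
        OmR = F * benzene.dipoles[0, 1, 2]
        seq = PulseSequence((Pulse(0.0, benzene.energies[1], 0.0,
                                   np.array([0, 0, F]), 1e9),))
        cfg = PropagationConfig(dt=fs_to_au(0.0036), t_final=np.pi / OmR,
                                store_stride=64)
        tr = propagate_tdse(benzene, seq, cfg, np.array([1, 0], complex))
        p0 = np.abs(tr.coeffs[:, 0]) ** 2
        assert np.abs(p0 - np.cos(OmR * tr.times / 2) ** 2).max() < 0.01

    def test_second_order_convergence(self, benzene):
        # halving dt reduces the end-time error ~4x against a tight ODE solve
        seq = sequence_for_scan(
            Pulse.from_lab(0, 5.61, 0.3, 5e-3, 0.5), fs_to_au(1.0),
            fs_to_au(1.0), (0.0, 0.5, 1.0), t1=fs_to_au(2.0))
        t_final = fs_to_au(8.0)
        E = benzene.energies

        def rhs(t, y):
            C = y[:2] + 1j * y[2:]
            H = build_hamiltonian(benzene, field_at(seq, t))
            dC = -1j * (H @ C)
            return np.concatenate([dC.real, dC.imag])

        ref = solve_ivp(rhs, (0, t_final), [1, 0, 0, 0], rtol=1e-12,
                        atol=1e-14, dense_output=True).y[:, -1]
        ref = ref[:2] + 1j * ref[2:]
        errs = []
        for dt_fs in (0.004, 0.002):
            cfg = PropagationConfig(dt=fs_to_au(dt_fs), t_final=t_final,
                                    store_stride=int(round(t_final / fs_to_au(dt_fs))))
            tr = propagate_tdse(benzene, seq, cfg, np.array([1, 0], complex))
            errs.append(np.linalg.norm(tr.coeffs[-1] - ref))
        assert 3.0 < errs[0] / errs[1] < 6.0

    def test_global_phase_leaves_polarization_unchanged(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=30.0)
        seq = _free_seq(benzene, amp=3e-4)
        C0 = np.array([1, 1], complex) / np.sqrt(2)
        P1 = polarization(propagate_tdse(benzene, seq, cfg, C0), benzene)
        P2 = polarization(
            propagate_tdse(benzene, seq, cfg, np.exp(0.7j) * C0), benzene)
        np.testing.assert_allclose(P1, P2, atol=1e-12)

    def test_batched_matches_serial_bitwise(self, benzene):
        # two scan points propagated together == one at a time
        E = benzene.energies
        V = benzene.dipole_along([0, 0, 1]) * 3e-4
        centers = np.array([[100.0, 300.0, 700.0], [100.0, 500.0, 900.0]])
        phases = np.array([[0.0, 0.5, 1.0], [1.5, 0.0, 0.5]])
        C0 = np.zeros((2, 2), complex)
        C0[:, 0] = 1.0
        kw = dict(detect_matrix=benzene.dipole_along([0, 0, 1]),
                  detect_start=np.array([0, 0]), detect_stride=8,
                  detect_count=100)
        both = propagate_batch(E, V, E[1], fs_to_au(2.0), centers, phases,
                               1.0, 1500, C0, **kw)
        for b in range(2):
            kw1 = dict(kw)
            kw1["detect_start"] = np.array([0])
            one = propagate_batch(E, V, E[1], fs_to_au(2.0),
                                  centers[b:b + 1], phases[b:b + 1],
                                  1.0, 1500, C0[b:b + 1], **kw1)
            np.testing.assert_array_equal(one["P"][0], both["P"][b])

    def test_large_step_raises_stability_error(self, benzene):
        cfg = PropagationConfig(dt=fs_to_au(0.15), t_final=fs_to_au(10.0))
        with pytest.raises(StabilityError):
            propagate_tdse(benzene, _free_seq(benzene), cfg,
                           np.array([1, 0], complex))


class TestDephasingChannels:
    def test_per_state_calibrated_rate_is_1_over_T2(self, dimer):
        T2 = fs_to_au(60.0)
        cfg = PropagationConfig(method="sse", dephasing_T2=T2)
        ch = dephasing_channels(dimer, cfg)
        assert ch.shape == (6, 6)
        for a in range(6):
            for b in range(a + 1, 6):
                assert np.isclose(coherence_decay_rate(ch, a, b), 1.0 / T2)

    def test_literal_convention_doubles_rate(self, benzene):
        T2 = fs_to_au(60.0)
        cfg = PropagationConfig(method="sse", dephasing_T2=T2,
                                t2_convention="literal")
        ch = dephasing_channels(benzene, cfg)
        assert np.isclose(coherence_decay_rate(ch, 0, 1), 2.0 / T2)

    def test_per_pair_calibrated_rate(self, dimer):
        T2 = fs_to_au(60.0)
        cfg = PropagationConfig(method="sse", dephasing_T2=T2,
                                channel_mode="per_pair")
        ch = dephasing_channels(dimer, cfg)
        assert ch.shape == (15, 6)
        assert np.isclose(coherence_decay_rate(ch, 1, 4), 1.0 / T2)

    def test_jump_plan_deterministic(self):
        p1 = draw_jump_plan(substream(7, 3), 0.001, 20000, 1.0)
        p2 = draw_jump_plan(substream(7, 3), 0.001, 20000, 1.0)
        assert p1 == p2 and len(p1) > 0


class TestSse:
    def test_no_channels_matches_tdse_bitwise(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=30.0, method="sse",
                                         n_traj=1)
        seq = _free_seq(benzene, amp=3e-4)
        C0 = np.array([1, 0], complex)
        tr_s = propagate_sse(benzene, seq, cfg, C0, 0)
        tr_t = propagate_tdse(benzene, seq,
                              PropagationConfig.from_lab(t_final_fs=30.0), C0)
        np.testing.assert_array_equal(tr_s.coeffs, tr_t.coeffs)

    def test_jumps_preserve_populations_per_trajectory(self, dimer):
        cfg = PropagationConfig.from_lab(t_final_fs=120.0, method="sse",
                                         t2_fs=20.0, seed=11)
        C0 = np.ones(6, complex) / np.sqrt(6)
        tr = propagate_sse(dimer, _free_seq(dimer), cfg, C0, 3)
        assert len(tr.jump_log) > 0
        assert np.abs(np.abs(tr.coeffs) ** 2 - 1 / 6).max() < 1e-4

    def test_ensemble_coherence_decay_and_populations(self, benzene):
        # 500-trajectory ensemble against the exact pure-dephasing
        # Lindblad solution |rho01(t)| = e^{-t/T2}/2
        T2 = fs_to_au(60.0)
        n_traj, seed = 500, 9
        cfg = PropagationConfig(dt=fs_to_au(0.0242), t_final=fs_to_au(120.0),
                                method="sse", dephasing_T2=T2, seed=seed)
        ch = dephasing_channels(benzene, cfg)
        rate = total_jump_rate(ch)
        n_steps = int(round(cfg.t_final / cfg.dt))
        plans = [draw_jump_plan(substream(seed, j), rate, n_steps, cfg.dt)
                 for j in range(n_traj)]
        C0 = np.tile([1, 1], (n_traj, 1)).astype(complex) / np.sqrt(2)
        res = propagate_batch(benzene.energies, 0 * ch[:2, :2].astype(float),
                              benzene.energies[1], 1e9, [[0.0]], [[0.0]],
                              cfg.dt, n_steps, C0,
                              field_index=np.zeros(n_traj, dtype=np.intp),
                              coeff_stride=200, jump_events=plans, channels=ch)
        C = res["coeffs"]
        t = res["times"]
        coh = np.abs((np.conj(C[:, :, 0]) * C[:, :, 1]).mean(axis=0))
        target = 0.5 * np.exp(-t / T2)
        sel = t > 0
        # Monte-Carlo tolerance ~ 1/sqrt(N)
        assert np.abs(coh[sel] / target[sel] - 1).max() < 6.0 / np.sqrt(n_traj)
        pops = (np.abs(C) ** 2).mean(axis=0)
        assert np.abs(pops - 0.5).max() < 1e-4


class TestDensityAndPolarization:
    def test_single_trajectory_density_is_pure(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=20.0)
        tr = propagate_tdse(benzene, _free_seq(benzene, 3e-4), cfg,
                            np.array([1, 0], complex))
        rho = average_density([tr]).rho
        # purity up to the leapfrog norm oscillation (~1e-5 here)
        np.testing.assert_allclose(np.einsum("tab,tbc->tac", rho, rho), rho,
                                   atol=1e-4)

    def test_two_orthogonal_states_mix(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=20.0)
        seq = _free_seq(benzene)
        t1 = propagate_tdse(benzene, seq, cfg, np.array([1, 0], complex))
        t2 = propagate_tdse(benzene, seq, cfg, np.array([0, 1], complex))
        rho = average_density([t1, t2]).rho
        np.testing.assert_allclose(np.trace(rho, axis1=1, axis2=2), 1.0,
                                   atol=1e-4)
        ev = np.linalg.eigvalsh(rho[-1])
        np.testing.assert_allclose(ev, [0.5, 0.5], atol=1e-4)

    def test_mismatched_grids_rejected(self, benzene):
        seq = _free_seq(benzene)
        t1 = propagate_tdse(benzene, seq,
                            PropagationConfig.from_lab(t_final_fs=20.0),
                            np.array([1, 0], complex))
        t2 = propagate_tdse(benzene, seq,
                            PropagationConfig.from_lab(t_final_fs=10.0),
                            np.array([1, 0], complex))
        with pytest.raises(ValueError):
            average_density([t1, t2])

    def test_ground_state_polarization_vanishes(self, benzene):
        cfg = PropagationConfig.from_lab(t_final_fs=20.0)
        tr = propagate_tdse(benzene, _free_seq(benzene), cfg,
                            np.array([1, 0], complex))
        np.testing.assert_allclose(polarization(tr, benzene), 0.0, atol=1e-14)

    def test_superposition_polarization_closed_form(self, benzene):
        # P_z(t) = mu * cos(E1 t) for the equal superposition, field-free
        # (up to the scheme's O(dt^2) phase dispersion)
        dt = fs_to_au(0.002)
        cfg = PropagationConfig(dt=dt, t_final=fs_to_au(8.0), store_stride=10)
        tr = propagate_tdse(benzene, _free_seq(benzene), cfg,
                            np.array([1, 1], complex) / np.sqrt(2))
        P = polarization(tr, benzene)
        m = benzene.dipoles[0, 1, 2]
        np.testing.assert_allclose(P[:, 2],
                                   m * np.cos(benzene.energies[1] * tr.times),
                                   atol=5e-3)
        np.testing.assert_allclose(P[:, :2], 0.0, atol=1e-14)
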