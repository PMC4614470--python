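import numpy as np
import pytest

from cortadapt.mechanics import LoadWaveform
from cortadapt.poroelastic import (PoroMaterial, solve_consolidation,
                                   stimulus_for_sectors, storage_coefficient,
                                   surface_stimulus)

MAT = PoroMaterial()
C_COEF = MAT.consolidation_coefficient()


def terzaghi_series(x_m, length_m, c, t, p0, n_terms=4001):
    m = np.arange(1, n_terms, 2)
    return (4.0 * p0 / np.pi) * np.sum(
        np.sin(np.outer(x_m, m) * np.pi / length_m) / m
        * np.exp(-(m * np.pi / length_m) ** 2 * c * t), axis=1)


class TestStorage:
    def test_stiff_grain_value(self):
        mat = PoroMaterial(storage_model="stiff-grain")
        assert storage_coefficient(mat) == pytest.approx(0.05 / 2.3e9)

    def test_full_formula_matches_independent_algebra(self):
        mat = PoroMaterial()
        k_d = 17.0e9 / (3.0 * (1.0 - 2.0 * 0.41))
        expected = 0.05 / 2.3e9 + (0.14 - 0.05) * (1.0 - 0.14) / k_d
        assert storage_coefficient(mat) == pytest.approx(expected, rel=1e-12)

    def test_incompressible_fluid_limit(self):
        # alpha -> 1, K_f -> inf: only the grain term (1 - phi)/K_s remains
        mat = PoroMaterial(alpha=1.0 - 1e-9, k_f_mpa=1e15)
        k_d = 17.0e9 / (3.0 * (1.0 - 2.0 * 0.41))
        k_s = k_d / 1e-9
        assert storage_coefficient(mat) == pytest.approx(
            (1.0 - 0.05 - 1e-9) / k_s, rel=1e-3)

    def test_alpha_below_phi_falls_back_to_stiff_grain(self):
        mat = PoroMaterial(alpha=0.04)
        assert storage_coefficient(mat) == pytest.approx(0.05 / 2.3e9)


class TestConsolidation:
    def test_zero_forcing_stays_zero(self):
        t = 0.005 * np.arange(1, 101)
        sol = solve_consolidation(MAT, 200.0, np.zeros(100), t)
        assert np.all(sol.p_pa == 0.0)
        assert np.all(sol.v_um_s == 0.0)

    def test_terzaghi_relaxation_within_one_percent(self):
        length = 200.0
        l_m = length * 1e-6
        t_end = 0.1 * l_m ** 2 / C_COEF
        n = 400
        times = (t_end / n) * np.arange(1, n + 1)
        p0 = 1.0e3
        sol = solve_consolidation(MAT, length, np.zeros(n), times, n_x=200,
                                  p_init_pa=p0)
        exact = terzaghi_series(sol.x_um * 1e-6, l_m, C_COEF, t_end, p0)
        err = np.linalg.norm(sol.p_pa[:, -1] - exact) / np.linalg.norm(exact)
        assert err < 0.01

    def test_second_order_spatial_convergence(self):
        """With temporal error made negligible, halving dx cuts the
        Terzaghi error by about 4x."""
        length = 200.0
        l_m = length * 1e-6
        t_end = 0.1 * l_m ** 2 / C_COEF
        n = 6400
        times = (t_end / n) * np.arange(1, n + 1)
        errs = []
        for n_x in (50, 100):
            sol = solve_consolidation(MAT, length, np.zeros(n), times,
                                      n_x=n_x, p_init_pa=1.0e3)
            exact = terzaghi_series(sol.x_um * 1e-6, l_m, C_COEF, t_end,
                                    1.0e3)
            errs.append(np.linalg.norm(sol.p_pa[:, -1] - exact)
                        / np.linalg.norm(exact))
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.5

    def test_harmonic_steady_state_amplitude(self):
        """Steady oscillatory response matches the complex-diffusion
        closed form within 1%."""
        length = 80.0
        l_m = length * 1e-6
        freq = 10.0
        om = 2.0 * np.pi * freq
        n_per = 100
        n_cycles = 10
        dt = 1.0 / (freq * n_per)
        n = n_per * n_cycles
        times = dt * np.arange(1, n + 1)
        eps0 = 1.0e-3
        sol = solve_consolidation(MAT, length, eps0 * np.sin(om * times),
                                  times, n_x=150)
        s = storage_coefficient(MAT)
        gamma = np.sqrt(1j * om / C_COEF)
        x = sol.x_um * 1e-6
        p_hat = (-MAT.alpha * eps0 / s) * (
            1.0 - np.cosh(gamma * (x - l_m / 2)) / np.cosh(gamma * l_m / 2))
        amp_num = np.abs(sol.p_pa[:, -n_per:]).max(axis=1)
        inner = slice(1, -1)
        err = (np.linalg.norm(amp_num[inner] - np.abs(p_hat)[inner])
               / np.linalg.norm(np.abs(p_hat)[inner]))
        assert err < 0.01

    def test_velocity_peaks_adjacent_to_drained_faces(self):
        wf = LoadWaveform.trapezoid()
        sol = solve_consolidation(MAT, 200.0, -1.2e-3 * wf.normalized(),
                                  wf.times, n_x=200)
        profile = np.abs(sol.v_um_s).max(axis=1)
        assert profile.argmax() in (0, 1, 198, 199)

    def test_linearity_in_forcing(self):
        wf = LoadWaveform.trapezoid()
        s1 = solve_consolidation(MAT, 180.0, -1e-3 * wf.normalized(),
                                 wf.times, n_x=100)
        s2 = solve_consolidation(MAT, 180.0, -2e-3 * wf.normalized(),
                                 wf.times, n_x=100)
        np.testing.assert_allclose(s2.p_pa, 2.0 * s1.p_pa, rtol=1e-10,
                                   atol=1e-12)

    def test_discrete_mass_balance(self):
        """Summing the update over interior nodes must balance boundary
        fluxes plus the strain source exactly (telescoping Laplacian)."""
        wf = LoadWaveform.trapezoid()
        n_x = 120
        sol = solve_consolidation(MAT, 200.0, -1.2e-3 * wf.normalized(),
                                  wf.times, n_x=n_x)
        s = storage_coefficient(MAT)
        dx = 200.0e-6 / (n_x - 1)
        r = C_COEF * wf.dt / dx ** 2
        strain = np.concatenate([[0.0], -1.2e-3 * wf.normalized()])
        p = np.concatenate([np.zeros((n_x, 1)), sol.p_pa], axis=1)
        scale = np.abs(sol.p_pa).max()
        for k in range(len(wf.times)):
            theta = sol.theta[k]
            pn, pn1 = p[:, k], p[:, k + 1]
            lhs = np.sum(pn1[1:-1] - pn[1:-1])
            def bnd(q):
                return (q[-1] - q[-2]) - (q[1] - q[0])
            flux = r * (theta * bnd(pn1) + (1.0 - theta) * bnd(pn))
            source = -(MAT.alpha / s) * (strain[k + 1] - strain[k])
            rhs = flux + (n_x - 2) * source
            assert abs(lhs - rhs) < 1e-6 * scale

    def test_pressure_decays_after_unload(self):
        """Residual pressure at the end of the 0.5 s window is a small
        fraction of the cycle maximum and decays monotonically once the
        load is removed."""
        wf = LoadWaveform.trapezoid()
        sol = solve_consolidation(MAT, 200.0, -1.2e-3 * wf.normalized(),
                                  wf.times, n_x=200)
        env = np.abs(sol.p_pa).max(axis=0)
        assert env[-1] < 0.10 * env.max()
        tail = env[25:]  # after the 0.1 s load cycle (frames 21+)
        assert np.all(np.diff(tail) <= 1e-9 * env.max())

    def test_robin_with_permeable_membrane_approaches_drained(self):
        wf = LoadWaveform.trapezoid()
        strain = -1.2e-3 * wf.normalized()
        drained = solve_consolidation(MAT, 200.0, strain, wf.times, n_x=100)
        mat = PoroMaterial(k_membrane_m2=1e-12)  # effectively open faces
        robin = solve_consolidation(mat, 200.0, strain, wf.times, n_x=100,
                                    bc="robin")
        scale = np.abs(drained.p_pa).max()
        assert np.abs(robin.p_pa - drained.p_pa).max() < 0.02 * scale

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            solve_consolidation(MAT, 200.0, np.zeros(10),
                                0.005 * np.arange(1, 11), n_x=10)


class TestStimulus:
    def test_symmetric_problem_has_equal_face_velocities(self):
        wf = LoadWaveform.trapezoid()
        sol = solve_consolidation(MAT, 200.0, -1.2e-3 * wf.normalized(),
                                  wf.times, n_x=200)
        np.testing.assert_allclose(np.abs(sol.v_um_s[0]),
                                   np.abs(sol.v_um_s[-1]), rtol=1e-8,
                                   atol=1e-12)

    def test_stimulus_doubles_with_force(self):
        wf = LoadWaveform.trapezoid()
        psi1 = stimulus_for_sectors(MAT, np.array([200.0]),
                                    np.array([-1e-3]), wf).psi_um_s
        psi2 = stimulus_for_sectors(MAT, np.array([200.0]),
                                    np.array([-2e-3]), wf).psi_um_s
        np.testing.assert_allclose(psi2, 2.0 * psi1, rtol=1e-12)

    def test_stimulus_peaks_during_ramps_not_hold(self):
        wf = LoadWaveform.trapezoid()
        psi = stimulus_for_sectors(MAT, np.array([200.0]),
                                   np.array([-1.2e-3]), wf).psi_um_s[0]
        hold = (wf.times > 0.026) & (wf.times < 0.074)
        ramps = ~hold & (wf.times <= 0.1)
        assert psi[ramps].max() > psi[hold].max()

    def test_batched_stimulus_matches_single_sector_solve(self):
        wf = LoadWaveform.trapezoid()
        walls = np.array([150.0, 200.0, 150.0, np.nan])
        strains = np.array([-1e-3, -2e-3, 2e-3, -1e-3])
        psi = stimulus_for_sectors(MAT, walls, strains, wf, n_x=100,
                                   quantize_um=0.5).psi_um_s
        for i in range(3):
            sol = solve_consolidation(MAT, walls[i],
                                      strains[i] * wf.normalized(),
                                      wf.times, n_x=100)
            np.testing.assert_allclose(psi[i], np.abs(sol.v_um_s[0]),
                                       rtol=1e-9, atol=1e-15)
        assert np.all(psi[3] == 0.0)

    def test_surface_stimulus_stacks_face_values(self):
        wf = LoadWaveform.trapezoid()
        sols = [solve_consolidation(MAT, 200.0,
                                    a * wf.normalized(), wf.times, n_x=80)
                for a in (-1e-3, 2e-3)]
        hist = surface_stimulus(sols)
        assert hist.psi_um_s.shape == (2, 100)
        assert np.all(hist.psi_um_s >= 0.0)
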